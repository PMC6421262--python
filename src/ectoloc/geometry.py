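"""Triangulated cardiac and torso geometry.

The heart is represented as a single closed surface that carries both the
epicardium and the endocardium (the convention of the equivalent-dipole-layer
source model): an outer half-ellipsoid shell (epi), an inner shell (endo) and a
basal rim joining them. The rim is built with an intermediate, unlabeled ring of
vertices — the cut face of the myocardial wall — so that no mesh edge connects
an epi vertex directly to an endo vertex. Direct wall crossings are added as
explicit *connector* edges (one per endo vertex, to its nearest epi vertex);
these are the transmural edges of the conduction graph and are excluded from
on-surface geodesic distances.

Units: millimetres throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "TriangleMesh",
    "HeartModel",
    "TorsoModel",
    "RegionSpec",
    "generate_heart",
    "generate_torso",
    "ellipsoid_surface",
    "geodesic_distance",
    "geodesic_distances",
]

EPI, ENDO, UNLABELED = "epi", "endo", "unlabeled"


@dataclass
class TriangleMesh:
    """A triangle surface mesh with optional per-vertex epi/endo labels."""

    vertices: np.ndarray  # (V, 3) float, mm
    triangles: np.ndarray  # (F, 3) int
    vertex_labels: np.ndarray | None = None  # (V,) str in {epi, endo, unlabeled}

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (F, 3)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle vertex index out of range")
        if self.vertex_labels is None:
            self.vertex_labels = np.full(len(self.vertices), UNLABELED, dtype=object)
        else:
            self.vertex_labels = np.asarray(self.vertex_labels, dtype=object)
            if self.vertex_labels.shape != (len(self.vertices),):
                raise ValueError("vertex_labels must have one entry per vertex")
            bad = set(self.vertex_labels) - {EPI, ENDO, UNLABELED}
            if bad:
                raise ValueError(f"unknown vertex labels: {sorted(bad)}")

    # -- basic quantities ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric lumping: one third of each incident triangle's area."""
        areas = self.triangle_areas()
        out = np.zeros(self.n_vertices)
        np.add.at(out, self.triangles.ravel(), np.repeat(areas / 3.0, 3))
        return out

    def signed_volume(self) -> float:
        """Sum of signed tetrahedron volumes; positive for outward orientation."""
        v = self.vertices[self.triangles]
        return float(np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2])) / 6.0)

    def unique_edges(self) -> np.ndarray:
        """Undirected edges (E, 2) with i < j."""
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.unique_edges()) + self.n_triangles

    def is_closed(self) -> bool:
        """True iff every undirected edge is shared by exactly two triangles and
        the winding is consistent (each directed edge appears exactly once)."""
        d = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        directed = {(int(a), int(b)) for a, b in d}
        if len(directed) != len(d):  # duplicated directed edge -> inconsistent winding
            return False
        return all((b, a) in directed for a, b in directed)


@dataclass
class HeartModel:
    """Closed heart surface plus the conduction graph's edge list.

    ``edges`` contains all mesh edges and any explicitly added wall-crossing
    connector edges; ``edge_transmural`` flags the latter. Transmural flags may
    appear only on edges joining an epi- and an endo-labeled vertex.
    """

    mesh: TriangleMesh
    node_areas: np.ndarray = field(init=False)
    edge_index: np.ndarray = field(init=False)  # (E, 2) int, i < j
    edge_lengths: np.ndarray = field(init=False)  # (E,) mm
    edge_transmural: np.ndarray = field(init=False)  # (E,) bool
    connector_edges: np.ndarray | None = None  # (C, 2) int, set before __post_init__ via factory

    def __post_init__(self) -> None:
        if not self.mesh.is_closed():
            raise ValueError("HeartModel requires a closed, consistently oriented mesh")
        if self.mesh.signed_volume() <= 0:
            raise ValueError("HeartModel mesh must be outward oriented (signed volume > 0)")
        self.node_areas = self.mesh.vertex_areas()
        edges = self.mesh.unique_edges()
        if self.connector_edges is not None and len(self.connector_edges):
            conn = np.sort(np.asarray(self.connector_edges, dtype=np.int64), axis=1)
            edges = np.unique(np.concatenate([edges, conn]), axis=0)
            conn_set = {tuple(e) for e in conn}
        else:
            conn_set = set()
        self.edge_index = edges
        d = self.mesh.vertices[edges[:, 0]] - self.mesh.vertices[edges[:, 1]]
        self.edge_lengths = np.linalg.norm(d, axis=1)
        labels = self.mesh.vertex_labels
        epi_endo = np.array(
            [{labels[i], labels[j]} == {EPI, ENDO} for i, j in edges], dtype=bool
        )
        in_conn = np.array([tuple(e) in conn_set for e in edges], dtype=bool)
        self.edge_transmural = epi_endo & in_conn
        if np.any(in_conn & ~epi_endo):
            raise ValueError("connector (transmural) edges must join an epi and an endo vertex")

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_vertices

    def edge_graph(self, weights: np.ndarray | None = None, *, include_transmural: bool = True
                   ) -> csr_matrix:
        """Symmetric sparse adjacency with the given per-edge weights (default lengths)."""
        w = self.edge_lengths if weights is None else np.asarray(weights, dtype=float)
        keep = np.ones(len(self.edge_index), dtype=bool)
        if not include_transmural:
            keep = ~self.edge_transmural
        i, j = self.edge_index[keep].T
        ww = w[keep]
        n = self.n_nodes
        return csr_matrix(
            (np.concatenate([ww, ww]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        )


@dataclass
class TorsoModel:
    """Body-surface electrode layout, optionally with a closed torso surface."""

    electrode_positions: np.ndarray  # (P, 3) mm
    surface: TriangleMesh | None = None

    def __post_init__(self) -> None:
        self.electrode_positions = np.atleast_2d(
            np.asarray(self.electrode_positions, dtype=float)
        )
        if self.electrode_positions.shape[0] < 2:
            raise ValueError("need at least 2 electrodes")
        if self.electrode_positions.shape[1] != 3:
            raise ValueError("electrode positions must be (P, 3)")

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_positions)


@dataclass(frozen=True)
class RegionSpec:
    """A spherical region in which the conduction velocity is multiplied by
    ``cv_factor`` (e.g. 1/3 for a three-fold slowdown)."""

    center: tuple[float, float, float]
    radius: float  # mm
    cv_factor: float  # dimensionless, > 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("region radius must be > 0")
        if self.cv_factor <= 0:
            raise ValueError("cv_factor must be > 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.linalg.norm(p - np.asarray(self.center), axis=1) <= self.radius


# -- synthetic generation ---------------------------------------------------


def _lathe_closed(pole_a: np.ndarray, rings: list[np.ndarray], pole_b: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate a closed surface of revolution topology: pole, ring stack, pole.

    All rings must have the same vertex count M. Returns (vertices, triangles)
    with winding such that a sphere built from a north-pole-first stack ordered
    top (+z) to bottom (-z) is outward oriented.
    """
    m = len(rings[0])
    offset = 0
    ia = offset
    verts = [pole_a.reshape(1, 3)]
    offset += 1
    ring_idx = []
    for r in rings:
        if len(r) != m:
            raise ValueError("all rings must have equal vertex counts")
        ring_idx.append(np.arange(offset, offset + m))
        verts.append(r)
        offset += m
    ib = offset
    verts.append(pole_b.reshape(1, 3))
    tris = []
    r0 = ring_idx[0]
    for k in range(m):
        tris.append((ia, r0[(k + 1) % m], r0[k]))
    for a, b in zip(ring_idx[:-1], ring_idx[1:]):
        for k in range(m):
            k1 = (k + 1) % m
            tris.append((a[k], a[k1], b[k]))
            tris.append((a[k1], b[k1], b[k]))
    rl = ring_idx[-1]
    for k in range(m):
        tris.append((ib, rl[k], rl[(k + 1) % m]))
    return np.concatenate(verts), np.asarray(tris, dtype=np.int64)


def _ring(radius_x: float, radius_y: float, z: float, m: int, phase: float = 0.0) -> np.ndarray:
    phi = 2 * np.pi * np.arange(m) / m + phase
    return np.column_stack([radius_x * np.cos(phi), radius_y * np.sin(phi), np.full(m, z)])


def ellipsoid_surface(center, radii, n_theta: int = 12, n_phi: int = 16) -> TriangleMesh:
    """Closed UV-triangulated ellipsoid (poles along +-z)."""
    center = np.asarray(center, dtype=float)
    rx, ry, rz = (float(r) for r in radii)
    thetas = np.pi * np.arange(1, n_theta) / n_theta
    rings = [_ring(rx * np.sin(t), ry * np.sin(t), rz * np.cos(t), n_phi) for t in thetas]
    v, f = _lathe_closed(np.array([0.0, 0.0, rz]), rings, np.array([0.0, 0.0, -rz]))
    mesh = TriangleMesh(v + center, f)
    if mesh.signed_volume() <= 0:  # pragma: no cover - orientation fixed by construction
        mesh = TriangleMesh(mesh.vertices, mesh.triangles[:, ::-1])
    return mesh


def generate_heart(
    n_subdiv: int = 3,
    long_axis: float = 90.0,
    short_axis: float = 50.0,
    wall_thickness: float = 10.0,
    seed: int = 0,
    jitter: float = 0.1,
) -> HeartModel:
    """Synthetic ventricle-like closed surface: epi and endo half-ellipsoid
    shells joined at a basal rim, with transmural connector edges.

    Parameters
    ----------
    n_subdiv : mesh resolution; the vertex count grows roughly as 80*n_subdiv**2.
    long_axis : apex-to-base depth of the outer (epi) shell, mm.
    short_axis : equatorial radius of the outer shell, mm.
    wall_thickness : epi-to-endo wall thickness, mm.
    seed : deterministic vertex jitter, making the mesh mildly irregular.
    jitter : jitter amplitude as a fraction of the mean edge spacing.
    """
    if not (long_axis > wall_thickness > 0 and short_axis > wall_thickness):
        raise ValueError("require axes > wall_thickness > 0")
    if n_subdiv < 1:
        raise ValueError("n_subdiv must be >= 1")
    m = 8 * n_subdiv
    k = 5 * n_subdiv
    a_out, b_out = float(long_axis), float(short_axis)
    a_in, b_in = a_out - wall_thickness, b_out - wall_thickness

    # Ring stack from the epi apex (bottom of epi, z=-a_out, playing the role of
    # the "north" pole after a flip) down the outside, across the rim and back
    # up the inside to the endo apex. We build it as a lathe from the epi apex.
    thetas = 0.5 * np.pi * np.arange(1, k + 1) / k  # last ring exactly at the rim
    epi_rings = [_ring(b_out * np.sin(t), b_out * np.sin(t), -a_out * np.cos(t), m)
                 for t in thetas]
    mid_ring = [_ring(b_out - wall_thickness / 2.0, b_out - wall_thickness / 2.0, 0.0, m,
                      phase=np.pi / m)]
    endo_rings = [_ring(b_in * np.sin(t), b_in * np.sin(t), -a_in * np.cos(t), m)
                  for t in thetas[::-1]]
    rings = epi_rings + mid_ring + endo_rings
    pole_epi = np.array([0.0, 0.0, -a_out])
    pole_endo = np.array([0.0, 0.0, -a_in])
    v, f = _lathe_closed(pole_epi, rings, pole_endo)
    # The lathe yields a consistent winding; orient it outward (the enclosed
    # solid is the myocardial wall, so the signed volume must be positive).
    if TriangleMesh(v, f).signed_volume() <= 0:
        f = f[:, ::-1]

    labels = np.full(len(v), UNLABELED, dtype=object)
    n_epi = 1 + k * m
    labels[:n_epi] = EPI
    labels[n_epi + m:] = ENDO

    rng = np.random.default_rng(seed)
    spacing = 0.5 * np.pi * a_out / k
    disp = rng.uniform(-jitter * spacing, jitter * spacing, size=v.shape)
    disp[0] = disp[-1] = 0.0  # keep the poles on the axis
    v = v + disp

    mesh = TriangleMesh(v, f, labels)
    if mesh.signed_volume() <= 0:
        raise RuntimeError("degenerate jitter produced an inverted mesh")

    # Wall-crossing connector edges: each endo vertex to its nearest epi vertex.
    epi_idx = np.flatnonzero(labels == EPI)
    endo_idx = np.flatnonzero(labels == ENDO)
    tree = cKDTree(v[epi_idx])
    _, nearest = tree.query(v[endo_idx])
    connectors = np.column_stack([endo_idx, epi_idx[nearest]])
    return HeartModel(mesh=mesh, connector_edges=connectors)


def _fibonacci_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform directions on the unit sphere (golden-spiral lattice with a
    seeded azimuthal offset)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0)) + rng.uniform(0.0, 2.0 * np.pi)
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _farthest_point_sample(points: np.ndarray, n: int, rng: np.random.Generator
                           ) -> np.ndarray:
    """Greedy farthest-point subset of ``points`` (quasi-uniform coverage)."""
    if n > len(points):
        raise ValueError(f"cannot sample {n} electrodes from {len(points)} vertices")
    chosen = [int(rng.integers(len(points)))]
    d = np.linalg.norm(points - points[chosen[0]], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(chosen)


def generate_torso(
    heart: HeartModel,
    n_electrodes: int = 240,
    standoff: float = 40.0,
    seed: int = 0,
    with_surface: bool = True,
) -> TorsoModel:
    """Electrodes quasi-uniform on an ellipsoid enclosing the heart at roughly
    ``standoff`` mm; optionally also a closed torso surface on that ellipsoid."""
    if n_electrodes < 2:
        raise ValueError("need at least 2 electrodes")
    if standoff <= 0:
        raise ValueError("standoff must be > 0")
    hv = heart.mesh.vertices
    center = hv.mean(axis=0)
    half = np.abs(hv - center).max(axis=0)
    radii = half + standoff
    rng = np.random.default_rng(seed)

    surface = None
    if with_surface:
        # size the torso mesh so electrodes can sit on its vertices
        n_phi = max(16, int(np.ceil(np.sqrt(2.5 * n_electrodes))) + 2)
        n_theta = max(12, n_phi)
        surface = ellipsoid_surface(center, radii, n_theta=n_theta, n_phi=n_phi)
        electrodes = surface.vertices[
            _farthest_point_sample(surface.vertices, n_electrodes, rng)
        ]
    else:
        dirs = _fibonacci_directions(n_electrodes, rng)
        electrodes = center + dirs * radii

    tree = cKDTree(hv)
    dmin, _ = tree.query(electrodes)
    if np.any(dmin < 0.25 * standoff):
        raise ValueError("standoff too small: electrode too close to / inside the heart")
    return TorsoModel(electrode_positions=electrodes, surface=surface)


# -- geodesics ---------------------------------------------------------------


def geodesic_distances(heart: HeartModel, source: int) -> np.ndarray:
    """On-surface shortest-path distances (mm) from ``source`` to every vertex
    along mesh edges, excluding transmural connector edges. Unreachable vertices
    are reported as ``inf``."""
    n = heart.n_nodes
    if not (0 <= source < n):
        raise IndexError("source vertex out of range")
    g = heart.edge_graph(include_transmural=False)
    return dijkstra(g, directed=False, indices=source)


def geodesic_distance(heart: HeartModel, i: int, j: int) -> float:
    """Shortest on-surface path length between vertices i and j (mm).

    Symmetric, zero iff ``i == j``; ``inf`` signals an unreachable pair."""
    n = heart.n_nodes
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError("vertex index out of range")
    if i == j:
        return 0.0
    d = geodesic_distances(heart, i)[j]
    if not np.isfinite(d):
        warnings.warn(f"vertices {i} and {j} are not geodesically connected")
    return float(d)
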