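"""Equivalent-dipole-layer (EDL) forward model.

During depolarization each heart-surface element behaves as a uniform double
layer that switches on at its activation time, so the body-surface potential is
a Heaviside-weighted superposition of per-node lead fields:

    y(t) = sum_n A[:, n] * area_n * H(t - tau_n),        H(0) = 1.

The infinite-medium lead field of a uniform double layer over a triangle is its
signed solid angle at the observation point (van Oosterom & Strackee closed
form), lumped barycentrically to the triangle's vertices and scaled by 1/(4*pi).
A closed, fully activated layer therefore produces no external field — the
defining cancellation property of the EDL, used as a hard correctness check.

For a bounded homogeneous conductor the infinite-medium potentials are
corrected by a collocation boundary-element solve on the torso surface (the
singular Neumann system is deflated; potentials carry a zero-mean gauge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import HeartModel, TorsoModel, TriangleMesh
from .propagation import ActivationSequence

__all__ = [
    "TransferMatrix",
    "BSPM",
    "triangle_solid_angles",
    "total_solid_angle",
    "point_surface_distance",
    "point_inside_surface",
    "solid_angle_transfer",
    "bounded_torso_correction",
    "simulate_bspm",
    "read_bspm",
    "write_bspm",
]


@dataclass
class TransferMatrix:
    """Electrode potentials per unit dipole-layer strength per unit area at
    each heart node."""

    A: np.ndarray  # (P, N)
    medium: str  # {"infinite", "bounded-homogeneous"}
    electrode_positions: np.ndarray  # (P, 3)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.A)):
            raise ValueError("transfer matrix entries must be finite")
        if self.A.shape[0] != len(self.electrode_positions):
            raise ValueError("row count must match the electrode count")


@dataclass
class BSPM:
    """Body surface potential map: electrodes x time samples."""

    potentials: np.ndarray  # (P, T)
    dt: float  # ms

    def __post_init__(self) -> None:
        self.potentials = np.atleast_2d(np.asarray(self.potentials, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.potentials.shape[1] < 2:
            raise ValueError("a BSPM needs at least 2 time samples")

    @property
    def n_electrodes(self) -> int:
        return self.potentials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.potentials.shape[1]

    @property
    def span(self) -> float:
        """Duration covered by the sample grid, (T - 1) * dt in ms."""
        return (self.n_samples - 1) * self.dt


def triangle_solid_angles(vertices: np.ndarray, triangles: np.ndarray,
                          point: np.ndarray) -> np.ndarray:
    """Signed solid angle (sr) of each triangle at ``point``.

    Uses the closed-form two-argument arctangent expression; the sign follows
    the triangle winding, chosen so an outward-oriented closed surface subtends
    +4*pi at interior points.
    """
    r = vertices[triangles] - np.asarray(point, dtype=float)  # (F, 3, 3)
    r1, r2, r3 = r[:, 0], r[:, 1], r[:, 2]
    n1 = np.linalg.norm(r1, axis=1)
    n2 = np.linalg.norm(r2, axis=1)
    n3 = np.linalg.norm(r3, axis=1)
    num = np.einsum("ij,ij->i", r1, np.cross(r2, r3))
    den = (
        n1 * n2 * n3
        + np.einsum("ij,ij->i", r1, r2) * n3
        + np.einsum("ij,ij->i", r1, r3) * n2
        + np.einsum("ij,ij->i", r2, r3) * n1
    )
    return 2.0 * np.arctan2(num, den)


def total_solid_angle(mesh: TriangleMesh, point: np.ndarray) -> float:
    """Total signed solid angle of a surface at a point: 4*pi inside a closed
    outward-oriented surface, 0 outside."""
    return float(np.sum(triangle_solid_angles(mesh.vertices, mesh.triangles, point)))


def point_surface_distance(mesh: TriangleMesh, point: np.ndarray) -> float:
    """Exact unsigned distance from a point to the closest mesh triangle."""
    p = np.asarray(point, dtype=float)
    tri = mesh.vertices[mesh.triangles]  # (F, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]

    def seg_dist2(u, v):
        uv = v - u
        t = np.einsum("ij,ij->i", p - u, uv) / np.maximum(
            np.einsum("ij,ij->i", uv, uv), 1e-300
        )
        proj = u + np.clip(t, 0.0, 1.0)[:, None] * uv
        return np.einsum("ij,ij->i", p - proj, p - proj)

    best = np.minimum(np.minimum(seg_dist2(a, b), seg_dist2(a, c)), seg_dist2(b, c))
    # in-plane projection, kept only where it falls inside the triangle
    n = np.cross(b - a, c - a)
    nn = np.maximum(np.einsum("ij,ij->i", n, n), 1e-300)
    dist_plane = np.einsum("ij,ij->i", p - a, n) / np.sqrt(nn)
    proj = p - dist_plane[:, None] * (n / np.sqrt(nn)[:, None])
    v0, v1, v2 = c - a, b - a, proj - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d02 = np.einsum("ij,ij->i", v0, v2)
    d12 = np.einsum("ij,ij->i", v1, v2)
    denom = np.maximum(d00 * d11 - d01 * d01, 1e-300)
    u = (d11 * d02 - d01 * d12) / denom
    w = (d00 * d12 - d01 * d02) / denom
    inside = (u >= 0) & (w >= 0) & (u + w <= 1)
    best = np.where(inside, np.minimum(best, dist_plane**2), best)
    return float(np.sqrt(np.min(best)))


def point_inside_surface(mesh: TriangleMesh, point: np.ndarray) -> bool:
    """Winding-number test: total solid angle ~4*pi inside, ~0 outside."""
    return abs(total_solid_angle(mesh, point)) > 2.0 * np.pi


def _lumped_solid_angles(mesh: TriangleMesh, points: np.ndarray) -> np.ndarray:
    """(len(points), V) matrix of per-vertex solid angles: each triangle's
    angle split equally among its three vertices."""
    out = np.zeros((len(points), mesh.n_vertices))
    tri = mesh.triangles
    for p, pt in enumerate(points):
        omega = triangle_solid_angles(mesh.vertices, tri, pt) / 3.0
        np.add.at(out[p], tri.ravel(), np.repeat(omega, 3))
    return out


def solid_angle_transfer(heart: HeartModel, torso: TorsoModel | np.ndarray,
                         min_distance: float = 1e-6) -> TransferMatrix:
    """Infinite-medium EDL transfer matrix from exact per-triangle solid angles.

    Rejects electrodes lying on (or numerically touching) the heart surface,
    where the solid angle is singular.
    """
    electrodes = (
        torso.electrode_positions if isinstance(torso, TorsoModel) else np.atleast_2d(torso)
    )
    for p, e in enumerate(electrodes):
        if point_surface_distance(heart.mesh, e) < min_distance:
            raise ValueError(
                f"electrode {p} lies on the heart surface; the solid angle is "
                "singular there"
            )
    lumped = _lumped_solid_angles(heart.mesh, electrodes)
    A = lumped / (4.0 * np.pi) / heart.node_areas[None, :]
    return TransferMatrix(A=A, medium="infinite", electrode_positions=np.asarray(electrodes))


def _bem_system(torso_surface: TriangleMesh) -> np.ndarray:
    """Collocation matrix B with B[i, j] the lumped solid angle of the torso
    surface at vertex j seen from vertex i; singular self-terms are folded into
    the diagonal via the closed-surface row-sum identity (sum_j B[i, j] = 2*pi
    for a point on the surface)."""
    v, tri = torso_surface.vertices, torso_surface.triangles
    n = torso_surface.n_vertices
    B = np.zeros((n, n))
    for i in range(n):
        keep = ~np.any(tri == i, axis=1)  # triangles incident to i are singular
        omega = triangle_solid_angles(v, tri[keep], v[i]) / 3.0
        np.add.at(B[i], tri[keep].ravel(), np.repeat(omega, 3))
    np.fill_diagonal(B, 0.0)
    diag = 2.0 * np.pi - B.sum(axis=1)
    B[np.arange(n), np.arange(n)] = diag
    return B


def bounded_torso_correction(
    A_inf: TransferMatrix,
    heart: HeartModel,
    torso_surface: TriangleMesh,
    surface_tol: float = 1.0,
) -> TransferMatrix:
    """Correct an infinite-medium transfer matrix for a bounded homogeneous
    torso via a boundary-element collocation solve.

    The surface potential phi satisfies (I - B/(2*pi)) phi = 2 phi_inf; the
    singular Neumann system is deflated with a rank-one term and the result is
    gauged to zero mean. Electrodes within ``surface_tol`` mm of a torso vertex
    take that vertex's potential (a warning is issued for larger gaps when no
    interior evaluation is possible); strictly interior electrodes are
    evaluated with the representation formula
    phi(y) = phi_inf(y) + (1/4*pi) sum_j Omega_j(y) phi_j, which recovers the
    infinite-medium limit as the torso recedes.
    """
    if not torso_surface.is_closed():
        raise ValueError("torso surface must be a closed mesh")
    if torso_surface.signed_volume() <= 0:
        raise ValueError("torso surface must be outward oriented")
    tv = torso_surface.vertices
    n = len(tv)

    # infinite-medium node potentials at the torso vertices
    phi_inf_surf = solid_angle_transfer(heart, tv).A * heart.node_areas[None, :]

    B = _bem_system(torso_surface)
    M = np.eye(n) - B / (2.0 * np.pi) + np.ones((n, n)) / n  # deflated
    phi_surf = np.linalg.solve(M, 2.0 * phi_inf_surf)
    phi_surf -= phi_surf.mean(axis=0, keepdims=True)  # zero-mean gauge

    electrodes = A_inf.electrode_positions
    d2 = np.linalg.norm(electrodes[:, None, :] - tv[None, :, :], axis=2)
    nearest = np.argmin(d2, axis=1)
    gap = d2[np.arange(len(electrodes)), nearest]

    inside = np.array([point_inside_surface(torso_surface, e) for e in electrodes])

    phi_e = np.empty((len(electrodes), phi_surf.shape[1]))
    lumped = None
    for p in range(len(electrodes)):
        if gap[p] <= surface_tol or not inside[p]:
            if gap[p] > surface_tol:
                warnings.warn(
                    f"electrode {p} is {gap[p]:.1f} mm from the torso surface; "
                    "using nearest-vertex potential"
                )
            phi_e[p] = phi_surf[nearest[p]]
        else:
            if lumped is None:
                lumped = {}
            om = _lumped_solid_angles(torso_surface, electrodes[p:p + 1])[0]
            phi_inf_e = solid_angle_transfer(heart, electrodes[p:p + 1]).A[0] \
                * heart.node_areas
            phi_e[p] = phi_inf_e + (om @ phi_surf) / (4.0 * np.pi)
    A = phi_e / heart.node_areas[None, :]
    return TransferMatrix(A=A, medium="bounded-homogeneous",
                          electrode_positions=electrodes)


def simulate_bspm(
    A: TransferMatrix,
    act: ActivationSequence,
    node_areas: np.ndarray,
    dt: float = 1.0,
    span: float | None = None,
    onset: float = 0.0,
) -> BSPM:
    """Synthesize the BSPM of an activation sequence on the grid t = 0, dt, ...

    Each node switches on at ``tau + onset`` (H(0) = 1, so a node contributes
    from its own activation instant). ``span`` defaults to max(tau) + onset
    rounded up to a whole millisecond; a span that would truncate the
    depolarization is rejected.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    tau = act.tau + onset
    tmax = float(np.max(tau))
    if span is None:
        span = float(np.ceil(tmax))
    if span < tmax:
        raise ValueError(f"span {span} ms truncates the QRS (max activation {tmax:.3f} ms)")
    t = np.arange(0.0, span + 0.5 * dt, dt)
    if len(t) < 2:
        raise ValueError("span/dt yield fewer than 2 samples")
    sources = (t[None, :] >= tau[:, None]).astype(float)  # (N, T) indicator
    Y = (A.A * np.asarray(node_areas)[None, :]) @ sources
    return BSPM(potentials=Y, dt=dt)


# -- BSPM text I/O -----------------------------------------------------------


def write_bspm(bspm: BSPM, path) -> None:
    """Delimited text, rows = electrodes, with a 'dt=<ms>' header line."""
    np.savetxt(path, bspm.potentials, fmt="%.9g", header=f"dt={bspm.dt:g}")


def read_bspm(path) -> BSPM:
    first = Path(path).read_text().splitlines()[0].strip()
    if not first.startswith("#") or "dt=" not in first:
        raise ValueError(f"{path}: missing 'dt=<ms>' header line")
    dt = float(first.split("dt=")[1].split()[0])
    return BSPM(potentials=np.loadtxt(path, ndmin=2), dt=dt)
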