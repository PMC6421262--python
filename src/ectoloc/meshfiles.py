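"""Strict text readers/writers for triangle meshes and electrode layouts.

Supported mesh formats: OFF, ascii PLY, and legacy ascii VTK polydata. The
parsers are deliberately strict — non-triangular faces are rejected rather than
triangulated, and malformed input raises :class:`MeshParseError` carrying the
offending line number. File indices are converted to the package-wide 0-based
convention at this boundary.

Vertex labels are not part of these interchange formats; write/read them with
:func:`write_labels` / :func:`read_labels` sidecars when needed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .geometry import TriangleMesh

__all__ = [
    "MeshParseError",
    "read_mesh",
    "write_mesh",
    "read_electrodes",
    "write_electrodes",
    "read_labels",
    "write_labels",
    "save_transfer_cache",
    "load_transfer_cache",
]

_FORMATS = ("off", "ply", "vtk")


class MeshParseError(ValueError):
    """Malformed mesh file; ``line`` is the 1-based offending line number."""

    def __init__(self, path, line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def read_mesh(path, fmt: str | None = None) -> TriangleMesh:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    lines = path.read_text().splitlines()
    reader = {"off": _read_off, "ply": _read_ply, "vtk": _read_vtk}[fmt]
    return reader(path, lines)


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    writer = {"off": _write_off, "ply": _write_ply, "vtk": _write_vtk}[fmt]
    path.write_text(writer(mesh))


# -- OFF ---------------------------------------------------------------------


def _tokens(path, lines, i, skip_comments=("#",)):
    """Yield (line_number, token_list) for non-empty, non-comment lines from i."""
    for ln in range(i, len(lines)):
        s = lines[ln].strip()
        if not s or s.startswith(skip_comments):
            continue
        yield ln + 1, s.split()


def _read_off(path, lines) -> TriangleMesh:
    it = _tokens(path, lines, 0)
    try:
        ln, tok = next(it)
    except StopIteration:
        raise MeshParseError(path, 1, "empty OFF file") from None
    if tok[0].upper() != "OFF":
        raise MeshParseError(path, ln, "missing OFF header")
    counts = tok[1:]
    if not counts:
        try:
            ln, counts = next(it)
        except StopIteration:
            raise MeshParseError(path, ln, "missing vertex/face counts") from None
    if len(counts) < 2:
        raise MeshParseError(path, ln, "expected vertex, face (and edge) counts")
    try:
        nv, nf = int(counts[0]), int(counts[1])
    except ValueError:
        raise MeshParseError(path, ln, "non-integer counts") from None
    verts, faces = [], []
    for ln, tok in it:
        if len(verts) < nv:
            if len(tok) < 3:
                raise MeshParseError(path, ln, "vertex line needs 3 coordinates")
            try:
                verts.append([float(t) for t in tok[:3]])
            except ValueError:
                raise MeshParseError(path, ln, "non-numeric vertex coordinate") from None
        elif len(faces) < nf:
            try:
                n = int(tok[0])
                idx = [int(t) for t in tok[1:1 + n]]
            except (ValueError, IndexError):
                raise MeshParseError(path, ln, "malformed face line") from None
            if n != 3:
                raise MeshParseError(path, ln, f"non-triangular face with {n} vertices")
            faces.append(idx)
    if len(verts) != nv or len(faces) != nf:
        raise MeshParseError(path, len(lines), "truncated OFF file")
    return TriangleMesh(np.array(verts), np.array(faces, dtype=np.int64))


def _write_off(mesh: TriangleMesh) -> str:
    out = ["OFF", f"{mesh.n_vertices} {mesh.n_triangles} 0"]
    out += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
    out += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
    return "\n".join(out) + "\n"


# -- ascii PLY ---------------------------------------------------------------


def _read_ply(path, lines) -> TriangleMesh:
    if not lines or lines[0].strip() != "ply":
        raise MeshParseError(path, 1, "missing 'ply' magic")
    nv = nf = None
    elements = []  # order of (name, count)
    body_start = None
    for i, raw in enumerate(lines[1:], start=2):
        tok = raw.strip().split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise MeshParseError(path, i, "only ascii PLY is supported")
        elif tok[0] == "element":
            try:
                elements.append((tok[1], int(tok[2])))
            except (IndexError, ValueError):
                raise MeshParseError(path, i, "malformed element declaration") from None
        elif tok[0] == "end_header":
            body_start = i
            break
    if body_start is None:
        raise MeshParseError(path, len(lines), "missing end_header")
    counts = dict(elements)
    nv, nf = counts.get("vertex"), counts.get("face")
    if nv is None or nf is None:
        raise MeshParseError(path, body_start, "PLY must declare vertex and face elements")
    verts, faces = [], []
    it = _tokens(path, lines, body_start)
    for ln, tok in it:
        if len(verts) < nv:
            try:
                verts.append([float(t) for t in tok[:3]])
            except ValueError:
                raise MeshParseError(path, ln, "non-numeric vertex coordinate") from None
        elif len(faces) < nf:
            try:
                n = int(tok[0])
                idx = [int(t) for t in tok[1:1 + n]]
            except ValueError:
                raise MeshParseError(path, ln, "malformed face line") from None
            if n != 3:
                raise MeshParseError(path, ln, f"non-triangular face with {n} vertices")
            faces.append(idx)
    if len(verts) != nv or len(faces) != nf:
        raise MeshParseError(path, len(lines), "truncated PLY file")
    return TriangleMesh(np.array(verts), np.array(faces, dtype=np.int64))


def _write_ply(mesh: TriangleMesh) -> str:
    out = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {mesh.n_triangles}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    out += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
    out += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
    return "\n".join(out) + "\n"


# -- legacy VTK polydata -----------------------------------------------------


def _read_vtk(path, lines) -> TriangleMesh:
    rows = [(i + 1, l.strip().split()) for i, l in enumerate(lines) if l.strip()]
    if not rows or rows[0][1][0] != "#" or "vtk" not in (t.lower() for t in rows[0][1]):
        raise MeshParseError(path, 1, "missing '# vtk DataFile' header")
    pos = 1  # skip the title line while locating the ASCII marker
    while pos < len(rows) and rows[pos][1][0].upper() not in ("ASCII", "BINARY"):
        pos += 1
    if pos >= len(rows):
        raise MeshParseError(path, len(lines), "missing ASCII/BINARY marker")
    ln, tok = rows[pos]
    if tok[0].upper() != "ASCII":
        raise MeshParseError(path, ln, "only ascii legacy VTK is supported")
    pos += 1
    try:
        ln, tok = rows[pos]
        if tok[0].upper() != "DATASET" or tok[1].upper() != "POLYDATA":
            raise MeshParseError(path, ln, "expected DATASET POLYDATA")
        pos += 1
        ln, tok = rows[pos]
    except IndexError:
        raise MeshParseError(path, len(lines), "truncated VTK file") from None
    if tok[0].upper() != "POINTS":
        raise MeshParseError(path, ln, "expected POINTS section")
    nv = int(tok[1])
    coords = []
    pos += 1
    while len(coords) < 3 * nv and pos < len(rows):
        ln, tok = rows[pos]
        try:
            coords.extend(float(t) for t in tok)
        except ValueError:
            raise MeshParseError(path, ln, "non-numeric point coordinate") from None
        pos += 1
    if len(coords) != 3 * nv:
        raise MeshParseError(path, len(lines), "truncated POINTS section")
    if pos >= len(rows):
        raise MeshParseError(path, len(lines), "missing POLYGONS section")
    ln, tok = rows[pos]
    if tok[0].upper() != "POLYGONS":
        raise MeshParseError(path, ln, "expected POLYGONS section")
    nf = int(tok[1])
    faces = []
    pos += 1
    while len(faces) < nf and pos < len(rows):
        ln, tok = rows[pos]
        try:
            n = int(tok[0])
            idx = [int(t) for t in tok[1:1 + n]]
        except ValueError:
            raise MeshParseError(path, ln, "malformed polygon line") from None
        if n != 3:
            raise MeshParseError(path, ln, f"non-triangular face with {n} vertices")
        faces.append(idx)
        pos += 1
    if len(faces) != nf:
        raise MeshParseError(path, len(lines), "truncated POLYGONS section")
    return TriangleMesh(np.array(coords).reshape(nv, 3), np.array(faces, dtype=np.int64))


def _write_vtk(mesh: TriangleMesh) -> str:
    out = [
        "# vtk DataFile Version 3.0",
        "ectoloc surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} float",
    ]
    out += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
    out.append(f"POLYGONS {mesh.n_triangles} {4 * mesh.n_triangles}")
    out += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
    return "\n".join(out) + "\n"


# -- electrodes and labels ---------------------------------------------------


def read_electrodes(path) -> np.ndarray:
    """3-column whitespace/comma delimited electrode coordinates (mm)."""
    try:
        arr = np.loadtxt(path, ndmin=2, delimiter=None, comments="#")
    except ValueError:
        arr = np.loadtxt(path, ndmin=2, delimiter=",", comments="#")
    if arr.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns (x y z), got {arr.shape[1]}")
    return arr


def write_electrodes(positions: np.ndarray, path) -> None:
    np.savetxt(path, np.atleast_2d(positions), fmt="%.9g", header="x y z (mm)")


def read_labels(path) -> np.ndarray:
    return np.array(Path(path).read_text().split(), dtype=object)


def write_labels(labels, path) -> None:
    Path(path).write_text("\n".join(str(l) for l in labels) + "\n")


# -- transfer-matrix cache ---------------------------------------------------


def _checksum(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def save_transfer_cache(A: np.ndarray, path, *, mesh: TriangleMesh,
                        electrodes: np.ndarray, medium: str) -> None:
    """Binary .npy cache with a JSON sidecar recording geometry checksums."""
    path = Path(path)
    np.save(path, A)
    sidecar = {
        "medium": medium,
        "mesh_checksum": _checksum(mesh.vertices, mesh.triangles),
        "electrode_checksum": _checksum(np.asarray(electrodes)),
        "shape": list(A.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_transfer_cache(path, *, mesh: TriangleMesh, electrodes: np.ndarray
                        ) -> tuple[np.ndarray, str] | None:
    """Return (A, medium) if the cache exists and its checksums match, else None."""
    path = Path(path)
    side = path.with_suffix(".json")
    npy = path if path.suffix == ".npy" else path.with_suffix(".npy")
    if not (side.exists() and npy.exists()):
        return None
    meta = json.loads(side.read_text())
    if meta["mesh_checksum"] != _checksum(mesh.vertices, mesh.triangles):
        return None
    if meta["electrode_checksum"] != _checksum(np.asarray(electrodes)):
        return None
    return np.load(npy), meta["medium"]
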