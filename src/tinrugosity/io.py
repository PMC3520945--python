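"""Mesh and point-cloud file I/O.

PLY is the canonical on-disk format (ASCII and binary-little-endian both
accepted); OBJ and STL are supported for interchange.  Only pure-triangle
surfaces are accepted: a file containing a quad or larger polygon is
rejected with the offending face index, rather than being silently
triangulated.  Point clouds come in as XYZ/CSV text with columns
Easting, Northing, vertical (header optional, comma or whitespace
delimited).

File parsing itself is delegated to :mod:`trimesh`; this module adds the
strict-triangle contract and the package's mesh type on top.
"""

from __future__ import annotations

import io as _stdio
import os
from pathlib import Path

import numpy as np
import trimesh

from .errors import MeshFormatError
from .mesh import TriangleMesh, delaunay_triangulate

__all__ = ["load_mesh", "save_mesh", "load_point_cloud", "load_xyz"]

_FORMATS = {"ply", "obj", "stl"}


def _infer_format(path: Path, fmt: str) -> str:
    fmt = fmt.lower()
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r} (use ply, obj or stl)")
    return fmt


def _scan_obj_faces(path: Path) -> None:
    face_idx = 0
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "f":
                if len(parts) - 1 != 3:
                    raise MeshFormatError(
                        f"face {face_idx} has {len(parts) - 1} vertices; only triangles are supported"
                    )
                face_idx += 1


def _scan_ply_faces(path: Path) -> None:
    """Reject non-triangular faces in a PLY file, naming the face index.

    ASCII bodies are scanned row by row.  For binary bodies the header's
    face count is remembered and compared with the triangle count trimesh
    actually produced (trimesh fan-triangulates polygons, which changes
    the count).
    """
    with open(path, "rb") as fh:
        header = []
        while True:
            line = fh.readline().decode("ascii", errors="replace").strip()
            header.append(line)
            if line == "end_header":
                break
            if not line and fh.tell() > 10_000_000:
                raise MeshFormatError("PLY header not terminated")
        fmt_line = next((l for l in header if l.startswith("format")), "")
        elements: list[tuple[str, int]] = []
        for l in header:
            if l.startswith("element"):
                _, name, count = l.split()
                elements.append((name, int(count)))
        if "ascii" not in fmt_line:
            return  # binary: handled by the post-load count check
        counts = dict(elements)
        n_vert = counts.get("vertex", 0)
        body = fh.read().decode("ascii", errors="replace").splitlines()
    rows = [r for r in body if r.strip()]
    face_rows = rows[n_vert : n_vert + counts.get("face", 0)]
    for i, row in enumerate(face_rows):
        arity = int(row.split()[0])
        if arity != 3:
            raise MeshFormatError(f"face {i} has {arity} vertices; only triangles are supported")


def _ply_header_face_count(path: Path) -> int | None:
    with open(path, "rb") as fh:
        head = fh.read(65536).decode("ascii", errors="replace")
    for line in head.splitlines():
        if line.startswith("element face"):
            return int(line.split()[2])
        if line.strip() == "end_header":
            break
    return None


def load_mesh(path, format: str = "auto") -> TriangleMesh:
    """Load a triangle mesh from PLY, OBJ or STL.

    Vertex order is preserved as stored in the file (no merging or
    reordering).  STL stores a triangle soup, so vertices are duplicated
    per face on load.

    Raises
    ------
    MeshFormatError
        For unsupported formats or non-triangular faces (the error names
        the face index where detectable).
    OSError
        If the file does not exist or cannot be read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "obj":
        _scan_obj_faces(path)
    elif fmt == "ply":
        _scan_ply_faces(path)
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False, maintain_order=True)
    except Exception as exc:
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path} contains no mesh geometry")
        tm = trimesh.util.concatenate(geoms)
    if fmt == "ply":
        expected = _ply_header_face_count(path)
        if expected is not None and len(tm.faces) != expected:
            raise MeshFormatError(
                f"{path}: {expected} faces declared but {len(tm.faces)} triangles parsed; "
                "file contains non-triangular faces"
            )
    faces = np.asarray(tm.faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshFormatError(f"{path} does not contain a pure-triangle surface")
    return TriangleMesh(vertices=np.asarray(tm.vertices, dtype=np.float64), triangles=faces)


def save_mesh(mesh: TriangleMesh, path, format: str = "auto") -> None:
    """Write a mesh to PLY (ASCII), OBJ or STL.

    Round trip contract: ``load_mesh(save_mesh(m))`` reproduces vertex
    coordinates within 1e-6 m and identical connectivity (STL excepted —
    it duplicates vertices per triangle, but preserves triangle geometry).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if mesh.n_triangles < 1:
        raise ValueError("refusing to write a mesh with no triangles")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    os.makedirs(path.parent or Path("."), exist_ok=True)
    if fmt == "ply":
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
    elif fmt == "obj":
        data = trimesh.exchange.obj.export_obj(tm).encode()
    else:
        data = trimesh.exchange.stl.export_stl_ascii(tm).encode()
    with open(path, "wb") as fh:
        fh.write(data)


def load_point_cloud(path, delimiter: str | None = None) -> np.ndarray:
    """Read an XYZ/CSV point cloud as an (n, 3) array of E, N, vertical.

    The first row is skipped if it is not numeric (a header).  Comma and
    whitespace delimiters are auto-detected.
    """
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    lines = [l for l in text.splitlines() if l.strip() and not l.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"{path} contains no data rows")
    if delimiter is None:
        delimiter = "," if "," in lines[0] or (len(lines) > 1 and "," in lines[1]) else None
    start = 0
    try:
        [float(x) for x in lines[0].replace(",", " ").split()[:3]]
    except ValueError:
        start = 1
    arr = np.loadtxt(_stdio.StringIO("\n".join(lines[start:])), delimiter=delimiter)
    arr = np.atleast_2d(arr)
    if arr.shape[1] < 3:
        raise ValueError(f"{path}: expected at least 3 columns (E, N, Z), got {arr.shape[1]}")
    return np.ascontiguousarray(arr[:, :3], dtype=np.float64)


def load_xyz(path, delimiter: str | None = None) -> TriangleMesh:
    """Read a point cloud and Delaunay-triangulate it into a TIN."""
    return delaunay_triangulate(load_point_cloud(path, delimiter=delimiter))
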