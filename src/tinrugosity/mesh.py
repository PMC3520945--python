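"""Triangulated irregular network (TIN) data model and geometric primitives.

The terrain surface is a set of triangular faces connecting 3D vertices.
Coordinates follow the (Easting, Northing, up) right-handed convention in
metres: axis 0 is Easting, axis 1 is Northing, axis 2 is vertical with up
positive.  Bathymetric depth is therefore a *negative* vertical coordinate;
readers of depth-positive files must negate before constructing a mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .errors import DegenerateGeometryError

__all__ = [
    "TriangleMesh",
    "Plane",
    "triangle_area",
    "triangle_areas",
    "triangle_normal",
    "triangle_normals",
    "point_plane_distance",
    "delaunay_triangulate",
    "edge_length_stats",
]

#: vertical component below which a normal is treated as horizontal
_VERTICAL_TOL = 1e-12


@dataclass
class TriangleMesh:
    """A triangulated terrain surface.

    Parameters
    ----------
    vertices : (n_vertices, 3) float array
        Vertex coordinates as (Easting, Northing, vertical-up) in metres.
    triangles : (n_triangles, 3) int array
        Vertex-index triples; each triangle must reference three distinct,
        valid vertex indices.
    metadata : dict, optional
        Free-form annotations.  Synthetic generators attach the analytic
        height function here under ``"height_fn"`` for oracle checks.

    Zero-area (collinear) triangles are retained but contribute nothing to
    any area-based quantity; construction emits a warning listing them.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be an (m, 3) array of indices")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertex coordinates must be finite")
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise ValueError("triangle indices out of range")
            t = self.triangles
            if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
                raise ValueError("triangles must have three distinct vertex indices")
            degen = np.flatnonzero(triangle_areas(self) == 0.0)
            if degen.size:
                warnings.warn(
                    f"mesh contains {degen.size} zero-area triangle(s) at indices "
                    f"{degen[:10].tolist()}{'...' if degen.size > 10 else ''}; "
                    "they contribute 0 to all areas",
                    stacklevel=3,
                )
        # lazily built spatial index (see features._MeshIndex)
        self._index = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_corners(self) -> np.ndarray:
        """Return corner coordinates as an (n_triangles, 3, 3) array."""
        return self.vertices[self.triangles]

    def validate_for_features(self) -> None:
        """Check the minimum size contract for feature operations."""
        if self.n_vertices < 3 or self.n_triangles < 1:
            raise ValueError(
                "feature operations need >= 3 vertices and >= 1 triangle "
                f"(got {self.n_vertices} vertices, {self.n_triangles} triangles)"
            )


@dataclass
class Plane:
    """A plane ``normal . p + offset = 0`` with a unit normal.

    Used both for the vertical slicing plane of the virtual chain and for
    the PCA plane of best fit.  ``offset`` is the signed distance of the
    origin from the plane along ``-normal``, in metres.
    """

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        self.offset = float(self.offset)
        norm = np.linalg.norm(self.normal)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0.0:
                raise ValueError("plane normal must be non-zero")
            self.normal = self.normal / norm

    @classmethod
    def from_point_normal(cls, point, normal) -> "Plane":
        normal = np.asarray(normal, dtype=np.float64)
        normal = normal / np.linalg.norm(normal)
        return cls(normal=normal, offset=-float(normal @ np.asarray(point, dtype=np.float64)))


def triangle_area(corners) -> float:
    """Area of one triangle: half the magnitude of the edge cross product.

    Degenerate (collinear) triangles return 0 rather than raising.
    """
    c = np.asarray(corners, dtype=np.float64).reshape(3, 3)
    return 0.5 * float(np.linalg.norm(np.cross(c[1] - c[0], c[2] - c[0])))


def triangle_areas(mesh: TriangleMesh, triangle_indices=None) -> np.ndarray:
    """Vectorised triangle areas for all (or selected) mesh triangles."""
    tri = mesh.triangles if triangle_indices is None else mesh.triangles[triangle_indices]
    c = mesh.vertices[tri]
    cross = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def _orient_up(normals: np.ndarray) -> np.ndarray:
    """Flip unit normals so the vertical component is >= 0.

    Overhead-imaged terrain has outward normals with an upward component.
    Exactly horizontal normals are tie-broken to Northing >= 0, then
    Easting >= 0, so the convention is a total order.
    """
    n = normals.copy()
    z = n[:, 2]
    flip = z < -_VERTICAL_TOL
    horiz = np.abs(z) <= _VERTICAL_TOL
    flip |= horiz & (n[:, 1] < -_VERTICAL_TOL)
    flip |= horiz & (np.abs(n[:, 1]) <= _VERTICAL_TOL) & (n[:, 0] < 0)
    n[flip] *= -1.0
    return n


def triangle_normal(corners) -> np.ndarray:
    """Unit normal of one triangle, oriented upward (see `_orient_up`)."""
    c = np.asarray(corners, dtype=np.float64).reshape(3, 3)
    cross = np.cross(c[1] - c[0], c[2] - c[0])
    norm = np.linalg.norm(cross)
    if norm == 0.0:
        raise DegenerateGeometryError("degenerate triangle has no normal")
    return _orient_up((cross / norm)[None, :])[0]


def triangle_normals(mesh: TriangleMesh, triangle_indices=None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised oriented unit normals and areas.

    Returns
    -------
    normals : (k, 3) array
        Upward-oriented unit normals; zero rows for degenerate triangles.
    areas : (k,) array
        Triangle areas (0 for degenerate ones).
    """
    tri = mesh.triangles if triangle_indices is None else mesh.triangles[triangle_indices]
    c = mesh.vertices[tri]
    cross = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])
    norms = np.linalg.norm(cross, axis=1)
    areas = 0.5 * norms
    ok = norms > 0
    normals = np.zeros_like(cross)
    normals[ok] = cross[ok] / norms[ok, None]
    normals[ok] = _orient_up(normals[ok])
    return normals, areas


def point_plane_distance(points, plane: Plane) -> np.ndarray | float:
    """Unsigned point-to-plane distance ``|normal . v + offset|`` in metres."""
    p = np.asarray(points, dtype=np.float64)
    d = np.abs(p @ plane.normal + plane.offset)
    return float(d) if p.ndim == 1 else d


def delaunay_triangulate(points, metadata: dict | None = None) -> TriangleMesh:
    """Triangulate a 3D point cloud into a 2.5D TIN.

    The Delaunay triangulation is computed on the Easting-Northing
    projection of the points (the overhead-survey setting: one height per
    horizontal position); the vertical coordinate is carried through
    unchanged.  Vertex order is preserved from the input.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 points are given or all points are collinear in
        the E-N projection.
    """
    p = np.asarray(points, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(p) < 3:
        raise DegenerateGeometryError("need at least 3 points to triangulate")
    try:
        tri = Delaunay(p[:, :2])
    except Exception as exc:  # qhull reports degeneracy in its own type
        raise DegenerateGeometryError(f"Delaunay triangulation failed: {exc}") from exc
    if tri.simplices.size == 0:
        raise DegenerateGeometryError("points are collinear in the E-N projection")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # qhull slivers may be zero-area
        return TriangleMesh(vertices=p, triangles=tri.simplices, metadata=metadata or {})


def _unique_edges(mesh: TriangleMesh) -> np.ndarray:
    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
    edges = np.sort(edges, axis=1)
    return np.unique(edges, axis=0)


def edge_length_stats(mesh: TriangleMesh) -> dict:
    """Mean, median and max length over the mesh's unique triangle edges.

    The median edge length is the resolution proxy used to default the
    chain selection threshold.
    """
    edges = _unique_edges(mesh)
    lengths = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    return {
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
        "max": float(lengths.max()),
        "n_edges": int(len(lengths)),
    }
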