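"""Windowed area-based rugosity, slope and aspect over a TIN.

For a rectangular window over the terrain, the surface area A_s is the
sum of the areas of the triangles falling entirely within the window, and
the projected area A_p is the sum of each triangle's area foreshortened
onto a reference plane, ``A_p = sum_i A_i |n_i . n_plane|``.  The
area-based rugosity index is R = A_s / A_p.

Projecting onto the horizontal E-N plane couples rugosity with slope
(steep but flat terrain looks rugose); projecting onto the plane of best
fit — obtained by PCA of the window's vertices, the least-variance
eigenvector being the plane normal — decouples the two.  The fitted
normal also yields slope (angle to vertical) and aspect (compass
direction the surface faces) nearly for free.

Windows with too few triangles, zero projected area, or zero slope (for
aspect) yield missing values with a reason code rather than exceptions,
so exhaustive feature maps stay total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as _dc_fields

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError
from .mesh import TriangleMesh, triangle_normals

__all__ = [
    "WindowSpec",
    "WindowSubset",
    "PCABasis",
    "FeatureRecord",
    "extract_window",
    "surface_area",
    "fit_pca_plane",
    "projected_area",
    "rugosity",
    "slope",
    "aspect",
    "window_features",
    "multiscale_features",
]

#: minimum triangles for a defined window feature; a plane fit on fewer
#: is ill-conditioned at typical mesh resolutions
MIN_TRIANGLES = 10
#: slope below which aspect is undefined (deg equivalent of the 1e-9 cos bound)
_SLOPE_ZERO_TOL = 1e-9
_UP = np.array([0.0, 0.0, 1.0])


@dataclass
class WindowSpec:
    """A rectangular query window in the E-N plane.

    ``orientation`` is the angle of the window's long (length) axis from
    East, in degrees counter-clockwise; 0 means axis-aligned with length
    along Easting.
    """

    centre: tuple
    width: float
    length: float | None = None
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.length is None:
            self.length = self.width
        if self.width <= 0 or self.length <= 0:
            raise ValueError("window width and length must be positive")
        self.centre = (float(self.centre[0]), float(self.centre[1]))

    @property
    def half_diagonal(self) -> float:
        return 0.5 * float(np.hypot(self.width, self.length))


@dataclass
class WindowSubset:
    """Triangles (and the vertices they use) falling entirely in a window."""

    triangle_indices: np.ndarray
    vertex_indices: np.ndarray

    @property
    def n_triangles(self) -> int:
        return len(self.triangle_indices)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_indices)


@dataclass
class PCABasis:
    """Ordered orthonormal basis from PCA of window vertices.

    ``components`` rows are e1, e2, e3 by descending explained variance;
    e3 spans the least-variance direction.  ``normal`` is e3 oriented so
    its vertical component is >= 0 (outward normals of overhead-imaged
    terrain face upward); an exactly vertical best-fit plane is oriented
    to Northing >= 0 with a warning.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    centroid: np.ndarray
    normal: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = self.components[2].copy()
        if abs(n[2]) <= 1e-12:
            if n[1] < 0 or (n[1] == 0 and n[0] < 0):
                n = -n
            warnings.warn(
                "best-fit plane is vertical; normal oriented to Northing >= 0",
                stacklevel=3,
            )
        elif n[2] < 0:
            n = -n
        self.normal = n


@dataclass
class FeatureRecord:
    """Per-window terrain features.

    Undefined quantities are NaN and ``reason`` says why (``ok``,
    ``too_few_triangles``, ``zero_projected_area``, ``degenerate_plane``,
    ``zero_slope_aspect``).
    """

    centre_e: float
    centre_n: float
    window_size: float
    n_triangles: int = 0
    n_vertices: int = 0
    area_surface: float = np.nan
    area_proj_pca: float = np.nan
    area_proj_ne: float = np.nan
    rugosity_pca: float = np.nan
    rugosity_ne: float = np.nan
    slope_deg: float = np.nan
    aspect_deg: float = np.nan
    northness: float = np.nan
    eastness: float = np.nan
    reason: str = "ok"

    @classmethod
    def column_names(cls) -> list[str]:
        return [f.name for f in _dc_fields(cls)]


class _MeshIndex:
    """Spatial index over triangle centroids for windowed queries.

    A window query returns the triangles whose centroid lies within the
    window's bounding circle inflated by the largest centroid-to-corner
    distance in the mesh; the exact all-three-corners-inside test is then
    run on that candidate set only.  Results are identical to an
    exhaustive scan, without touching every triangle per query.
    """

    def __init__(self, mesh: TriangleMesh):
        corners = mesh.triangle_corners()[:, :, :2]
        self.centroids = corners.mean(axis=1)
        self.max_reach = float(
            np.max(np.linalg.norm(corners - self.centroids[:, None, :], axis=2))
        )
        self.tree = cKDTree(self.centroids)

    def candidates(self, spec: WindowSpec) -> np.ndarray:
        r = spec.half_diagonal + self.max_reach + 1e-12
        idx = self.tree.query_ball_point(np.asarray(spec.centre), r)
        return np.asarray(idx, dtype=np.int64)


def _get_index(mesh: TriangleMesh) -> _MeshIndex:
    if getattr(mesh, "_index", None) is None:
        mesh._index = _MeshIndex(mesh)
    return mesh._index


def _rotate_en(points_en: np.ndarray, centre, angle_deg: float) -> np.ndarray:
    """Rotate E-N coordinates about ``centre`` by ``angle_deg`` CCW."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    rel = points_en - np.asarray(centre)
    return rel @ np.array([[c, s], [-s, c]])


def extract_window(
    mesh: TriangleMesh, spec: WindowSpec, exhaustive: bool = False
) -> WindowSubset:
    """Triangles lying entirely inside a (possibly rotated) window.

    Membership is evaluated in the E-N projection after rotating
    coordinates by -orientation about the window centre.  The rectangle
    is closed: a triangle with a corner exactly on the boundary is IN.
    A vertex belongs to the subset only through membership of such a
    triangle.  ``exhaustive=True`` bypasses the spatial index (used to
    verify that indexed queries match the full scan).
    """
    if exhaustive:
        cand = np.arange(mesh.n_triangles, dtype=np.int64)
    else:
        cand = _get_index(mesh).candidates(spec)
    if cand.size == 0:
        return WindowSubset(cand, np.array([], dtype=np.int64))
    corners = mesh.vertices[mesh.triangles[cand]][:, :, :2]
    local = _rotate_en(corners.reshape(-1, 2), spec.centre, -spec.orientation)
    local = local.reshape(-1, 3, 2)
    half_l, half_w = 0.5 * spec.length, 0.5 * spec.width
    inside = (np.abs(local[:, :, 0]) <= half_l) & (np.abs(local[:, :, 1]) <= half_w)
    member = np.sort(cand[inside.all(axis=1)])
    verts = np.unique(mesh.triangles[member]) if member.size else np.array([], dtype=np.int64)
    return WindowSubset(triangle_indices=member, vertex_indices=verts)


def surface_area(subset: WindowSubset, mesh: TriangleMesh) -> float:
    """Contoured surface area A_s: sum of member-triangle areas (m^2)."""
    if subset.n_triangles == 0:
        return 0.0
    _, areas = triangle_normals(mesh, subset.triangle_indices)
    return float(areas.sum())


def fit_pca_plane(points, weights=None) -> PCABasis:
    """Plane of best fit by PCA of a point set.

    Eigen-decomposition of the (optionally weighted) covariance of the
    centred points, eigenvectors ordered by descending eigenvalue.  The
    least-variance eigenvector e3, oriented upward, is the plane normal.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points or a point set of rank < 2 after centring
        (collinear points define no unique plane).
    """
    p = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if len(p) < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points")
    if weights is not None:
        w = np.asarray(weights, dtype=np.float64)
        wsum = w.sum()
        if wsum <= 0:
            raise DegenerateGeometryError("plane fit weights sum to zero")
        centroid = (w[:, None] * p).sum(axis=0) / wsum
        centred = p - centroid
        cov = (centred * w[:, None]).T @ centred / wsum
    else:
        centroid = p.mean(axis=0)
        centred = p - centroid
        cov = centred.T @ centred / len(p)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    components = evecs[:, order].T
    scale = max(evals[0], 1e-300)
    if evals[1] / scale < 1e-12:
        raise DegenerateGeometryError("points are collinear; plane of best fit undefined")
    return PCABasis(components=components, eigenvalues=evals, centroid=centroid)


def projected_area(subset: WindowSubset, mesh: TriangleMesh, plane_normal) -> float:
    """Orthogonal projection of the window surface onto a plane (m^2).

    ``A_p = sum_i A_i |n_i . n_plane|``: each triangle's area scaled by
    the cosine between its face normal and the plane normal.  The dot
    product is taken in absolute value so back-facing (overhang)
    triangles add rather than cancel; overlapping projections then
    double-count, which inflates rugosity for overhangs (overhead-imaged
    meshes rarely contain them).  Always A_p <= A_s.
    """
    n_plane = np.asarray(plane_normal, dtype=np.float64)
    n_plane = n_plane / np.linalg.norm(n_plane)
    if subset.n_triangles == 0:
        return 0.0
    normals, areas = triangle_normals(mesh, subset.triangle_indices)
    return float(np.sum(areas * np.abs(normals @ n_plane)))


def slope(basis: PCABasis) -> float:
    """Slope angle alpha = arccos(n . k) in degrees, in [0, 90].

    The angle between the plane of best fit and the horizontal plane,
    i.e. between the upward-oriented fitted normal and vertical.
    """
    return float(np.degrees(np.arccos(np.clip(basis.normal @ _UP, -1.0, 1.0))))


def aspect(basis: PCABasis) -> tuple[float, float, float]:
    """Aspect psi and its (northness, eastness) components.

    psi = atan2(n_E, n_N) in degrees: the compass direction the fitted
    surface faces, 0 = North, +90 = East, range (-180, 180].
    northness = cos(psi), eastness = sin(psi) remove the angular
    wrap-around for analysis.  At zero slope the normal points straight
    up and the direction is undefined: all three are returned as NaN.
    """
    n = basis.normal
    if 1.0 - n[2] <= _SLOPE_ZERO_TOL:
        return (np.nan, np.nan, np.nan)
    psi = np.degrees(np.arctan2(n[0], n[1]))
    if psi <= -180.0:
        psi += 360.0
    rad = np.radians(psi)
    return (float(psi), float(np.cos(rad)), float(np.sin(rad)))


def rugosity(
    subset: WindowSubset,
    mesh: TriangleMesh,
    projection: str = "pca",
    min_triangles: int = MIN_TRIANGLES,
    pca_weighting: str = "vertex",
) -> dict:
    """Area-based rugosity R = A_s / A_p for one window subset.

    ``projection="pca"`` projects onto the plane of best fit of the
    subset's vertices; ``"horizontal"`` onto the E-N plane.  Undefined
    windows (fewer than ``min_triangles`` triangles, degenerate plane
    fit, or zero projected area) return NaN with a reason code instead of
    raising.

    Returns a dict with keys ``rugosity``, ``area_surface``,
    ``area_projected``, ``normal``, ``reason``.
    """
    if projection not in ("pca", "horizontal"):
        raise ValueError(f"unknown projection {projection!r}")
    out = {"rugosity": np.nan, "area_surface": np.nan, "area_projected": np.nan,
           "normal": None, "reason": "ok"}
    if subset.n_triangles < min_triangles:
        out["reason"] = "too_few_triangles"
        return out
    a_s = surface_area(subset, mesh)
    out["area_surface"] = a_s
    if projection == "pca":
        try:
            basis = _fit_window_plane(subset, mesh, pca_weighting)
        except DegenerateGeometryError:
            out["reason"] = "degenerate_plane"
            return out
        normal = basis.normal
    else:
        normal = _UP
    a_p = projected_area(subset, mesh, normal)
    out["area_projected"] = a_p
    out["normal"] = normal
    if a_p <= 0.0:
        out["reason"] = "zero_projected_area"
        return out
    out["rugosity"] = a_s / a_p
    return out


def _fit_window_plane(subset: WindowSubset, mesh: TriangleMesh, pca_weighting: str) -> PCABasis:
    if pca_weighting == "vertex":
        return fit_pca_plane(mesh.vertices[subset.vertex_indices])
    if pca_weighting == "area":
        normals, areas = triangle_normals(mesh, subset.triangle_indices)
        centroids = mesh.vertices[mesh.triangles[subset.triangle_indices]].mean(axis=1)
        return fit_pca_plane(centroids, weights=areas)
    raise ValueError(f"unknown pca_weighting {pca_weighting!r}")


def window_features(
    mesh: TriangleMesh,
    spec: WindowSpec,
    min_triangles: int = MIN_TRIANGLES,
    pca_weighting: str = "vertex",
    exhaustive: bool = False,
) -> FeatureRecord:
    """All terrain features for one window: the single-window pipeline.

    Composes extract_window -> fit_pca_plane -> rugosity (both
    projections) -> slope -> aspect into one FeatureRecord.
    """
    subset = extract_window(mesh, spec, exhaustive=exhaustive)
    rec = FeatureRecord(
        centre_e=spec.centre[0],
        centre_n=spec.centre[1],
        window_size=max(spec.width, spec.length),
        n_triangles=subset.n_triangles,
        n_vertices=subset.n_vertices,
    )
    if subset.n_triangles < min_triangles:
        rec.reason = "too_few_triangles"
        return rec
    rec.area_surface = surface_area(subset, mesh)
    try:
        basis = _fit_window_plane(subset, mesh, pca_weighting)
    except DegenerateGeometryError:
        rec.reason = "degenerate_plane"
        return rec
    rec.area_proj_pca = projected_area(subset, mesh, basis.normal)
    rec.area_proj_ne = projected_area(subset, mesh, _UP)
    rec.slope_deg = slope(basis)
    rec.aspect_deg, rec.northness, rec.eastness = aspect(basis)
    bad = []
    if rec.area_proj_pca > 0:
        rec.rugosity_pca = rec.area_surface / rec.area_proj_pca
    else:
        bad.append("zero_projected_area")
    if rec.area_proj_ne > 0:
        rec.rugosity_ne = rec.area_surface / rec.area_proj_ne
    if np.isnan(rec.aspect_deg):
        bad.append("zero_slope_aspect")
    if bad:
        rec.reason = ",".join(bad)
    return rec


def _grid_centres(mesh: TriangleMesh, stride: float, margin: float) -> np.ndarray:
    lo = mesh.vertices[:, :2].min(axis=0) + margin
    hi = mesh.vertices[:, :2].max(axis=0) - margin
    if np.any(hi < lo):
        return np.empty((0, 2))
    es = np.arange(lo[0], hi[0] + 1e-9, stride)
    ns = np.arange(lo[1], hi[1] + 1e-9, stride)
    ee, nn = np.meshgrid(es, ns, indexing="ij")
    return np.column_stack([ee.ravel(), nn.ravel()])


def multiscale_features(
    mesh: TriangleMesh,
    window_sizes,
    centres: str = "every_vertex",
    stride: float | None = None,
    orientation: float = 0.0,
    min_triangles: int = MIN_TRIANGLES,
    pca_weighting: str = "vertex",
) -> list[pd.DataFrame]:
    """Feature fields at several window sizes (the multi-scale engine).

    ``centres`` is ``"every_vertex"`` (a window over every mesh vertex,
    the exhaustive map) or ``"grid"`` with ``stride`` metres between
    centres; grid centres are placed so every window fits inside the
    mesh's E-N bounding box.  One DataFrame per window size, one row per
    centre, with every FeatureRecord field; undefined features are NaN
    with a reason code, never fabricated numbers.
    """
    sizes = [float(s) for s in np.atleast_1d(window_sizes)]
    if any(s <= 0 for s in sizes):
        raise ValueError("window sizes must be positive")
    mesh.validate_for_features()
    out = []
    for size in sizes:
        if centres == "every_vertex":
            pts = mesh.vertices[:, :2]
        elif centres == "grid":
            if stride is None or stride <= 0:
                raise ValueError("grid centres need a positive stride")
            pts = _grid_centres(mesh, stride, margin=size / 2.0)
        else:
            raise ValueError(f"unknown centres mode {centres!r}")
        records = [
            window_features(
                mesh,
                WindowSpec(centre=(e, n), width=size, length=size, orientation=orientation),
                min_triangles=min_triangles,
                pca_weighting=pca_weighting,
            )
            for e, n in pts
        ]
        df = pd.DataFrame([r.__dict__ for r in records], columns=FeatureRecord.column_names())
        out.append(df)
    return out
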