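"""Placement-sensitivity and correlation machinery.

Two experiments characterise the terrain measures:

* **Chain translation.**  A transect's endpoints are rigidly displaced
  by small radii at evenly spaced compass angles (keeping the chain's
  orientation and tape length constant, like the coupling rod of a train
  wheel).  With radii {5, 10, 20, 40} cm and 12 angles this gives
  1 + 4 x 12 = 49 placements per transect.  Comparing the spread
  (max - min) of chain rugosity against the spread of window rugosity
  over the same placements quantifies how robust each measure is to
  small placement changes.

* **Correlation structure.**  Per-window slope, PCA-plane rugosity and
  horizontal-plane rugosity are correlated (Pearson) across window
  centres.  On terrain whose roughness is uniform but whose slope
  varies, horizontal-projection rugosity tracks slope strongly while
  PCA-plane rugosity does not — the decoupling that motivates fitting a
  plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .chain import chain_rugosity, chain_transect
from .errors import TinRugosityError
from .features import WindowSpec, window_features
from .mesh import TriangleMesh
from .synthetic import TerrainSpec, generate

__all__ = [
    "PlacementSet",
    "SensitivitySummary",
    "CorrelationReport",
    "translate_placements",
    "placement_sensitivity",
    "correlation_report",
    "peak_trough_correlation_experiment",
    "DEFAULT_RADII",
]

#: translation radii of the placement scheme (m): 5, 10, 20, 40 cm
DEFAULT_RADII = (0.05, 0.10, 0.20, 0.40)
#: angles per circle of the placement scheme
DEFAULT_N_ANGLES = 12


@dataclass
class PlacementSet:
    """The original endpoint pair plus its translated copies.

    Every pair preserves the original's E-N separation vector, so all
    placements share one orientation and tape length.  Ordering is
    deterministic: original first, then radius-major, angle-minor.
    """

    pairs: list
    radii: tuple
    n_angles: int

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SensitivitySummary:
    """Min / mean / max of a metric over a placement set."""

    metric: str
    values: np.ndarray
    original: float
    n_undefined: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def min(self) -> float:
        return float(np.min(self.values))

    @property
    def max(self) -> float:
        return float(np.max(self.values))

    @property
    def spread(self) -> float:
        """max - min: the placement sensitivity of the metric."""
        return self.max - self.min


@dataclass
class CorrelationReport:
    """Pearson correlation matrix over per-centre feature fields."""

    matrix: pd.DataFrame
    n: int
    n_dropped: int
    fits: dict = field(default_factory=dict)

    def corr(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])


def translate_placements(
    v_s,
    v_e,
    radii=DEFAULT_RADII,
    n_angles: int = DEFAULT_N_ANGLES,
) -> PlacementSet:
    """Build the placement set for the translation experiment.

    Both endpoints are displaced by the same horizontal offset
    ``r * (cos(theta_k), sin(theta_k))`` with theta_k = k * 360/n_angles
    starting at 0 = East, counter-clockwise.  The count is always
    ``1 + len(radii) * n_angles`` (49 for the default 4 radii x 12
    angles).
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    radii = tuple(float(r) for r in np.atleast_1d(radii))
    if any(r < 0 for r in radii):
        raise ValueError("radii must be non-negative")
    v_s = np.asarray(v_s, dtype=np.float64).reshape(3)
    v_e = np.asarray(v_e, dtype=np.float64).reshape(3)
    pairs = [(v_s.copy(), v_e.copy())]
    angles = np.arange(n_angles) * (2 * np.pi / n_angles)
    for r in radii:
        for theta in angles:
            offset = np.array([r * np.cos(theta), r * np.sin(theta), 0.0])
            pairs.append((v_s + offset, v_e + offset))
    return PlacementSet(pairs=pairs, radii=radii, n_angles=n_angles)


def _surface_point(mesh: TriangleMesh, point: np.ndarray, tree: cKDTree) -> np.ndarray:
    """Re-look-up the vertical at a translated E-N location (nearest vertex)."""
    _, idx = tree.query(point[:2])
    return np.array([point[0], point[1], mesh.vertices[idx, 2]])


def placement_sensitivity(
    mesh: TriangleMesh,
    placements: PlacementSet,
    metric: str = "chain",
    gamma: float | None = None,
    width: float = 1.0,
    projection: str = "pca",
) -> SensitivitySummary:
    """Run a rugosity metric over every placement and summarise.

    ``metric="chain"`` runs the full virtual-chain pipeline per
    placement; endpoint verticals are re-sampled from the mesh surface at
    each translated E-N location (a displaced chain lies on the terrain).
    ``metric="window"`` evaluates an oriented rectangular window of the
    given ``width``, with length and orientation equal to the placement's
    separation, through the area-based pipeline.

    Placements that yield undefined values are dropped from the summary
    and counted in ``n_undefined``.
    """
    tree = cKDTree(mesh.vertices[:, :2])
    values = []
    n_undef = 0
    for v_s, v_e in placements.pairs:
        vs = _surface_point(mesh, v_s, tree)
        ve = _surface_point(mesh, v_e, tree)
        try:
            if metric == "chain":
                values.append(chain_rugosity(chain_transect(mesh, vs, ve, gamma=gamma)))
            elif metric == "window":
                sep = ve[:2] - vs[:2]
                length = float(np.linalg.norm(sep))
                orient = float(np.degrees(np.arctan2(sep[1], sep[0])))
                spec = WindowSpec(
                    centre=tuple((vs[:2] + ve[:2]) / 2.0),
                    width=width,
                    length=length,
                    orientation=orient,
                )
                rec = window_features(mesh, spec)
                r = rec.rugosity_pca if projection == "pca" else rec.rugosity_ne
                if np.isnan(r):
                    n_undef += 1
                else:
                    values.append(r)
            else:
                raise ValueError(f"unknown metric {metric!r}")
        except TinRugosityError:
            n_undef += 1
    if not values:
        raise TinRugosityError("all placements yielded undefined values")
    return SensitivitySummary(
        metric=metric,
        values=np.array(values),
        original=values[0] if n_undef == 0 else np.nan,
        n_undefined=n_undef,
    )


def least_squares_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: returns (r, slope, intercept)."""
    res = stats.linregress(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return (float(res.rvalue), float(res.slope), float(res.intercept))


def correlation_report(fields: pd.DataFrame | dict, fit_pairs=()) -> CorrelationReport:
    """Pearson correlation matrix over per-centre feature columns.

    Rows with any missing value are dropped (complete-case) and the drop
    count reported.  A zero-variance column yields NaN entries rather
    than raising.  ``fit_pairs`` requests (r, slope, intercept) OLS fits
    for specific column pairs.
    """
    df = pd.DataFrame(fields).astype(float)
    if df.shape[1] < 2:
        raise ValueError("need at least two fields to correlate")
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    if len(complete) < 3:
        raise ValueError("need at least 3 complete records")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = complete.corr(method="pearson")
    sd = complete.std(ddof=0)
    for col in complete.columns[sd == 0]:
        corr.loc[col, :] = np.nan
        corr.loc[:, col] = np.nan
        corr.loc[col, col] = np.nan
    fits = {
        (a, b): least_squares_fit(complete[a], complete[b]) for a, b in fit_pairs
    }
    return CorrelationReport(matrix=corr, n=len(complete), n_dropped=n_dropped, fits=fits)


def peak_trough_correlation_experiment(
    resolution: float = 0.005,
    extent: float = 6.0,
    window: float = 1.0,
    stride: float = 0.25,
    amplitude: float = 1.0,
    width: float = 1.0,
) -> tuple[pd.DataFrame, CorrelationReport]:
    """Slope/rugosity correlation structure on the peak-and-trough surface.

    Generates the exponential peak-and-trough terrain, computes slope,
    PCA-plane rugosity and horizontal-plane rugosity in square windows on
    a stride grid of centres, and returns the per-centre table plus the
    Pearson correlation report over the three fields.

    Defaults follow the reference configuration: 5 mm mesh resolution,
    1 m x 1 m windows; centres are subsampled on a stride grid to keep
    the experiment desk-scale.
    """
    from .features import multiscale_features

    mesh = generate(TerrainSpec(
        "peak_trough", (extent, extent), resolution,
        {"amplitude": amplitude, "width": width},
    ))
    df = multiscale_features(
        mesh, [window], centres="grid", stride=stride
    )[0]
    fields = df[["slope_deg", "rugosity_pca", "rugosity_ne"]].rename(
        columns={"slope_deg": "slope", "rugosity_pca": "R_pca", "rugosity_ne": "R_ne"}
    )
    return df, correlation_report(fields)
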