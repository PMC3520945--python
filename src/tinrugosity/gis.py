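"""Feature-field export: CSV and ESRI ASCII grids for GIS interoperability."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["write_feature_csv", "write_ascii_grid", "write_ascii_grids"]

NODATA = -9999.0

#: FeatureRecord columns that make sense as rasters
_GRID_FEATURES = (
    "rugosity_pca",
    "rugosity_ne",
    "slope_deg",
    "aspect_deg",
    "northness",
    "eastness",
)


def write_feature_csv(df: pd.DataFrame, path) -> None:
    """One row per window centre with all feature fields."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")


def write_ascii_grid(df: pd.DataFrame, feature: str, path, cellsize: float) -> None:
    """Grid one feature column by nearest centre into an ESRI ASCII raster.

    Cells take the value of the nearest window centre within one cell
    diagonal; cells farther from any centre, or centres with missing
    values, become NODATA (-9999).
    """
    if feature not in df.columns:
        raise KeyError(f"unknown feature column {feature!r}")
    e, n = df["centre_e"].to_numpy(), df["centre_n"].to_numpy()
    vals = df[feature].to_numpy(dtype=float)
    e0, e1 = e.min(), e.max()
    n0, n1 = n.min(), n.max()
    ncols = max(int(round((e1 - e0) / cellsize)) + 1, 1)
    nrows = max(int(round((n1 - n0) / cellsize)) + 1, 1)
    ee = e0 + (np.arange(ncols) + 0.5) * cellsize - cellsize / 2
    nn = n0 + (np.arange(nrows) + 0.5) * cellsize - cellsize / 2
    ge, gn = np.meshgrid(ee, nn)
    tree = cKDTree(np.column_stack([e, n]))
    dist, idx = tree.query(np.column_stack([ge.ravel(), gn.ravel()]))
    grid = vals[idx]
    grid[dist > cellsize * np.sqrt(2)] = NODATA
    grid[~np.isfinite(grid)] = NODATA
    grid = grid.reshape(nrows, ncols)[::-1]  # row 1 = northern edge
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {e0 - cellsize / 2:.9g}\nyllcorner {n0 - cellsize / 2:.9g}\n"
        f"cellsize {cellsize:.9g}\nNODATA_value {NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt="%.6g")


def write_ascii_grids(df: pd.DataFrame, out_dir, window_size: float,
                      cellsize: float, features=_GRID_FEATURES) -> list[Path]:
    """One .asc file per feature for one window size."""
    out_dir = Path(out_dir)
    written = []
    for feature in features:
        path = out_dir / f"{feature}_w{window_size:g}m.asc"
        write_ascii_grid(df, feature, path, cellsize)
        written.append(path)
    return written
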