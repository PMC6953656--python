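"""Site-level environmental parameter tables.

Joins the per-site centroid geography with values extracted from the
continuous raster stack (with the progressive-coarsening nodata
fallback) and labels from the categorical class grids.  Sites where any
layer remains missing after the fallback are excluded and reported,
never silently filled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import RasterGrid, classify_points, extract_at_points

__all__ = ["build_env_table"]


def build_env_table(
    sites: pd.DataFrame,
    env_stack: dict[str, RasterGrid],
    class_grids: dict[str, RasterGrid] | None = None,
    max_fallback_factor: int = 8,
    percent_columns: tuple[str, ...] = (),
):
    """Assemble one row of environmental parameters per site.

    Parameters
    ----------
    sites
        Frame with columns ``site``, ``lat``, ``lon`` (centroids).
    env_stack
        Named continuous rasters; column order follows insertion order.
    class_grids
        Named categorical rasters (e.g. clime, ecoregion); labels are
        looked up without fallback.
    percent_columns
        Columns contractually bounded to [0, 100] (vegetation-cover
        fractions); violations raise.

    Returns ``(env_table, report)``; the report lists excluded sites and
    the fallback factors used per layer.
    """
    if sites.empty:
        raise ValueError("empty site list")
    class_grids = class_grids or {}
    lats = sites["lat"].to_numpy(dtype=float)
    lons = sites["lon"].to_numpy(dtype=float)
    out = sites[["site", "lat", "lon"]].reset_index(drop=True).copy()
    missing = np.zeros(len(out), dtype=bool)
    provenance: dict[str, np.ndarray] = {}
    for name, grid in env_stack.items():
        res = extract_at_points(grid, lons, lats, max_fallback_factor=max_fallback_factor)
        out[name] = res.values
        provenance[name] = res.factor
        missing |= res.missing
    for name, grid in class_grids.items():
        res = classify_points(grid, lons, lats)
        out[name] = res.values.astype(int)
        missing |= res.missing
    for col in percent_columns:
        vals = out.loc[~missing, col]
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError(f"column {col!r} outside [0, 100]")
    excluded = out.loc[missing, "site"].tolist()
    out = out[~missing].reset_index(drop=True)
    report = {
        "n_sites": len(out),
        "n_excluded": len(excluded),
        "excluded_sites": excluded,
        "fallback_factors": {k: v[~missing] for k, v in provenance.items()},
    }
    return out, report
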