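"""Predictor covariates: raster extraction, canopy cover, standardization.

Altitude is read off the DEM cell containing each site; canopy cover is
derived from a canopy-height model by binary reclassification (vegetation
taller than a height threshold) followed by a circular-neighbourhood density;
covariates entering cokriging are standardized to zero mean and unit (sample)
standard deviation, with the metadata kept so values can be mapped back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .io import Raster

__all__ = [
    "extract_raster_at_points",
    "canopy_cover_from_chm",
    "standardize",
    "unstandardize",
    "Standardization",
]

#: plot area (m²) used as the canopy-cover denominator for a 20 m radius;
#: kept as the conventional printed constant rather than π·20² = 1256.64
CANOPY_PLOT_AREA_20M = 1256.4


def extract_raster_at_points(raster: Raster, sites) -> np.ndarray:
    """Value of the raster cell containing each site (nearest-cell rule).

    Sites outside the raster extent raise an error naming the offenders;
    nodata cells yield NaN with a warning.
    """
    import warnings

    import pandas as pd

    if isinstance(sites, pd.DataFrame):
        x = sites["x"].to_numpy(dtype=float)
        y = sites["y"].to_numpy(dtype=float)
        ids = sites["site_id"].to_numpy() if "site_id" in sites else np.arange(len(x))
    else:
        xy = np.asarray(sites, dtype=float)
        x, y = xy[:, 0], xy[:, 1]
        ids = np.arange(len(x))
    row, col = raster.cell_index(x, y)
    outside = (row < 0) | (row >= raster.nrows) | (col < 0) | (col >= raster.ncols)
    if outside.any():
        raise ValueError(
            f"sites outside raster extent: {list(np.asarray(ids)[outside][:10])}"
        )
    vals = raster.values[row, col].astype(float)
    nodata = np.isclose(vals, raster.nodata)
    if nodata.any():
        warnings.warn(f"{int(nodata.sum())} sites fall on nodata cells")
        vals[nodata] = np.nan
    return vals


def canopy_cover_from_chm(
    chm: Raster,
    height_threshold: float = 2.0,
    radius: float = 20.0,
    plot_area: float | None = None,
) -> Raster:
    """Canopy cover (%) from a canopy-height model.

    Cells with vegetation height above ``height_threshold`` (exactly at the
    threshold counts as open — the documented tie rule) become 1, others 0;
    the binary raster is summed over a true circular neighbourhood of
    ``radius`` metres (cells whose centre lies within the radius) and divided
    by the reference plot area, as cover percent clipped to [0, 100].
    """
    if radius <= chm.cell_size:
        raise ValueError("neighbourhood radius must exceed the cell size")
    if plot_area is None:
        if radius == 20.0:
            plot_area = CANOPY_PLOT_AREA_20M
        else:
            plot_area = np.pi * radius**2
    binary = (chm.values > height_threshold).astype(float)
    ncell = int(np.floor(radius / chm.cell_size))
    offs = np.arange(-ncell, ncell + 1) * chm.cell_size
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    mask = (dx**2 + dy**2) <= radius**2
    counts = convolve(binary, mask.astype(float), mode="constant", cval=0.0)
    cover = np.clip(100.0 * counts * chm.cell_size**2 / plot_area, 0.0, 100.0)
    return chm.copy_with(cover)


@dataclass(frozen=True)
class Standardization:
    mean: float
    sd: float


def standardize(values) -> tuple[np.ndarray, Standardization]:
    """(v − mean)/sd with the sample (n−1) standard deviation."""
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        raise ZeroDivisionError("constant covariate cannot be standardized")
    return (v - mean) / sd, Standardization(mean, sd)


def unstandardize(z, meta: Standardization) -> np.ndarray:
    return np.asarray(z, dtype=float) * meta.sd + meta.mean
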