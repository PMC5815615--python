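"""Isoscape rasters: kriged prediction surfaces with 95% confidence bounds."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Raster, write_raster
from .kriging import predict_grid

__all__ = ["Isoscape", "build_isoscape", "summarize_isoscape", "grid_from_polygon"]

#: Gaussian multiplier for a two-sided 95% interval
Z95 = 1.96


@dataclass
class Isoscape:
    """Prediction, kriging-variance and CI rasters for one variable/method."""

    prediction: Raster
    variance: Raster
    ci_low: Raster
    ci_high: Raster
    method: str = ""
    variable: str = ""

    def write(self, directory, stem: str | None = None):
        """Write the four rasters as ESRI ASCII grids; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = stem or f"{self.variable or 'var'}_{self.method or 'kriged'}"
        paths = {}
        for name, r in [
            ("prediction", self.prediction),
            ("variance", self.variance),
            ("ci_low", self.ci_low),
            ("ci_high", self.ci_high),
        ]:
            paths[name] = write_raster(r, directory / f"{stem}_{name}.asc")
        return paths


def grid_from_polygon(polygon, resolution: float = 250.0,
                      nodata: float = -9999.0) -> Raster:
    """Raster mask over a polygon: cells whose centre is inside get 1."""
    from shapely.geometry import Point
    from shapely.prepared import prep

    minx, miny, maxx, maxy = polygon.bounds
    ncols = int(np.ceil((maxx - minx) / resolution))
    nrows = int(np.ceil((maxy - miny) / resolution))
    mask = Raster(minx, miny, resolution,
                  np.full((nrows, ncols), nodata), nodata)
    xs, ys = mask.cell_centers()
    prepared = prep(polygon)
    for r in range(nrows):
        for c in range(ncols):
            if prepared.contains(Point(xs[c], ys[r])):
                mask.values[r, c] = 1.0
    return mask


def build_isoscape(
    sites,
    values,
    model_or_lmc,
    method: str,
    mask: Raster,
    values_covariate=None,
    covariate_raster=None,
    variable: str = "",
) -> Isoscape:
    """Krige over the mask and attach 95% CI surfaces.

    CI = prediction ± 1.96·sqrt(kriging variance), cell-wise; nodata masks of
    the four rasters are identical.  Warns when sites fall outside the mask
    footprint.
    """
    import warnings

    import pandas as pd

    xy = sites[["x", "y"]].to_numpy(dtype=float) if isinstance(
        sites, pd.DataFrame) else np.asarray(sites, dtype=float)
    xmin, ymin, xmax, ymax = mask.bounds
    if ((xy[:, 0] < xmin) | (xy[:, 0] > xmax) |
            (xy[:, 1] < ymin) | (xy[:, 1] > ymax)).any():
        warnings.warn("some sites fall outside the prediction mask extent")
    pred, var = predict_grid(
        sites, values, model_or_lmc, method, mask,
        values_covariate=values_covariate, covariate_raster=covariate_raster,
    )
    valid = pred.mask_valid()
    half = np.zeros_like(pred.values)
    half[valid] = Z95 * np.sqrt(var.values[valid])
    lo = np.where(valid, pred.values - half, mask.nodata)
    hi = np.where(valid, pred.values + half, mask.nodata)
    return Isoscape(
        prediction=pred, variance=var,
        ci_low=pred.copy_with(lo), ci_high=pred.copy_with(hi),
        method=method, variable=variable,
    )


def summarize_isoscape(iso: Isoscape) -> dict:
    """Nodata-aware extrema and quantiles of prediction and CI width.

    Reports both the full CI width (high − low) and the half-width, since
    "the 95% confidence interval" is quoted either way in applied work.
    """
    valid = iso.prediction.mask_valid()
    if not valid.any():
        raise ValueError("isoscape has no valid cells to summarize")
    p = iso.prediction.values[valid]
    width = iso.ci_high.values[valid] - iso.ci_low.values[valid]
    q = lambda v: {f"q{int(100 * t)}": float(np.quantile(v, t))
                   for t in (0.05, 0.5, 0.95)}
    return {
        "n_cells": int(valid.sum()),
        "prediction_min": float(p.min()),
        "prediction_max": float(p.max()),
        "ci_width_min": float(width.min()),
        "ci_width_max": float(width.max()),
        "ci_half_width_min": float(width.min() / 2),
        "ci_half_width_max": float(width.max() / 2),
        "prediction_quantiles": q(p),
        "ci_width_quantiles": q(width),
    }
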