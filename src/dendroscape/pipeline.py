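"""End-to-end pipeline: exploration → variography → kriging → LOOCV → isoscapes.

For each isotope series the pipeline computes descriptive statistics and the
normality gate, screens covariates by Pearson correlation, picks the
cokriging covariate by regression AIC, tests spatial autocorrelation
(Moran's I), fits variogram models for every requested family (raw for
ordinary kriging, trend residuals for universal kriging, a linear model of
coregionalization for cokriging), cross-validates the four kriging methods
leave-one-out, ranks them by MSDR-closest-to-1, and grids the selected
method's isoscape with 95% confidence surfaces.  Everything is deterministic
under the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariates import standardize
from .exploratory import aic_table, describe, morans_i, pearson_screen
from .io import ISOTOPE_COLUMNS, write_site_table
from .isoscape import build_isoscape, grid_from_polygon, summarize_isoscape
from .kriging import METHODS
from .validation import CVReport, loocv, rank_models
from .variogram import (
    FAMILIES,
    empirical_variogram,
    cross_variogram,
    fit_all_families,
    fit_trend,
    fit_lmc,
    select_model,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "demo"]

log = logging.getLogger("dendroscape")

AIC_CANDIDATES = (
    "mean_summer_temperature",
    "altitude",
    "summer_radiation",
    "canopy_cover",
)


@dataclass
class PipelineConfig:
    isotope_cols: tuple = ISOTOPE_COLUMNS
    covariate_cols: tuple = AIC_CANDIDATES
    lag_width: float = 2500.0
    max_dist: float | None = None
    families: tuple = FAMILIES
    methods: tuple = METHODS
    grid_resolution: float = 1000.0
    build_isoscapes: bool = True
    cokriging_covariate: str | None = None  # None → lowest-AIC candidate
    covariate_at_targets: bool = True
    seed: int = 0
    output_dir: str | None = None

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("output_dir", None)  # identifies the analysis, not its location
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    describe: pd.DataFrame
    pearson: pd.DataFrame
    aic: pd.DataFrame
    moran: pd.DataFrame
    variogram_fits: dict
    cv_reports: dict  # (series, method) -> CVReport
    rankings: dict  # series -> ranking frame
    selected_covariate: dict
    selected_method: dict
    cv_table: pd.DataFrame  # Table-2 layout: "rmse–msdr" per method column
    isoscapes: dict = field(default_factory=dict)
    isoscape_summaries: dict = field(default_factory=dict)


def _provenance(config: PipelineConfig) -> list[str]:
    return [
        f"dendroscape {__version__}",
        f"config_hash: {config.config_hash()}",
        f"seed: {config.seed}",
    ]


def _series_models(sites, z, config):
    """Fitted variogram models per kriging method for one series."""
    fits = {}
    emp_raw = empirical_variogram(sites, z, lag_width=config.lag_width,
                                  max_dist=config.max_dist)
    fits["KriO"] = select_model(fit_all_families(emp_raw, config.families))
    for method, order in (("KriL", 1), ("KriQ", 2)):
        _, resid = fit_trend(sites, z, order=order)
        emp = empirical_variogram(sites, resid, lag_width=config.lag_width,
                                  max_dist=config.max_dist)
        fits[method] = select_model(fit_all_families(emp, config.families))
    return fits, emp_raw


def run_pipeline(sites: pd.DataFrame, config: PipelineConfig | None = None,
                 polygon=None) -> PipelineResult:
    """Run the full analysis on a site table; optionally write artifacts.

    ``sites`` needs x, y, the isotope columns and the candidate covariates.
    ``polygon`` (shapely) bounds the isoscape grid; defaults to the convex
    hull of the sites.  When ``config.output_dir`` is set, every table, fit
    and raster is written there with a provenance header.
    """
    from shapely.geometry import MultiPoint

    config = config or PipelineConfig()
    iso_cols = [c for c in config.isotope_cols if c in sites.columns]
    if not iso_cols:
        raise ValueError("no isotope columns found in the site table")
    cov_cols = [c for c in config.covariate_cols if c in sites.columns]
    xy = sites[["x", "y"]].to_numpy(dtype=float)

    # --- exploratory stage ---------------------------------------------
    desc = pd.DataFrame(
        {c: describe(sites[c].dropna().to_numpy()) for c in iso_cols + cov_cols}
    ).T.rename_axis("variable").reset_index()
    screen = pearson_screen(sites, iso_cols, cov_cols + ["x", "y"])
    aic = aic_table(sites, iso_cols, cov_cols) if cov_cols else pd.DataFrame()
    moran_rows = []
    for c in iso_cols:
        m = morans_i(sites, sites[c].to_numpy(float), seed=config.seed)
        moran_rows.append({"isotope": c, "moran_i": m.i, "expected": m.expected,
                           "p_perm": m.p_perm})
    moran = pd.DataFrame(moran_rows)

    selected_covariate = {}
    for c in iso_cols:
        if config.cokriging_covariate:
            selected_covariate[c] = config.cokriging_covariate
        elif not aic.empty:
            sub = aic[aic.isotope == c]
            selected_covariate[c] = sub.loc[sub.aic.idxmin(), "covariate"]
        else:
            selected_covariate[c] = None
        log.info("series %s: cokriging covariate = %s", c, selected_covariate[c])

    # --- variography + cross-validation --------------------------------
    variogram_fits: dict = {}
    cv_reports: dict = {}
    rankings: dict = {}
    selected_method: dict = {}
    for c in iso_cols:
        ok_rows = sites[c].notna()
        sub = sites[ok_rows].reset_index(drop=True)
        if ok_rows.sum() < len(sites):
            log.info("series %s: dropping %d sites with missing values",
                     c, int((~ok_rows).sum()))
        z = sub[c].to_numpy(float)
        fits, emp_raw = _series_models(sub, z, config)
        lmc = None
        zc = None
        if "CoK" in config.methods and selected_covariate[c]:
            zc, _ = standardize(sub[selected_covariate[c]].to_numpy(float))
            direct_b = empirical_variogram(sub, zc, lag_width=config.lag_width,
                                           max_dist=config.max_dist)
            cross = cross_variogram(sub, z, zc, lag_width=config.lag_width,
                                    max_dist=config.max_dist)
            lmc = fit_lmc(emp_raw, direct_b, cross, fits["KriO"])
            fits["CoK"] = lmc
        variogram_fits[c] = fits

        reports = []
        for method in config.methods:
            if method == "CoK":
                if lmc is None:
                    continue
                rep = loocv(sub, z, lmc, "CoK", values_covariate=zc,
                            covariate_at_targets=config.covariate_at_targets)
            else:
                rep = loocv(sub, z, fits[method], method)
            cv_reports[(c, method)] = rep
            reports.append(rep)
        if not reports:  # exploratory-only run
            selected_method[c] = None
            continue
        ranking = rank_models(reports)
        rankings[c] = ranking
        selected_method[c] = ranking.loc[0, "method"]
        log.info("series %s: selected method = %s (MSDR %.3f, RMSE %.3f)",
                 c, selected_method[c], ranking.loc[0, "msdr"],
                 ranking.loc[0, "rmse"])

    cv_table = pd.DataFrame(
        {
            m: [
                f"{cv_reports[(c, m)].rmse:.2f}–{cv_reports[(c, m)].msdr:.3g}"
                if (c, m) in cv_reports else ""
                for c in iso_cols
            ]
            for m in config.methods
        },
        index=iso_cols,
    ).rename_axis("series")

    result = PipelineResult(
        config=config, describe=desc, pearson=screen, aic=aic, moran=moran,
        variogram_fits=variogram_fits, cv_reports=cv_reports, rankings=rankings,
        selected_covariate=selected_covariate, selected_method=selected_method,
        cv_table=cv_table,
    )

    # --- isoscapes for the selected method ------------------------------
    if config.build_isoscapes:
        if polygon is None:
            polygon = MultiPoint([tuple(p) for p in xy]).convex_hull
        mask = grid_from_polygon(polygon, resolution=config.grid_resolution)
        for c in iso_cols:
            method = selected_method[c]
            if method is None:
                continue
            ok_rows = sites[c].notna()
            sub = sites[ok_rows].reset_index(drop=True)
            z = sub[c].to_numpy(float)
            kwargs = {}
            model = variogram_fits[c][method]
            if method == "CoK":
                kwargs["values_covariate"], _ = standardize(
                    sub[selected_covariate[c]].to_numpy(float))
            iso = build_isoscape(sub, z, model, method, mask,
                                 variable=c, **kwargs)
            result.isoscapes[c] = iso
            result.isoscape_summaries[c] = summarize_isoscape(iso)

    if config.output_dir:
        _write_outputs(result, sites)
    return result


def _write_outputs(result: PipelineResult, sites: pd.DataFrame):
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    head = _provenance(result.config)

    def wcsv(df: pd.DataFrame, name: str, index=False):
        with open(out / name, "w") as fh:
            for line in head:
                fh.write(f"# {line}\n")
            df.to_csv(fh, index=index, float_format="%.12g")

    write_site_table(sites, out / "sites.csv", header_lines=head)
    wcsv(result.describe, "describe.csv")
    wcsv(result.pearson, "pearson.csv")
    if not result.aic.empty:
        wcsv(result.aic, "aic.csv")
    wcsv(result.moran, "moran.csv")
    wcsv(result.cv_table, "cv_table.csv", index=True)
    for c, ranking in result.rankings.items():
        wcsv(ranking, f"ranking_{c}.csv")
    for (c, m), rep in result.cv_reports.items():
        wcsv(rep.table, f"cv_{c}_{m}.csv")
    fits_json = {}
    for c, fits in result.variogram_fits.items():
        fits_json[c] = {}
        for m, model in fits.items():
            if m == "CoK":
                fits_json[c][m] = {
                    "structures": [list(s) for s in model.structures],
                    "b_nugget": model.b_nugget.tolist(),
                    "b_structs": [B.tolist() for B in model.b_structs],
                    "psd_binding": model.psd_binding,
                }
            else:
                fits_json[c][m] = {
                    k: v for k, v in model.__dict__.items() if v is not None
                }
    meta = {"provenance": head, "selected_covariate": result.selected_covariate,
            "selected_method": result.selected_method,
            "isoscape_summaries": result.isoscape_summaries}
    (out / "variogram_fits.json").write_text(json.dumps(fits_json, indent=2))
    (out / "summary.json").write_text(json.dumps(meta, indent=2, default=str))
    for c, iso in result.isoscapes.items():
        iso.write(out / "isoscapes", stem=f"{c}_{iso.method}")


def demo(output_dir=None, seed: int = 7) -> PipelineResult:
    """Small end-to-end run on a 40-site synthetic dataset (seconds)."""
    from .synth import make_trentino_like

    ds = make_trentino_like(seed=seed, n_sites=40)
    config = PipelineConfig(
        grid_resolution=5000.0,
        seed=seed,
        output_dir=str(output_dir) if output_dir else None,
    )
    return run_pipeline(ds.sites, config, polygon=ds.polygon)
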