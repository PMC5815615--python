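"""Pre-kriging exploratory statistics.

Kriging assumes approximately Gaussian, spatially autocorrelated data, so the
pipeline first screens every isotope series: descriptive statistics with a
Shapiro–Wilk normality gate, Pearson correlations against the candidate
covariates and coordinates, AIC ranking of single-covariate regressions (the
rule that picks the cokriging covariate), and a permutation test of Moran's I
for spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "describe",
    "pearson_screen",
    "render_pearson_table",
    "covariate_aic",
    "aic_table",
    "morans_i",
    "MoranResult",
]


def describe(values) -> dict:
    """Mean, sample sd, min/max, adjusted Fisher–Pearson skewness, excess
    kurtosis and the Shapiro–Wilk normality test.

    Constant input yields sd = 0 and ``normality_defined = False``.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("descriptive statistics need n >= 3")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    out = {
        "n": len(v),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)),
        "min": float(v.min()),
        "max": float(v.max()),
    }
    if out["sd"] == 0:
        out.update(skewness=0.0, kurtosis=np.nan, shapiro_w=np.nan,
                   shapiro_p=np.nan, normality_defined=False)
        return out
    out["skewness"] = float(stats.skew(v, bias=False))
    out["kurtosis"] = float(stats.kurtosis(v, bias=False))  # excess
    w, p = stats.shapiro(v)
    out.update(shapiro_w=float(w), shapiro_p=float(p), normality_defined=True)
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_screen(
    sites: pd.DataFrame,
    isotope_cols: list[str],
    covariate_cols: list[str],
) -> pd.DataFrame:
    """Pearson r (with two-sided p) between each isotope and each covariate.

    ``x`` and ``y`` may appear among the covariates as longitude/latitude
    proxies (coordinates are projected metres).  Returns a long-format frame
    with columns isotope, covariate, r, p, stars.  Zero-variance covariates
    are flagged with NaN.
    """
    rows = []
    for iso in isotope_cols:
        zi = sites[iso].to_numpy(dtype=float)
        for cov in covariate_cols:
            zc = sites[cov].to_numpy(dtype=float)
            ok = np.isfinite(zi) & np.isfinite(zc)
            if ok.sum() < 4:
                raise ValueError(f"fewer than 4 complete pairs for {iso} ~ {cov}")
            if np.std(zc[ok]) == 0 or np.std(zi[ok]) == 0:
                rows.append({"isotope": iso, "covariate": cov, "r": np.nan,
                             "p": np.nan, "stars": "", "n": int(ok.sum())})
                continue
            r, p = stats.pearsonr(zi[ok], zc[ok])
            rows.append({"isotope": iso, "covariate": cov, "r": float(r),
                         "p": float(p), "stars": _stars(p), "n": int(ok.sum())})
    return pd.DataFrame(rows)


def render_pearson_table(screen: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Wide isotope × covariate table with stars; values not significant at
    ``alpha`` are left blank in the rendering (they stay in the long table)."""
    def fmt(row):
        if not np.isfinite(row["r"]) or row["p"] >= alpha:
            return ""
        return f"{row['r']:.2f}{row['stars']}"

    out = screen.assign(cell=screen.apply(fmt, axis=1))
    return out.pivot(index="isotope", columns="covariate", values="cell")


def covariate_aic(sites: pd.DataFrame, isotope_col: str, covariate_col: str) -> float:
    """AIC of the simple linear regression isotope ~ covariate.

    Gaussian-likelihood form AIC = n·ln(RSS/n) + 2k with k = 3 (intercept,
    slope, error variance); only differences across covariates matter.  A
    numerically perfect fit is floored at machine scale and yields a very
    large negative AIC.
    """
    z = sites[isotope_col].to_numpy(dtype=float)
    c = sites[covariate_col].to_numpy(dtype=float)
    ok = np.isfinite(z) & np.isfinite(c)
    z, c = z[ok], c[ok]
    n = len(z)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    X = np.column_stack([np.ones(n), (c - c.mean()) / (c.std() or 1.0)])
    if np.linalg.matrix_rank(X) < 2:
        raise np.linalg.LinAlgError("singular regression design (constant covariate)")
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    rss = float(resid @ resid)
    rss = max(rss, n * np.finfo(float).tiny ** 0.5)
    return float(n * np.log(rss / n) + 2 * 3)


def aic_table(sites: pd.DataFrame, isotope_cols, covariate_cols) -> pd.DataFrame:
    """AIC of every isotope × covariate regression, plus the per-isotope
    winner (lowest AIC — the covariate used for cokriging)."""
    recs = []
    for iso in isotope_cols:
        for cov in covariate_cols:
            recs.append(
                {"isotope": iso, "covariate": cov,
                 "aic": covariate_aic(sites, iso, cov)}
            )
    df = pd.DataFrame(recs)
    df["selected"] = False
    for iso in isotope_cols:
        i = df.loc[df.isotope == iso, "aic"].idxmin()
        df.loc[i, "selected"] = True
    return df


@dataclass
class MoranResult:
    i: float
    expected: float
    p_perm: float
    n_perm: int


def _inverse_distance_weights(xy: np.ndarray, cutoff: float | None,
                              row_standardize: bool) -> np.ndarray:
    d = squareform(pdist(xy))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    if cutoff is not None:
        w[d > cutoff] = 0.0
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs
    return w


def morans_i(
    sites,
    values,
    weights: np.ndarray | None = None,
    cutoff: float | None = None,
    row_standardize: bool = True,
    n_perm: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with a one-sided (greater) permutation p-value.

    I = (n/S0) · Σ_ij w_ij (z_i − z̄)(z_j − z̄) / Σ_i (z_i − z̄)²; its null
    expectation is −1/(n−1).  Default weights are row-standardized inverse
    Euclidean distance with an optional cutoff; a custom weights matrix (e.g.
    rook contiguity) may be passed instead.  The p-value is the rank of the
    observed I among ``n_perm`` random relabellings of the values over the
    locations (seed-controlled).
    """
    z = np.asarray(values, dtype=float)
    n = len(z)
    if n < 5 and weights is None:
        raise ValueError("Moran's I needs at least 5 sites")
    if np.std(z) == 0:
        raise ValueError("Moran's I undefined for constant values")
    if weights is None:
        import pandas as pd

        xy = sites[["x", "y"]].to_numpy(dtype=float) if isinstance(
            sites, pd.DataFrame) else np.asarray(sites, dtype=float)
        weights = _inverse_distance_weights(xy, cutoff, row_standardize)
    w = np.asarray(weights, dtype=float)
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("all spatial weights are zero")

    def stat(v):
        dz = v - v.mean()
        return (len(v) / s0) * (dz @ w @ dz) / (dz @ dz)

    i_obs = float(stat(z))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat(rng.permutation(z)) >= i_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MoranResult(i=i_obs, expected=-1.0 / (n - 1), p_perm=float(p),
                       n_perm=n_perm)
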