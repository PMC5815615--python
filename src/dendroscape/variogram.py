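"""Empirical variography and parametric variogram models.

Semivariance is the central object of the package: γ(h) is half the expected
squared difference between values separated by lag distance h.  Empirical
variograms are binned estimates of γ; parametric models (spherical,
exponential, linear, Matérn with Stein's parameterization) are fitted to them
by weighted least squares and compared by RSS/AIC.  Cross-variograms between a
variable and a covariate are fitted jointly under a linear model of
coregionalization (LMC) with positive-semidefinite coefficient matrices, which
is what cokriging consumes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "TrendModel",
    "CoregionalizationModel",
    "model_gamma",
    "empirical_variogram",
    "cross_variogram",
    "variogram_map",
    "fit_trend",
    "fit_model",
    "select_model",
    "fit_lmc",
]

FAMILIES = ("spherical", "exponential", "linear", "matern_stein")

#: default lag width in metres (the binning step used throughout)
DEFAULT_LAG_WIDTH = 2500.0


@dataclass
class EmpiricalVariogram:
    """Binned semivariance estimates.

    ``lag_centers`` are bin midpoints in metres, ``semivariance`` the γ̂
    estimates (squared per-mil for isotope data) and ``pair_counts`` the
    number of point pairs per bin.  Bins with no pairs are dropped.
    """

    lag_centers: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray
    lag_width: float = DEFAULT_LAG_WIDTH
    direction: float | None = None
    tolerance: float | None = None
    is_cross: bool = False

    def __post_init__(self):
        self.lag_centers = np.asarray(self.lag_centers, dtype=float)
        self.semivariance = np.asarray(self.semivariance, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if not np.all(np.diff(self.lag_centers) > 0):
            raise ValueError("lag_centers must be strictly increasing")
        if not self.is_cross and np.any(self.semivariance < 0):
            raise ValueError("direct semivariance must be non-negative")


@dataclass
class VariogramModel:
    """Parametric variogram γ(h) = c0 + c·g(h/a).

    ``family`` is one of spherical / exponential / linear / matern_stein.
    ``nugget`` (c0) is the discontinuity at the origin (micro-scale plus
    measurement variance); ``partial_sill`` (c) the additional variance at the
    plateau; ``range_`` (a) the distance scale in metres.  The linear family
    has no sill: ``slope`` is the semivariance increase per metre and
    ``partial_sill``/``range_`` are unused.  ``kappa`` is the Matérn
    smoothness (matern_stein only).
    """

    family: str
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_: float = 1.0
    kappa: float | None = None
    slope: float | None = None
    rss: float | None = None
    aic: float | None = None
    converged: bool = True

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0:
            raise ValueError("nugget must be non-negative")
        if self.family == "linear":
            if self.slope is None:
                raise ValueError("linear family requires a slope")
            if self.slope < 0:
                raise ValueError("slope must be non-negative")
        else:
            if self.partial_sill < 0 or self.range_ <= 0:
                raise ValueError("partial sill must be >= 0 and range > 0")
        if self.family == "matern_stein":
            if self.kappa is None or self.kappa <= 0:
                raise ValueError("matern_stein requires kappa > 0")

    @property
    def sill(self) -> float:
        """Total sill c0 + c (infinite for the linear family)."""
        if self.family == "linear":
            return np.inf
        return self.nugget + self.partial_sill

    @property
    def n_params(self) -> int:
        return {"spherical": 3, "exponential": 3, "linear": 2, "matern_stein": 4}[
            self.family
        ]

    def __call__(self, h):
        return model_gamma(self, h)


def _gamma_structure(family: str, h: np.ndarray, a: float, kappa: float | None):
    """Unit-sill structure g(h) with g(0)=0 and g(inf)=1 (bounded families)."""
    if family == "spherical":
        u = np.minimum(h / a, 1.0)
        return 1.5 * u - 0.5 * u**3
    if family == "exponential":
        return 1.0 - np.exp(-h / a)
    if family == "matern_stein":
        # Stein's parameterization: argument h*sqrt(2*kappa)/a, so that the
        # range parameter keeps a comparable meaning across smoothness values.
        u = h * np.sqrt(2.0 * kappa) / a
        out = np.ones_like(u)
        pos = u > 0
        with np.errstate(over="ignore"):
            bes = special.kv(kappa, u[pos])
        term = (2.0 ** (1.0 - kappa) / special.gamma(kappa)) * u[pos] ** kappa * bes
        # kv underflows to 0 for large arguments: structure correctly -> 1
        term = np.where(np.isfinite(term), term, 0.0)
        out[pos] = 1.0 - term
        return np.clip(out, 0.0, None)
    raise ValueError(family)


def model_gamma(model: VariogramModel, h) -> np.ndarray | float:
    """Evaluate γ(h) for a fitted model.

    γ(0) = 0 exactly (a point is identical to itself); the nugget is the
    h → 0+ limit.  Negative lags are a domain error.
    """
    h_arr = np.asarray(h, dtype=float)
    scalar = h_arr.ndim == 0
    h_arr = np.atleast_1d(h_arr)
    if np.any(h_arr < 0):
        raise ValueError("lag distances must be non-negative")
    if model.family == "linear":
        gamma = model.nugget + model.slope * h_arr
    else:
        gamma = model.nugget + model.partial_sill * _gamma_structure(
            model.family, h_arr, model.range_, model.kappa
        )
    gamma = np.where(h_arr == 0, 0.0, gamma)
    return float(gamma[0]) if scalar else gamma


# ---------------------------------------------------------------------------
# empirical variograms
# ---------------------------------------------------------------------------


def _coords(sites) -> np.ndarray:
    import pandas as pd

    if isinstance(sites, pd.DataFrame):
        return sites[["x", "y"]].to_numpy(dtype=float)
    return np.asarray(sites, dtype=float)


def _pair_arrays(xy: np.ndarray):
    """Index pairs, distances and lag vectors for all unordered point pairs."""
    n = len(xy)
    ii, jj = np.triu_indices(n, k=1)
    d = xy[jj] - xy[ii]
    dist = np.hypot(d[:, 0], d[:, 1])
    return ii, jj, dist, d


def _bin_pairs(dist, max_dist, lag_width):
    nbins = int(np.ceil(max_dist / lag_width))
    edges = np.arange(nbins + 1) * lag_width
    idx = np.digitize(dist, edges) - 1
    keep = (idx >= 0) & (idx < nbins)
    return idx, keep, edges, nbins


def default_max_dist(xy: np.ndarray) -> float:
    """One third of the maximum inter-site distance, a common variography rule."""
    return float(pdist(xy).max()) / 3.0


def empirical_variogram(
    sites,
    values,
    lag_width: float = DEFAULT_LAG_WIDTH,
    max_dist: float | None = None,
    direction: float | None = None,
    tol: float | None = None,
) -> EmpiricalVariogram:
    """Omnidirectional or directional binned semivariogram.

    γ̂(h) = Σ_{pairs in bin} (z_i − z_j)² / (2 N(h)).  Directional mode keeps
    pairs whose bearing (degrees clockwise from north, modulo 180°) is within
    ``tol`` of ``direction``.
    """
    xy = _coords(sites)
    z = np.asarray(values, dtype=float)
    if len(xy) != len(z):
        raise ValueError("sites and values must have equal length")
    if len(xy) < 2:
        raise ValueError("need at least two sites")
    if len(xy) < 10:
        warnings.warn("fewer than 10 sites: empirical variogram will be noisy")
    ii, jj, dist, dvec = _pair_arrays(xy)
    if max_dist is None:
        max_dist = default_max_dist(xy)
    sel = np.ones(len(dist), dtype=bool)
    if direction is not None:
        if tol is None:
            tol = 22.5
        bearing = np.degrees(np.arctan2(dvec[:, 0], dvec[:, 1])) % 180.0
        delta = np.abs(bearing - direction % 180.0)
        delta = np.minimum(delta, 180.0 - delta)
        sel = delta <= tol
    idx, keep, edges, nbins = _bin_pairs(dist, max_dist, lag_width)
    keep &= sel & (dist > 0)
    sq = (z[ii[keep]] - z[jj[keep]]) ** 2
    counts = np.bincount(idx[keep], minlength=nbins)
    sums = np.bincount(idx[keep], weights=sq, minlength=nbins)
    nonempty = counts > 0
    if not nonempty.any():
        raise ValueError("no point pairs fall in any lag bin")
    centers = (edges[:-1] + edges[1:]) / 2.0
    return EmpiricalVariogram(
        lag_centers=centers[nonempty],
        semivariance=sums[nonempty] / (2.0 * counts[nonempty]),
        pair_counts=counts[nonempty],
        lag_width=lag_width,
        direction=direction,
        tolerance=tol,
    )


def cross_variogram(
    sites,
    values_a,
    values_b,
    lag_width: float = DEFAULT_LAG_WIDTH,
    max_dist: float | None = None,
) -> EmpiricalVariogram:
    """Binned cross-semivariogram of two co-located variables.

    γ̂_ab(h) = Σ (a_i − a_j)(b_i − b_j) / (2 N(h)); may be negative.
    """
    xy = _coords(sites)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if not (len(xy) == len(a) == len(b)):
        raise ValueError("both variables must be observed at the same sites")
    ii, jj, dist, _ = _pair_arrays(xy)
    if max_dist is None:
        max_dist = default_max_dist(xy)
    idx, keep, edges, nbins = _bin_pairs(dist, max_dist, lag_width)
    keep &= dist > 0
    prod = (a[ii[keep]] - a[jj[keep]]) * (b[ii[keep]] - b[jj[keep]])
    counts = np.bincount(idx[keep], minlength=nbins)
    sums = np.bincount(idx[keep], weights=prod, minlength=nbins)
    nonempty = counts > 0
    if not nonempty.any():
        raise ValueError("no point pairs fall in any lag bin")
    centers = (edges[:-1] + edges[1:]) / 2.0
    return EmpiricalVariogram(
        lag_centers=centers[nonempty],
        semivariance=sums[nonempty] / (2.0 * counts[nonempty]),
        pair_counts=counts[nonempty],
        lag_width=lag_width,
        is_cross=True,
    )


def variogram_map(sites, values, cell: float, max_dist: float | None = None):
    """Semivariance binned by lag *vector* (Δx, Δy) — the anisotropy map.

    Returns ``(grid, xedges, yedges)``; the grid is centro-symmetric by
    construction since every unordered pair contributes at +Δ and −Δ.
    Cells with no pairs hold NaN.
    """
    xy = _coords(sites)
    z = np.asarray(values, dtype=float)
    ii, jj, dist, dvec = _pair_arrays(xy)
    if max_dist is None:
        max_dist = default_max_dist(xy)
    keep = (dist > 0) & (np.abs(dvec) <= max_dist).all(axis=1)
    dvec = dvec[keep]
    sq = (z[ii[keep]] - z[jj[keep]]) ** 2
    ncell = int(np.ceil(max_dist / cell))
    edges = np.arange(-ncell, ncell + 1) * cell
    # both orientations of each pair
    dx = np.concatenate([dvec[:, 0], -dvec[:, 0]])
    dy = np.concatenate([dvec[:, 1], -dvec[:, 1]])
    w = np.concatenate([sq, sq])
    sums, _, _ = np.histogram2d(dx, dy, bins=[edges, edges], weights=w)
    counts, _, _ = np.histogram2d(dx, dy, bins=[edges, edges])
    with np.errstate(invalid="ignore"):
        grid = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    return grid, edges, edges


# ---------------------------------------------------------------------------
# polynomial trend removal
# ---------------------------------------------------------------------------

_MONOMIALS = {
    0: [(0, 0)],
    1: [(0, 0), (1, 0), (0, 1)],
    2: [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)],
}


@dataclass
class TrendModel:
    """Polynomial-in-(x, y) mean surface fitted by ordinary least squares.

    Coefficients are stored for the *centred and scaled* coordinates used
    internally (for conditioning with UTM-magnitude coordinates) together
    with the centring metadata, and exposed in raw coordinates via
    :attr:`coefficients`.
    """

    order: int
    coeffs_scaled: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    residual_variance: float = 0.0

    def design(self, xy: np.ndarray) -> np.ndarray:
        u = (xy - self.center) / self.scale
        return np.column_stack(
            [u[:, 0] ** p * u[:, 1] ** q for p, q in _MONOMIALS[self.order]]
        )

    def __call__(self, xy) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return self.design(xy) @ self.coeffs_scaled

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients on raw-coordinate monomials 1, x, y[, x², xy, y²]."""
        cx, cy = self.center
        sx, sy = self.scale
        c = self.coeffs_scaled
        out = np.zeros(len(_MONOMIALS[self.order]))
        for coef, (p, q) in zip(c, _MONOMIALS[self.order]):
            # expand ((x-cx)/sx)^p ((y-cy)/sy)^q into raw monomials
            for a in range(p + 1):
                for b in range(q + 1):
                    term = (
                        coef
                        / (sx**p * sy**q)
                        * special.comb(p, a)
                        * special.comb(q, b)
                        * (-cx) ** (p - a)
                        * (-cy) ** (q - b)
                    )
                    k = _MONOMIALS[self.order].index((a, b))
                    out[k] += term

        return out


def fit_trend(sites, values, order: int = 1):
    """OLS polynomial surface of given order; returns (TrendModel, residuals)."""
    if order not in (0, 1, 2):
        raise ValueError("trend order must be 0, 1 or 2")
    xy = _coords(sites)
    z = np.asarray(values, dtype=float)
    nterm = len(_MONOMIALS[order])
    if len(z) <= nterm:
        raise ValueError("not enough sites for the requested trend order")
    center = xy.mean(axis=0)
    scale = xy.std(axis=0)
    scale[scale == 0] = 1.0
    model = TrendModel(order=order, coeffs_scaled=np.zeros(nterm), center=center, scale=scale)
    X = model.design(xy)
    coeffs, _, rank, _ = np.linalg.lstsq(X, z, rcond=None)
    if rank < nterm:
        raise np.linalg.LinAlgError("trend design matrix is rank-deficient")
    model.coeffs_scaled = coeffs
    resid = z - X @ coeffs
    model.residual_variance = float(resid.var(ddof=min(nterm, len(z) - 1)))
    return model, resid


# ---------------------------------------------------------------------------
# model fitting and selection
# ---------------------------------------------------------------------------


def _wls_weights(emp: EmpiricalVariogram, scheme: str) -> np.ndarray:
    h = emp.lag_centers
    n = emp.pair_counts.astype(float)
    if scheme == "n_over_h2":
        return n / h**2
    if scheme == "n":
        return n
    if scheme == "cressie":
        return n  # combined with model value inside the objective
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def _variogram_aic(rss: float, m: int, k: int) -> float:
    # Gaussian-likelihood AIC on the binned estimates; floored RSS guards
    # the degenerate perfect-fit case.
    rss = max(rss, 1e-300)
    return m * np.log(rss / m) + 2 * k


def fit_model(
    emp: EmpiricalVariogram,
    family: str,
    init: dict | None = None,
    weights: str = "n_over_h2",
) -> VariogramModel:
    """Weighted-least-squares fit of one model family to a binned variogram.

    The objective is Σ_h w_h (γ̂(h) − γ(h; θ))² with w_h = N(h)/h² by default.
    Reported RSS is the unweighted residual sum of squares over bins and
    AIC = m·ln(RSS/m) + 2k with m bins and k free parameters, so that models
    of different complexity are comparable on the same bins.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    h = emp.lag_centers
    g = emp.semivariance
    m = len(h)
    if m < 4:
        raise ValueError("need at least 4 non-empty lag bins to fit a model")
    w = _wls_weights(emp, weights)

    if family == "linear":
        # weighted linear regression, closed form; slope clipped at 0
        X = np.column_stack([np.ones(m), h])
        W = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * W[:, None], g * W, rcond=None)
        c0, b = max(beta[0], 0.0), max(beta[1], 0.0)
        resid = g - (c0 + b * h)
        rss = float(resid @ resid)
        return VariogramModel(
            "linear", nugget=c0, slope=b, rss=rss,
            aic=_variogram_aic(rss, m, 2), converged=True,
        )

    nugget0 = max(float(g[0]), 0.0)
    sill0 = max(float(np.mean(g[-max(m // 3, 1):])), 1e-12)
    range0 = float(h[-1]) / 3.0

    def residuals(theta, kappa=None):
        c0, c, a = theta
        mdl = VariogramModel(family, nugget=c0, partial_sill=c, range_=a, kappa=kappa)
        gm = model_gamma(mdl, np.maximum(h, 1e-12))
        if weights == "cressie":
            wt = emp.pair_counts / np.maximum(gm, 1e-12) ** 2
        else:
            wt = w
        return np.sqrt(wt) * (g - gm)

    starts = [
        (max(nugget0, 1e-9 * sill0), max(sill0 - nugget0, 1e-9 * sill0), range0),
        (1e-9 * sill0, sill0, range0 * 2),
        (0.5 * sill0, 0.5 * sill0, range0 / 2),
    ]
    if init:
        starts.insert(
            0,
            (
                init.get("nugget", nugget0),
                init.get("partial_sill", sill0),
                init.get("range_", range0),
            ),
        )
    lb = [0.0, 0.0, 1e-6 * h[-1]]
    ub = [np.inf, np.inf, 100.0 * h[-1]]

    kappas = [None]
    if family == "matern_stein":
        if init and "kappa" in init:
            kappas = [init["kappa"]]
        else:
            kappas = list(np.exp(np.linspace(np.log(0.05), np.log(10.0), 9)))

    best = None
    for kappa in kappas:
        for x0 in starts:
            try:
                sol = optimize.least_squares(
                    residuals, x0, kwargs={"kappa": kappa}, bounds=(lb, ub),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
                )
            except Exception:
                continue
            cost = sol.cost
            if best is None or cost < best[0]:
                best = (cost, sol.x, kappa, sol.success)
    if best is None:
        raise RuntimeError(f"variogram fit failed for family {family!r}")
    _, (c0, c, a), kappa, ok = best

    if family == "matern_stein" and len(kappas) > 1:
        # refine kappa jointly around the best grid point
        def residuals4(theta):
            return residuals(theta[:3], kappa=theta[3])

        sol = optimize.least_squares(
            residuals4, [c0, c, a, kappa],
            bounds=([0, 0, lb[2], 0.05], [np.inf, np.inf, ub[2], 10.0]),
            xtol=1e-12, ftol=1e-12, max_nfev=2000,
        )
        if sol.cost <= best[0]:
            c0, c, a, kappa = sol.x
            ok = sol.success

    model = VariogramModel(
        family, nugget=float(c0), partial_sill=float(c), range_=float(a),
        kappa=None if kappa is None else float(kappa), converged=bool(ok),
    )
    resid = g - model_gamma(model, np.maximum(h, 1e-12))
    model.rss = float(resid @ resid)
    model.aic = _variogram_aic(model.rss, m, model.n_params)
    return model


def fit_all_families(emp: EmpiricalVariogram, families=FAMILIES, **kw):
    """Fit every candidate family; failed fits are dropped."""
    out = []
    for fam in families:
        try:
            out.append(fit_model(emp, fam, **kw))
        except Exception:
            continue
    return out


def select_model(candidates: list[VariogramModel]) -> VariogramModel:
    """Pick the candidate with lowest AIC; ties by RSS, then fewest parameters."""
    conv = [c for c in candidates if c.converged]
    if not conv:
        raise ValueError("no converged variogram model candidates")
    return min(conv, key=lambda c: (round(c.aic, 9), round(c.rss, 12), c.n_params))


# ---------------------------------------------------------------------------
# linear model of coregionalization
# ---------------------------------------------------------------------------


@dataclass
class CoregionalizationModel:
    """Two-variable LMC: γ_ij(h) = Σ_k B_k[i,j] g_k(h).

    ``structures`` is a list of (family, range, kappa) tuples for the
    non-nugget structures g_k (unit sill, g(0)=0 → 1); a nugget structure is
    always present as ``b_nugget``.  Each 2×2 coefficient matrix is positive
    semidefinite, which guarantees a valid joint model.
    """

    structures: list[tuple]
    b_nugget: np.ndarray
    b_structs: list[np.ndarray]
    psd_binding: bool = False

    def gamma(self, i: int, j: int, h) -> np.ndarray:
        h_arr = np.atleast_1d(np.asarray(h, dtype=float))
        out = np.where(h_arr > 0, self.b_nugget[i, j], 0.0).astype(float)
        for (fam, a, kappa), B in zip(self.structures, self.b_structs):
            out = out + B[i, j] * _gamma_structure(fam, h_arr, a, kappa)
        out = np.where(h_arr == 0, 0.0, out)
        return out

    def direct_model_sill(self, i: int) -> float:
        return float(self.b_nugget[i, i] + sum(B[i, i] for B in self.b_structs))

    def min_eigenvalue(self) -> float:
        vals = [np.linalg.eigvalsh(self.b_nugget).min()]
        vals += [np.linalg.eigvalsh(B).min() for B in self.b_structs]
        return float(min(vals))


def _psd_clip(B: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def fit_lmc(
    direct_a: EmpiricalVariogram,
    direct_b: EmpiricalVariogram,
    cross: EmpiricalVariogram,
    shared_structures: list[tuple] | VariogramModel,
    max_sweeps: int = 100,
    tol: float = 1e-8,
) -> CoregionalizationModel:
    """Fit a two-variable LMC on a triplet of variograms sharing lag bins.

    ``shared_structures`` gives the common structure functions, either as a
    list of (family, range, kappa) tuples or a fitted :class:`VariogramModel`
    whose non-nugget structure is reused.  Coefficients are fitted by WLS per
    variable pair, then projected onto the PSD cone and refitted
    (Goulard–Voltz style) until stable.
    """
    if isinstance(shared_structures, VariogramModel):
        m = shared_structures
        if m.family == "linear":
            # use a spherical proxy spanning the observed lags for the shared
            # structure; the unbounded slope cannot enter a PSD-constrained LMC
            shared_structures = [("spherical", float(direct_a.lag_centers[-1]), None)]
        else:
            shared_structures = [(m.family, m.range_, m.kappa)]
    structures = [
        (fam, a, kappa) for fam, a, kappa in (
            s if len(s) == 3 else (*s, None) for s in shared_structures
        )
    ]

    h = direct_a.lag_centers
    for other in (direct_b, cross):
        if len(other.lag_centers) != len(h) or not np.allclose(other.lag_centers, h):
            raise ValueError("LMC triplet must share identical lag bins")

    nk = len(structures)
    G = np.column_stack(
        [np.ones(len(h))] + [_gamma_structure(f, h, a, k) for f, a, k in structures]
    )  # design: nugget + structures
    emps = {(0, 0): direct_a, (1, 1): direct_b, (0, 1): cross}
    W = {key: _wls_weights(e, "n_over_h2") for key, e in emps.items()}

    def wls_pair(key, target):
        w = np.sqrt(W[key])
        beta, *_ = np.linalg.lstsq(G * w[:, None], target * w, rcond=None)
        return beta

    # initial unconstrained fits (direct fits clipped at zero)
    coefs = {}
    for key, e in emps.items():
        beta = wls_pair(key, e.semivariance)
        if key[0] == key[1]:
            beta = np.clip(beta, 0.0, None)
        coefs[key] = beta

    def assemble():
        mats = []
        for k in range(nk + 1):
            B = np.array(
                [
                    [coefs[(0, 0)][k], coefs[(0, 1)][k]],
                    [coefs[(0, 1)][k], coefs[(1, 1)][k]],
                ]
            )
            mats.append(B)
        return mats

    binding = False
    prev = None
    for _ in range(max_sweeps):
        mats = assemble()
        clipped = [_psd_clip(B) for B in mats]
        if any(not np.allclose(B, C, atol=1e-12) for B, C in zip(mats, clipped)):
            binding = True
        for k, C in enumerate(clipped):
            coefs[(0, 0)][k] = C[0, 0]
            coefs[(1, 1)][k] = C[1, 1]
            coefs[(0, 1)][k] = C[0, 1]
        # refit the cross coefficients under the Cauchy-Schwarz bound from the
        # (fixed) direct coefficients
        beta = wls_pair((0, 1), emps[(0, 1)].semivariance)
        for k in range(nk + 1):
            bound = np.sqrt(coefs[(0, 0)][k] * coefs[(1, 1)][k])
            if abs(beta[k]) > bound:
                binding = True
            coefs[(0, 1)][k] = np.clip(beta[k], -bound, bound)
        cur = np.concatenate([coefs[k] for k in sorted(coefs)])
        if prev is not None and np.max(np.abs(cur - prev)) < tol:
            break
        prev = cur

    mats = assemble()
    mats = [_psd_clip(B) for B in mats]
    model = CoregionalizationModel(
        structures=structures,
        b_nugget=mats[0],
        b_structs=mats[1:],
        psd_binding=binding,
    )
    if model.min_eigenvalue() < -1e-10:
        raise RuntimeError("LMC fit failed to produce PSD coefficient matrices")
    return model
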