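"""Exact best-linear-unbiased-prediction (kriging) solvers.

All systems are assembled in semivariance form, which keeps the unbounded
linear variogram valid under the unbiasedness constraints:

* ordinary kriging (OK): unknown constant mean, Σλ = 1;
* universal kriging (UK): polynomial drift in (x, y) of order 1 or 2, one
  constraint per monomial;
* cokriging (CoK): joint prediction from the primary variable and a
  co-located covariate under a linear model of coregionalization, with
  Σλ_primary = 1 and Σλ_covariate = 0.

Every solver returns the weights, Lagrange multipliers, the prediction and
the kriging variance.  Predictions are exact at data locations (σ² = 0 there,
the convention of most geostatistics software, even with a nonzero nugget).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist, pdist, squareform

from .variogram import CoregionalizationModel, VariogramModel, model_gamma

__all__ = ["KrigingSolution", "ok_predict", "uk_predict", "cok_predict", "predict_grid"]

METHODS = ("KriO", "KriL", "KriQ", "CoK")


@dataclass
class KrigingSolution:
    """Weights, multipliers, prediction and kriging variance of one solve."""

    weights: np.ndarray
    covariate_weights: np.ndarray | None
    multipliers: np.ndarray
    prediction: float
    variance: float

    def __post_init__(self):
        # tiny negative variances are numerical noise; anything larger is a bug
        if self.variance < -1e-8:
            raise FloatingPointError(
                f"negative kriging variance {self.variance}: invalid model"
            )
        self.variance = max(self.variance, 0.0)


def _as_xy(sites) -> np.ndarray:
    import pandas as pd

    if isinstance(sites, pd.DataFrame):
        return sites[["x", "y"]].to_numpy(dtype=float)
    xy = np.asarray(sites, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("sites must be an (n, 2) coordinate array or a site table")
    return xy


def _check_duplicates(xy: np.ndarray):
    if len(xy) > 1 and pdist(xy).min() == 0.0:
        raise ValueError(
            "duplicate site coordinates: deduplicate (see read_site_table) "
            "before kriging"
        )


def _drift_basis(xy: np.ndarray, order: int, center, scale) -> np.ndarray:
    """Monomials of centred/scaled coordinates up to ``order`` (incl. constant).

    Centring and scaling only re-parameterize the drift space (the span is
    unchanged), but keep the augmented system well-conditioned with
    UTM-magnitude coordinates.
    """
    u = (xy - center) / scale
    cols = [np.ones(len(xy))]
    if order >= 1:
        cols += [u[:, 0], u[:, 1]]
    if order >= 2:
        cols += [u[:, 0] ** 2, u[:, 0] * u[:, 1], u[:, 1] ** 2]
    return np.column_stack(cols)


def _solve_augmented(G: np.ndarray, F: np.ndarray, rhs_g: np.ndarray,
                     rhs_f: np.ndarray, jitter_scale: float):
    """Solve [[G, F], [F', 0]] [w; mu] = [rhs_g; rhs_f] with one jitter retry."""
    n, p = F.shape
    A = np.zeros((n + p, n + p))
    A[:n, :n] = G
    A[:n, n:] = F
    A[n:, :n] = F.T
    b = np.concatenate([rhs_g, rhs_f])
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        A[:n, :n] += np.eye(n) * (1e-10 * max(jitter_scale, 1.0))
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "kriging system singular even after diagonal jitter"
            ) from exc
    return sol[:n], sol[n:]


def _gamma_matrix(model: VariogramModel, xy: np.ndarray) -> np.ndarray:
    d = squareform(pdist(xy))
    G = model_gamma(model, d.ravel()).reshape(d.shape)
    np.fill_diagonal(G, 0.0)
    return G


def _jitter_scale(model: VariogramModel) -> float:
    return model.nugget + (
        model.partial_sill if model.family != "linear" else model.slope
    )


def _uk_solution(sites, values, model, target, order) -> KrigingSolution:
    xy = _as_xy(sites)
    z = np.asarray(values, dtype=float)
    _check_duplicates(xy)
    nterm = {0: 1, 1: 3, 2: 6}[order]
    if len(z) < nterm + 1:
        raise ValueError("not enough sites for the requested drift order")
    center = xy.mean(axis=0)
    scale = np.maximum(xy.std(axis=0), 1e-12)
    F = _drift_basis(xy, order, center, scale)
    if np.linalg.matrix_rank(F) < F.shape[1]:
        raise np.linalg.LinAlgError("collinear drift basis (degenerate site layout)")
    G = _gamma_matrix(model, xy)
    s0 = np.asarray(target, dtype=float).reshape(1, 2)
    g0 = model_gamma(model, cdist(xy, s0).ravel())
    f0 = _drift_basis(s0, order, center, scale).ravel()
    lam, mu = _solve_augmented(G, F, g0, f0, _jitter_scale(model))
    pred = float(lam @ z)
    var = float(lam @ g0 + mu @ f0)
    return KrigingSolution(lam, None, mu, pred, var)


def ok_predict(sites, values, model: VariogramModel, target) -> KrigingSolution:
    """Ordinary kriging at one target point (unknown constant mean)."""
    return _uk_solution(sites, values, model, target, order=0)


def uk_predict(sites, values, model: VariogramModel, target,
               trend_order: int = 1) -> KrigingSolution:
    """Universal kriging with a linear (order 1) or quadratic (order 2) drift."""
    if trend_order not in (1, 2):
        raise ValueError("trend_order must be 1 or 2")
    return _uk_solution(sites, values, model, target, order=trend_order)


def cok_predict(
    sites,
    values_primary,
    values_covariate,
    lmc: CoregionalizationModel,
    target,
    covariate_at_target: float | None = None,
) -> KrigingSolution:
    """Co-located ordinary cokriging of the primary variable.

    The covariate (typically standardized altitude) is observed at the same
    sites; if ``covariate_at_target`` is given it is used as an additional
    covariate observation at the prediction point itself (the covariate is
    usually known everywhere from the DEM).  Unbiasedness: primary weights
    sum to 1, covariate weights sum to 0.
    """
    xy = _as_xy(sites)
    z1 = np.asarray(values_primary, dtype=float)
    z2 = np.asarray(values_covariate, dtype=float)
    if not (len(xy) == len(z1) == len(z2)):
        raise ValueError("cokriging requires co-located primary and covariate")
    _check_duplicates(xy)
    if lmc.min_eigenvalue() < -1e-10:
        raise ValueError("coregionalization model is not positive semidefinite")

    s0 = np.asarray(target, dtype=float).reshape(1, 2)
    xy2 = xy
    z2_obs = z2
    at_target = covariate_at_target is not None
    if at_target and cdist(xy, s0).min() == 0.0:
        at_target = False  # covariate already observed at this location
    if at_target:
        xy2 = np.vstack([xy, s0])
        z2_obs = np.append(z2, covariate_at_target)

    n1, n2 = len(xy), len(xy2)
    d11 = squareform(pdist(xy))
    d22 = squareform(pdist(xy2))
    d12 = cdist(xy, xy2)
    G = np.zeros((n1 + n2, n1 + n2))
    G[:n1, :n1] = lmc.gamma(0, 0, d11.ravel()).reshape(n1, n1)
    G[n1:, n1:] = lmc.gamma(1, 1, d22.ravel()).reshape(n2, n2)
    G[:n1, n1:] = lmc.gamma(0, 1, d12.ravel()).reshape(n1, n2)
    G[n1:, :n1] = G[:n1, n1:].T
    np.fill_diagonal(G, 0.0)

    F = np.zeros((n1 + n2, 2))
    F[:n1, 0] = 1.0
    F[n1:, 1] = 1.0

    d10 = cdist(xy, s0).ravel()
    d20 = cdist(xy2, s0).ravel()
    rhs = np.concatenate([lmc.gamma(0, 0, d10), lmc.gamma(0, 1, d20)])
    jit = lmc.direct_model_sill(0) + lmc.direct_model_sill(1)
    w, mu = _solve_augmented(G, F, rhs, np.array([1.0, 0.0]), jit)
    lam, nu = w[:n1], w[n1:]
    pred = float(lam @ z1 + nu @ z2_obs)
    var = float(w @ rhs + mu[0])
    return KrigingSolution(lam, nu, mu, pred, var)


# ---------------------------------------------------------------------------
# gridded prediction
# ---------------------------------------------------------------------------


def predict_grid(
    sites,
    values,
    model_or_lmc,
    method: str,
    grid,
    values_covariate=None,
    covariate_raster=None,
):
    """Kriged prediction and variance rasters over the valid cells of ``grid``.

    ``grid`` is a :class:`~dendroscape.io.Raster` mask: cells equal to the
    nodata value are skipped.  For ``CoK`` the covariate must be supplied at
    the sites; if ``covariate_raster`` is given its (standardized) cell values
    are used as collocated covariate observations at each target.

    The left-hand system matrix does not depend on the target, so it is
    factorized once and reused for every cell.
    """
    import warnings

    from .io import Raster

    if method not in METHODS:
        raise ValueError(f"unknown kriging method {method!r}; expected {METHODS}")
    xy = _as_xy(sites)
    z = np.asarray(values, dtype=float)
    _check_duplicates(xy)

    valid = grid.mask_valid()
    pred = np.full(grid.values.shape, grid.nodata, dtype=float)
    var = np.full(grid.values.shape, grid.nodata, dtype=float)
    if not valid.any():
        warnings.warn("prediction mask has no valid cells; returning empty rasters")
        return grid.copy_with(pred), grid.copy_with(var)

    xs, ys = grid.cell_centers()
    rows, cols = np.nonzero(valid)
    targets = np.column_stack([xs[cols], ys[rows]])

    if method in ("KriO", "KriL", "KriQ"):
        model = model_or_lmc
        order = {"KriO": 0, "KriL": 1, "KriQ": 2}[method]
        center = xy.mean(axis=0)
        scale = np.maximum(xy.std(axis=0), 1e-12)
        F = _drift_basis(xy, order, center, scale)
        G = _gamma_matrix(model, xy)
        n, p = F.shape
        A = np.zeros((n + p, n + p))
        A[:n, :n] = G
        A[:n, n:] = F
        A[n:, :n] = F.T
        try:
            lu = lu_factor(A)
        except Exception:
            A[:n, :n] += np.eye(n) * (1e-10 * max(_jitter_scale(model), 1.0))
            lu = lu_factor(A)
        g0 = model_gamma(model, cdist(xy, targets).ravel()).reshape(n, -1)
        f0 = _drift_basis(targets, order, center, scale).T
        B = np.vstack([g0, f0])
        sol = lu_solve(lu, B)
        lam, mu = sol[:n], sol[n:]
        pred[rows, cols] = z @ lam
        var[rows, cols] = np.maximum(
            np.einsum("ij,ij->j", lam, g0) + np.einsum("ij,ij->j", mu, f0), 0.0
        )
        # exactness at cells containing a datum
        at_site = np.isclose(cdist(xy, targets), 0.0).any(axis=0)
        if at_site.any():
            hit = cdist(xy, targets[at_site]).argmin(axis=0)
            pred[rows[at_site], cols[at_site]] = z[hit]
            var[rows[at_site], cols[at_site]] = 0.0
    else:  # CoK — per-target solves (collocated covariate changes the system)
        if values_covariate is None:
            raise ValueError("CoK requires values_covariate")
        cov_at = None
        if covariate_raster is not None:
            r, c = covariate_raster.cell_index(targets[:, 0], targets[:, 1])
            cov_at = covariate_raster.values[r, c]
        for k, s0 in enumerate(targets):
            sol = cok_predict(
                xy, z, values_covariate, model_or_lmc, s0,
                covariate_at_target=None if cov_at is None else float(cov_at[k]),
            )
            pred[rows[k], cols[k]] = sol.prediction
            var[rows[k], cols[k]] = sol.variance
    return grid.copy_with(pred), grid.copy_with(var)
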