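"""Independent brute-force oracles used only by the test suite.

Deliberately written with plain loops and a different mathematical route
(covariance-form constrained BLUP, explicit pair enumeration) than the
package implementation, so agreement is evidence of correctness rather than
shared code.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_variogram(xy, z, lag_width, max_dist):
    """All-pairs binned semivariogram via explicit loops."""
    n = len(xy)
    nbins = math.ceil(max_dist / lag_width)
    sums = [0.0] * nbins
    counts = [0] * nbins
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(xy[i], xy[j])
            if d <= 0:
                continue
            # mirror np.digitize half-open bins [k*w, (k+1)*w)
            k = int(d // lag_width)
            if k >= nbins:
                continue
            sums[k] += (z[i] - z[j]) ** 2
            counts[k] += 1
    centers, gammas, ns = [], [], []
    for k in range(nbins):
        if counts[k] > 0:
            centers.append((k + 0.5) * lag_width)
            gammas.append(sums[k] / (2.0 * counts[k]))
            ns.append(counts[k])
    return np.array(centers), np.array(gammas), np.array(ns)


def brute_force_cross_variogram(xy, za, zb, lag_width, max_dist):
    n = len(xy)
    nbins = math.ceil(max_dist / lag_width)
    sums = [0.0] * nbins
    counts = [0] * nbins
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(xy[i], xy[j])
            if d <= 0:
                continue
            k = int(d // lag_width)
            if k >= nbins:
                continue
            sums[k] += (za[i] - za[j]) * (zb[i] - zb[j])
            counts[k] += 1
    centers, gammas = [], []
    for k in range(nbins):
        if counts[k] > 0:
            centers.append((k + 0.5) * lag_width)
            gammas.append(sums[k] / (2.0 * counts[k]))
    return np.array(centers), np.array(gammas)


def blup_oracle(obs_xy, obs_var, z, gamma_fn, target, drift_fns=None,
                pseudo_sill=None):
    """Constrained minimum-variance linear predictor, covariance form.

    ``obs_xy``: (m, 2) observation coordinates; ``obs_var``: length-m array
    of variable indices (0 = primary, 1 = covariate); ``gamma_fn(i, j, h)``:
    (cross-)semivariance; ``target``: coordinates of the primary-variable
    prediction point; ``drift_fns``: list of basis functions f(x, y) the
    primary weights must reproduce (default [1] — ordinary kriging).  For
    two-variable problems the covariate weights are constrained to sum to 0.

    Uses a pseudo-covariance C = K − γ with an arbitrary large constant K,
    which the constraints make immaterial; solves the KKT system directly and
    evaluates the error variance from its quadratic form.
    """
    obs_xy = np.asarray(obs_xy, dtype=float)
    obs_var = np.asarray(obs_var, dtype=int)
    m = len(obs_xy)
    if drift_fns is None:
        drift_fns = [lambda x, y: 1.0]
    if pseudo_sill is None:
        # anything comfortably above the largest semivariance in play
        dmax = max(
            math.dist(obs_xy[i], obs_xy[j])
            for i in range(m) for j in range(m)
        ) + math.dist(target, obs_xy[0])
        pseudo_sill = 10.0 * max(
            abs(gamma_fn(a, b, dmax)) + abs(gamma_fn(a, b, dmax / 2)) + 1.0
            for a in (0, 1) for b in (0, 1)
        )
    K = pseudo_sill

    def cov(i_var, j_var, h):
        return K - gamma_fn(i_var, j_var, h)

    C = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            h = math.dist(obs_xy[i], obs_xy[j])
            C[i, j] = cov(obs_var[i], obs_var[j], h)
    c0 = np.array(
        [cov(obs_var[i], 0, math.dist(obs_xy[i], target)) for i in range(m)]
    )
    c00 = cov(0, 0, 0.0)

    # constraints: primary weights reproduce each drift basis function at the
    # target; covariate weights (if any) sum to zero
    cons, rhs = [], []
    for f in drift_fns:
        row = np.array(
            [f(*obs_xy[i]) if obs_var[i] == 0 else 0.0 for i in range(m)]
        )
        cons.append(row)
        rhs.append(f(*target))
    if (obs_var == 1).any():
        cons.append((obs_var == 1).astype(float))
        rhs.append(0.0)
    B = np.array(cons).T
    b = np.array(rhs)

    p = B.shape[1]
    kkt = np.zeros((m + p, m + p))
    kkt[:m, :m] = C
    kkt[:m, m:] = B
    kkt[m:, :m] = B.T
    sol = np.linalg.solve(kkt, np.concatenate([c0, b]))
    w = sol[:m]
    pred = float(w @ z)
    var = float(w @ C @ w - 2.0 * w @ c0 + c00)
    return pred, var, w
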