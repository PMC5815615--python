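# Methods

This note documents the statistical models implemented in dendroscape, the
conventions and defaults chosen where several are defensible, what the
synthetic data generator does and does not emulate, and the package's known
limitations.

## Spatial model

Each isotope series z(s) (‰, per site s in projected metres) is modelled as
a Gaussian random field

    z(s) = m(s) + ε(s),

with m(s) an unknown constant (ordinary kriging), a polynomial in the
coordinates of order 1 or 2 (universal kriging), or a constant plus a
linearly coregionalized covariate signal (cokriging).  Spatial dependence of
ε is carried by the semivariogram γ(h) = ½ E[(ε(s) − ε(s+h))²].  All
distances are Euclidean in the projected CRS; no geographic (lat/lon)
computation occurs anywhere, which is appropriate for domains of ~100 km in
a UTM zone.

### Variogram families

With nugget c₀ ≥ 0, partial sill c ≥ 0 and range a > 0:

- spherical: γ = c₀ + c·(1.5 h/a − 0.5 (h/a)³) for h ≤ a, else c₀ + c
- exponential: γ = c₀ + c·(1 − e^{−h/a})
- linear: γ = c₀ + b·h (no sill; b in ‰²/m)
- Matérn, Stein's parameterization:
  γ = c₀ + c·(1 − (2^{1−κ}/Γ(κ)) u^κ K_κ(u)), u = h√(2κ)/a.
  This form keeps the meaning of a roughly stable across the smoothness κ;
  it reduces to the exponential at κ = ½ (verified in the tests to 1e-9)
  and approaches a Gaussian model as κ → ∞.

γ(0) = 0 exactly; the nugget is the h → 0⁺ limit.  The nugget absorbs
measurement error and micro-scale variation — including the within-site
variance of the five pooled trees per site, which is not modelled
explicitly (the survey design pools them before analysis).

### Empirical variograms and fitting

Pairs are binned by separation with a default lag width of 2,500 m up to a
default maximum distance of ⅓ of the largest inter-site distance.  Lag
centres are bin midpoints.  Directional variograms keep pairs whose bearing
(mod 180°) is within a tolerance of the requested direction; the variogram
map bins by lag vector and is centro-symmetric by construction.  Anisotropy
is diagnosed with these tools but final models are isotropic; geometric
anisotropy correction is out of scope.

Models are fitted by weighted least squares with weights N(h)/h² (the
common default emphasising well-estimated short lags); N(h) and Cressie
weights are available.  Multistart initial values: nugget from the first
bin, sill from the late-lag mean, range from ⅓ of the maximum lag; κ is
first selected on a log grid over [0.05, 10] and then refined jointly.
Reported RSS is unweighted over bins, and AIC = m·ln(RSS/m) + 2k with m bins
and k free parameters (2 for linear, 3 for spherical/exponential, 4 for
Matérn) — a Gaussian-likelihood form whose differences, not levels, matter.
Model selection takes the lowest AIC, ties broken by RSS, then parsimony.

For universal kriging the variogram is fitted to the residuals of the
order-1 or order-2 trend (ordinary least squares on centred, scaled
monomials); standard practice, since the raw variogram of a trended field
grows without bound.

### Linear model of coregionalization

For cokriging, the two direct variograms and the cross-variogram
γ_ab(h) = ½ E[(a_i − a_j)(b_i − b_j)] are expressed on shared structures
(nugget + the structure of the primary's selected model; a spherical
structure spanning the observed lags stands in when the primary selected
the unbounded linear family).  Coefficient matrices are fitted per pair by
WLS, then projected onto the positive-semidefinite cone and refitted
(Goulard–Voltz-style alternation, ≤100 sweeps, tolerance 1e-8), with the
cross coefficient clipped to the Cauchy–Schwarz bound of the direct
coefficients.  The fit reports whether the PSD constraint was binding; the
returned model always satisfies min eigenvalue ≥ −1e-10.

### Kriging systems

All solvers use the semivariance formulation, which remains valid for the
unbounded linear model under the unbiasedness constraints.  Ordinary
kriging solves the (n+1)×(n+1) system with Σλ = 1; universal kriging adds
one constraint per drift monomial (3 linear, 6 quadratic); cokriging solves
the joint system with Σλ_primary = 1 and Σλ_covariate = 0.  The drift basis
is centred and scaled internally for conditioning (the spanned space, and
hence the solution, is unchanged).  Singular systems get one retry with a
1e-10·sill diagonal jitter.  Predictions are exact at data locations with
σ² = 0 even under a nonzero nugget — the convention of most geostatistical
software; the alternative "noisy data" reading (σ² = c₀ at data points) is
not implemented.

Cokriging is co-located (covariate observed at the sample sites), with an
optional covariate observation at the prediction point itself.  The LOOCV
routine supplies the held-out site's covariate value by default: altitude
comes from an exhaustive DEM, so it is known at every prediction target,
and that knowledge is precisely why cokriging helps when the covariate
carries fine-scale signal.  The strictly co-located variant (no target
covariate) is a flag away.  All solves use the full site set (global
neighbourhood); with n ≈ 150 there is no need for moving windows.

### Cross-validation and ranking

Leave-one-out: variogram/LMC parameters are fitted once on all data and
frozen across folds (the behaviour of standard software; refitting per fold
would be ~150× the cost for a second-order effect).  RMSE is reported in ‰;
MSDR = mean(e²/σ²) should be 1 when the variogram is correct — this
calibration property is verified on simulated fields in the acceptance
suite (mean MSDR within [0.9, 1.1] over 200 replicates).  Ranking sorts by
|MSDR − 1| with ties within 0.005 broken by lower RMSE; because the
RMSE-first ordering can disagree, it is reported alongside.

### Isoscapes

The 95% confidence surfaces use the Gaussian multiplier:
CI = prediction ± 1.96·√σ².  Summaries report both CI width and half-width,
since "the confidence interval ranges…" is quoted both ways in applied
work.  Grid masks come from a polygon (cells whose centre is inside) at a
default resolution of 250 m for single surfaces; the full pipeline default
is 1 km, which keeps a four-series cokriged run to minutes on one CPU while
remaining much finer than the ~6.5 km site spacing.  Rasters are ESRI ASCII
grids (bit-exact round trip); GeoTIFF is not supported without an optional
dependency.

## Supporting procedures

- **Two-point normalization**: raw instrument deltas are placed on the
  VSMOW scale by the affine map fixing two certified standards (e.g. USGS54
  δ²H = −154.4 ‰ and USGS56 δ²H = −44 ‰) to their reference values.
- **Cross-dating**: Gleichläufigkeit is the percentage agreement of
  first-difference signs over the overlap; a flat step in one series scores
  ½ (Eckstein–Bauch convention; two flat steps agree fully).  The t statistic
  is the plain correlation t = r√(n−2)/√(1−r²) on raw widths — not the
  Baillie–Pilcher variant on detrended series, a deliberate simplification
  noted here because sources are often vague about which is meant.
- **Canopy cover**: CHM cells above a 2 m height threshold (equality counts
  as open) are binarized, summed over a true circular 20 m neighbourhood
  (cell centres within the radius) and divided by the conventional plot
  area 1,256.4 m².  That constant is kept although π·20² = 1256.64; both
  the denominator and the radius are configurable.  Grid-module
  implementations that approximate the circle by a square window will
  differ by a few percent near edges.
- **Raster cell membership** is half-open: [edge, edge + cellsize) in both
  axes, so boundary points belong deterministically to the cell whose lower
  edge they touch.
- **Moran's I** uses row-standardized inverse-distance weights by default
  (no cutoff), with E[I] = −1/(n−1) and a one-sided permutation p-value
  (default 999 permutations, seeded).  The weight scheme is configurable
  because no single convention dominates.
- **Covariate AIC** uses AIC = n·ln(RSS/n) + 2k with k = 3 for the simple
  regression; candidates are the four field covariates (temperature,
  altitude, radiation, canopy cover), not the coordinates, which enter the
  trend instead.  Standardization uses the sample (n−1) standard deviation.

## Synthetic data: what it does and does not emulate

`make_trentino_like` generates the regional study conditions: 151 uniform
random sites in an irregular ~120 km alpine polygon (UTM-magnitude
coordinates); an altitude field spanning exactly 547–1974 m built from a
regional (45 km range, 45% of variance) plus a ridge/valley (6 km range,
55%) spherical structure — most altitude variance sits below the ~6.5 km
site spacing, which is what makes an exhaustive elevation covariate
genuinely informative; four isotope columns whose pooled min/max are mapped
exactly onto 21.0–24.8 ‰ (δ¹⁸O) and −105.6…−57.0 ‰ (δ²H) and whose sample
correlations with altitude (−0.35, −0.65, −0.39, −0.30) and northing
(−0.10, −0.22, −0.52, −0.54) are pinned exactly by an orthogonalized mixing
construction, the 2013 columns enriched relative to 2014; spatially
structured residuals (spherical, 30–45 km ranges) that are strongly
nugget-dominated (nugget fractions 0.75 for δ¹⁸O and 0.85 for δ²H, keeping
the effective δ²H nugget below ≈30 ‰²); and covariates in which temperature
follows the lapse rate with weather noise (corr ≈ −0.5 with altitude) while
radiation and canopy cover are essentially uninformative.

Not emulated: precipitation-isotope physics (no Rayleigh distillation, no
isotopes-in-precipitation surfaces), within-site tree-to-tree variance
(folded into the nugget, as pooling makes it unidentifiable), valley-shaped
anisotropy, non-Gaussian tails, and inter-annual correlation structure
beyond the shared altitude/latitude signals.  Passing tests on this
generator therefore demonstrate that the estimators are correct and
well-calibrated under the stated conditions — not that real tree-ring data
meet those conditions.

## Numerical choices

Dense Cholesky factorization for field simulation (exact; fine for
n ≲ 3000 — here n is 151–500), with a 1e-10·sill jitter and a single 1e-6
fallback before raising.  The unbounded linear variogram is simulated as an
intrinsic process via the covariance b·(D − h) with D the point-set
diameter.  Variogram fits floor a vanishing RSS before the log in AIC.
Duplicate coordinates are rejected by the kriging solvers and averaged (with
a warning) by the site-table reader.  All randomness flows through
`numpy.random.default_rng` seeds; every generator is bit-for-bit
reproducible, and the pipeline's CSV outputs are byte-identical across
reruns of the same configuration and seed.

## Problem sizes in the tests

Monte-Carlo checks use sizes chosen to keep the whole suite within a few
minutes while leaving comfortable statistical margins: 200 replicates for
field-level calibration properties (marginal variance, γ̂ at a/2, MSDR at
n = 151), 100 replicates for range recovery at n = 300, 50 replicates for
LMC coefficient recovery (n = 200 on a domain eight ranges wide) and for the
cokriging-vs-kriging comparison (n = 80, cross-sill 0.9).

## Limitations

- No kriging with external drift, block or indicator kriging, or >2-variable
  cokriging; no k-fold or spatial-block cross-validation.
- Isotropic final models only; anisotropy is diagnosed, not corrected.
- No CRS handling or reprojection: inputs must already share one projected
  CRS in metres.
- The LMC uses the primary variable's structure for both variables; a
  covariate with a very different range is only approximated.
- Provenance *assignment* (posterior surfaces for an unknown sample) is a
  natural next step but is not implemented; the package stops at the
  predicted surfaces and their uncertainty.
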