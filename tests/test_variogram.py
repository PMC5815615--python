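import numpy as np
import pytest

from dendroscape.synth import FieldSpec, simulate_grf
from dendroscape.variogram import (
    CoregionalizationModel,
    EmpiricalVariogram,
    VariogramModel,
    cross_variogram,
    empirical_variogram,
    fit_all_families,
    fit_lmc,
    fit_model,
    fit_trend,
    model_gamma,
    select_model,
    variogram_map,
)
from oracles import brute_force_cross_variogram, brute_force_variogram


class TestModelGamma:
    def test_spherical_closed_form(self):
        m = VariogramModel("spherical", nugget=0.0, partial_sill=1.0, range_=30_000)
        assert model_gamma(m, 15_000) == pytest.approx(0.6875)
        assert model_gamma(m, 30_000) == pytest.approx(1.0)
        assert model_gamma(m, 60_000) == pytest.approx(1.0)

    def test_matern_stein_kappa_half_equals_exponential(self):
        ste = VariogramModel("matern_stein", nugget=0.1, partial_sill=2.0,
                             range_=20_000, kappa=0.5)
        exp = VariogramModel("exponential", nugget=0.1, partial_sill=2.0,
                             range_=20_000)
        h = np.linspace(1.0, 100_000, 500)
        np.testing.assert_allclose(model_gamma(ste, h), model_gamma(exp, h),
                                   atol=1e-9)

    @pytest.mark.parametrize("model", [
        VariogramModel("spherical", nugget=0.3, partial_sill=1.2, range_=10_000),
        VariogramModel("exponential", nugget=0.0, partial_sill=2.0, range_=5_000),
        VariogramModel("linear", nugget=0.2, slope=1e-4),
        VariogramModel("matern_stein", nugget=0.1, partial_sill=1.0,
                       range_=8_000, kappa=1.5),
    ])
    def test_nugget_limit_and_monotone(self, model):
        assert model_gamma(model, 0.0) == 0.0
        assert model_gamma(model, 1e-9) == pytest.approx(model.nugget, abs=1e-6)
        h = np.linspace(1.0, 30_000, 400)
        g = model_gamma(model, h)
        assert (np.diff(g) >= -1e-10).all()

    def test_negative_lag_is_domain_error(self):
        m = VariogramModel("spherical")
        with pytest.raises(ValueError):
            model_gamma(m, -1.0)


class TestEmpiricalVariogram:
    def test_constant_field_is_zero(self, rng):
        xy = rng.uniform(0, 1000, (30, 2))
        emp = empirical_variogram(xy, np.full(30, 3.3), lag_width=100)
        assert (emp.semivariance == 0).all()

    def test_two_points_single_bin(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0]])
        with pytest.warns(UserWarning):
            emp = empirical_variogram(xy, np.array([0.0, 2.0]), lag_width=20,
                                      max_dist=20)
        assert emp.semivariance[0] == pytest.approx(2.0)  # 2² / (2·1)
        assert emp.pair_counts[0] == 1

    @pytest.mark.parametrize("n", [5, 17, 30])
    def test_matches_brute_force_oracle(self, n, rng):
        xy = rng.uniform(0, 10_000, (n, 2))
        z = rng.normal(0, 2, n)
        lag, max_dist = 800.0, 6000.0
        if n < 10:
            with pytest.warns(UserWarning):
                emp = empirical_variogram(xy, z, lag_width=lag, max_dist=max_dist)
        else:
            emp = empirical_variogram(xy, z, lag_width=lag, max_dist=max_dist)
        c, g, k = brute_force_variogram(xy, z, lag, max_dist)
        np.testing.assert_allclose(emp.lag_centers, c)
        np.testing.assert_allclose(emp.semivariance, g, atol=1e-12)
        np.testing.assert_array_equal(emp.pair_counts, k)

    def test_directional_filter_keeps_only_aligned_pairs(self):
        # three collinear E-W points plus one to the north
        xy = np.array([[0, 0], [100, 0], [200, 0], [0, 100.0]])
        z = np.array([0.0, 1.0, 0.0, 5.0])
        ew = empirical_variogram(xy, z, lag_width=150, max_dist=300,
                                 direction=90, tol=10)
        assert ew.pair_counts.sum() == 3  # the three E-W pairs only

    def test_no_pairs_raises(self):
        xy = np.array([[0.0, 0.0], [10_000.0, 0.0]])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no point pairs"):
                empirical_variogram(xy, np.array([0.0, 1.0]), lag_width=10,
                                    max_dist=100)


class TestVariogramMap:
    def test_centrosymmetric(self, rng):
        xy = rng.uniform(0, 5000, (40, 2))
        z = rng.normal(0, 1, 40)
        grid, _, _ = variogram_map(xy, z, cell=500.0, max_dist=2000.0)
        flipped = grid[::-1, ::-1]
        both = np.isfinite(grid) & np.isfinite(flipped)
        np.testing.assert_allclose(grid[both], flipped[both], atol=1e-12)

    def test_y_only_field_shows_ns_structure(self, rng):
        xy = rng.uniform(0, 10_000, (150, 2))
        z = 1e-3 * xy[:, 1]  # varies with northing only
        grid, xe, ye = variogram_map(xy, z, cell=1000.0, max_dist=5000.0)
        mid = grid.shape[0] // 2
        ns = np.nanmean(grid[mid, :])   # Δx ≈ 0 row varies along Δy axis
        ew = np.nanmean(grid[:, mid])
        assert ns > 5 * ew


class TestFitTrend:
    def test_linear_surface_recovered_exactly(self, rng):
        xy = rng.uniform(0, 100, (25, 2))
        z = 3.0 + 2.0 * xy[:, 0]
        model, resid = fit_trend(xy, z, order=1)
        np.testing.assert_allclose(model.coefficients, [3.0, 2.0, 0.0], atol=1e-8)
        np.testing.assert_allclose(resid, 0.0, atol=1e-8)

    def test_quadratic_surface_zero_residuals(self, rng):
        xy = rng.uniform(-10, 10, (40, 2))
        z = 1.0 - 0.5 * xy[:, 0] + 0.25 * xy[:, 1] ** 2 + xy[:, 0] * xy[:, 1]
        _, resid = fit_trend(xy, z, order=2)
        np.testing.assert_allclose(resid, 0.0, atol=1e-8)

    def test_detrending_stabilizes_large_lag_variance(self, rng):
        n = 200
        xy = rng.uniform(0, 50_000, (n, 2))
        spec = FieldSpec(VariogramModel("spherical", nugget=0.1,
                                        partial_sill=0.5, range_=15_000))
        z = simulate_grf(xy, spec, seed=4) + 1e-4 * xy[:, 1]
        raw = empirical_variogram(xy, z, lag_width=2500)
        _, resid = fit_trend(xy, z, order=1)
        det = empirical_variogram(xy, resid, lag_width=2500)
        assert det.semivariance[-1] < raw.semivariance[-1]


class TestFitModel:
    def _exact_emp(self, model, hmax=60_000, nbins=20):
        h = (np.arange(nbins) + 0.5) * (hmax / nbins)
        return EmpiricalVariogram(
            lag_centers=h, semivariance=model_gamma(model, h),
            pair_counts=np.full(nbins, 50), lag_width=hmax / nbins,
        )

    def test_self_consistency_on_exact_spherical_curve(self):
        true = VariogramModel("spherical", nugget=0.2, partial_sill=1.0,
                              range_=30_000)
        fit = fit_model(self._exact_emp(true), "spherical")
        assert fit.nugget == pytest.approx(0.2, abs=1e-6)
        assert fit.partial_sill == pytest.approx(1.0, abs=1e-6)
        assert fit.range_ == pytest.approx(30_000, rel=1e-6)

    def test_scale_equivariance(self, rng):
        xy = rng.uniform(0, 60_000, (120, 2))
        z = simulate_grf(xy, FieldSpec(VariogramModel(
            "spherical", nugget=0.2, partial_sill=1.0, range_=20_000)), seed=9)
        emp1 = empirical_variogram(xy, z, lag_width=2500)
        emp2 = empirical_variogram(xy, 3.0 * z, lag_width=2500)
        f1 = fit_model(emp1, "spherical")
        f2 = fit_model(emp2, "spherical")
        assert f2.nugget == pytest.approx(9.0 * f1.nugget, rel=1e-4, abs=1e-9)
        assert f2.partial_sill == pytest.approx(9.0 * f1.partial_sill, rel=1e-4)
        assert f2.range_ == pytest.approx(f1.range_, rel=1e-4)

    def test_spherical_wins_on_spherical_curve(self):
        true = VariogramModel("spherical", nugget=0.1, partial_sill=1.0,
                              range_=25_000)
        fits = fit_all_families(self._exact_emp(true))
        by_rss = {f.family: f.rss for f in fits}
        assert by_rss["spherical"] == min(by_rss.values())

    def test_parameter_recovery_from_simulations(self, rng):
        # median fitted spherical range within 20% of the generating 30 km
        true = VariogramModel("spherical", nugget=0.2, partial_sill=1.0,
                              range_=30_000)
        ranges = []
        for rep in range(30):
            xy = rng.uniform(0, 120_000, (300, 2))
            z = simulate_grf(xy, FieldSpec(true), seed=1000 + rep)
            emp = empirical_variogram(xy, z, lag_width=2500)
            ranges.append(fit_model(emp, "spherical").range_)
        assert abs(np.median(ranges) - 30_000) / 30_000 < 0.2

    def test_too_few_bins_raises(self):
        emp = EmpiricalVariogram(lag_centers=[1.0, 2.0, 3.0],
                                 semivariance=[1.0, 1.0, 1.0],
                                 pair_counts=[5, 5, 5])
        with pytest.raises(ValueError, match="4"):
            fit_model(emp, "spherical")


class TestSelectModel:
    def test_single_candidate_returned(self):
        m = VariogramModel("spherical", rss=1.0, aic=5.0)
        assert select_model([m]) is m

    def test_equal_aic_tie_broken_by_rss(self):
        a = VariogramModel("spherical", rss=2.0, aic=5.0)
        b = VariogramModel("exponential", rss=1.0, aic=5.0)
        assert select_model([a, b]) is b

    def test_unconverged_candidates_excluded(self):
        a = VariogramModel("spherical", rss=0.1, aic=-10.0, converged=False)
        b = VariogramModel("exponential", rss=1.0, aic=5.0)
        assert select_model([a, b]) is b
        with pytest.raises(ValueError):
            select_model([a])


class TestCrossVariogram:
    def test_identical_variables_equal_direct(self, rng):
        xy = rng.uniform(0, 10_000, (40, 2))
        z = rng.normal(0, 1, 40)
        direct = empirical_variogram(xy, z, lag_width=1000, max_dist=5000)
        cross = cross_variogram(xy, z, z, lag_width=1000, max_dist=5000)
        np.testing.assert_allclose(cross.semivariance, direct.semivariance,
                                   atol=1e-12)

    def test_negated_variable_flips_sign(self, rng):
        xy = rng.uniform(0, 10_000, (40, 2))
        z = rng.normal(0, 1, 40)
        direct = empirical_variogram(xy, z, lag_width=1000, max_dist=5000)
        cross = cross_variogram(xy, z, -z, lag_width=1000, max_dist=5000)
        np.testing.assert_allclose(cross.semivariance, -direct.semivariance,
                                   atol=1e-12)

    def test_matches_brute_force(self, rng):
        xy = rng.uniform(0, 10_000, (25, 2))
        a = rng.normal(0, 1, 25)
        b = rng.normal(0, 1, 25)
        cross = cross_variogram(xy, a, b, lag_width=900, max_dist=6000)
        c, g = brute_force_cross_variogram(xy, a, b, 900, 6000)
        np.testing.assert_allclose(cross.lag_centers, c)
        np.testing.assert_allclose(cross.semivariance, g, atol=1e-12)

    def test_independent_fields_average_near_zero(self, rng):
        xy = rng.uniform(0, 50_000, (80, 2))
        spec = FieldSpec(VariogramModel("spherical", nugget=0.1,
                                        partial_sill=1.0, range_=15_000))
        means = []
        for rep in range(100):
            a = simulate_grf(xy, spec, seed=2 * rep)
            b = simulate_grf(xy, spec, seed=2 * rep + 1)
            cross = cross_variogram(xy, a, b, lag_width=5000, max_dist=25_000)
            means.append(cross.semivariance.mean())
        mc_sd = np.std(means, ddof=1)
        assert abs(np.mean(means)) < 2 * mc_sd


class TestLMC:
    def _triplet(self, rng, b_cross):
        """Simulate a joint pair from a known 1-structure + nugget LMC."""
        from scipy.spatial.distance import pdist, squareform
        from dendroscape.variogram import _gamma_structure

        # domain eight ranges wide so the variography noise is modest
        n = 200
        xy = rng.uniform(0, 120_000, (n, 2))
        d = squareform(pdist(xy))
        struct_cov = 1.0 - _gamma_structure("spherical", d, 15_000, None)
        B1 = np.array([[1.0, b_cross], [b_cross, 1.0]])
        B0 = np.array([[0.3, 0.0], [0.0, 0.1]])
        cov = np.kron(B1, struct_cov) + np.kron(B0, np.eye(n))
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(2 * n))
        u = L @ rng.standard_normal(2 * n)
        za, zb = u[:n], u[n:]
        lag, md = 4000.0, 40_000.0
        return (
            empirical_variogram(xy, za, lag_width=lag, max_dist=md),
            empirical_variogram(xy, zb, lag_width=lag, max_dist=md),
            cross_variogram(xy, za, zb, lag_width=lag, max_dist=md),
        )

    def test_zero_cross_input_gives_zero_cross_coefficients(self):
        h = (np.arange(10) + 0.5) * 2000.0
        from dendroscape.variogram import _gamma_structure

        g = _gamma_structure("spherical", h, 12_000, None)
        mk = lambda vals, cross=False: EmpiricalVariogram(
            lag_centers=h, semivariance=vals, pair_counts=np.full(10, 40),
            lag_width=2000.0, is_cross=cross)
        da = mk(0.2 + 1.0 * g)
        db = mk(0.1 + 0.8 * g)
        cr = mk(np.zeros(10), cross=True)
        lmc = fit_lmc(da, db, cr, [("spherical", 12_000.0, None)])
        assert abs(lmc.b_nugget[0, 1]) < 1e-8
        assert all(abs(B[0, 1]) < 1e-8 for B in lmc.b_structs)
        assert not lmc.psd_binding

    def test_recovers_known_coefficients(self, rng):
        errs = []
        for rep in range(50):
            da, db, cr = self._triplet(np.random.default_rng(100 + rep), 0.7)
            lmc = fit_lmc(da, db, cr, [("spherical", 15_000.0, None)])
            errs.append(abs(lmc.b_structs[0][0, 1] - 0.7) / 0.7)
        assert np.median(errs) < 0.25

    def test_inconsistent_cross_is_clipped_to_cauchy_schwarz(self):
        h = (np.arange(10) + 0.5) * 2000.0
        from dendroscape.variogram import _gamma_structure

        g = _gamma_structure("spherical", h, 12_000, None)
        mk = lambda vals, cross=False: EmpiricalVariogram(
            lag_centers=h, semivariance=vals, pair_counts=np.full(10, 40),
            lag_width=2000.0, is_cross=cross)
        da = mk(0.5 * g + 0.01)
        db = mk(0.5 * g + 0.01)
        cr = mk(3.0 * g + 1.0, cross=True)  # cross² > product everywhere
        lmc = fit_lmc(da, db, cr, [("spherical", 12_000.0, None)])
        assert lmc.psd_binding
        for B in [lmc.b_nugget] + lmc.b_structs:
            assert abs(B[0, 1]) <= np.sqrt(B[0, 0] * B[1, 1]) + 1e-10
        assert lmc.min_eigenvalue() >= -1e-10

    def test_mismatched_bins_raise(self):
        h1 = (np.arange(10) + 0.5) * 2000.0
        h2 = (np.arange(8) + 0.5) * 2000.0
        mk = lambda h: EmpiricalVariogram(
            lag_centers=h, semivariance=np.ones(len(h)),
            pair_counts=np.full(len(h), 5))
        with pytest.raises(ValueError, match="lag bins"):
            fit_lmc(mk(h1), mk(h2), mk(h1), [("spherical", 10_000.0, None)])
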