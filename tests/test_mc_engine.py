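"""Monte Carlo engine: DGM, OLS fits, percentile summaries, coverage, stability."""

import dataclasses
import math

import numpy as np
import numpy.testing as npt
import pytest

from reexpress.mc_engine import (
    DegenerateDesignError,
    DGMConfig,
    McSample,
    coverage_vs_constant,
    fit_slope,
    mc_stability,
    run_mc,
    sample_exposure,
    simulate_outcome,
    summarize_percentiles,
    variability_grid,
)


def small_config(**overrides):
    base = dict(n_obs=50, sigma=0.45, noise_sd=1.0, space="logged",
                n_sims=200, seed=11)
    base.update(overrides)
    return DGMConfig(**base)


class TestSampleExposure:
    def test_zero_sigma_degenerates_to_median(self):
        x = sample_exposure(10, 8.0, 0.0, 10.0, np.random.default_rng(0))
        npt.assert_allclose(x, 8.0, rtol=1e-12)

    def test_large_sample_matches_analytic_median_and_log_sd(self):
        x = sample_exposure(100_000, 8.0, 0.25, 10.0, np.random.default_rng(1))
        assert np.all(x > 0)
        assert np.median(x) == pytest.approx(8.0, rel=0.01)
        assert np.std(np.log10(x), ddof=1) == pytest.approx(0.25, rel=0.02)

    def test_same_seed_reproduces_vector(self):
        a = sample_exposure(100, 8.0, 0.45, 10.0, np.random.default_rng(42))
        b = sample_exposure(100, 8.0, 0.45, 10.0, np.random.default_rng(42))
        npt.assert_array_equal(a, b)

    def test_log_base_other_than_ten(self):
        # same natural-log spread regardless of declared base
        x = sample_exposure(200_000, 8.0, 0.25 * math.log(10) / math.log(2),
                            2.0, np.random.default_rng(2))
        assert np.std(np.log(x), ddof=1) == pytest.approx(0.25 * math.log(10), rel=0.02)


class TestSimulateOutcome:
    def test_noiseless_unlogged_is_identity_on_exposure(self):
        config = small_config(noise_sd=0.0, space="unlogged")
        x = sample_exposure(50, 8.0, 0.45, 10.0, np.random.default_rng(3))
        y = simulate_outcome(x, config, np.random.default_rng(4))
        npt.assert_array_equal(y, x)

    def test_noiseless_logged_is_log10_of_exposure(self):
        config = small_config(noise_sd=0.0, space="logged")
        x = sample_exposure(50, 8.0, 0.45, 10.0, np.random.default_rng(5))
        y = simulate_outcome(x, config, np.random.default_rng(6))
        npt.assert_allclose(y, np.log10(x), rtol=1e-12)

    def test_noise_independent_of_exposure(self):
        config = small_config(noise_sd=1.0, space="unlogged", n_obs=200_000)
        x = sample_exposure(200_000, 8.0, 0.45, 10.0, np.random.default_rng(7))
        y = simulate_outcome(x, config, np.random.default_rng(8))
        resid = y - config.beta_dgm * x
        assert abs(np.corrcoef(resid, x)[0, 1]) < 0.01


class TestFitSlope:
    def test_exact_affine_recovery(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, se = fit_slope(x, 2.5 * x - 1.0)
        assert slope == pytest.approx(2.5, rel=1e-14)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_brute_force_to_12_digits(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        # independent oracle: solve (A'A) b = A'y directly, then the classical
        # SE formula from the inverse normal matrix
        a = np.column_stack([np.ones_like(x), x])
        coef = np.linalg.solve(a.T @ a, a.T @ y)
        resid = y - a @ coef
        s2 = float(resid @ resid) / (len(x) - 2)
        se_oracle = math.sqrt(s2 * np.linalg.inv(a.T @ a)[1, 1])
        slope, se = fit_slope(x, y)
        assert slope == pytest.approx(coef[1], rel=1e-12)
        assert se == pytest.approx(se_oracle, rel=1e-12)

    def test_matches_statsmodels_cross_check(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        x = rng.lognormal(2.0, 1.0, 40)
        y = 1.5 * x + rng.normal(0, 2.0, 40)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        slope, se = fit_slope(x, y)
        assert slope == pytest.approx(fit.params[1], rel=1e-10)
        assert se == pytest.approx(fit.bse[1], rel=1e-10)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_slope(np.ones(10), np.arange(10.0))
        with pytest.raises(DegenerateDesignError):
            fit_slope(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="mismatch"):
            fit_slope(np.arange(5.0), np.arange(4.0))


class TestRunMc:
    def test_bitwise_reproducible_given_seed(self):
        config = small_config()
        a, b = run_mc(config), run_mc(config)
        npt.assert_array_equal(a.estimand_hats, b.estimand_hats)
        npt.assert_array_equal(a.logged_ses, b.logged_ses)

    def test_growing_n_sims_extends_rather_than_reshuffles(self):
        small = run_mc(small_config(n_sims=50))
        large = run_mc(small_config(n_sims=100))
        npt.assert_array_equal(small.estimand_hats, large.estimand_hats[:50])

    def test_noiseless_unlogged_recovers_dgm_slope_every_iteration(self):
        sample = run_mc(small_config(noise_sd=0.0, space="unlogged", n_sims=50))
        npt.assert_allclose(sample.estimand_hats, 1.0, rtol=1e-9)

    def test_noiseless_logged_recovers_dgm_slope_on_logged_scale(self):
        sample = run_mc(small_config(noise_sd=0.0, space="logged", n_sims=50))
        npt.assert_allclose(sample.logged_hats, 1.0, rtol=1e-9)

    def test_vectors_have_n_sims_length(self):
        sample = run_mc(small_config(n_sims=37))
        for name in ("estimand_hats", "estimand_ses", "logged_hats", "logged_ses"):
            assert getattr(sample, name).shape == (37,)


class TestSummarizePercentiles:
    def test_constant_sample_has_zero_deviation(self):
        config = small_config(noise_sd=0.0, space="unlogged", n_sims=50)
        summary = summarize_percentiles(run_mc(config))
        assert summary.lower_pct == pytest.approx(0.0, abs=1e-7)
        assert summary.upper_pct == pytest.approx(0.0, abs=1e-7)
        assert summary.mean_hat == pytest.approx(1.0, rel=1e-12)

    def test_normal_sample_matches_quantile_oracle(self):
        # N(1, 0.5^2): 5th/95th percentiles sit at +-1.6449*0.5 around the
        # mean, i.e. deviations of -+82.2% of the mean
        rng = np.random.default_rng(12)
        hats = rng.normal(1.0, 0.5, 1_000_000)
        sample = McSample(hats, np.zeros_like(hats), hats, np.zeros_like(hats),
                          small_config(n_sims=1_000_000))
        summary = summarize_percentiles(sample)
        assert summary.lower_pct == pytest.approx(-82.24, abs=1.0)
        assert summary.upper_pct == pytest.approx(82.24, abs=1.0)
        assert summary.sd_hat == pytest.approx(0.5, rel=0.01)

    def test_quantiles_match_sorted_order_statistics(self):
        # type-7 linear interpolation, checked against a brute-force oracle
        values = np.sin(np.arange(101) * 2.17) * 7.0 + 2.0
        sample = McSample(values, np.zeros(101), values, np.zeros(101),
                          small_config(n_sims=101))
        summary = summarize_percentiles(sample)

        def type7(sorted_vals, p):
            h = (len(sorted_vals) - 1) * p
            lo = math.floor(h)
            return sorted_vals[lo] + (h - lo) * (
                sorted_vals[min(lo + 1, len(sorted_vals) - 1)] - sorted_vals[lo]
            )

        ordered = np.sort(values)
        mean = values.mean()
        assert summary.lower_pct == pytest.approx(
            100 * (type7(ordered, 0.05) - mean) / mean, rel=1e-12
        )
        assert summary.upper_pct == pytest.approx(
            100 * (type7(ordered, 0.95) - mean) / mean, rel=1e-12
        )

    def test_raw_ratio_reading_available(self):
        values = np.linspace(0.5, 1.5, 101)
        sample = McSample(values, np.zeros(101), values, np.zeros(101),
                          small_config(n_sims=101))
        dev = summarize_percentiles(sample, as_deviation=True)
        raw = summarize_percentiles(sample, as_deviation=False)
        assert raw.lower_pct == pytest.approx(dev.lower_pct + 100, rel=1e-12)

    def test_zero_mean_rejected(self):
        values = np.concatenate([np.ones(50), -np.ones(50)])
        sample = McSample(values, np.zeros(100), values, np.zeros(100),
                          small_config(n_sims=100))
        with pytest.raises(ZeroDivisionError):
            summarize_percentiles(sample)


class TestCoverage:
    def test_infinite_intervals_cover_everything(self):
        sample = run_mc(small_config(n_sims=50))
        stub = dataclasses.replace(
            sample, estimand_ses=np.full(50, np.inf)
        )
        assert coverage_vs_constant(stub).coverage == 1.0

    def test_far_target_covered_never(self):
        sample = run_mc(small_config(n_sims=50))
        assert coverage_vs_constant(sample, target=1e12).coverage == 0.0

    def test_unlogged_dgm_gives_nominal_coverage_of_constant_target(self):
        config = DGMConfig(n_obs=162, sigma=0.45, space="unlogged",
                           noise_sd=1.0, n_sims=2000, seed=21)
        result = coverage_vs_constant(run_mc(config), scale="estimand")
        assert result.coverage == pytest.approx(0.95, abs=0.02)
        assert result.mc_se == pytest.approx(
            math.sqrt(result.coverage * (1 - result.coverage) / 2000), rel=1e-12
        )

    def test_logged_scale_coverage_under_logged_dgm(self):
        config = small_config(space="logged", n_sims=400, n_obs=100, seed=31)
        result = coverage_vs_constant(run_mc(config), scale="logged")
        assert result.coverage == pytest.approx(0.95, abs=0.04)


class TestStabilityAndGrid:
    def test_random_target_sd_plateaus_while_mc_se_shrinks(self):
        config = DGMConfig(n_obs=162, sigma=0.25, space="logged", noise_sd=1.0,
                           n_sims=2000, seed=41)
        frame = mc_stability(config, [500, 2000])
        sd = dict(zip(frame.n_sims, frame.sd_hat))
        se = dict(zip(frame.n_sims, frame.se_of_mean))
        assert 0.8 <= sd[2000] / sd[500] <= 1.25
        assert 0.4 <= se[2000] / se[500] <= 0.65

    def test_noiseless_unlogged_sd_is_zero_at_every_count(self):
        config = small_config(noise_sd=0.0, space="unlogged", n_sims=100)
        frame = mc_stability(config, [20, 50])
        npt.assert_allclose(frame.sd_hat, 0.0, atol=1e-9)

    def test_stability_input_validation(self):
        with pytest.raises(ValueError):
            mc_stability(small_config(), [])
        with pytest.raises(ValueError):
            mc_stability(small_config(), [10])

    def test_relative_variability_shrinks_with_study_size(self):
        grid = variability_grid(n_obs_values=(162, 1500), sigmas=(0.25,),
                                n_sims=400, seed=51)
        small = grid[grid.n_obs == 162].iloc[0]
        big = grid[grid.n_obs == 1500].iloc[0]
        assert abs(big.lower_pct) < abs(small.lower_pct)
        assert big.upper_pct < small.upper_pct

    def test_sigma_effect_in_noise_dominated_regime(self):
        # when residual noise dominates the signal, relative variability
        # decreases from sigma=0.25 to 0.65 (the attenuation-vs-spread
        # trade-off); under light noise the lognormal's heavy tails invert
        # this - see the methods note
        grid = variability_grid(n_obs_values=(162,), sigmas=(0.25, 0.65),
                                noise_sd=4.0, n_sims=400, seed=61)
        lo_sigma = grid[grid.sigma == 0.25].iloc[0]
        hi_sigma = grid[grid.sigma == 0.65].iloc[0]
        assert abs(hi_sigma.lower_pct) < abs(lo_sigma.lower_pct)

    def test_grid_has_one_row_per_scenario(self):
        grid = variability_grid(n_obs_values=(30, 60), sigmas=(0.25, 0.45, 0.65),
                                n_sims=50, seed=71)
        assert len(grid) == 6
        assert set(grid.columns) >= {"n_obs", "sigma", "mean_hat", "lower_pct",
                                     "upper_pct", "sd_hat"}


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_obs": 2},
            {"sigma": 0.0},
            {"log_base": 1.0},
            {"median": 0.0},
            {"noise_sd": -1.0},
            {"space": "mixed"},
            {"n_sims": 1},
            {"level": 1.0},
            {"seed": -1},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        base = dict(n_obs=50, sigma=0.45)
        base.update(kwargs)
        with pytest.raises(ValueError):
            DGMConfig(**base)
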