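"""Allometric mixed model: oracles, symmetries, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from sexallometry import (
    FitConfig,
    SingleSexError,
    center_log_weight,
    compare_substrain_models,
    fit_allometry,
    generate_trait,
    nakagawa_r2,
    residual_sd_by_sex,
    spec_from_scenario,
    variance_missed_by_common_slope,
)
from sexallometry.dataset import TraitDataset
from sexallometry.lmm import _REMLProblem, build_design

from _oracles import dense_reml_neg2ll


class TestCenterLogWeight:
    def test_constant_weights(self, raw_rows):
        df = raw_rows(n=4, weight=[np.e] * 4)
        ds = TraitDataset("lean_mass", "morphology", df)
        x, gm = center_log_weight(ds)
        assert gm == pytest.approx(1.0)
        np.testing.assert_allclose(x, 0.0, atol=1e-15)

    def test_symmetric_pair(self, raw_rows):
        df = raw_rows(n=4, weight=[1.0, np.e**2, 1.0, np.e**2])
        ds = TraitDataset("lean_mass", "morphology", df)
        x, gm = center_log_weight(ds)
        assert gm == pytest.approx(1.0)
        np.testing.assert_allclose(x, [-1, 1, -1, 1], atol=1e-12)

    def test_centring_identity(self, base_spec):
        ds = generate_trait(base_spec(n_f=10, n_m=10))
        x, _ = center_log_weight(ds)
        assert abs(x.mean()) < 1e-12


class TestFitAllometry:
    def test_noise_free_exact_line(self, noise_free_spec):
        ds = generate_trait(noise_free_spec(slope_f=0.5, slope_m=0.5))
        fit = fit_allometry(ds)
        assert fit.converged
        assert fit.slope_f == pytest.approx(0.5, abs=1e-8)
        assert fit.beta[2] == pytest.approx(0.0, abs=1e-8)
        assert fit.beta[3] == pytest.approx(0.0, abs=1e-8)
        sd_f, _, sd_m, _ = residual_sd_by_sex(fit)
        assert sd_f < 1e-6 and sd_m < 1e-6

    def test_single_sex_signal(self, raw_rows):
        df = raw_rows(n=6, sex=["female"] * 6)
        ds = TraitDataset("lean_mass", "morphology", df)
        with pytest.raises(SingleSexError):
            fit_allometry(ds, FitConfig(min_per_sex=1))

    def test_min_per_sex_floor(self, base_spec):
        ds = generate_trait(base_spec(n_f=10, n_m=500))
        with pytest.raises(ValueError, match="min_per_sex"):
            fit_allometry(ds)

    def test_dropped_singleton_random_terms_recorded(self, base_spec):
        ds = generate_trait(base_spec(n_metadata_groups=1, n_substrains=1))
        fit = fit_allometry(ds)
        assert set(fit.dropped_random_terms) == {"metadata_group", "substrain"}
        assert "batch" in fit.varcomp

    def test_ols_equivalence_degenerate_case(self, base_spec):
        """No grouping factors, heteroscedasticity off: estimates, SEs and
        p-values match ordinary least squares (two-line regression)."""
        ds = generate_trait(base_spec(n_batches=1, var_batch_intercept=0.0))
        cfg = FitConfig(heteroscedastic=False)
        fit = fit_allometry(ds, cfg)
        design = build_design(ds)
        ols = sm.OLS(design["y"], design["X"]).fit()
        np.testing.assert_allclose(fit.beta, ols.params, rtol=1e-6)
        np.testing.assert_allclose(fit.se_beta, ols.bse, rtol=1e-6)
        np.testing.assert_allclose(fit.p_beta, ols.pvalues, rtol=1e-6, atol=1e-250)
        assert fit.sd_resid_f == pytest.approx(np.sqrt(ols.mse_resid), rel=1e-6)

    @pytest.mark.parametrize(
        "structure",
        [
            dict(n_batches=6),
            dict(n_batches=5, n_metadata_groups=3,
                 cov_mg=[[0.02, 0.005], [0.005, 0.01]]),
            dict(n_batches=4, n_metadata_groups=3, n_substrains=3,
                 cov_mg=[[0.02, 0.005], [0.005, 0.01]],
                 cov_strain=[[0.01, 0.0], [0.0, 0.005]]),
        ],
    )
    def test_reml_matches_dense_oracle(self, base_spec, structure):
        """Restricted log-likelihood at the optimum equals a direct dense
        marginal-covariance evaluation on n <= 200 to 1e-6."""
        structure = {
            k: (np.array(v) if isinstance(v, list) else v) for k, v in structure.items()
        }
        spec = base_spec(n_f=90, n_m=90, sd_m=0.15, intercept_m=1.1,
                         var_batch_intercept=0.01, seed=11, **structure)
        ds = generate_trait(spec)
        fit = fit_allometry(ds, FitConfig(min_per_sex=10))
        assert fit.converged
        design = build_design(ds)
        problem = _REMLProblem(design, heteroscedastic=True)
        dense = dense_reml_neg2ll(design, fit.opt_par, problem)
        assert problem.deviance(fit.opt_par) == pytest.approx(dense, abs=1e-6)
        assert -2.0 * fit.loglik == pytest.approx(dense, abs=1e-6)

    def test_scale_equivariance(self, base_spec):
        """Multiplying trait values by c shifts both intercepts by log c and
        changes no slope, SD, or p-value."""
        ds = generate_trait(base_spec(seed=21))
        fit1 = fit_allometry(ds)
        scaled = TraitDataset(
            ds.trait_name, ds.functional_group,
            ds.data.assign(trait_value=ds.data["trait_value"] * 7.0),
        )
        fit2 = fit_allometry(scaled)
        assert fit2.intercept_f - fit1.intercept_f == pytest.approx(np.log(7), abs=1e-6)
        assert fit2.intercept_m - fit1.intercept_m == pytest.approx(np.log(7), abs=1e-6)
        assert fit2.slope_f == pytest.approx(fit1.slope_f, abs=1e-6)
        np.testing.assert_allclose(fit2.beta[2:], fit1.beta[2:], atol=1e-6)
        np.testing.assert_allclose(fit2.p_beta[2:], fit1.p_beta[2:], rtol=1e-3)
        assert fit2.sd_resid_f == pytest.approx(fit1.sd_resid_f, rel=1e-5)
        assert fit2.r2_marginal == pytest.approx(fit1.r2_marginal, abs=1e-6)

    def test_sex_relabel_symmetry(self, base_spec):
        """Swapping sex labels negates both contrasts, swaps the residual
        SDs, and leaves p-values unchanged."""
        ds = generate_trait(base_spec(sd_m=0.18, intercept_m=1.1, seed=31))
        fit1 = fit_allometry(ds)
        swapped = TraitDataset(
            ds.trait_name, ds.functional_group,
            ds.data.assign(sex=ds.data["sex"].map({"male": "female", "female": "male"})),
        )
        fit2 = fit_allometry(swapped)
        np.testing.assert_allclose(fit2.beta[2:], -fit1.beta[2:], atol=1e-5)
        assert fit2.sd_resid_f == pytest.approx(fit1.sd_resid_m, rel=1e-4)
        assert fit2.sd_resid_m == pytest.approx(fit1.sd_resid_f, rel=1e-4)
        np.testing.assert_allclose(fit2.p_beta[2:], fit1.p_beta[2:], rtol=1e-3)

    def test_scenario_c_recovery(self):
        """Scenario C trait (deltas 0.1 / 0.05, sd 0.15 / 0.20, n=3000/sex):
        Wald 95% CIs cover both true contrasts; SD ratio within 5% of 0.75
        (female/male)."""
        spec = spec_from_scenario(
            "C", 0.1, 0.05, trait_name="c_trait", n_f=3000, n_m=3000,
            sd_f=0.15, sd_m=0.20, n_batches=20, var_batch_intercept=0.004, seed=17,
        )
        ds = generate_trait(spec)
        fit = fit_allometry(ds)
        for j, truth in [(2, 0.1), (3, 0.05)]:
            lo = fit.beta[j] - 1.96 * fit.se_beta[j]
            hi = fit.beta[j] + 1.96 * fit.se_beta[j]
            assert lo <= truth <= hi
        assert fit.sd_resid_f / fit.sd_resid_m == pytest.approx(0.75, rel=0.05)


class TestResidualSD:
    def test_equal_sd_recovery(self, base_spec):
        ds = generate_trait(base_spec(n_f=10_000, n_m=10_000, sd_f=0.1, sd_m=0.1, seed=5))
        sd_f, se_f, sd_m, se_m = residual_sd_by_sex(fit_allometry(ds))
        assert sd_f == pytest.approx(0.1, rel=0.03)
        assert sd_m == pytest.approx(0.1, rel=0.03)
        assert se_f > 0 and se_m > 0

    def test_sd_ratio_recovery(self, base_spec):
        ds = generate_trait(base_spec(n_f=5000, n_m=5000, sd_f=0.1, sd_m=0.2, seed=6))
        sd_f, _, sd_m, _ = residual_sd_by_sex(fit_allometry(ds))
        assert sd_m / sd_f == pytest.approx(2.0, rel=0.05)

    def test_sd_se_matches_analytic_information(self, base_spec):
        """With no random effects the observed-information SE of log SD
        should match the analytic 1/sqrt(2(n-1))."""
        ds = generate_trait(base_spec(n_batches=1, var_batch_intercept=0.0, seed=8))
        fit = fit_allometry(ds)
        assert fit.se_log_sd_f == pytest.approx(1 / np.sqrt(2 * (fit.n_f - 1)), rel=0.1)


class TestNakagawaR2:
    def test_noise_free_r2_is_one(self, noise_free_spec):
        fit = fit_allometry(generate_trait(noise_free_spec()))
        r2m, r2c = nakagawa_r2(fit)
        assert r2m == pytest.approx(1.0, abs=1e-6)
        assert r2c == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_r2_near_zero(self, base_spec):
        spec = base_spec(slope_f=0.0, slope_m=0.0, n_batches=1,
                         var_batch_intercept=0.0, n_f=2000, n_m=2000)
        fit = fit_allometry(generate_trait(spec))
        r2m, _ = nakagawa_r2(fit)
        assert r2m < 0.01

    def test_known_variance_partition(self, base_spec):
        """Fixed 0.5, batch 0.25, residual 0.25 => R2m ~ 0.5, R2c ~ 0.75."""
        spec = base_spec(
            n_f=5000, n_m=5000, slope_f=1.0, slope_m=1.0,
            weight_logsd=np.sqrt(0.5), sd_f=0.5, sd_m=0.5,
            n_batches=60, var_batch_intercept=0.25, seed=13,
        )
        fit = fit_allometry(generate_trait(spec))
        r2m, r2c = nakagawa_r2(fit)
        assert r2m == pytest.approx(0.5, abs=0.05)
        assert r2c == pytest.approx(0.75, abs=0.05)
        assert r2m <= r2c <= 1.0


class TestSubstrainComparison:
    def test_single_substrain_not_applicable(self, base_spec):
        cmp_ = compare_substrain_models(generate_trait(base_spec(n_substrains=1)))
        assert not cmp_.applicable

    def test_large_substrain_variance_favours_inclusion(self, base_spec):
        hits = 0
        for seed in range(5):
            spec = base_spec(
                n_f=400, n_m=400, n_substrains=4,
                cov_strain=np.array([[0.5, 0.0], [0.0, 0.001]]), seed=seed + 1,
            )
            cmp_ = compare_substrain_models(generate_trait(spec))
            assert cmp_.applicable
            hits += cmp_.delta_aic > 10 and cmp_.p_value < 0.05
        assert hits >= 4

    def test_null_substrain_variance_small_delta(self, base_spec):
        hits = 0
        for seed in range(5):
            spec = base_spec(n_f=400, n_m=400, n_substrains=4, seed=seed + 50)
            cmp_ = compare_substrain_models(generate_trait(spec))
            hits += cmp_.delta_aic <= 4
        assert hits >= 4

    def test_delta_aic_identity(self, base_spec):
        spec = base_spec(n_f=200, n_m=200, n_substrains=3,
                         cov_strain=np.array([[0.02, 0.0], [0.0, 0.001]]), seed=2)
        cmp_ = compare_substrain_models(generate_trait(spec))
        assert cmp_.delta_aic == pytest.approx(cmp_.aic_without - cmp_.aic_with_substrain)


class TestVarianceMissedByCommonSlope:
    def test_equal_slopes_near_zero(self, base_spec):
        ds = generate_trait(base_spec(n_f=2000, n_m=2000, seed=3))
        fit = fit_allometry(ds)
        assert variance_missed_by_common_slope(ds, fit) < 0.01

    def test_monotone_in_delta_slope(self, base_spec):
        props = []
        for delta in (0.05, 0.15, 0.3):
            spec = spec_from_scenario(
                "A", 0.0, delta, trait_name=f"a_{delta}",
                n_f=2000, n_m=2000, sd_f=0.1, sd_m=0.1,
                n_batches=10, var_batch_intercept=0.004, seed=19,
            )
            ds = generate_trait(spec)
            props.append(variance_missed_by_common_slope(ds, fit_allometry(ds)))
        assert props[0] < props[1] < props[2]

    def test_noise_free_matches_analytic_gap(self):
        """Noise-free scenario A with sexes sharing the weight distribution:
        the missed share equals (delta^2/4) / (b_common^2 + delta^2/4)."""
        b_f, delta = 0.3, 0.2
        spec = spec_from_scenario(
            "A", 0.0, delta, trait_name="a_exact", slope_f=b_f,
            n_f=4000, n_m=4000, sd_f=0.0, sd_m=0.0,
            n_batches=1, var_batch_intercept=0.0,
            weight_logmean_m=float(np.log(22.0)), seed=23,
        )
        ds = generate_trait(spec)
        cfg = FitConfig(heteroscedastic=False)  # exact-line data degenerates varIdent
        fit = fit_allometry(ds, cfg)
        prop = variance_missed_by_common_slope(ds, fit, cfg)
        b_common = b_f + delta / 2.0
        expected = (delta**2 / 4.0) / (b_common**2 + delta**2 / 4.0)
        assert prop == pytest.approx(expected, abs=0.02)
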