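"""Multilevel meta-analysis: REML oracles, intervals, correlation model."""

import numpy as np
import pytest
from scipy import optimize

from sexallometry import (
    EffectSize,
    fit_effect_size_correlations,
    fit_meta_regression,
    fit_multilevel_meta,
    prediction_interval,
)
from sexallometry.effects import effects_to_table
from sexallometry.meta import _MetaREML, CORR_KINDS


def make_effects(y, v, groups=None, tg=None, kind="intercept_diff", state="folded"):
    out = []
    for i, (yi, vi) in enumerate(zip(y, v)):
        out.append(
            EffectSize(
                unit_id=f"u{i}",
                kind=kind,
                es=float(yi),
                se=float(np.sqrt(vi)),
                state=state,
                functional_group=None if groups is None else groups[i],
                trait_group=None if tg is None else tg[i],
            )
        )
    return out


def simulate_hierarchy(rng, k, mu, tau_tg, tau_unit, v_range=(0.001, 0.005), per_group=2):
    n_g = k // per_group
    tg = np.repeat([f"g{j}" for j in range(n_g)], per_group)[:k]
    u_g = rng.normal(0, tau_tg, n_g)
    v = rng.uniform(*v_range, k)
    theta = mu + u_g[[int(t[1:]) for t in tg]] + rng.normal(0, tau_unit, k)
    y = theta + rng.normal(0, np.sqrt(v))
    return y, v, tg


class TestMultilevelMeta:
    def test_homogeneous_limit(self):
        es = make_effects([0.2] * 10, [1e-6] * 10)
        res = fit_multilevel_meta(es)
        assert res.mu == pytest.approx(0.2, abs=1e-4)
        assert res.tau2_total < 1e-5
        assert res.pi95[0] == pytest.approx(res.ci95[0], abs=0.02)
        assert res.significant

    def test_grid_search_oracle_k3(self):
        """REML solution on 3 hand-built effects matches an independent
        grid-search + polish maximizer of the restricted likelihood to 1e-4."""
        y = np.array([0.10, 0.25, 0.18])
        v = np.array([0.004, 0.009, 0.006])
        es = make_effects(y, v)
        res = fit_multilevel_meta(es, random_levels=())
        X = np.ones((3, 1))
        problem = _MetaREML(y, v, X, {})

        # independent maximizer: coarse log-grid then Nelder-Mead polish
        grid = np.linspace(-25, 3, 200)
        best = min(grid, key=lambda g: problem.neg2_reml(np.array([g])))
        polished = optimize.minimize(
            lambda g: problem.neg2_reml(np.asarray(g)), [best],
            method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12},
        )
        beta, _ = problem.gls(polished.x)
        assert res.mu == pytest.approx(float(beta[0]), abs=1e-4)
        assert res.tau2_by_level["unit"] == pytest.approx(
            float(np.exp(polished.x[0])), abs=1e-4
        )

    def test_fixed_effect_limit_identity(self):
        """With all tau2 forced to ~0 the GLS mean equals the inverse-variance
        fixed-effect mean to 1e-8."""
        rng = np.random.default_rng(5)
        y = rng.normal(0.1, 0.05, 20)
        v = rng.uniform(0.001, 0.01, 20)
        problem = _MetaREML(y, v, np.ones((20, 1)), {})
        beta, cov = problem.gls(np.array([-60.0]))
        fixed = np.sum(y / v) / np.sum(1 / v)
        assert float(beta[0]) == pytest.approx(fixed, abs=1e-8)
        assert float(cov[0, 0]) == pytest.approx(1 / np.sum(1 / v), rel=1e-6)

    def test_fixed_effect_se_limit_large_k(self):
        """tau2 = 0 data, large k: se_mu within 1% of (sum 1/v)^(-1/2)."""
        rng = np.random.default_rng(11)
        v = rng.uniform(0.0004, 0.002, 400)
        y = 0.15 + rng.normal(0, np.sqrt(v))
        res = fit_multilevel_meta(make_effects(y, v), random_levels=())
        assert res.se_mu == pytest.approx(1 / np.sqrt(np.sum(1 / v)), rel=0.01)

    def test_recovery_two_level(self):
        """mu and total heterogeneity recovered in a k=300 simulation."""
        rng = np.random.default_rng(2)
        y, v, tg = simulate_hierarchy(rng, 300, mu=0.1, tau_tg=0.05, tau_unit=0.05)
        res = fit_multilevel_meta(make_effects(y, v, tg=tg), random_levels=("trait_group",))
        assert res.ci95[0] < 0.1 < res.ci95[1]
        assert res.tau2_total == pytest.approx(0.005, rel=0.5)

    def test_ordering_invariance(self):
        rng = np.random.default_rng(9)
        y, v, tg = simulate_hierarchy(rng, 40, 0.1, 0.05, 0.05)
        es = make_effects(y, v, tg=tg)
        res1 = fit_multilevel_meta(es, random_levels=("trait_group",))
        perm = rng.permutation(40)
        res2 = fit_multilevel_meta([es[i] for i in perm], random_levels=("trait_group",))
        assert res2.mu == pytest.approx(res1.mu, abs=1e-6)
        assert res2.tau2_total == pytest.approx(res1.tau2_total, rel=1e-3)

    def test_too_few_effects(self):
        with pytest.raises(ValueError):
            fit_multilevel_meta(make_effects([0.1, 0.2], [0.01, 0.01]))


class TestMetaRegression:
    def test_two_group_recovery(self):
        rng = np.random.default_rng(21)
        k = 100
        y1 = 0.05 + rng.normal(0, 0.03, k) + rng.normal(0, 0.02, k)
        y2 = 0.25 + rng.normal(0, 0.03, k) + rng.normal(0, 0.02, k)
        v = np.full(2 * k, 0.0004)
        es = make_effects(
            np.concatenate([y1, y2]), v, groups=["lo"] * k + ["hi"] * k
        )
        res = fit_meta_regression(es)
        tab = res.moderator_estimates.set_index("level")
        assert tab.loc["lo", "ci_lo"] < 0.05 < tab.loc["lo", "ci_hi"]
        assert tab.loc["hi", "ci_lo"] < 0.25 < tab.loc["hi", "ci_hi"]

    def test_identical_groups_share_mu(self):
        rng = np.random.default_rng(3)
        y = 0.1 + rng.normal(0, 0.02, 60)
        v = np.full(60, 0.0004)
        es = make_effects(y, v, groups=list(np.repeat(["a", "b", "c"], 20)))
        res = fit_meta_regression(es)
        mus = res.moderator_estimates["mu"]
        assert mus.max() - mus.min() < 0.03

    def test_singleton_level_excluded(self):
        y = [0.1] * 10 + [0.4]
        v = [0.001] * 11
        es = make_effects(y, v, groups=["a"] * 10 + ["solo"])
        res = fit_meta_regression(es)
        assert res.excluded_levels == ["solo"]
        assert "solo" not in set(res.moderator_estimates["level"]) if res.moderator_estimates is not None else True


class TestPredictionInterval:
    def test_zero_tau_pi_equals_ci(self):
        es = make_effects([0.2] * 12, [1e-6] * 12)
        res = fit_multilevel_meta(es, random_levels=())
        lo, hi = prediction_interval(res)
        assert lo == pytest.approx(res.ci95[0], abs=1e-3)
        assert hi == pytest.approx(res.ci95[1], abs=1e-3)

    def test_pi_widens_with_heterogeneity(self):
        rng = np.random.default_rng(7)
        v = np.full(60, 0.0004)
        base = 0.1 + rng.normal(0, 0.01, 60)
        wide = 0.1 + rng.normal(0, 0.08, 60)
        r1 = fit_multilevel_meta(make_effects(base, v), random_levels=())
        r2 = fit_multilevel_meta(make_effects(wide, v), random_levels=())
        assert (r2.pi95[1] - r2.pi95[0]) > (r1.pi95[1] - r1.pi95[0])
        assert r1.pi95[0] <= r1.ci95[0] and r1.pi95[1] >= r1.ci95[1]


class TestCorrelationModel:
    def _table(self, rng, n=80, rho=0.8, v_scale=1e-6, tau_tg=0.0):
        """Units with latent correlation rho between the first two kinds."""
        cov = np.eye(4) * 0.04
        cov[0, 1] = cov[1, 0] = rho * 0.04
        latent = rng.multivariate_normal(np.zeros(4), cov, size=n)
        mean = np.array([0.5, 0.3, 0.4, 0.6])
        effects = []
        for i in range(n):
            for j, kind in enumerate(CORR_KINDS):
                se = np.sqrt(v_scale)
                effects.append(
                    EffectSize(
                        unit_id=f"u{i}", kind=kind,
                        es=float(mean[j] + latent[i, j] + rng.normal(0, se)),
                        se=float(se), state="log_folded",
                        functional_group="g1" if i % 2 else "g2",
                        trait_group=f"tg{i}",
                    )
                )
        return effects_to_table(effects), latent

    def test_vanishing_sampling_variance_limit(self):
        """v -> 0: the estimate converges to the Pearson correlation of the
        latent draws (after removing group means)."""
        rng = np.random.default_rng(31)
        table, latent = self._table(rng, n=80, rho=0.8)
        res = fit_effect_size_correlations(table, n_boot=0)
        direct = np.corrcoef(latent[:, 0], latent[:, 1])[0, 1]
        assert res.corr[0, 1] == pytest.approx(direct, abs=0.05)
        assert res.corr[0, 1] > 0.6

    def test_independent_latents_near_zero(self):
        rng = np.random.default_rng(13)
        table, _ = self._table(rng, n=100, rho=0.0)
        res = fit_effect_size_correlations(table, n_boot=0)
        off = res.corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.25

    def test_matrix_properties_and_bootstrap_interval(self):
        rng = np.random.default_rng(17)
        table, _ = self._table(rng, n=40, rho=0.8)
        res = fit_effect_size_correlations(table, n_boot=12, seed=4)
        np.testing.assert_allclose(res.corr, res.corr.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(res.corr), 1.0)
        assert np.linalg.eigvalsh(res.corr).min() > -1e-8
        lo, hi = res.pair_interval("intercept_diff", "slope_diff")
        assert lo <= res.corr[0, 1] + 0.2 and hi >= res.corr[0, 1] - 0.2
        assert res.pair_significant("intercept_diff", "slope_diff")

    def test_too_few_units_error(self):
        rng = np.random.default_rng(1)
        table, _ = self._table(rng, n=10)
        with pytest.raises(ValueError, match="at least"):
            fit_effect_size_correlations(table, n_boot=0)
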