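"""Multilevel meta-analysis of folded effect sizes and effect-size correlations.

The univariate model pools one effect-size kind across traits with known
sampling variances v_i and three random levels — functional group, trait
group, and the effect-size identifier (unit level, the meta-analytic
residual):

    y_i = mu + u_fg(i) + u_tg(i) + u_i + e_i,
    u_l ~ N(0, tau_l^2),  e_i ~ N(0, v_i)

Variance components are estimated by REML (log-parameterised, L-BFGS with
restarts), mu by GLS.  The 95% CI is mu +/- z * se_mu; the 95% prediction
interval mu +/- z * sqrt(sum tau^2 + se_mu^2) describes the likely effect of
a future trait and carries the heterogeneity.  Meta-regression replaces the
intercept by per-functional-group means (cell-means coding) with shared
variance components.

The quad-variate correlation model treats each unit's four log-folded
effects as one observation of a latent 4-vector: per-kind functional-group
fixed effects, a diagonal trait-group random effect, an unstructured 4x4
unit-level covariance (the quantity of interest, reported as a correlation
matrix), plus known sampling variances.  Estimation is maximum likelihood;
intervals come from a parametric bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from .effects import EffectSize

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))
DEFAULT_RANDOM_LEVELS = ("functional_group", "trait_group")


@dataclass
class MetaResult:
    """Pooled meta-analytic estimate with CI, PI and variance components."""

    k: int
    mu: float
    se_mu: float
    ci95: tuple[float, float]
    pi95: tuple[float, float]
    tau2_by_level: dict[str, float]
    converged: bool = True
    kind: str | None = None
    moderator: str | None = None
    moderator_estimates: pd.DataFrame | None = None
    excluded_levels: list[str] = field(default_factory=list)
    loglik: float | None = None

    @property
    def significant(self) -> bool:
        """CI excludes zero."""
        return self.ci95[0] > 0.0 or self.ci95[1] < 0.0

    @property
    def tau2_total(self) -> float:
        return float(sum(self.tau2_by_level.values()))


@dataclass
class CorrelationResult:
    """Latent correlation matrix among the four effect-size kinds."""

    kinds: list[str]
    corr: np.ndarray
    cov_unit: np.ndarray
    tau2_trait_group: np.ndarray
    ci95: np.ndarray | None = None  # (4, 4, 2) bootstrap percentile intervals
    n_units: int = 0
    n_boot: int = 0
    converged: bool = True

    def pair_interval(self, kind_a: str, kind_b: str) -> tuple[float, float]:
        i, j = self.kinds.index(kind_a), self.kinds.index(kind_b)
        return tuple(self.ci95[i, j])

    def pair_significant(self, kind_a: str, kind_b: str) -> bool:
        lo, hi = self.pair_interval(kind_a, kind_b)
        return lo > 0.0 or hi < 0.0


def _level_codes(labels: Sequence) -> tuple[np.ndarray, int]:
    cats = pd.Categorical(labels)
    return cats.codes.astype(np.int64), len(cats.categories)


class _MetaREML:
    """REML criterion for the multilevel meta-analytic model."""

    def __init__(
        self,
        y: np.ndarray,
        v: np.ndarray,
        X: np.ndarray,
        levels: dict[str, np.ndarray],
    ):
        self.y = y
        self.v = v
        self.X = X
        self.k, self.p = X.shape
        # indicator matrices for each non-unit random level
        self.level_names = list(levels)
        self.J = []
        for name in self.level_names:
            codes, n_levels = _level_codes(levels[name])
            Z = np.zeros((self.k, n_levels))
            Z[np.arange(self.k), codes] = 1.0
            self.J.append(Z @ Z.T)

    def _V(self, log_tau2: np.ndarray) -> np.ndarray:
        tau2 = np.exp(log_tau2)
        V = np.diag(self.v + tau2[-1])  # unit-level heterogeneity
        for t2, J in zip(tau2[:-1], self.J):
            V = V + t2 * J
        return V

    def neg2_reml(self, log_tau2: np.ndarray) -> float:
        try:
            V = self._V(log_tau2)
            c = cho_factor(V, lower=True)
            ld_V = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
            Vi_X = cho_solve(c, self.X)
            XtViX = self.X.T @ Vi_X
            cx = cho_factor(XtViX, lower=True)
            ld_X = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
            beta = cho_solve(cx, Vi_X.T @ self.y)
            r = self.y - self.X @ beta
            quad = float(r @ cho_solve(c, r))
        except np.linalg.LinAlgError:
            return np.inf
        return (self.k - self.p) * _LOG2PI + ld_V + ld_X + quad

    def gls(self, log_tau2: np.ndarray):
        V = self._V(log_tau2)
        c = cho_factor(V, lower=True)
        Vi_X = cho_solve(c, self.X)
        XtViX = self.X.T @ Vi_X
        cov_beta = np.linalg.inv(XtViX)
        beta = cov_beta @ (Vi_X.T @ self.y)
        return beta, cov_beta


def _fit_meta_core(
    y: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    levels: dict[str, np.ndarray],
    n_starts: int = 3,
    seed: int = 0,
) -> tuple[_MetaREML, np.ndarray, bool]:
    problem = _MetaREML(y, v, X, levels)
    n_par = len(levels) + 1
    rng = np.random.default_rng(seed + 77)
    base = np.full(n_par, np.log(max(np.var(y), 1e-4) / n_par))
    best, ok = None, False
    for attempt in range(n_starts):
        start = base if attempt == 0 else base + rng.normal(0, 1.0, n_par)
        res = optimize.minimize(
            problem.neg2_reml,
            start,
            method="L-BFGS-B",
            bounds=[(-30.0, 10.0)] * n_par,
            options={"maxiter": 500, "ftol": 1e-10},
        )
        if res.success and np.isfinite(res.fun):
            if best is None or res.fun < best.fun - 1e-9:
                best, ok = res, True
            if attempt == 0:
                break
    if best is None:
        best = optimize.OptimizeResult(x=base, fun=problem.neg2_reml(base))
    return problem, np.asarray(best.x), ok


def _effects_arrays(es_list: Sequence[EffectSize]):
    kinds = {e.kind for e in es_list}
    states = {e.state for e in es_list}
    if len(kinds) > 1 or len(states) > 1:
        raise ValueError("all effect sizes must share kind and state")
    y = np.array([e.es for e in es_list], dtype=float)
    v = np.array([e.variance for e in es_list], dtype=float)
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    fg = np.array([e.functional_group or "all" for e in es_list])
    tg = np.array([e.trait_group or e.unit_id for e in es_list])
    return y, v, fg, tg, kinds.pop()


def fit_multilevel_meta(
    es_list: Sequence[EffectSize],
    random_levels: Sequence[str] = DEFAULT_RANDOM_LEVELS,
    seed: int = 0,
) -> MetaResult:
    """Intercept-only multilevel meta-analysis of one effect-size kind.

    ``random_levels`` selects the grouping random effects (functional group
    and/or trait group); the unit level is always present.  Levels with a
    single category contribute nothing and collapse gracefully.
    """
    if len(es_list) < 3:
        raise ValueError("need at least 3 effect sizes")
    y, v, fg, tg, kind = _effects_arrays(es_list)
    X = np.ones((len(y), 1))
    level_map = {}
    if "functional_group" in random_levels and len(set(fg)) > 1:
        level_map["functional_group"] = fg
    if "trait_group" in random_levels and len(set(tg)) > 1:
        level_map["trait_group"] = tg

    problem, log_tau2, ok = _fit_meta_core(y, v, X, level_map, seed=seed)
    beta, cov_beta = problem.gls(log_tau2)
    mu = float(beta[0])
    se_mu = float(np.sqrt(cov_beta[0, 0]))
    tau2 = dict(zip(list(level_map) + ["unit"], np.exp(log_tau2)))
    z = norm.ppf(0.975)
    ci = (mu - z * se_mu, mu + z * se_mu)
    pi_sd = np.sqrt(sum(tau2.values()) + se_mu**2)
    pi = (mu - z * pi_sd, mu + z * pi_sd)
    return MetaResult(
        k=len(y),
        mu=mu,
        se_mu=se_mu,
        ci95=ci,
        pi95=pi,
        tau2_by_level=tau2,
        converged=ok,
        kind=kind,
        loglik=-0.5 * problem.neg2_reml(log_tau2),
    )


def fit_meta_regression(
    es_list: Sequence[EffectSize],
    moderator: str = "functional_group",
    random_levels: Sequence[str] = ("trait_group",),
    seed: int = 0,
) -> MetaResult:
    """Meta-regression with a categorical moderator (cell-means coding).

    Per-level pooled estimates with CI and PI share the variance components;
    moderator levels with a single effect size are excluded with a logged
    reason.  A single-level moderator falls back to the intercept-only model
    with a warning.
    """
    all_es = list(es_list)
    labels = np.array([getattr(e, moderator) or "all" for e in es_list])
    counts = pd.Series(labels).value_counts()
    excluded = sorted(counts[counts < 2].index)
    if excluded:
        logger.info("moderator levels with k = 1 excluded: %s", excluded)
        keep = ~np.isin(labels, excluded)
        es_list = [e for e, k in zip(es_list, keep) if k]
        labels = labels[keep]
    level_names = sorted(set(labels))
    if len(level_names) < 2:
        logger.warning("moderator has a single usable level; falling back to intercept model")
        res = fit_multilevel_meta(all_es, random_levels=random_levels, seed=seed)
        res.moderator = moderator
        res.excluded_levels = excluded
        return res

    y, v, fg, tg, kind = _effects_arrays(es_list)
    X = np.zeros((len(y), len(level_names)))
    for j, name in enumerate(level_names):
        X[labels == name, j] = 1.0
    level_map = {}
    if "trait_group" in random_levels and len(set(tg)) > 1:
        level_map["trait_group"] = tg

    problem, log_tau2, ok = _fit_meta_core(y, v, X, level_map, seed=seed)
    beta, cov_beta = problem.gls(log_tau2)
    tau2 = dict(zip(list(level_map) + ["unit"], np.exp(log_tau2)))
    z = norm.ppf(0.975)
    pi_var = sum(tau2.values())
    rows = []
    for j, name in enumerate(level_names):
        mu_j = float(beta[j])
        se_j = float(np.sqrt(cov_beta[j, j]))
        rows.append(
            {
                "level": name,
                "k": int((labels == name).sum()),
                "mu": mu_j,
                "se": se_j,
                "ci_lo": mu_j - z * se_j,
                "ci_hi": mu_j + z * se_j,
                "pi_lo": mu_j - z * np.sqrt(pi_var + se_j**2),
                "pi_hi": mu_j + z * np.sqrt(pi_var + se_j**2),
            }
        )
    table = pd.DataFrame(rows)
    # overall weighted mean for the headline fields
    w = 1.0 / (np.diag(cov_beta))
    mu = float(np.sum(beta * w) / np.sum(w))
    se_mu = float(np.sqrt(1.0 / np.sum(w)))
    return MetaResult(
        k=len(y),
        mu=mu,
        se_mu=se_mu,
        ci95=(mu - z * se_mu, mu + z * se_mu),
        pi95=(mu - z * np.sqrt(pi_var + se_mu**2), mu + z * np.sqrt(pi_var + se_mu**2)),
        tau2_by_level=tau2,
        converged=ok,
        kind=kind,
        moderator=moderator,
        moderator_estimates=table,
        excluded_levels=excluded,
        loglik=-0.5 * problem.neg2_reml(log_tau2),
    )


def prediction_interval(result: MetaResult, level: str | None = None) -> tuple[float, float]:
    """95% prediction interval, overall or for one moderator level."""
    if not result.converged:
        raise ValueError("meta-model did not converge")
    if level is None:
        return result.pi95
    if result.moderator_estimates is None:
        raise ValueError("result has no moderator levels")
    row = result.moderator_estimates.set_index("level").loc[level]
    return float(row["pi_lo"]), float(row["pi_hi"])


# ---------------------------------------------------------------------------
# quad-variate correlation model
# ---------------------------------------------------------------------------

CORR_KINDS = ["intercept_diff", "slope_diff", "sd_diff", "fit_zr"]


def _corr_from_chol(params: np.ndarray) -> np.ndarray:
    """4x4 covariance from a 10-vector log-Cholesky parameterisation."""
    L = np.zeros((4, 4))
    k = 0
    for i in range(4):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(params[k])
            else:
                L[i, j] = params[k]
            k += 1
    return L @ L.T


class _QuadVariateML:
    """Marginal ML for the quad-variate latent-correlation model.

    Per unit u in trait group g with fixed-effect row x_u:
        y_u = B' x_u + eta_g + theta_u + e_u
    eta_g ~ N(0, diag(tau2)), theta_u ~ N(0, Sigma_unit) (unstructured),
    e_u ~ N(0, diag(v_u)) known.  Blocks factorise by trait group.
    """

    def __init__(self, Y, V, Xf, tg_codes):
        self.Y = Y          # (n, 4)
        self.V = V          # (n, 4) sampling variances
        self.Xf = Xf        # (n, g) fixed-effect design (per kind, shared)
        self.tg = tg_codes  # (n,)
        self.n = Y.shape[0]
        self.groups = [np.flatnonzero(tg_codes == c) for c in np.unique(tg_codes)]
        self.p = Xf.shape[1]
        # per-block constants (design kron and stacked responses)
        self._Xb = [np.kron(Xf[idx], np.eye(4)) for idx in self.groups]
        self._yb = [Y[idx].reshape(-1) for idx in self.groups]

    @staticmethod
    def split(params):
        return params[:10], np.exp(params[10:14])

    def _block_cov(self, idx, Sigma, tau2):
        m = len(idx)
        d = 4 * m
        C = np.zeros((d, d))
        T = np.diag(tau2)
        for a in range(m):
            sa = slice(4 * a, 4 * a + 4)
            C[sa, sa] = Sigma + T + np.diag(self.V[idx[a]])
            for b in range(a + 1, m):
                sb = slice(4 * b, 4 * b + 4)
                C[sa, sb] = T
                C[sb, sa] = T
        return C

    def neg2ll(self, params: np.ndarray) -> float:
        chol_par, tau2 = self.split(params)
        Sigma = _corr_from_chol(chol_par)
        # profile fixed effects by GLS across blocks
        p4 = 4 * self.p
        XtViX = np.zeros((p4, p4))
        XtViy = np.zeros(p4)
        pieces = []
        try:
            for g, idx in enumerate(self.groups):
                C = self._block_cov(idx, Sigma, tau2)
                c = cho_factor(C, lower=True)
                yb = self._yb[g]
                Xb = self._Xb[g]
                ViX = cho_solve(c, Xb)
                XtViX += Xb.T @ ViX
                XtViy += ViX.T @ yb
                pieces.append((c, yb, Xb))
            beta = np.linalg.solve(XtViX, XtViy)
            out = 0.0
            for c, yb, Xb in pieces:
                r = yb - Xb @ beta
                out += 2.0 * float(np.sum(np.log(np.diag(c[0]))))
                out += float(r @ cho_solve(c, r))
            out += 4.0 * self.n * _LOG2PI
        except np.linalg.LinAlgError:
            return np.inf
        return out


def _complete_units_table(es_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a log-folded effect table to one row per unit with all 4 kinds."""
    t = es_table[es_table["kind"].isin(CORR_KINDS)]
    wide_es = t.pivot_table(index="unit_id", columns="kind", values="es")
    wide_v = t.pivot_table(index="unit_id", columns="kind", values="variance")
    complete = wide_es.dropna().index.intersection(wide_v.dropna().index)
    meta_cols = t.drop_duplicates("unit_id").set_index("unit_id")
    out = pd.DataFrame(index=complete)
    for k in CORR_KINDS:
        out[f"es_{k}"] = wide_es.loc[complete, k]
        out[f"v_{k}"] = wide_v.loc[complete, k]
    out["functional_group"] = meta_cols.loc[complete, "functional_group"]
    out["trait_group"] = meta_cols.loc[complete, "trait_group"].fillna(
        pd.Series(complete, index=complete)
    )
    return out


def fit_effect_size_correlations(
    es_table: pd.DataFrame,
    moderator: str = "functional_group",
    n_boot: int = 200,
    seed: int = 0,
    min_units: int = 20,
) -> CorrelationResult:
    """Correlations among the four effect-size kinds (log-folded scale).

    ``es_table`` is the tidy output of
    :func:`sexallometry.effects.effects_to_table` in ``log_folded`` state.
    Units missing any kind are dropped; fewer than ``min_units`` complete
    units is an error.  Returns the unit-level latent correlation matrix with
    parametric-bootstrap percentile intervals (``n_boot`` refits; a pair is
    "significant" when its interval excludes zero).
    """
    wide = _complete_units_table(es_table)
    n = len(wide)
    if n < min_units:
        raise ValueError(f"need at least {min_units} complete units, got {n}")

    Y = wide[[f"es_{k}" for k in CORR_KINDS]].to_numpy(dtype=float)
    V = wide[[f"v_{k}" for k in CORR_KINDS]].to_numpy(dtype=float)
    labels = wide[moderator].astype(str).to_numpy() if moderator else np.repeat("all", n)
    levels = sorted(set(labels))
    Xf = np.zeros((n, len(levels)))
    for j, name in enumerate(levels):
        Xf[labels == name, j] = 1.0
    tg_codes, n_tg_levels = _level_codes(wide["trait_group"].astype(str))
    # with all-singleton trait groups the group variance is confounded with
    # the unit-level diagonal; drop the random effect in that case
    has_tg = n_tg_levels < n

    def fit_once(Y_, seed_) -> tuple[np.ndarray, np.ndarray, bool]:
        prob = _QuadVariateML(Y_, V, Xf, tg_codes)
        resid = Y_ - Xf @ np.linalg.lstsq(Xf, Y_, rcond=None)[0]
        S0 = np.cov(resid.T) + 1e-6 * np.eye(4)
        L0 = np.linalg.cholesky(S0)
        start = []
        for i in range(4):
            for j in range(i + 1):
                start.append(np.log(L0[i, j]) if i == j else L0[i, j])
        chol_bounds = [
            (-12.0, 6.0) if i in (0, 2, 5, 9) else (-20.0, 20.0) for i in range(10)
        ]
        if has_tg:
            start += [np.log(max(np.trace(S0) / 40.0, 1e-6))] * 4
            tau_bounds = [(-25.0, 5.0)] * 4
        else:
            start += [-25.0] * 4
            tau_bounds = [(-25.0, -25.0)] * 4
        res = optimize.minimize(
            prob.neg2ll,
            np.asarray(start),
            method="L-BFGS-B",
            bounds=chol_bounds + tau_bounds,
            options={"maxiter": 400, "ftol": 1e-9},
        )
        chol_par, tau2 = prob.split(res.x)
        Sigma = _corr_from_chol(chol_par)
        return Sigma, tau2, bool(res.success)

    Sigma, tau2, ok = fit_once(Y, seed)
    d = np.sqrt(np.diag(Sigma))
    corr = Sigma / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed + 991)
        beta_hat = np.linalg.lstsq(Xf, Y, rcond=None)[0]
        mean = Xf @ beta_hat
        boots = np.empty((n_boot, 4, 4))
        n_tg = int(tg_codes.max()) + 1
        chol_S = np.linalg.cholesky(Sigma + 1e-10 * np.eye(4))
        for b in range(n_boot):
            eta = rng.normal(size=(n_tg, 4)) * np.sqrt(tau2)
            theta = rng.normal(size=(n, 4)) @ chol_S.T
            e = rng.normal(size=(n, 4)) * np.sqrt(V)
            Yb = mean + eta[tg_codes] + theta + e
            Sb, _, _ = fit_once(Yb, seed + b)
            db = np.sqrt(np.diag(Sb))
            cb = Sb / np.outer(db, db)
            np.fill_diagonal(cb, 1.0)
            boots[b] = cb
        ci = np.stack(
            [np.percentile(boots, 2.5, axis=0), np.percentile(boots, 97.5, axis=0)],
            axis=-1,
        )

    return CorrelationResult(
        kinds=list(CORR_KINDS),
        corr=corr,
        cov_unit=Sigma,
        tau2_trait_group=tau2,
        ci95=ci,
        n_units=n,
        n_boot=n_boot,
        converged=ok,
    )


def meta_to_dict(result: MetaResult) -> dict:
    d = {
        "k": result.k,
        "kind": result.kind,
        "mu": result.mu,
        "se_mu": result.se_mu,
        "ci95": list(result.ci95),
        "pi95": list(result.pi95),
        "tau2": result.tau2_by_level,
        "significant": result.significant,
        "converged": result.converged,
    }
    if result.moderator_estimates is not None:
        d["moderator"] = result.moderator
        d["levels"] = result.moderator_estimates.to_dict(orient="records")
    return d


def orchard_export(es_list: Sequence[EffectSize], result: MetaResult) -> pd.DataFrame:
    """Unit-level effects plus model rows, directly plottable as an orchard
    plot (point estimate, CI, PI per group)."""
    rows = [
        {
            "row_type": "effect",
            "unit_id": e.unit_id,
            "level": e.functional_group,
            "es": e.es,
            "se": e.se,
            "n": e.n_total,
        }
        for e in es_list
    ]
    if result.moderator_estimates is not None:
        for _, r in result.moderator_estimates.iterrows():
            rows.append(
                {
                    "row_type": "model",
                    "unit_id": f"pooled[{r['level']}]",
                    "level": r["level"],
                    "es": r["mu"],
                    "se": r["se"],
                    "ci_lo": r["ci_lo"],
                    "ci_hi": r["ci_hi"],
                    "pi_lo": r["pi_lo"],
                    "pi_hi": r["pi_hi"],
                }
            )
    else:
        rows.append(
            {
                "row_type": "model",
                "unit_id": "pooled",
                "level": "all",
                "es": result.mu,
                "se": result.se_mu,
                "ci_lo": result.ci95[0],
                "ci_hi": result.ci95[1],
                "pi_lo": result.pi95[0],
                "pi_hi": result.pi95[1],
            }
        )
    return pd.DataFrame(rows)
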