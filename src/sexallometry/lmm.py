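"""Heteroscedastic linear mixed models for static allometry, fit by REML.

Per trait, the model on the log-log scale is::

    log(value) ~ gmc(log(weight)) * sex
                 + (1 | batch)
                 + (gmc(log(weight)) | metadata_group)
                 + (gmc(log(weight)) | substrain)

with sex-specific residual variances (group-wise heteroscedasticity).  The
fixed-effect vector is (female intercept, female slope, sex contrast on
intercept, sex contrast on slope); because the continuous predictor is
grand-mean-centred, the intercepts are predicted values for a female or male
of average weight and the intercept contrast is a log response ratio.

Estimation maximises the restricted likelihood with the scaled-covariance
("penalized least squares") formulation: random-effect covariances are
expressed relative to the female residual variance through a relative
Cholesky factor Lambda, the female residual variance and the fixed effects
are profiled out, and the criterion is optimised over a low-dimensional
vector of variance parameters (log scales and Cholesky off-diagonals for
2x2 intercept/slope blocks, plus the log residual-SD ratio male/female).
Random terms whose grouping factor has a single level are dropped and
recorded.  Cross-products are precomputed per sex, so each criterion
evaluation costs only small dense linear algebra regardless of n.

The restricted log-likelihood convention used throughout (and by the dense
oracle in the tests) is

    -2 l_R = (n - p) log(2 pi) + log|V| + log|X' V^-1 X| + r' V^-1 r

with r the GLS residual at the profiled fixed effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.stats import chi2, t as t_dist

from .dataset import NotConvergedError, SingleSexError, TraitDataset

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FitConfig:
    """Optimizer and inference settings for :func:`fit_allometry`."""

    min_per_sex: int = 20
    heteroscedastic: bool = True
    n_starts: int = 3          # jittered restarts before declaring failure
    jitter_sd: float = 0.7
    tol: float = 1e-8
    max_iter: int = 500
    df_rule: str = "innermost"  # "innermost" (t) or "normal" (z)
    log_bound: float = 8.0      # |log scale| bound for variance parameters


@dataclass
class RandomTerm:
    name: str
    codes: np.ndarray       # 0-based level codes, shape (n,)
    n_levels: int
    with_slope: bool

    @property
    def n_cols(self) -> int:
        return self.n_levels * (2 if self.with_slope else 1)

    @property
    def n_theta(self) -> int:
        return 3 if self.with_slope else 1


@dataclass
class AllometryFit:
    """Fitted allometric mixed model for one trait."""

    trait_name: str
    converged: bool
    n_f: int
    n_m: int
    beta: np.ndarray | None = None          # (f intercept, f slope, d intercept, d slope)
    se_beta: np.ndarray | None = None
    p_beta: np.ndarray | None = None
    df_resid: float | None = None
    sd_resid_f: float | None = None
    sd_resid_m: float | None = None
    se_log_sd_f: float | None = None
    se_log_sd_m: float | None = None
    varcomp: dict | None = None
    var_fixed: float | None = None
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    loglik: float | None = None
    aic: float | None = None
    n_params: int | None = None
    grand_mean_log_weight: float | None = None
    dropped_random_terms: list[str] = field(default_factory=list)
    opt_par: np.ndarray | None = None   # variance parameters at the optimum
    interaction: bool = True
    functional_group: str | None = None
    message: str = ""

    # convenience accessors -------------------------------------------------
    @property
    def intercept_f(self) -> float:
        return float(self.beta[0])

    @property
    def slope_f(self) -> float:
        return float(self.beta[1])

    @property
    def intercept_m(self) -> float:
        return float(self.beta[0] + self.beta[2])

    @property
    def slope_m(self) -> float:
        return float(self.beta[1] + self.beta[3]) if self.interaction else self.slope_f

    @property
    def contrast_intercept(self) -> tuple[float, float, float]:
        """(estimate, SE, p) of the male - female intercept contrast."""
        return float(self.beta[2]), float(self.se_beta[2]), float(self.p_beta[2])

    @property
    def contrast_slope(self) -> tuple[float, float, float]:
        if not self.interaction:
            raise ValueError("model fitted without the sex x weight interaction")
        return float(self.beta[3]), float(self.se_beta[3]), float(self.p_beta[3])

    @property
    def n_total(self) -> int:
        return self.n_f + self.n_m


@dataclass
class ModelComparison:
    """AIC comparison of the model with vs without the sub-strain random term."""

    trait_name: str
    applicable: bool
    aic_with_substrain: float | None = None
    aic_without: float | None = None
    delta_aic: float | None = None
    lrt_statistic: float | None = None
    p_value: float | None = None
    reason: str = ""
    # convention: restricted likelihoods with identical fixed effects; LRT
    # p halved for the variance-component boundary (50:50 mixture on 3 df)


def center_log_weight(ds: TraitDataset) -> tuple[np.ndarray, float]:
    """Grand-mean-centred log body weight and the grand mean of log weight.

    The grand mean pools both sexes, so the model intercepts refer to an
    average-weight animal regardless of sex.
    """
    w = ds.data["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    logw = np.log(w)
    gm = float(logw.mean())
    return logw - gm, gm


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _codes(series: pd.Series) -> tuple[np.ndarray, int]:
    cats = pd.Categorical(series)
    return cats.codes.astype(np.int64), len(cats.categories)


def build_design(
    ds: TraitDataset,
    interaction: bool = True,
    include_substrain: bool = True,
) -> dict:
    """Assemble the fixed design, response, sex mask and random terms."""
    x, gm = center_log_weight(ds)
    sex = ds.data["sex"].to_numpy()
    male = (sex == "male").astype(float)
    if male.min() == male.max():
        raise SingleSexError(f"trait {ds.trait_name!r} has a single sex")
    y = np.log(ds.data["trait_value"].to_numpy(dtype=float))
    if interaction:
        X = np.column_stack([np.ones_like(x), x, male, male * x])
        names = ["intercept_f", "slope", "sex_male", "sex_male:slope"]
    else:
        X = np.column_stack([np.ones_like(x), x, male])
        names = ["intercept_f", "slope", "sex_male"]

    terms: list[RandomTerm] = []
    dropped: list[str] = []
    spec = [("batch", False), ("metadata_group", True)]
    if include_substrain:
        spec.append(("substrain", True))
    for col, with_slope in spec:
        codes, n_levels = _codes(ds.data[col])
        if n_levels <= 1:
            dropped.append(col)
        else:
            terms.append(RandomTerm(col, codes, n_levels, with_slope))

    return {
        "X": X,
        "beta_names": names,
        "y": y,
        "x": x,
        "male": male.astype(bool),
        "grand_mean": gm,
        "terms": terms,
        "dropped": dropped,
    }


def _build_Z(terms: Sequence[RandomTerm], x: np.ndarray) -> sparse.csr_matrix | None:
    n = len(x)
    blocks = []
    for term in terms:
        rows = np.arange(n)
        if term.with_slope:
            row = np.concatenate([rows, rows])
            col = np.concatenate([2 * term.codes, 2 * term.codes + 1])
            dat = np.concatenate([np.ones(n), x])
        else:
            row, col, dat = rows, term.codes, np.ones(n)
        blocks.append(sparse.csr_matrix((dat, (row, col)), shape=(n, term.n_cols)))
    if not blocks:
        return None
    return sparse.hstack(blocks, format="csr")


def _lambda_from_theta(terms: Sequence[RandomTerm], theta: np.ndarray) -> np.ndarray:
    """Relative covariance factor (block diagonal, dense) from the variance
    parameters: intercept-only terms use exp(theta); (intercept, slope)
    blocks use a log-Cholesky parameterisation (log d1, off, log d2)."""
    q = sum(t.n_cols for t in terms)
    lam = np.zeros((q, q))
    pos = 0
    k = 0
    for term in terms:
        if term.with_slope:
            l11 = np.exp(theta[k])
            l21 = theta[k + 1]
            l22 = np.exp(theta[k + 2])
            k += 3
            block = np.array([[l11, 0.0], [l21, l22]])
            for j in range(term.n_levels):
                i = pos + 2 * j
                lam[i : i + 2, i : i + 2] = block
            pos += term.n_cols
        else:
            s = np.exp(theta[k])
            k += 1
            for j in range(term.n_levels):
                lam[pos + j, pos + j] = s
            pos += term.n_cols
    return lam


class _REMLProblem:
    """Profiled REML criterion with per-sex precomputed cross-products."""

    def __init__(self, design: dict, heteroscedastic: bool = True):
        X, y, male = design["X"], design["y"], design["male"]
        self.n, self.p = X.shape
        self.male = male
        self.n_m = int(male.sum())
        self.terms = design["terms"]
        self.het = heteroscedastic
        self.n_theta = sum(t.n_theta for t in self.terms)
        self.n_par = self.n_theta + (1 if heteroscedastic else 0)

        Z = _build_Z(self.terms, design["x"])
        self.q = 0 if Z is None else Z.shape[1]
        f, m = ~male, male
        self.XtX = (X[f].T @ X[f], X[m].T @ X[m])
        self.Xty = (X[f].T @ y[f], X[m].T @ y[m])
        self.yty = (float(y[f] @ y[f]), float(y[m] @ y[m]))
        if Z is not None:
            Zf, Zm = Z[f], Z[m]
            self.ZtZ = ((Zf.T @ Zf).toarray(), (Zm.T @ Zm).toarray())
            self.ZtX = (Zf.T @ X[f], Zm.T @ X[m])
            self.Zty = (Zf.T @ y[f], Zm.T @ y[m])
        self.Z = Z

    def split(self, par: np.ndarray) -> tuple[np.ndarray, float]:
        theta = par[: self.n_theta]
        log_r = par[self.n_theta] if self.het else 0.0
        return theta, float(log_r)

    def _assemble(self, w: float):
        ZtWZ = self.ZtZ[0] + w * self.ZtZ[1] if self.q else None
        ZtWX = self.ZtX[0] + w * self.ZtX[1] if self.q else None
        ZtWy = self.Zty[0] + w * self.Zty[1] if self.q else None
        XtWX = self.XtX[0] + w * self.XtX[1]
        XtWy = self.Xty[0] + w * self.Xty[1]
        ytWy = self.yty[0] + w * self.yty[1]
        return ZtWZ, ZtWX, ZtWy, XtWX, XtWy, ytWy

    def profiled_pieces(self, par: np.ndarray):
        """Solve the penalized least squares problem at the given variance
        parameters; returns (pwrss, ldL2, ldRX2, logdetW, beta, RX, lam)."""
        theta, log_r = self.split(par)
        w = np.exp(-2.0 * log_r)  # male residual weight = (sd_f/sd_m)^2
        ZtWZ, ZtWX, ZtWy, XtWX, XtWy, ytWy = self._assemble(w)
        logdetW = self.n_m * np.log(w)

        if self.q:
            lam = _lambda_from_theta(self.terms, theta)
            A = lam.T @ ZtWZ @ lam + np.eye(self.q)
            L = cholesky(A, lower=True)
            RZX = solve_triangular(L, lam.T @ ZtWX, lower=True)
            cu = solve_triangular(L, lam.T @ ZtWy, lower=True)
            RXtRX = XtWX - RZX.T @ RZX
            ldL2 = 2.0 * float(np.sum(np.log(np.diag(L))))
        else:
            lam, L, RZX, cu = None, None, None, None
            RXtRX = XtWX
            ldL2 = 0.0

        RX = cho_factor(RXtRX, lower=True)
        ldRX2 = 2.0 * float(np.sum(np.log(np.diag(RX[0]))))
        rhs = XtWy - (RZX.T @ cu if self.q else 0.0)
        beta = cho_solve(RX, rhs)
        cu_beta = (cu - RZX @ beta) if self.q else None
        pwrss = ytWy - float(beta @ XtWy)
        if self.q:
            pwrss -= float(cu_beta @ cu)
        pwrss = max(pwrss, 1e-300)
        return pwrss, ldL2, ldRX2, logdetW, beta, RX, lam, (L, cu_beta)

    def deviance(self, par: np.ndarray) -> float:
        """Profiled -2 restricted log-likelihood.

        Numerically degenerate parameter points (failed factorizations at
        extreme scales) return a large finite penalty sloping back toward
        the feasible region, so gradient-based line searches stay usable.
        """
        try:
            pwrss, ldL2, ldRX2, logdetW, *_ = self.profiled_pieces(par)
            nmp = self.n - self.p
            sigma2 = pwrss / nmp
            dev = nmp * (_LOG2PI + np.log(sigma2) + 1.0) + ldL2 + ldRX2 - logdetW
        except np.linalg.LinAlgError:
            dev = np.nan
        if not np.isfinite(dev):
            return 1e10 * (1.0 + float(np.sum(np.square(par))))
        return dev

    def deviance_unprofiled(self, par: np.ndarray, log_sigma_f: float) -> float:
        """-2 restricted log-likelihood with the female residual SD explicit
        (used for the observed-information SEs of the residual SDs)."""
        try:
            pwrss, ldL2, ldRX2, logdetW, *_ = self.profiled_pieces(par)
        except np.linalg.LinAlgError:
            return np.inf
        nmp = self.n - self.p
        sigma2 = np.exp(2.0 * log_sigma_f)
        return (
            nmp * (_LOG2PI + np.log(sigma2))
            + ldL2
            + ldRX2
            - logdetW
            + pwrss / sigma2
        )


def _start_values(problem: _REMLProblem) -> np.ndarray:
    start = []
    for term in problem.terms:
        if term.with_slope:
            start += [-1.0, 0.0, -1.0]
        else:
            start += [-1.0]
    if problem.het:
        start += [0.0]
    return np.asarray(start, dtype=float)


def _hessian(f, x0: np.ndarray, step: float = 1e-4) -> np.ndarray:
    k = len(x0)
    H = np.empty((k, k))
    h = step * (1.0 + np.abs(x0))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _extract_varcomp(problem: _REMLProblem, lam: np.ndarray | None, sigma2_f: float) -> dict:
    out: dict[str, object] = {}
    pos = 0
    if lam is None:
        return out
    for term in problem.terms:
        if term.with_slope:
            block = lam[pos : pos + 2, pos : pos + 2]
            cov = sigma2_f * (block @ block.T)
            out[term.name] = {
                "cov": cov,
                "var_intercept": float(cov[0, 0]),
                "var_slope": float(cov[1, 1]),
                "corr": float(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))
                if cov[0, 0] > 0 and cov[1, 1] > 0
                else 0.0,
            }
        else:
            s = lam[pos, pos]
            out[term.name] = {"var_intercept": float(sigma2_f * s * s)}
        pos += term.n_cols
    return out


def fit_allometry(
    ds: TraitDataset,
    cfg: FitConfig | None = None,
    interaction: bool = True,
    include_substrain: bool = True,
) -> AllometryFit:
    """Fit the heteroscedastic allometric mixed model for one trait.

    Returns an :class:`AllometryFit`; non-convergence is reported through
    ``converged=False`` rather than an exception, so a pipeline can skip the
    trait.  Random terms with a single level are dropped and listed in
    ``dropped_random_terms``.

    Raises
    ------
    SingleSexError
        If only one sex is present (the sex-contrast model is undefined).
    ValueError
        If either sex has fewer than ``cfg.min_per_sex`` observations or any
        trait value is non-positive.
    """
    cfg = cfg or FitConfig()
    values = ds.data["trait_value"].to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError(
            f"trait {ds.trait_name!r} has non-positive values; adjust to ratio scale first"
        )
    design = build_design(ds, interaction=interaction, include_substrain=include_substrain)
    n_f = int((~design["male"]).sum())
    n_m = int(design["male"].sum())
    if min(n_f, n_m) < cfg.min_per_sex:
        raise ValueError(
            f"trait {ds.trait_name!r}: fewer than min_per_sex={cfg.min_per_sex} "
            f"observations in one sex ({n_f}F/{n_m}M)"
        )

    problem = _REMLProblem(design, heteroscedastic=cfg.heteroscedastic)
    fit = AllometryFit(
        trait_name=ds.trait_name,
        converged=False,
        n_f=n_f,
        n_m=n_m,
        dropped_random_terms=design["dropped"],
        interaction=interaction,
        functional_group=ds.functional_group,
        grand_mean_log_weight=design["grand_mean"],
    )

    rng = np.random.default_rng(12345)
    x0 = _start_values(problem)
    bounds = []
    k = 0
    for term in problem.terms:
        if term.with_slope:
            bounds += [(-cfg.log_bound, cfg.log_bound), (-50.0, 50.0),
                       (-cfg.log_bound, cfg.log_bound)]
        else:
            bounds += [(-cfg.log_bound, cfg.log_bound)]
    if problem.het:
        bounds += [(-cfg.log_bound, cfg.log_bound)]

    def _polish(res):
        """Nelder-Mead refinement from the gradient-based solution; keeps
        whichever point has the lower criterion."""
        nm = optimize.minimize(
            problem.deviance,
            res.x,
            method="Nelder-Mead",
            options={
                "xatol": 1e-7,
                "fatol": cfg.tol,
                "maxfev": 400 * max(len(res.x), 1),
            },
        )
        return nm if nm.fun < res.fun else res

    best = None
    for attempt in range(cfg.n_starts):
        start = x0 if attempt == 0 else x0 + rng.normal(0.0, cfg.jitter_sd, size=len(x0))
        if len(start) == 0:
            best = optimize.OptimizeResult(x=start, fun=problem.deviance(start), success=True)
            break
        res = optimize.minimize(
            problem.deviance,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": cfg.max_iter, "ftol": cfg.tol, "gtol": 1e-7, "eps": 1e-6},
        )
        res = _polish(res)
        if np.isfinite(res.fun) and res.fun < 1e9:
            best = res if best is None or res.fun < best.fun else best
            break
        if best is None or (np.isfinite(res.fun) and res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e9:
        fit.message = "optimizer failed"
        return fit

    par = np.asarray(best.x, dtype=float)
    pwrss, ldL2, ldRX2, logdetW, beta, RX, lam, _ = problem.profiled_pieces(par)
    n, p = problem.n, problem.p
    sigma2_f = pwrss / (n - p)
    theta, log_r = problem.split(par)
    sd_f = float(np.sqrt(sigma2_f))
    sd_m = float(sd_f * np.exp(log_r)) if cfg.heteroscedastic else sd_f

    cov_beta = sigma2_f * cho_solve(RX, np.eye(p))
    se_beta = np.sqrt(np.diag(cov_beta))

    if cfg.df_rule == "innermost" and problem.terms:
        innermost = max(t.n_levels for t in problem.terms)
        df = max(n - p - innermost, 1)
    else:
        df = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se_beta
    p_beta = np.clip(2.0 * t_dist.sf(np.abs(tstat), df), 1e-300, 1.0)

    # observed-information SEs for the per-sex log residual SDs
    log_sigma_f = np.log(sd_f)
    if cfg.heteroscedastic:
        def dev_full(phi: np.ndarray) -> float:
            return problem.deviance_unprofiled(phi[:-1], phi[-1])

        phi0 = np.concatenate([par, [log_sigma_f]])
        try:
            H = 0.5 * _hessian(dev_full, phi0)
            cov_phi = np.linalg.inv(H)
            i_r = problem.n_theta          # index of log_r in par
            i_s = len(phi0) - 1            # index of log_sigma_f
            v_s = cov_phi[i_s, i_s]
            v_m = cov_phi[i_s, i_s] + cov_phi[i_r, i_r] + 2.0 * cov_phi[i_s, i_r]
            if v_s <= 0 or v_m <= 0:
                raise np.linalg.LinAlgError
            se_log_sd_f = float(np.sqrt(v_s))
            se_log_sd_m = float(np.sqrt(v_m))
        except np.linalg.LinAlgError:
            se_log_sd_f = float(np.sqrt(1.0 / (2.0 * (n_f - 1))))
            se_log_sd_m = float(np.sqrt(1.0 / (2.0 * (n_m - 1))))
    else:
        se_log_sd_f = se_log_sd_m = float(np.sqrt(1.0 / (2.0 * (n - p))))

    varcomp = _extract_varcomp(problem, lam, sigma2_f)

    # variance partition for marginal / conditional R^2
    X = design["X"]
    fitted_fixed = X @ beta
    var_fixed = float(np.var(fitted_fixed))
    var_random = sum(vc["var_intercept"] for vc in varcomp.values())
    var_resid = 0.5 * (sd_f**2 + sd_m**2)
    denom = var_fixed + var_random + var_resid
    r2m = var_fixed / denom if denom > 0 else 0.0
    r2c = (var_fixed + var_random) / denom if denom > 0 else 0.0

    loglik = -0.5 * problem.deviance(par)
    n_params = p + problem.n_par + 1  # beta + variance parameters + sigma_f
    fit.converged = True
    fit.opt_par = par
    fit.beta = np.asarray(beta, dtype=float)
    fit.se_beta = se_beta
    fit.p_beta = p_beta
    fit.df_resid = float(df)
    fit.sd_resid_f = sd_f
    fit.sd_resid_m = sd_m
    fit.se_log_sd_f = se_log_sd_f
    fit.se_log_sd_m = se_log_sd_m
    fit.varcomp = varcomp
    fit.var_fixed = var_fixed
    fit.r2_marginal = float(min(max(r2m, 0.0), 1.0))
    fit.r2_conditional = float(min(max(r2c, r2m), 1.0))
    fit.loglik = float(loglik)
    fit.aic = float(-2.0 * loglik + 2.0 * n_params)
    fit.n_params = n_params
    return fit


def residual_sd_by_sex(fit: AllometryFit) -> tuple[float, float, float, float]:
    """Per-sex residual SDs with standard errors, ``(sd_f, se_f, sd_m, se_m)``.

    SEs come from the observed information of the restricted likelihood on
    the log-SD scale, back-transformed (``se_sd = sd * se_log_sd``).
    """
    if not fit.converged:
        raise NotConvergedError(f"trait {fit.trait_name!r} did not converge")
    return (
        fit.sd_resid_f,
        fit.sd_resid_f * fit.se_log_sd_f,
        fit.sd_resid_m,
        fit.sd_resid_m * fit.se_log_sd_m,
    )


def nakagawa_r2(fit: AllometryFit) -> tuple[float, float]:
    """Marginal and conditional R-squared of a converged fit.

    Marginal: variance of the fixed-effect predictions over the total
    (fixed + random-intercept-scale + mean residual) variance.  Conditional
    adds the random-effect variance to the numerator.
    """
    if not fit.converged:
        raise NotConvergedError(f"trait {fit.trait_name!r} did not converge")
    return fit.r2_marginal, fit.r2_conditional


def compare_substrain_models(ds: TraitDataset, cfg: FitConfig | None = None) -> ModelComparison:
    """AIC comparison of the applied model vs the model without sub-strain.

    Only applicable when the trait has more than one sub-strain.  Both models
    share identical fixed effects, so restricted-likelihood AICs are
    comparable; the likelihood-ratio p-value for the three sub-strain
    covariance parameters is halved for the boundary (50:50 mixture).
    """
    if ds.n_substrains <= 1:
        return ModelComparison(ds.trait_name, applicable=False, reason="single sub-strain")
    full = fit_allometry(ds, cfg, include_substrain=True)
    reduced = fit_allometry(ds, cfg, include_substrain=False)
    if not (full.converged and reduced.converged):
        return ModelComparison(
            ds.trait_name, applicable=False, reason="a model did not converge"
        )
    lrt = max(0.0, -2.0 * (reduced.loglik - full.loglik))
    p = float(np.clip(0.5 * chi2.sf(lrt, df=3), 1e-300, 1.0))
    return ModelComparison(
        trait_name=ds.trait_name,
        applicable=True,
        aic_with_substrain=full.aic,
        aic_without=reduced.aic,
        delta_aic=reduced.aic - full.aic,
        lrt_statistic=lrt,
        p_value=p,
    )


def variance_missed_by_common_slope(
    ds: TraitDataset, fit: AllometryFit, cfg: FitConfig | None = None
) -> float | None:
    """Share of the explained variance lost by forcing a common slope.

    Refits without the sex x weight interaction and returns the drop in
    marginal R-squared as a proportion of the full model's marginal
    R-squared, in [0, 1]; ``None`` if the reduced fit fails.
    """
    if not fit.converged:
        raise NotConvergedError(f"trait {fit.trait_name!r} did not converge")
    reduced = fit_allometry(ds, cfg, interaction=False)
    if not reduced.converged:
        logger.info("reduced (common-slope) fit failed for %r", ds.trait_name)
        return None
    if fit.r2_marginal <= 0:
        return 0.0
    prop = (fit.r2_marginal - reduced.r2_marginal) / fit.r2_marginal
    return float(min(max(prop, 0.0), 1.0))


def fits_to_table(fits: Sequence[AllometryFit]) -> pd.DataFrame:
    """One tidy row per trait with all scalar fit quantities."""
    rows = []
    for f in fits:
        row = {
            "trait_name": f.trait_name,
            "functional_group": f.functional_group,
            "converged": f.converged,
            "n_f": f.n_f,
            "n_m": f.n_m,
        }
        if f.converged:
            row.update(
                intercept_f=f.intercept_f,
                intercept_m=f.intercept_m,
                slope_f=f.slope_f,
                slope_m=f.slope_m,
                contrast_intercept=f.beta[2],
                se_contrast_intercept=f.se_beta[2],
                p_contrast_intercept=f.p_beta[2],
                contrast_slope=f.beta[3] if f.interaction else np.nan,
                se_contrast_slope=f.se_beta[3] if f.interaction else np.nan,
                p_contrast_slope=f.p_beta[3] if f.interaction else np.nan,
                sd_resid_f=f.sd_resid_f,
                sd_resid_m=f.sd_resid_m,
                r2_marginal=f.r2_marginal,
                r2_conditional=f.r2_conditional,
                loglik=f.loglik,
                aic=f.aic,
                dropped_random_terms=",".join(f.dropped_random_terms),
            )
        rows.append(row)
    return pd.DataFrame(rows)
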