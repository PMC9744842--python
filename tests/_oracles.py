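"""Independent oracles shared by the unit and acceptance tests.

These deliberately avoid the package's own computational paths: dense
marginal-covariance likelihood evaluation, eigendecomposition-based Li-Ji
merging, and brute-force grid maximizers.
"""

import numpy as np
from scipy.stats import chi2

from sexallometry.lmm import _build_Z, _lambda_from_theta


def dense_reml_neg2ll(design, par, problem):
    """-2 restricted log-likelihood by explicit construction of the marginal
    covariance matrix: slogdet factorizations and a GLS residual."""
    X, y, x, male = design["X"], design["y"], design["x"], design["male"]
    n, p = X.shape
    pwrss, *_ = problem.profiled_pieces(par)
    sigma2_f = pwrss / (n - p)
    theta, log_r = problem.split(par)
    if problem.q:
        Z = _build_Z(design["terms"], x).toarray()
        lam = _lambda_from_theta(design["terms"], theta)
        G = sigma2_f * (lam @ lam.T)
        V = Z @ G @ Z.T
    else:
        V = np.zeros((n, n))
    V = V + np.diag(np.where(male, sigma2_f * np.exp(2 * log_r), sigma2_f))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld_V = np.linalg.slogdet(V)
    _, ld_X = np.linalg.slogdet(XtViX)
    return (n - p) * np.log(2 * np.pi) + ld_V + ld_X + float(r @ Vi @ r)


def eigen_li_ji_merge(p_list, r):
    """Li-Ji/Fisher merged p via numpy eigendecomposition of the explicit
    equicorrelation matrix."""
    p = np.asarray(p_list, dtype=float)
    k = len(p)
    if k == 1:
        return float(p[0])
    R = np.full((k, k), r)
    np.fill_diagonal(R, 1.0)
    lam = np.round(np.linalg.eigvalsh(R), 10)  # de-fuzz integer eigenvalues
    m_eff = float(np.sum((lam >= 1) + (lam - np.floor(lam))))
    fisher = -2.0 * np.sum(np.log(p))
    return float(chi2.sf(fisher * m_eff / k, df=2 * m_eff))
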