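"""Brute-force REML/GLS reference for tiny mixed-model instances.

Independent of the package's fitting path: the marginal covariance
V = sum_k s_k^2 Z_k Z_k' + s_e^2 I is assembled explicitly, the REML
log-likelihood

    l = -1/2 [ log|V| + log|X' V^-1 X| + r' V^-1 r ],   r = y - X b_gls

is evaluated by dense linear algebra, and the variance parameters are found
by direct numerical optimisation with multiple starts.  Only feasible for a
handful of observations, which is the point.
"""

import numpy as np
from scipy import optimize


def reml_loglik(log_sds, y, X, Z_list):
    """REML log-likelihood at variance parameters exp(log_sds).

    log_sds orders the random-effect SDs first (one per Z in Z_list) and the
    residual SD last.
    """
    sds = np.exp(np.asarray(log_sds, dtype=float))
    n = len(y)
    V = sds[-1] ** 2 * np.eye(n)
    for s, Z in zip(sds[:-1], Z_list):
        V += s**2 * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    A = XtVinv @ X
    beta = np.linalg.solve(A, XtVinv @ y)
    r = y - X @ beta
    sign1, logdetV = np.linalg.slogdet(V)
    sign2, logdetA = np.linalg.slogdet(A)
    if sign1 <= 0 or sign2 <= 0:
        return -np.inf
    return -0.5 * (logdetV + logdetA + r @ Vinv @ r)


def gls_beta_cov(sds, y, X, Z_list):
    """GLS fixed effects and their covariance at fixed variance parameters."""
    n = len(y)
    V = sds[-1] ** 2 * np.eye(n)
    for s, Z in zip(sds[:-1], Z_list):
        V += s**2 * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    cov = np.linalg.inv(A)
    beta = cov @ X.T @ Vinv @ y
    return beta, cov


def reml_fit(y, X, Z_list, n_starts=8, seed=0):
    """Maximise the REML log-likelihood by brute-force multi-start BFGS."""
    rng = np.random.default_rng(seed)
    k = len(Z_list) + 1
    best = None
    starts = [np.zeros(k) - 1.5] + [rng.uniform(-4, 0.5, size=k) for _ in range(n_starts - 1)]
    for x0 in starts:
        res = optimize.minimize(
            lambda p: -reml_loglik(p, y, X, Z_list),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    sds = np.exp(best.x)
    beta, cov = gls_beta_cov(sds, y, X, Z_list)
    return {"beta": beta, "cov": cov, "sds": sds, "loglik": -best.fun}


def site_indicator(sites):
    """n x m indicator matrix of site membership."""
    sites = np.asarray(sites)
    uniq = np.unique(sites)
    return (sites[:, None] == uniq[None, :]).astype(float)
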