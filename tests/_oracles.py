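"""Independent reference implementations used to validate the package.

These oracles deliberately avoid the package's own solvers: REML is computed
by direct optimization of the restricted likelihood on the observation-level
covariance V, and kernel predictions come from the closed-form kernel-ridge
solution.  They are slow but straightforward to audit.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def direct_reml_neg2ll(log_s2, y, X, ZK_list):
    """-2 restricted log-likelihood evaluated on V (up to the same constant
    convention as the package: log|V| + log|X'Vinv X| + y'Py)."""
    s2 = np.exp(np.asarray(log_s2, dtype=float))
    n = y.size
    V = s2[-1] * np.eye(n)
    for (Z, K), s in zip(ZK_list, s2[:-1]):
        V += s * (Z @ Z.T if K is None else Z @ K @ Z.T)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return np.inf
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    sign2, logdetX = np.linalg.slogdet(XtVX)
    if sign2 <= 0:
        return np.inf
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    return logdetV + logdetX + float(r @ Vinv @ r)


def direct_reml(y, X, ZK_list, starts=None, maxiter=4000):
    """Brute-force REML: Nelder-Mead over log variance components.

    ZK_list is a list of (Z, K-or-None) pairs; the residual component is
    implicit.  Returns (variances array incl. residual last, loglik).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    c = len(ZK_list) + 1
    vary = float(np.var(y))
    if starts is None:
        starts = [np.full(c, np.log(vary / c)),
                  np.full(c, np.log(vary / c)) + np.linspace(-1, 1, c)]
    best = None
    for x0 in starts:
        res = minimize(direct_reml_neg2ll, x0, args=(y, X, ZK_list),
                       method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-12,
                                "maxfev": maxiter * c, "maxiter": maxiter * c})
        if best is None or res.fun < best.fun:
            best = res
    return np.exp(best.x), -0.5 * float(best.fun)


def gls_intercept(y, V):
    """GLS estimate of the intercept under covariance V."""
    Vinv_1 = np.linalg.solve(V, np.ones_like(y))
    return float(Vinv_1 @ y) / float(Vinv_1 @ np.ones_like(y))


def kernel_ridge_predict(y, K, s2g, s2e):
    """Closed-form BLUP of g in y = 1*mu + g + e, g ~ N(0, K s2g):
    g_hat = s2g K (s2g K + s2e I)^-1 (y - mu), with mu from GLS."""
    n = y.size
    V = s2g * K + s2e * np.eye(n)
    mu = gls_intercept(y, V)
    return s2g * (K @ np.linalg.solve(V, y - mu)), mu


def mme_blup(y, X, Z, K, s2u, s2e):
    """Henderson MME solution at fixed variances (independent oracle)."""
    n = y.size
    V = s2u * (Z @ K @ Z.T) + s2e * np.eye(n)
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    u = s2u * (K @ Z.T @ (Vinv @ (y - X @ beta)))
    return beta, u
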