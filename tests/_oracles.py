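"""Independent reference implementations used only as test oracles.

Everything here is deliberately naive and dense so it shares no code
path with the package: scalar Cox-de Boor recursion for spline values,
a dense-matrix Newton iteration for coefficient estimates, and dense
inversion for variances.
"""

import numpy as np
from scipy.special import gammaln


def deboor(x, t, r, k=3):
    """Value of the r-th degree-k B-spline at scalar x, by the raw
    Cox-de Boor recursion on knot vector t."""
    if k == 0:
        # half-open intervals; close the last one
        if t[r] <= x < t[r + 1]:
            return 1.0
        if x == t[-1] and t[r] < x <= t[r + 1]:
            return 1.0
        return 0.0
    left = 0.0
    if t[r + k] > t[r]:
        left = (x - t[r]) / (t[r + k] - t[r]) * deboor(x, t, r, k - 1)
    right = 0.0
    if t[r + k + 1] > t[r + 1]:
        right = (t[r + k + 1] - x) / (t[r + k + 1] - t[r + 1]) * deboor(x, t, r + 1, k - 1)
    return left + right


def dense_penalized_loglik(y, o, X, S, lam, theta, eps, beta):
    eta = o + X @ beta
    mu = np.exp(eta)
    ll = np.sum(gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
                + theta * (np.log(theta) - np.log(theta + mu))
                + np.where(y > 0, y * (np.log(mu) - np.log(theta + mu)), 0.0))
    P = lam * (S + eps * np.eye(S.shape[0]))
    return ll - beta @ P @ beta


def dense_newton(y, o, X, S, lam, theta, eps, beta0, tol=1e-10, max_iter=100):
    """Dense Newton-Raphson on the penalized NB log-likelihood, written
    from the formulas with numpy.linalg only."""
    X = np.asarray(X)
    S = np.asarray(S)
    beta = np.asarray(beta0, dtype=float).copy()
    P = lam * (S + eps * np.eye(S.shape[0]))
    obj = dense_penalized_loglik(y, o, X, S, lam, theta, eps, beta)
    for _ in range(max_iter):
        mu = np.exp(o + X @ beta)
        u = y - (y + theta) * mu / (mu + theta)
        g = X.T @ u - 2 * P @ beta
        if np.abs(g).max() < tol:
            break
        w = -theta * mu * (y + theta) / (mu + theta) ** 2
        H = X.T @ (w[:, None] * X) - 2 * P
        step = np.linalg.solve(H, g)
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            new = dense_penalized_loglik(y, o, X, S, lam, theta, eps, cand)
            if new >= obj - 1e-12 * (1 + abs(obj)):
                break
            scale *= 0.5
        beta = cand
        obj = new
    return beta


def dense_variances(H_block, basis_dense):
    """diag(X (-H)^{-1} X') by explicit dense inversion."""
    cov = np.linalg.inv(-np.asarray(H_block))
    return np.einsum("ij,jk,ik->i", basis_dense, cov, basis_dense)
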