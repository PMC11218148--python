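"""Independent reference implementations used only to cross-check the
package: a cyclic coordinate-descent elastic-net solver and a KKT
residual evaluator. Deliberately written from the optimality conditions,
sharing no code with the package's fitting path."""

import numpy as np


def _soft(x, thresh):
    return np.sign(x) * max(abs(x) - thresh, 0.0)


def enet_coordinate_descent(X, y, alpha, lam, tol=1e-12, max_iter=200_000):
    """Minimise (1/2n)||y - b - Xw||^2 + lam*(alpha*||w||_1
    + (1-alpha)/2*||w||_2^2) by cyclic coordinate descent.

    Returns (intercept, coef). Convergence: max parameter change per
    full sweep below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.zeros(p)
    b = float(y.mean())
    col_sq = (X ** 2).sum(axis=0) / n
    r = y - b - X @ w
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            if col_sq[j] == 0.0:
                continue
            r += X[:, j] * w[j]
            rho = float(X[:, j] @ r) / n
            new = _soft(rho, lam * alpha) / (col_sq[j] + lam * (1 - alpha))
            delta = max(delta, abs(new - w[j]))
            w[j] = new
            r -= X[:, j] * w[j]
        b_new = b + float(r.mean())
        r -= b_new - b
        delta = max(delta, abs(b_new - b))
        b = b_new
        if delta < tol:
            break
    return b, w


def enet_kkt_residuals(X, y, intercept, coef, alpha, lam):
    """Subgradient (KKT) residual per coordinate plus the intercept
    stationarity residual, evaluated from the optimality conditions."""
    X = np.asarray(X, dtype=float)
    n = len(y)
    r = y - intercept - X @ coef
    grad = -(X.T @ r) / n + lam * (1 - alpha) * coef
    res = np.empty(len(coef))
    for j, w in enumerate(coef):
        if w != 0.0:
            res[j] = abs(grad[j] + lam * alpha * np.sign(w))
        else:
            res[j] = max(0.0, abs(grad[j]) - lam * alpha)
    return res, abs(float(r.mean()))
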