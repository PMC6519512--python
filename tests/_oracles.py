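"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the code paths under test: the LASSO oracle is a
plain proximal-gradient (ISTA) loop, and the SVM oracle solves the primal
soft-margin quadratic program with SLSQP on (w, b, slack).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def ista_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    n_iter: int = 200_000,
    tol: float = 1e-14,
) -> tuple[np.ndarray, float]:
    """Proximal-gradient minimizer of (1/2n)||y - Xb - b0||^2 + lam*||b||_1."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    L = np.linalg.eigvalsh(X.T @ X / n).max() + 1e-12
    beta = np.zeros(p)
    b0 = y.mean()
    for _ in range(n_iter):
        resid = X @ beta + b0 - y
        grad = X.T @ resid / n
        new = beta - grad / L
        new = np.sign(new) * np.maximum(np.abs(new) - lam / L, 0.0)
        b0_new = float(np.mean(y - X @ new))
        if np.max(np.abs(new - beta)) < tol and abs(b0_new - b0) < tol:
            beta, b0 = new, b0_new
            break
        beta, b0 = new, b0_new
    return beta, b0


def lasso_objective(X, y, beta, b0, lam) -> float:
    resid = y - X @ beta - b0
    return float(resid @ resid) / (2 * len(y)) + lam * float(np.abs(beta).sum())


def qp_hinge_svm(X: np.ndarray, y01: np.ndarray, cost: float) -> float:
    """Optimal primal objective of the linear soft-margin SVM.

    Solves min 1/2||w||^2 + C*sum(xi) s.t. xi >= 0, xi >= 1 - s_i(w.x_i+b)
    with s = ±1 labels, via SLSQP on the stacked variable (w, b, xi).
    """
    X = np.asarray(X, float)
    s = np.where(np.asarray(y01, int) == 1, 1.0, -1.0)
    n, p = X.shape

    def objective(z):
        w = z[:p]
        xi = z[p + 1 :]
        return 0.5 * w @ w + cost * xi.sum()

    def jac(z):
        g = np.zeros_like(z)
        g[:p] = z[:p]
        g[p + 1 :] = cost
        return g

    constraints = []
    for i in range(n):

        def margin(z, i=i):
            w, b, xi = z[:p], z[p], z[p + 1 :]
            return xi[i] - (1.0 - s[i] * (X[i] @ w + b))

        constraints.append({"type": "ineq", "fun": margin})
    bounds = [(None, None)] * (p + 1) + [(0.0, None)] * n
    z0 = np.zeros(p + 1 + n)
    z0[p + 1 :] = 1.0
    best = np.inf
    for scale in (1.0, 0.1):
        res = minimize(
            objective,
            z0 * scale,
            jac=jac,
            bounds=bounds,
            constraints=constraints,
            method="SLSQP",
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        best = min(best, res.fun)
    return float(best)
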