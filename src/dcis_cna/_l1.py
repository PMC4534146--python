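"""L1-penalized logistic regression by cyclic coordinate descent.

Minimizes the glmnet-scale objective

    f(b0, b) = (1/n) * sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ]
               + lam * sum_j |b_j|,          eta = b0 + X b

with an unpenalized intercept.  The solver follows the standard penalized
GLM scheme: an outer iteratively-reweighted quadratic approximation of the
log-likelihood (weights frozen per outer step) with inner cyclic coordinate
descent and soft-thresholding on the weighted least-squares subproblem;
warm starts along a decreasing lambda path keep the iteration count small.
The hot loop is numba-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lambda_max", "fit_l1_path", "fit_l1_fixed", "l1_objective"]


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda that zeroes every slope at the intercept-only fit."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    p0 = y.mean()
    return float(np.max(np.abs(X.T @ (y - p0))) / n)


def l1_objective(X, y, intercept, beta, lam) -> float:
    """Penalized average negative log-likelihood (the quantity minimized)."""
    eta = intercept + X @ beta
    n = len(y)
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta)) / n
    return nll + lam * float(np.sum(np.abs(beta)))


@njit(cache=True)
def _cd_path(X, y, lams, tol, max_outer):  # pragma: no cover - numba
    n, p = X.shape
    L = lams.shape[0]
    coefs = np.zeros((L, p))
    intercepts = np.zeros(L)

    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar)) if 0.0 < ybar < 1.0 else 0.0
    beta = np.zeros(p)
    eta = np.full(n, b0)
    w = np.empty(n)
    s = np.empty(n)  # working residual z - b0 - X beta on the w scale
    h = np.empty(p)

    for li in range(L):
        lam = lams[li]
        for outer in range(max_outer):
            # quadratic approximation at the current estimate
            sw = 0.0
            for i in range(n):
                pi = 1.0 / (1.0 + np.exp(-eta[i]))
                wi = pi * (1.0 - pi)
                if wi < 1e-6:
                    wi = 1e-6
                w[i] = wi
                s[i] = (y[i] - pi) / wi
                sw += wi
            sw /= n
            for j in range(p):
                hj = 0.0
                for i in range(n):
                    hj += w[i] * X[i, j] * X[i, j]
                h[j] = hj / n

            # inner CD on the penalized weighted least-squares subproblem
            outer_step = 0.0
            for sweep in range(200):
                max_step = 0.0
                g0 = 0.0
                for i in range(n):
                    g0 += w[i] * s[i]
                d0 = g0 / n / sw
                if d0 != 0.0:
                    b0 += d0
                    for i in range(n):
                        s[i] -= d0
                    if abs(d0) > max_step:
                        max_step = abs(d0)
                for j in range(p):
                    if h[j] <= 0.0:
                        continue
                    g = 0.0
                    for i in range(n):
                        if X[i, j] != 0.0:
                            g += w[i] * X[i, j] * s[i]
                    g /= n
                    u = g + h[j] * beta[j]
                    if u > lam:
                        bj_new = (u - lam) / h[j]
                    elif u < -lam:
                        bj_new = (u + lam) / h[j]
                    else:
                        bj_new = 0.0
                    d = bj_new - beta[j]
                    if d != 0.0:
                        beta[j] = bj_new
                        for i in range(n):
                            if X[i, j] != 0.0:
                                s[i] -= d * X[i, j]
                        if abs(d) > max_step:
                            max_step = abs(d)
                if max_step > outer_step:
                    outer_step = max_step
                if max_step < 0.1 * tol:
                    break
            # refresh the linear predictor after the quadratic solve
            for i in range(n):
                ei = b0
                for j in range(p):
                    if beta[j] != 0.0 and X[i, j] != 0.0:
                        ei += beta[j] * X[i, j]
                eta[i] = ei
            if outer_step < tol:
                break
        coefs[li] = beta
        intercepts[li] = b0
    return intercepts, coefs


def fit_l1_path(
    X: np.ndarray,
    y: np.ndarray,
    lams: np.ndarray,
    tol: float = 1e-6,
    max_outer: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the lambda path (decreasing) with warm starts.

    Returns ``(intercepts, coefs)`` with ``coefs`` of shape
    ``(len(lams), n_features)``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lams = np.ascontiguousarray(lams, dtype=np.float64)
    return _cd_path(X, y, lams, tol, max_outer)


def fit_l1_fixed(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-9,
    max_outer: int = 500,
) -> tuple[float, np.ndarray]:
    """Fit at a single fixed lambda (no warm start)."""
    b0, B = fit_l1_path(X, y, np.array([lam]), tol=tol, max_outer=max_outer)
    return float(b0[0]), B[0]
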