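"""Lightweight PLS1 (NIPALS) returning coefficients for every component count.

CARS needs thousands of small PLSR fits (leave-one-out CV inside each Monte
Carlo run), and each fit must be scored at several component counts. A single
NIPALS pass yields nested coefficient vectors for 1..A components, which makes
leave-one-out affordable; sklearn's PLSRegression is the reference
implementation the results are checked against in the test suite.
"""

from __future__ import annotations

import numpy as np

from .errors import FitError

__all__ = ["pls1_coefficients", "loo_rmse_by_components"]


def pls1_coefficients(X: np.ndarray, y: np.ndarray, max_components: int):
    """Fit PLS1 and return coefficients for all component counts.

    Returns ``(B, intercepts)`` where ``B[a-1]`` is the p-vector of regression
    coefficients using ``a`` latent components (on the original, uncentered
    scale) and ``intercepts[a-1]`` the matching intercept. The number of
    extracted components may be less than ``max_components`` if the residual
    collapses early; remaining rows repeat the last valid solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != len(y):
        raise FitError("X and y sample counts differ")
    A = int(min(max_components, n - 1, p))
    if A < 1:
        raise FitError("need at least one extractable component")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    E = X - x_mean
    f = y - y_mean

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    n_extracted = 0
    for a in range(A):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(1.0, np.abs(f).max(initial=0.0)):
            break
        w /= nw
        t = E @ w
        tt = t @ t
        if tt <= 0:
            break
        P[:, a] = E.T @ t / tt
        q[a] = f @ t / tt
        W[:, a] = w
        E = E - np.outer(t, P[:, a])
        f = f - q[a] * t
        n_extracted = a + 1

    if n_extracted == 0:
        # y uncorrelated with X (or constant): coefficient is zero, mean model
        B = np.zeros((A, p))
        intercepts = np.full(A, y_mean)
        return B, intercepts

    B = np.zeros((A, p))
    intercepts = np.zeros(A)
    # R maps original X columns to scores: T = Xc R, with R = W (P' W)^-1
    PtW = P[:, :n_extracted].T @ W[:, :n_extracted]
    for a in range(1, n_extracted + 1):
        Ra = W[:, :a] @ np.linalg.solve(PtW[:a, :a], np.eye(a))
        beta = Ra @ q[:a]
        B[a - 1] = beta
        intercepts[a - 1] = y_mean - x_mean @ beta
    for a in range(n_extracted, A):
        B[a] = B[n_extracted - 1]
        intercepts[a] = intercepts[n_extracted - 1]
    return B, intercepts


def loo_rmse_by_components(X: np.ndarray, y: np.ndarray, max_components: int):
    """Leave-one-out RMSE for each component count 1..A (one fit per sample)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    A = int(min(max_components, n - 2, X.shape[1]))
    if A < 1:
        raise FitError("too few samples for leave-one-out PLS")
    sq = np.zeros(A)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        B, c = pls1_coefficients(X[mask], y[mask], A)
        pred = B @ X[i] + c
        sq += (pred - y[i]) ** 2
        mask[i] = True
    return np.sqrt(sq / n)
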