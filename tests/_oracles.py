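"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately uses a different algorithm (or a different
library) from the code path it checks.
"""
import math

import numpy as np


def brute_savgol(x, y, window, poly, deriv):
    """Per-window polynomial least squares, interior points only.

    Fits a degree-``poly`` polynomial to each window centred on a point and
    returns the ``deriv``-th derivative of the fit at the centre (per
    x-unit). Edge points are NaN.
    """
    h = window // 2
    out = np.full(y.size, np.nan)
    for i in range(h, y.size - h):
        xs = x[i - h : i + h + 1] - x[i]
        coef = np.polynomial.polynomial.polyfit(xs, y[i - h : i + h + 1], poly)
        out[i] = math.factorial(deriv) * coef[deriv]
    return out


def brute_lower_hull(x, y):
    """O(n^2) gift-wrapping lower convex hull; returns vertex indices.

    From each hull vertex, the next vertex is the point of minimum slope;
    among (numerically) equal slopes the farthest point wins, so collinear
    interior points are skipped as in a monotone-chain hull.
    """
    n = len(x)
    hull = [0]
    i = 0
    while i < n - 1:
        best = i + 1
        best_slope = (y[i + 1] - y[i]) / (x[i + 1] - x[i])
        for j in range(i + 2, n):
            slope = (y[j] - y[i]) / (x[j] - x[i])
            if slope < best_slope - 1e-12 * max(1.0, abs(best_slope)):
                best, best_slope = j, slope
            elif slope <= best_slope + 1e-12 * max(1.0, abs(best_slope)):
                best = j  # collinear: take the farthest point
        hull.append(best)
        i = best
    return np.asarray(hull)


def svd_pls(X, y, a_max):
    """PLS1 via per-component SVD of the cross-covariance, with deflation.

    Returns ``(x_mean, y_mean, beta_by_a)`` where ``beta_by_a[a]`` is the
    coefficient vector for a truncation of ``a + 1`` components.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    p = X.shape[1]
    W = np.empty((p, a_max))
    P = np.empty((p, a_max))
    q = np.empty(a_max)
    for a in range(a_max):
        C = (Xc.T @ yc).reshape(-1, 1)
        U, _, _ = np.linalg.svd(C, full_matrices=False)
        w = U[:, 0]
        t = Xc @ w
        tt = t @ t
        pa = Xc.T @ t / tt
        qa = (yc @ t) / tt
        Xc = Xc - np.outer(t, pa)
        yc = yc - qa * t
        W[:, a], P[:, a], q[a] = w, pa, qa
    betas = []
    for a in range(1, a_max + 1):
        betas.append(W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a]))
    return x_mean, y_mean, betas


def svd_pls_predict(X_train, y_train, X_test, a):
    x_mean, y_mean, betas = svd_pls(X_train, y_train, a)
    return y_mean + (np.asarray(X_test, float) - x_mean) @ betas[a - 1]


def explicit_loocv_rmsecv(X, y, a_max):
    """LOOCV RMSECV per component count via an explicit refit loop over the
    SVD-based PLS oracle."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    press = np.zeros(a_max)
    for i in range(n):
        keep = np.arange(n) != i
        for a in range(1, a_max + 1):
            pred = svd_pls_predict(X[keep], y[keep], X[i : i + 1], a)[0]
            press[a - 1] += (y[i] - pred) ** 2
    return np.sqrt(press / n)
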