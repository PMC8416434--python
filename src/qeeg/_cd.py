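"""Elastic-net penalized logistic regression by coordinate descent.

glmnet-style solver: an outer iteratively-reweighted least squares (IRLS)
quadratic approximation to the binomial log-likelihood, an inner cyclic
coordinate descent with soft-thresholding on the penalized weighted least
squares problem, and warm starts down a descending lambda path. The
objective for one lambda is

    (1/n) sum_i log(1 + exp(-y~_i eta_i))
        + lambda * (alpha ||beta||_1 + (1 - alpha)/2 ||beta||_2^2)

with alpha the lasso/ridge mixing weight and the intercept unpenalized.
Columns are assumed standardized by the caller (mean 0, variance 1); the
returned coefficients are on that standardized scale.

The hot loops are numba-jitted: the permutation-test x cross-validation
workload runs hundreds of thousands of path fits, which rules out
general-purpose solvers at this problem size.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PMIN = 1e-5  # probability clamp, as in glmnet
_WMIN = 1e-5  # working-weight floor


@njit(cache=True, inline="always")
def _cd_sweep(X, wv, r, beta, den, active_only, lam_l1, lam_l2, pf, n):
    """One coordinate-descent pass; returns the largest coefficient change."""
    p = X.shape[1]
    max_delta = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        num = 0.0
        for i in range(X.shape[0]):
            num += wv[i] * X[i, j] * r[i]
        num = num / n + den[j] * bj
        l1_j = lam_l1 * pf[j]
        d_j = den[j] + lam_l2 * pf[j]
        if num > l1_j:
            bn = (num - l1_j) / d_j
        elif num < -l1_j:
            bn = (num + l1_j) / d_j
        else:
            bn = 0.0
        d = bn - bj
        if d != 0.0:
            beta[j] = bn
            for i in range(X.shape[0]):
                r[i] -= X[i, j] * d
            if abs(d) > max_delta:
                max_delta = abs(d)
    return max_delta


@njit(cache=True)
def _cd_quadratic(X, wv, z, beta, b0, lam_l1, lam_l2, pf, tol, max_sweeps):
    """Coordinate descent on the penalized weighted LS subproblem.

    Full passes alternate with cheap active-set passes; the weighted
    column norms (denominators) are fixed within one subproblem.
    ``pf`` holds per-feature penalty factors (0 leaves a column, e.g. a
    covariate, unpenalized).
    """
    n, p = X.shape
    sw = wv.sum()
    r = z - b0 - X @ beta
    den = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += wv[i] * X[i, j] * X[i, j]
        den[j] = s / n
    sweeps = 0
    while sweeps < max_sweeps:
        # intercept (unpenalized)
        num0 = 0.0
        for i in range(n):
            num0 += wv[i] * r[i]
        d0 = num0 / sw
        if d0 != 0.0:
            b0 += d0
            for i in range(n):
                r[i] -= d0
        max_delta = _cd_sweep(X, wv, r, beta, den, False, lam_l1, lam_l2, pf, n)
        sweeps += 1
        if max_delta < tol and abs(d0) < tol:
            break
        if p > 64:
            # iterate on the active set until stable, then re-check all
            while sweeps < max_sweeps:
                max_delta = _cd_sweep(X, wv, r, beta, den, True, lam_l1, lam_l2, pf, n)
                sweeps += 1
                if max_delta < tol:
                    break
    return b0


@njit(cache=True)
def en_logistic_path(X, y, lambdas, l1_ratio, tol=1e-7, max_irls=50, max_sweeps=200,
                     penalty_factor=None):
    """Fit the full descending-lambda path with warm starts.

    Returns (coefs (L, p), intercepts (L,), n_iter (L,)). ``y`` in {0,1};
    ``X`` standardized. ``penalty_factor`` scales the penalty per feature
    (default all ones; 0 exempts a column).
    """
    n, p = X.shape
    if penalty_factor is None:
        pf = np.ones(p)
    else:
        pf = penalty_factor
    L = lambdas.shape[0]
    coefs = np.zeros((L, p))
    icepts = np.zeros(L)
    iters = np.zeros(L, dtype=np.int64)

    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        # degenerate single-class input: intercept at the clamp, no signal
        ybar = min(max(ybar, _PMIN), 1.0 - _PMIN)
    beta = np.zeros(p)
    b0 = np.log(ybar / (1.0 - ybar))

    eta = np.empty(n)
    mu = np.empty(n)
    wv = np.empty(n)
    z = np.empty(n)
    for l in range(L):
        lam = lambdas[l]
        lam_l1 = lam * l1_ratio
        lam_l2 = lam * (1.0 - l1_ratio)
        for it in range(max_irls):
            eta = b0 + X @ beta
            for i in range(n):
                e = eta[i]
                if e > 30.0:
                    e = 30.0
                elif e < -30.0:
                    e = -30.0
                m = 1.0 / (1.0 + np.exp(-e))
                if m < _PMIN:
                    m = _PMIN
                elif m > 1.0 - _PMIN:
                    m = 1.0 - _PMIN
                mu[i] = m
                w = m * (1.0 - m)
                if w < _WMIN:
                    w = _WMIN
                wv[i] = w
                z[i] = eta[i] + (y[i] - m) / w
            beta_old = beta.copy()
            b0_old = b0
            b0 = _cd_quadratic(X, wv, z, beta, b0, lam_l1, lam_l2, pf, tol, max_sweeps)
            delta = abs(b0 - b0_old)
            for j in range(p):
                d = abs(beta[j] - beta_old[j])
                if d > delta:
                    delta = d
            if delta < tol * 10.0:
                break
        iters[l] = it + 1
        coefs[l] = beta
        icepts[l] = b0
    return coefs, icepts, iters


def lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    l1_ratio: float,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 0.01,
    penalty_factor: np.ndarray | None = None,
) -> np.ndarray:
    """Log-spaced descending lambda path from the null-model lambda_max.

    lambda_max = max_j |x_j . (y - ybar)| / (n * alpha * pf_j) over the
    penalized features is the smallest penalty at which every penalized
    coefficient is zero.
    """
    n = X.shape[0]
    alpha = max(l1_ratio, 1e-3)
    mu = np.full(n, y.mean())
    if penalty_factor is not None:
        pen = penalty_factor > 0
        if not pen.any():
            return np.geomspace(1.0, lambda_min_ratio, n_lambdas)
        # KKT: penalized features stay zero relative to the fit that
        # already includes the unpenalized columns
        free = X[:, ~pen]
        if free.shape[1]:
            mu = _unpenalized_logistic_mu(free, y)
        grad = np.abs(X[:, pen].T @ (y - mu)) / penalty_factor[pen]
    else:
        grad = np.abs(X.T @ (y - mu))
    # hair above the KKT boundary so the first solution is exactly null
    lam_max = np.max(grad) / (n * alpha) * (1 + 1e-6)
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)


def _unpenalized_logistic_mu(F: np.ndarray, y: np.ndarray, n_iter: int = 25) -> np.ndarray:
    """Fitted probabilities of a plain logistic fit on columns F (Newton)."""
    A = np.column_stack([np.ones(len(y)), F])
    b = np.zeros(A.shape[1])
    for _ in range(n_iter):
        eta = np.clip(A @ b, -30, 30)
        mu = np.clip(1 / (1 + np.exp(-eta)), _PMIN, 1 - _PMIN)
        w = mu * (1 - mu)
        H = A.T @ (A * w[:, None]) + 1e-8 * np.eye(A.shape[1])
        step = np.linalg.solve(H, A.T @ (y - mu))
        b += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(A @ b, -30, 30)
    return np.clip(1 / (1 + np.exp(-eta)), _PMIN, 1 - _PMIN)


@njit(cache=True)
def binomial_deviance(X, y, coefs, icepts):
    """Mean binomial deviance of each path solution on (X, y)."""
    L = coefs.shape[0]
    n = X.shape[0]
    out = np.empty(L)
    for l in range(L):
        eta = icepts[l] + X @ coefs[l]
        dev = 0.0
        for i in range(n):
            e = eta[i]
            if e > 30.0:
                e = 30.0
            elif e < -30.0:
                e = -30.0
            m = 1.0 / (1.0 + np.exp(-e))
            if m < _PMIN:
                m = _PMIN
            elif m > 1.0 - _PMIN:
                m = 1.0 - _PMIN
            if y[i] > 0.5:
                dev += -2.0 * np.log(m)
            else:
                dev += -2.0 * np.log(1.0 - m)
        out[l] = dev / n
    return out
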