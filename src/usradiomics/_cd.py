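"""Coordinate-descent path solver for L1-penalized logistic regression.

Minimizes, for each penalty weight lambda on a descending grid,

    f(b0, b) = (1/n) * sum_i log(1 + exp(-t_i (b0 + x_i' b))) + lambda ||b||_1

with t_i = 2 y_i - 1 and the intercept unpenalized.  The solver follows
the classic penalized-GLM recipe: an outer iteratively-reweighted
least-squares (IRLS) loop builds a weighted quadratic approximation of
the log-likelihood, an inner cyclic coordinate-descent loop solves the
resulting weighted lasso exactly via soft-thresholding, and solutions
are warm-started from the previous (larger) lambda.  Compiled with
numba; falls back to the pure-Python path if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = ["lasso_logistic_path"]

_W_FLOOR = 1e-5  # variance floor for the IRLS weights, as in glmnet
_P_CLIP = 1e-8


@njit(cache=True, fastmath=False)
def _update_feature(XT, w, r, beta, j, lam, n):  # pragma: no cover - jitted
    """One soft-threshold coordinate update; returns the coefficient change."""
    xj = XT[j]
    vj = 0.0
    rho = 0.0
    for i in range(n):
        wx = w[i] * xj[i]
        vj += wx * xj[i]
        rho += wx * r[i]
    vj /= n
    if vj <= 0.0:
        return 0.0
    rho = rho / n + vj * beta[j]
    if rho > lam:
        new = (rho - lam) / vj
    elif rho < -lam:
        new = (rho + lam) / vj
    else:
        new = 0.0
    d = new - beta[j]
    if d != 0.0:
        beta[j] = new
        for i in range(n):
            r[i] -= xj[i] * d
    return d


@njit(cache=True)
def _deviance(eta, y):  # pragma: no cover - jitted
    n = y.shape[0]
    dev = 0.0
    for i in range(n):
        pr = 1.0 / (1.0 + np.exp(-eta[i]))
        if pr < _P_CLIP:
            pr = _P_CLIP
        elif pr > 1.0 - _P_CLIP:
            pr = 1.0 - _P_CLIP
        dev -= 2.0 * (y[i] * np.log(pr) + (1.0 - y[i]) * np.log(1.0 - pr))
    return dev


@njit(cache=True)
def _path_kernel(XT, y, lambdas, tol, max_irls, max_cd, fdev, devmax):  # pragma: no cover
    p, n = XT.shape
    n_lam = lambdas.shape[0]
    coefs = np.zeros((n_lam, p))
    icepts = np.zeros(n_lam)

    ybar = y.sum() / n
    beta = np.zeros(p)
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    active = np.zeros(p, dtype=np.bool_)
    dev_null = _deviance(eta, y)
    prev_ratio = 0.0
    k_stop = n_lam

    for k in range(n_lam):
        lam = lambdas[k]
        for _ in range(max_irls):
            pr = 1.0 / (1.0 + np.exp(-eta))
            for i in range(n):
                if pr[i] < _P_CLIP:
                    pr[i] = _P_CLIP
                elif pr[i] > 1.0 - _P_CLIP:
                    pr[i] = 1.0 - _P_CLIP
            w = pr * (1.0 - pr)
            for i in range(n):
                if w[i] < _W_FLOOR:
                    w[i] = _W_FLOOR
            # working residual of the weighted least-squares subproblem
            r = (y - pr) / w
            delta_irls = 0.0

            # alternate full sweeps (which double as KKT checks) with
            # cheap sweeps over the current active set, glmnet-style
            for _outer in range(max_cd):
                max_change = 0.0
                wsum = w.sum()
                d0 = np.dot(w, r) / wsum
                b0 += d0
                r -= d0
                if abs(d0) > max_change:
                    max_change = abs(d0)
                for j in range(p):
                    d = _update_feature(XT, w, r, beta, j, lam, n)
                    if beta[j] != 0.0:
                        active[j] = True
                    if abs(d) > max_change:
                        max_change = abs(d)
                if max_change > delta_irls:
                    delta_irls = max_change
                if max_change < tol:
                    break  # a full sweep changed nothing: KKT satisfied
                for _inner in range(max_cd):
                    inner_change = 0.0
                    d0 = np.dot(w, r) / w.sum()
                    b0 += d0
                    r -= d0
                    if abs(d0) > inner_change:
                        inner_change = abs(d0)
                    for j in range(p):
                        if not active[j]:
                            continue
                        d = _update_feature(XT, w, r, beta, j, lam, n)
                        if abs(d) > inner_change:
                            inner_change = abs(d)
                    if inner_change > delta_irls:
                        delta_irls = inner_change
                    if inner_change < tol:
                        break
            # refresh the linear predictor for the next IRLS step
            for i in range(n):
                eta[i] = b0
            for j in range(p):
                bj = beta[j]
                if bj != 0.0:
                    xj = XT[j]
                    for i in range(n):
                        eta[i] += xj[i] * bj
            if delta_irls < tol:
                break
        coefs[k] = beta
        icepts[k] = b0
        # glmnet-style early path termination: once the training deviance
        # is (nearly) saturated or stops improving, deeper penalties only
        # chase quasi-separation and are useless to cross-validation
        ratio = 1.0 - _deviance(eta, y) / dev_null
        if ratio > devmax or (k > 0 and ratio - prev_ratio < fdev * ratio):
            k_stop = k + 1
            break
        prev_ratio = ratio
    return coefs, icepts, k_stop


def lasso_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-8,
    max_irls: int = 50,
    max_cd: int = 1000,
    fdev: float = 1e-5,
    devmax: float = 0.999,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fit the penalized path along a descending lambda grid.

    Returns (coefs [n_lambda x p], intercepts, k_stop) where k_stop is
    the number of grid points actually fit: the path terminates early
    when the fraction of null deviance explained exceeds ``devmax`` or
    improves by less than ``fdev`` (relative) between grid points, as
    in glmnet.  Pass ``fdev=0, devmax=1`` to force the full grid.
    """
    XT = np.ascontiguousarray(np.asarray(X, dtype=np.float64).T)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    return _path_kernel(XT, y, lambdas, tol, max_irls, max_cd, fdev, devmax)
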