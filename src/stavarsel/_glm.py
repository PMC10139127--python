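"""Small weighted logistic-regression engine (IRLS / Newton).

The jackknife variance estimator and the step-forward model-size scan both
need very large numbers of maximum-likelihood logistic refits on tiny
design matrices (tens of samples, at most ~10 features), where each refit
differs from the others only in its per-sample weights (a deleted sample is
a weight of zero).  Fitting them one at a time through a general-purpose
library carries per-call overhead that dwarfs the arithmetic, so the refits
are run here as a single batched Newton iteration over a weights matrix:
all subsample fits share the design matrix and are solved simultaneously.

Features are standardized internally for conditioning; returned
coefficients are on the original scale (the unpenalized MLE is
scale-equivariant, so this changes nothing but the arithmetic).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fit_logistic",
    "fit_logistic_batched",
    "logistic_deviance",
    "sigmoid",
]

# |standardized coefficient| above this is treated as numerically divergent
# (odds ratio > e^30 per SD): complete or quasi-complete separation.
_SEPARATION_COEF_BOUND = 30.0
_RIDGE_STABILIZER = 1e-6


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def logistic_deviance(y: np.ndarray, p: np.ndarray, w: np.ndarray | None = None) -> float | np.ndarray:
    """-2 * weighted log-likelihood, clipped away from log(0)."""
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = y * np.log(p) + (1.0 - y) * np.log(1.0 - p)
    if w is None:
        return -2.0 * ll.sum(axis=-1)
    return -2.0 * (w * ll).sum(axis=-1)


def _batched_irls(Xa, y, W, ridge, max_iter, tol):
    """Newton iterations for B weighted logistic fits sharing design Xa.

    Xa: (n, k+1) design with leading intercept column (standardized scale).
    W:  (B, n) nonnegative weights.  ridge: (B,) L2 penalty per fit, not
    applied to the intercept.  Returns beta (B, k+1) and convergence mask.
    """
    B, n = W.shape
    k1 = Xa.shape[1]
    beta = np.zeros((B, k1))
    # intercept init at weighted logit of prevalence (clipped)
    wy = (W * y).sum(1) / np.maximum(W.sum(1), 1e-12)
    wy = np.clip(wy, 1e-6, 1 - 1e-6)
    beta[:, 0] = np.log(wy / (1 - wy))
    pen_mask = np.ones(k1)
    pen_mask[0] = 0.0
    eta = beta @ Xa.T
    mu = sigmoid(eta)
    dev = logistic_deviance(y, mu, W) + ridge * (beta[:, 1:] ** 2).sum(1)
    active = np.ones(B, dtype=bool)
    for _ in range(max_iter):
        s = W * mu * (1.0 - mu) + 1e-10
        grad = ((y - mu) * W) @ Xa - 2.0 * ridge[:, None] * beta * pen_mask
        H = np.einsum("bn,ni,nj->bij", s, Xa, Xa)
        H += (2.0 * ridge[:, None, None] + 1e-12) * np.eye(k1) * pen_mask[None, :, None]
        H[:, 0, 0] += 1e-12
        try:
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            H += 1e-8 * np.eye(k1)
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        # step-halving: accept the first scale that does not worsen the
        # penalized deviance (vectorized over the batch)
        scale = np.ones(B)
        new_beta = beta + step
        for _half in range(30):
            eta = new_beta @ Xa.T
            mu_new = sigmoid(eta)
            new_dev = logistic_deviance(y, mu_new, W) + ridge * (new_beta[:, 1:] ** 2).sum(1)
            worse = active & (new_dev > dev + 1e-12)
            if not worse.any():
                break
            scale[worse] *= 0.5
            new_beta[worse] = beta[worse] + scale[worse, None] * step[worse]
        improved = active & (new_dev <= dev + 1e-12)
        beta[improved] = new_beta[improved]
        delta = np.abs(dev - new_dev)
        dev = np.where(improved, new_dev, dev)
        eta = beta @ Xa.T
        mu = sigmoid(eta)
        active = active & improved & (delta > tol * (np.abs(dev) + 1.0))
        # runaway coefficients terminate early (separation)
        active &= np.abs(beta).max(1) < 2 * _SEPARATION_COEF_BOUND
        if not active.any():
            break
    return beta


def fit_logistic_batched(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    *,
    max_iter: int = 60,
    tol: float = 1e-12,
):
    """Fit B weighted logistic regressions sharing the design matrix X.

    Parameters
    ----------
    X : (n, k) float array (k may be 0 for intercept-only models).
    y : (n,) array of 0/1 labels.
    weights : (B, n) nonnegative weights; a zero weight deletes a sample.

    Returns
    -------
    coef : (B, k) coefficients on the original scale.
    intercept : (B,) intercepts.
    separation : (B,) bool, True where the unpenalized MLE diverged and a
        weakly ridge-stabilized fit (penalty 1e-6) was substituted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    n, k = X.shape if X.ndim == 2 else (X.shape[0], 0)
    B = weights.shape[0]
    if k == 0:
        wy = (weights * y).sum(1) / np.maximum(weights.sum(1), 1e-12)
        wy = np.clip(wy, 1e-12, 1 - 1e-12)
        return (
            np.zeros((B, 0)),
            np.log(wy / (1 - wy)),
            np.zeros(B, dtype=bool),
        )
    mu_x = X.mean(axis=0)
    sd_x = X.std(axis=0, ddof=0)
    sd_x[sd_x == 0] = 1.0
    Xs = (X - mu_x) / sd_x
    Xa = np.hstack([np.ones((n, 1)), Xs])
    beta = _batched_irls(Xa, y, weights, np.zeros(B), max_iter, tol)
    separation = np.abs(beta[:, 1:]).max(axis=1) >= _SEPARATION_COEF_BOUND if k else np.zeros(B, bool)
    if separation.any():
        idx = np.where(separation)[0]
        beta_r = _batched_irls(
            Xa, y, weights[idx], np.full(idx.size, _RIDGE_STABILIZER), max_iter, tol
        )
        beta[idx] = beta_r
    coef = beta[:, 1:] / sd_x
    intercept = beta[:, 0] - (coef * mu_x).sum(axis=1)
    return coef, intercept, separation


def fit_logistic(X, y, *, sample_weight=None, max_iter: int = 60, tol: float = 1e-12):
    """Single maximum-likelihood logistic fit; see fit_logistic_batched."""
    n = len(y)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    coef, intercept, sep = fit_logistic_batched(
        np.asarray(X, float).reshape(n, -1), y, w[None, :], max_iter=max_iter, tol=tol
    )
    return coef[0], intercept[0], bool(sep[0])
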