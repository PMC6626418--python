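"""Exact t-SNE with explicit iteration control.

A self-contained optimizer is used (rather than a library front-end) because
the embedding protocol requires running a minimum number of iterations and
then continuing until a windowed mean-displacement stabilization criterion is
met, with a hard iteration cap — semantics that need in-loop access to the
coordinates.  Gradients are exact (no Barnes-Hut approximation) and jitted
with numba; cohorts here are small enough (n <= a few thousand) for the
O(n^2) cost to be acceptable.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from numba import njit

_MACHINE_EPS = np.finfo(np.float64).eps


@njit(cache=True, fastmath=True)
def _conditional_probabilities(d2: np.ndarray, perplexity: float) -> np.ndarray:
    """Row-wise conditional probabilities with per-point precision found by
    bisection so each row's entropy matches log(perplexity)."""
    n = d2.shape[0]
    target = np.log(perplexity)
    p_cond = np.zeros((n, n))
    for i in range(n):
        beta_lo = 0.0
        beta_hi = 0.0
        has_hi = False  # fastmath forbids an inf sentinel
        beta = 1.0
        for _ in range(64):
            sw = 0.0
            acc = 0.0  # sum of w * d2 for entropy
            for j in range(n):
                if j == i:
                    continue
                w = np.exp(-d2[i, j] * beta)
                sw += w
                acc += w * d2[i, j]
            if sw <= 0.0:
                h = 0.0
            else:
                # H = log(sw) + beta * E[d2]
                h = np.log(sw) + beta * acc / sw
            if abs(h - target) < 1e-6:
                break
            if h > target:
                beta_lo = beta
                beta = (beta + beta_hi) / 2.0 if has_hi else beta * 2.0
            else:
                beta_hi = beta
                has_hi = True
                beta = beta / 2.0 if beta_lo == 0.0 else (beta + beta_lo) / 2.0
        sw = 0.0
        for j in range(n):
            if j != i:
                p_cond[i, j] = np.exp(-d2[i, j] * beta)
                sw += p_cond[i, j]
        if sw > 0.0:
            for j in range(n):
                p_cond[i, j] /= sw
    return p_cond


def joint_probabilities(x: np.ndarray, perplexity: float) -> np.ndarray:
    """Symmetrized joint probabilities P for input vectors ``x``."""
    x = np.asarray(x, dtype=np.float64)
    sq = np.sum(x * x, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)
    p_cond = _conditional_probabilities(d2, float(perplexity))
    p = (p_cond + p_cond.T) / (2.0 * len(x))
    return np.maximum(p, _MACHINE_EPS)


@njit(cache=True, fastmath=True)
def _step(
    p: np.ndarray,
    y: np.ndarray,
    update: np.ndarray,
    gains: np.ndarray,
    w: np.ndarray,
    grad: np.ndarray,
    learning_rate: float,
    momentum: float,
) -> float:
    """One synchronous gradient-descent step (exact Student-t gradient,
    adaptive per-coordinate gains).

    Mutates y/update/gains in place (w and grad are scratch buffers) and
    returns the mean per-point displacement divided by the bounding radius
    of the updated embedding.
    """
    n = y.shape[0]
    sum_w = 0.0
    for i in range(n):
        w[i, i] = 0.0
        yi0 = y[i, 0]
        yi1 = y[i, 1]
        yi2 = y[i, 2]
        for j in range(i + 1, n):
            t0 = yi0 - y[j, 0]
            t1 = yi1 - y[j, 1]
            t2 = yi2 - y[j, 2]
            wij = 1.0 / (1.0 + t0 * t0 + t1 * t1 + t2 * t2)
            w[i, j] = wij
            w[j, i] = wij
            sum_w += 2.0 * wij
    inv_sum_w = 1.0 / sum_w
    for i in range(n):
        grad[i, 0] = 0.0
        grad[i, 1] = 0.0
        grad[i, 2] = 0.0
    # symmetric pair contributions: grad_i += coef*(y_i - y_j), grad_j -= ...
    for i in range(n):
        yi0 = y[i, 0]
        yi1 = y[i, 1]
        yi2 = y[i, 2]
        g0 = 0.0
        g1 = 0.0
        g2 = 0.0
        for j in range(i + 1, n):
            wij = w[i, j]
            coef = 4.0 * (p[i, j] - wij * inv_sum_w) * wij
            t0 = coef * (yi0 - y[j, 0])
            t1 = coef * (yi1 - y[j, 1])
            t2 = coef * (yi2 - y[j, 2])
            g0 += t0
            g1 += t1
            g2 += t2
            grad[j, 0] -= t0
            grad[j, 1] -= t1
            grad[j, 2] -= t2
        grad[i, 0] += g0
        grad[i, 1] += g1
        grad[i, 2] += g2
    disp_sum = 0.0
    for i in range(n):
        d = 0.0
        for k in range(3):
            g = grad[i, k]
            if (g > 0.0) == (update[i, k] > 0.0):
                gains[i, k] *= 0.8
            else:
                gains[i, k] += 0.2
            if gains[i, k] < 0.01:
                gains[i, k] = 0.01
            update[i, k] = momentum * update[i, k] - learning_rate * gains[i, k] * g
            y[i, k] += update[i, k]
            d += update[i, k] * update[i, k]
        disp_sum += np.sqrt(d)
    c0 = 0.0
    c1 = 0.0
    c2 = 0.0
    for i in range(n):
        c0 += y[i, 0]
        c1 += y[i, 1]
        c2 += y[i, 2]
    c0 /= n
    c1 /= n
    c2 /= n
    radius2 = 0.0
    for i in range(n):
        t0 = y[i, 0] - c0
        t1 = y[i, 1] - c1
        t2 = y[i, 2] - c2
        d = t0 * t0 + t1 * t1 + t2 * t2
        if d > radius2:
            radius2 = d
    if radius2 <= 0.0:
        return 0.0
    return disp_sum / (n * np.sqrt(radius2))


def kl_divergence(p: np.ndarray, y: np.ndarray) -> float:
    d2 = np.square(y[:, None, :] - y[None, :, :]).sum(-1)
    w = 1.0 / (1.0 + d2)
    np.fill_diagonal(w, 0.0)
    q = np.maximum(w / w.sum(), _MACHINE_EPS)
    mask = ~np.eye(len(y), dtype=bool)
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def optimize(
    p: np.ndarray,
    *,
    dim: int,
    learning_rate: float,
    n_iter_min: int,
    max_iter: int,
    stabilization_tol: float,
    stabilization_window: int,
    seed: int,
    early_exaggeration: float = 12.0,
    exaggeration_iter: int = 250,
) -> tuple[np.ndarray, float, int]:
    """Gradient descent with momentum and adaptive per-coordinate gains.

    Runs at least ``n_iter_min`` iterations and then continues until the mean
    per-point displacement (normalized by the current bounding radius),
    averaged over ``stabilization_window`` iterations, drops below
    ``stabilization_tol`` — or ``max_iter`` is reached.

    Returns (coordinates, final KL divergence, iterations run).
    """
    if dim != 3:
        raise ValueError("the optimizer is specialized for 3-D embeddings")
    n = p.shape[0]
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, 1e-4, size=(n, dim))
    update = np.zeros_like(y)
    gains = np.ones_like(y)
    w_buf = np.empty((n, n))
    grad_buf = np.empty((n, dim))

    p_eff = p * early_exaggeration
    window: deque[float] = deque(maxlen=stabilization_window)
    it = 0
    while it < max_iter:
        if it == exaggeration_iter:
            p_eff = p
        momentum = 0.5 if it < exaggeration_iter else 0.8
        rel_disp = _step(p_eff, y, update, gains, w_buf, grad_buf, learning_rate, momentum)
        it += 1
        window.append(rel_disp)
        if (
            it >= n_iter_min
            and len(window) == stabilization_window
            and sum(window) < stabilization_tol * stabilization_window
        ):
            break

    return y, kl_divergence(p, y), it
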