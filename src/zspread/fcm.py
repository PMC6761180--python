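"""Fuzzy c-means clustering.

Minimises the weighted within-cluster scatter

    J(U, C) = sum_i sum_k u_ik^m ||x_i - c_k||^2,   sum_k u_ik = 1,

by the standard alternating updates

    u_ik = 1 / sum_j (||x_i - c_k|| / ||x_i - c_j||)^(2/(m-1)),
    c_k  = sum_i u_ik^m x_i / sum_i u_ik^m.

A sample sitting exactly on a centre gets membership 1 there.  The fit
runs several seeded restarts (random centres drawn from the data
bounding box) and keeps the solution with the lowest objective; the
objective is non-increasing across iterations within each restart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FCMResult", "fuzzy_cmeans", "fcm_memberships", "fcm_objective"]


@dataclass
class FCMResult:
    centers: np.ndarray  # (k, d)
    memberships: np.ndarray  # (n, k), rows sum to 1
    objective: float
    objective_history: np.ndarray
    n_iter: int
    m: float


def _distances(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    return np.linalg.norm(x[:, None, :] - centers[None, :, :], axis=-1)


def fcm_memberships(x: np.ndarray, centers: np.ndarray, m: float = 2.0) -> np.ndarray:
    """Membership matrix for fixed centres (rows sum to one)."""
    d = _distances(np.atleast_2d(x), centers)
    u = np.zeros(d.shape)
    zero = d <= 0
    hit = zero.any(axis=1)
    if np.any(hit):
        # on-centre samples: all mass on the (first) coincident centre
        first = np.argmax(zero[hit], axis=1)
        u[np.flatnonzero(hit), first] = 1.0
    rest = ~hit
    if np.any(rest):
        p = 2.0 / (m - 1.0)
        dr = d[rest]
        u[rest] = 1.0 / np.sum((dr[:, :, None] / dr[:, None, :]) ** p, axis=2)
    return u


def fcm_objective(x: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float = 2.0) -> float:
    d2 = _distances(x, centers) ** 2
    return float(np.sum(u**m * d2))


def fuzzy_cmeans(
    x: np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_restarts: int = 20,
    seed: int = 0,
) -> FCMResult:
    """Fit fuzzy c-means with ``k`` clusters and fuzzifier ``m``.

    Convergence: max |U_new - U_old| < ``tol`` or ``max_iter``
    iterations; best of ``n_restarts`` seeded restarts by objective.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be 2-D (samples x features)")
    n, d = x.shape
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)

    best: FCMResult | None = None
    for _ in range(max(1, n_restarts)):
        # initial centres: distinct data points plus jitter, to avoid
        # coincident centres on degenerate inputs
        idx = rng.choice(n, size=k, replace=(n < k))
        centers = x[idx] + rng.normal(0.0, 1e-3 * (np.ptp(x) + 1e-12), (k, d))
        u = fcm_memberships(x, centers, m)
        history = [fcm_objective(x, centers, u, m)]
        for it in range(max_iter):
            w = u**m
            denom = w.sum(axis=0)[:, None]
            denom[denom == 0] = 1.0
            centers = (w.T @ x) / denom
            u_new = fcm_memberships(x, centers, m)
            history.append(fcm_objective(x, centers, u_new, m))
            delta = np.max(np.abs(u_new - u))
            u = u_new
            if delta < tol:
                break
        res = FCMResult(
            centers=centers,
            memberships=u,
            objective=history[-1],
            objective_history=np.asarray(history),
            n_iter=len(history) - 1,
            m=m,
        )
        if best is None or res.objective < best.objective:
            best = res
    assert best is not None
    return best
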