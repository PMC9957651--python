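"""Classical single-task fuzzy C-means on scalar image intensities.

The algorithm alternates the closed-form membership update

    u_ij = ||x_i - v_j||^(-2/(m-1)) / sum_l ||x_i - v_l||^(-2/(m-1))

with the fuzzily weighted centroid update

    v_j = sum_i u_ij^m x_i / sum_i u_ij^m

until the objective  J = sum_ij u_ij^m ||x_i - v_j||^2  changes by less
than an absolute tolerance, or a sweep cap is reached.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import FcmConfig, SegmentationResult, TaskData

logger = logging.getLogger(__name__)


def inverse_power_shares(a: np.ndarray, m: float, axis: int) -> np.ndarray:
    """Normalize ``a ** (-1/(m-1))`` along ``axis`` with zero-limit handling.

    This is the shared kernel of every fuzzy membership update: given
    non-negative dissimilarities ``a``, returns shares proportional to
    ``a ** (-1/(m-1))`` that sum to 1 along ``axis``.  Where one or more
    entries of a slice are exactly zero, the limit of the formula is a
    uniform split over the zero entries (and 0 elsewhere), which keeps the
    update deterministic and continuous.
    """
    a = np.asarray(a, dtype=float)
    zero = a == 0.0
    any_zero = zero.any(axis=axis, keepdims=True)
    # divide by the slice minimum first so the dominant term is exactly 1
    # and the power never overflows, only harmlessly underflows
    amin = np.where(zero, np.inf, a).min(axis=axis, keepdims=True)
    amin = np.where(np.isfinite(amin), amin, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        # huge ratios overflow to inf and their share cleanly underflows to 0
        inv = (a / amin) ** (-1.0 / (m - 1.0))
    inv = np.where(zero, 0.0, inv)
    total = inv.sum(axis=axis, keepdims=True)
    total[total == 0.0] = 1.0
    shares = inv / total
    n_zero = zero.sum(axis=axis, keepdims=True)
    uniform_over_zeros = np.where(zero, 1.0, 0.0) / np.maximum(n_zero, 1)
    return np.where(any_zero, uniform_over_zeros, shares)


def _check_dims(data: TaskData, U: np.ndarray | None, V: np.ndarray) -> None:
    V = np.asarray(V)
    if V.ndim != 1:
        raise ValueError("centroids must be a 1-D vector")
    if U is not None:
        U = np.asarray(U)
        if U.shape != (V.size, data.n_pixels):
            raise ValueError(
                f"membership matrix {U.shape} incompatible with "
                f"{V.size} centroids and {data.n_pixels} pixels"
            )


def fcm_objective(data: TaskData, U: np.ndarray, V: np.ndarray, m: float) -> float:
    """Fuzzified within-cluster sum of squared distances."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    _check_dims(data, U, V)
    d2 = (data.pixels[None, :] - V[:, None]) ** 2
    return float(np.sum(U**m * d2))


def fcm_membership_update(data: TaskData, V: np.ndarray, m: float) -> np.ndarray:
    """Closed-form membership update given fixed centroids.

    Pixels coinciding with one or more centroids receive a uniform split
    over the coinciding centroids (the zero-distance limit).
    """
    V = np.asarray(V, dtype=float)
    _check_dims(data, None, V)
    d2 = (data.pixels[None, :] - V[:, None]) ** 2
    return inverse_power_shares(d2, m, axis=0)


def fcm_centroid_update(
    data: TaskData,
    U: np.ndarray,
    m: float,
    prev_centroids: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form centroid update given fixed memberships.

    A cluster whose fuzzified membership mass is zero is degenerate: its
    centroid is left at ``prev_centroids`` (or the data mean if no previous
    value exists) and a warning is logged.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or U.shape[1] != data.n_pixels:
        raise ValueError("membership matrix incompatible with data")
    um = U**m
    mass = um.sum(axis=1)
    num = um @ data.pixels
    V = np.empty_like(mass)
    ok = mass > 0
    V[ok] = num[ok] / mass[ok]
    if not ok.all():
        logger.warning(
            "%d cluster(s) with zero membership mass; centroids frozen",
            int((~ok).sum()),
        )
        if prev_centroids is not None:
            V[~ok] = np.asarray(prev_centroids, dtype=float)[~ok]
        else:
            V[~ok] = data.pixels.mean()
    return V


def initial_centroids(pixels: np.ndarray, n_clusters: int, seed: int) -> np.ndarray:
    """Draw initial centroids as C distinct pixels, uniformly without replacement."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(pixels.size, size=n_clusters, replace=False)
    return np.asarray(pixels, dtype=float)[idx].copy()


def run_fcm(
    data: TaskData,
    config: FcmConfig,
    initial: np.ndarray | None = None,
) -> SegmentationResult:
    """Alternate membership and centroid updates until the objective settles.

    Centroids start at C distinct pixels drawn under ``config.seed``
    unless ``initial`` supplies them explicitly.  Reproducible: identical
    data + config (including seed) give bit-identical results.  Requires
    1 < C < N except for the degenerate C = 1 case, which converges to
    the plain mean immediately.
    """
    C, N, m = config.n_clusters, data.n_pixels, config.fuzzifier
    if C >= N:
        raise ValueError(f"need n_clusters < n_pixels, got C={C}, N={N}")
    if initial is not None:
        V = np.asarray(initial, dtype=float).copy()
        if V.shape != (C,):
            raise ValueError("initial centroids must have shape (C,)")
    else:
        V = initial_centroids(data.pixels, C, config.seed)
    trace: list[float] = []
    prev_obj = np.inf
    for _ in range(config.max_iter):
        U = fcm_membership_update(data, V, m)
        V = fcm_centroid_update(data, U, m, prev_centroids=V)
        obj = fcm_objective(data, U, V, m)
        trace.append(obj)
        if abs(prev_obj - obj) < config.tol:
            break
        prev_obj = obj
    labels = np.argmax(U, axis=0)
    return SegmentationResult(
        memberships=U,
        centroids=V,
        labels=labels,
        objective_trace=np.asarray(trace),
        n_iter=len(trace),
    )
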