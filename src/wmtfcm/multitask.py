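"""Weighted multitask fuzzy C-means (WMT-FCM).

T related segmentation tasks are clustered jointly by minimizing

    J = sum_t sum_i sum_j u_ij,t^m ||x_i,t - v_j,t||^2
      + lambda * sum_t sum_d sum_j w_d,t p_jd,t^m ||v_j,t - z_d||^2
      + gamma  * sum_t sum_d w_d,t log w_d,t

subject to columns of each U^(t), rows of each P^(t), and task-columns of
W lying on the probability simplex.  The first term is T independent FCM
problems; the second couples each task's private centroids v_j,t to shared
public centroids z_d through fuzzy public memberships p_jd,t; the third is
a Shannon-entropy regularizer whose minimizer makes the task weights a
softmax of the (negative, scaled) per-task dispersions around each public
centroid — tasks whose private centroids sit close to a public centroid
earn a larger say in it.

Every block (U, P, V, Z, W) has a closed-form minimizer with the other
blocks fixed, so one sweep of block-coordinate updates in the order
U -> P -> V -> Z -> W never increases J.
"""

from __future__ import annotations

import logging

import numpy as np

from .fcm import fcm_centroid_update, fcm_membership_update, inverse_power_shares
from .types import MultitaskState, SegmentationResult, TaskData, WmtConfig

logger = logging.getLogger(__name__)

_W_FLOOR = 1e-300  # entropy convention 0*log(0) = 0, realized by clamping


def derive_task_seeds(seed: int, n_tasks: int) -> list[int]:
    """Per-task initialization seeds split deterministically from one seed."""
    return [
        int(np.random.SeedSequence(entropy=seed, spawn_key=(t,)).generate_state(1)[0])
        for t in range(n_tasks)
    ]


# ---------------------------------------------------------------------------
# block updates (each is the exact minimizer with the other blocks fixed)
# ---------------------------------------------------------------------------


def update_private_membership(task: TaskData, V_t: np.ndarray, m: float) -> np.ndarray:
    """Private membership update; identical in form to single-task FCM."""
    return fcm_membership_update(task, V_t, m)


def update_public_membership(
    V_t: np.ndarray, Z: np.ndarray, w_t: np.ndarray, m: float
) -> np.ndarray:
    """Fuzzy assignment of one task's private centroids to the public ones.

    p_jd = (w_d ||v_j - z_d||^2)^(-1/(m-1)) / sum_l (w_l ||v_j - z_l||^2)^(-1/(m-1))

    The task weight enters inside the inverse power, so for equal distances
    a *smaller* weight yields a *larger* share (its term is cheaper in the
    weighted objective).  Rows sum to 1; a private centroid coinciding with
    public centroids gets a uniform split over the coinciding ones.
    """
    V_t = np.asarray(V_t, dtype=float)
    Z = np.asarray(Z, dtype=float)
    w_t = np.asarray(w_t, dtype=float)
    d2 = (V_t[:, None] - Z[None, :]) ** 2
    return inverse_power_shares(w_t[None, :] * d2, m, axis=1)


def update_private_centroids(
    task: TaskData,
    U_t: np.ndarray,
    P_t: np.ndarray,
    w_t: np.ndarray,
    Z: np.ndarray,
    m: float,
    balance: float,
    prev_centroids: np.ndarray | None = None,
) -> np.ndarray:
    """Private centroids: pixel mass blended with the pull of public centroids.

    v_j = (sum_i u_ij^m x_i + lambda sum_d w_d p_jd^m z_d)
        / (sum_i u_ij^m     + lambda sum_d w_d p_jd^m)

    With lambda = 0 this is exactly the single-task FCM centroid update.
    """
    if balance == 0.0:
        return fcm_centroid_update(task, U_t, m, prev_centroids=prev_centroids)
    um = np.asarray(U_t, dtype=float) ** m
    pm = np.asarray(P_t, dtype=float) ** m * np.asarray(w_t, dtype=float)[None, :]
    num = um @ task.pixels + balance * (pm @ np.asarray(Z, dtype=float))
    den = um.sum(axis=1) + balance * pm.sum(axis=1)
    V = np.empty_like(den)
    ok = den > 0
    V[ok] = num[ok] / den[ok]
    if not ok.all():
        logger.warning("zero-mass private centroid(s); frozen")
        V[~ok] = (
            np.asarray(prev_centroids, dtype=float)[~ok]
            if prev_centroids is not None
            else task.pixels.mean()
        )
    return V


def update_public_centroids(
    V: list[np.ndarray],
    P: list[np.ndarray],
    W: np.ndarray,
    m: float,
    prev_centroids: np.ndarray | None = None,
) -> np.ndarray:
    """Public centroids: weight- and membership-weighted mean of all private ones.

    z_d = sum_t sum_j w_d,t p_jd,t^m v_j,t / sum_t sum_j w_d,t p_jd,t^m
    """
    W = np.asarray(W, dtype=float)
    D = W.shape[0]
    num = np.zeros(D)
    den = np.zeros(D)
    for t in range(len(V)):
        pm = np.asarray(P[t], dtype=float) ** m  # (C_t, D)
        wpm = pm * W[None, :, t].reshape(1, D)
        num += wpm.T @ np.asarray(V[t], dtype=float)
        den += wpm.sum(axis=0)
    Z = np.empty(D)
    ok = den > 0
    Z[ok] = num[ok] / den[ok]
    if not ok.all():
        logger.warning("zero-mass public centroid(s); frozen")
        Z[~ok] = (
            np.asarray(prev_centroids, dtype=float)[~ok]
            if prev_centroids is not None
            else np.concatenate(V).mean()
        )
    return Z


def dispersion(V: list[np.ndarray], P: list[np.ndarray], Z: np.ndarray, m: float) -> np.ndarray:
    """D×T matrix of per-task dispersions sum_j p_jd,t^m ||v_j,t - z_d||^2."""
    Z = np.asarray(Z, dtype=float)
    cols = []
    for t in range(len(V)):
        d2 = (np.asarray(V[t], dtype=float)[:, None] - Z[None, :]) ** 2  # (C_t, D)
        cols.append((np.asarray(P[t], dtype=float) ** m * d2).sum(axis=0))
    return np.stack(cols, axis=1)  # (D, T)


def update_weights(
    V: list[np.ndarray],
    P: list[np.ndarray],
    Z: np.ndarray,
    m: float,
    balance: float,
    entropy_coef: float,
) -> np.ndarray:
    """Entropy-regularized optimal task weights.

    w_d,t = softmax_t( -lambda * dispersion_d,t / gamma )

    Computed with the usual max-shift so the exponentials never overflow.
    Rows (public clusters) sum to 1 over tasks.
    """
    logits = -balance * dispersion(V, P, Z, m) / entropy_coef  # (D, T)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def _check_simplex(state: MultitaskState, atol: float = 1e-6) -> None:
    for t, U in enumerate(state.U):
        if np.abs(U.sum(axis=0) - 1.0).max() > atol:
            raise ValueError(f"U columns of task {t} are off the simplex")
        if U.min() < -atol or U.max() > 1 + atol:
            raise ValueError(f"U entries of task {t} outside [0,1]")
    for t, P in enumerate(state.P):
        if np.abs(P.sum(axis=1) - 1.0).max() > atol:
            raise ValueError(f"P rows of task {t} are off the simplex")
    if np.abs(state.W.sum(axis=1) - 1.0).max() > atol:
        raise ValueError("W task-columns are off the simplex")


def wmt_objective_terms(
    tasks: list[TaskData], state: MultitaskState, config: WmtConfig
) -> tuple[float, float, float]:
    """The three objective terms (fidelity, coupling, entropy), separately."""
    m = config.fuzzifier
    fidelity = 0.0
    coupling = 0.0
    for t, task in enumerate(tasks):
        d2 = (task.pixels[None, :] - state.V[t][:, None]) ** 2
        fidelity += float(np.sum(state.U[t] ** m * d2))
        dz2 = (state.V[t][:, None] - state.Z[None, :]) ** 2
        coupling += float(
            np.sum(state.W[None, :, t].reshape(1, -1) * state.P[t] ** m * dz2)
        )
    w = np.clip(state.W, _W_FLOOR, None)
    entropy = float(np.sum(state.W * np.log(w)))
    return fidelity, config.balance * coupling, config.entropy_coef * entropy


def wmt_objective(
    tasks: list[TaskData], state: MultitaskState, config: WmtConfig
) -> float:
    """Full multitask objective; raises if the state violates the constraints."""
    _check_simplex(state)
    return float(sum(wmt_objective_terms(tasks, state, config)))


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def _initial_public_centroids(
    tasks: list[TaskData], V: list[np.ndarray], D: int, method: str
) -> np.ndarray:
    if method == "quantile":
        # spread Z over the pooled intensity distribution: the midpoints of
        # D equal-probability bins.  Robust: never starts with duplicated
        # public centroids, unlike averaging the random initial private ones.
        pooled = np.concatenate([t.pixels for t in tasks])
        return np.quantile(pooled, (2.0 * np.arange(D) + 1.0) / (2.0 * D))
    if method == "centroid-mean":
        sorted_V = [np.sort(v) for v in V]
        if all(v.size == D for v in sorted_V):
            return np.mean(np.stack(sorted_V), axis=0)
        pooled = np.sort(np.concatenate(sorted_V))
        return np.quantile(pooled, np.linspace(0.0, 1.0, D))
    raise ValueError(f"unknown public-centroid init: {method!r}")


def _quantile_anchor(pixels: np.ndarray, n: int) -> np.ndarray:
    return np.quantile(pixels, (2.0 * np.arange(n) + 1.0) / (2.0 * n))


def initialize_state(
    tasks: list[TaskData],
    config: WmtConfig,
    z_init: str = "quantile",
    v_init: str = "public-jitter",
    initial_private: list[np.ndarray] | None = None,
) -> MultitaskState:
    """Seeded initial block state.

    Z starts at pooled intensity quantiles (midpoints of D
    equal-probability bins; ``z_init="centroid-mean"`` instead averages
    sorted random private centroids).  Private centroids default to the
    shared public positions plus a small per-task seeded jitter
    (``v_init="public-jitter"``): the coupling term is O(λ·D) against a
    pixel term of O(N), far too weak to pull a task out of a bad basin
    after the fact, so the cross-task information has to enter at
    initialization.  ``v_init="random-pixels"`` reproduces the
    single-task FCM draw (distinct pixels per task, seeds split from
    ``config.seed``); ``initial_private`` overrides both.  W starts
    uniform at 1/T; P by one public-membership update; U by one private
    membership update.
    """
    from .fcm import initial_centroids

    T = len(tasks)
    counts = config.clusters_for(T)
    D = config.public_count(T)
    seeds = derive_task_seeds(config.seed, T)
    for t, task in enumerate(tasks):
        if counts[t] >= task.n_pixels:
            raise ValueError(
                f"task {t}: need n_clusters < n_pixels "
                f"(C={counts[t]}, N={task.n_pixels})"
            )
    pooled = np.concatenate([t.pixels for t in tasks])
    if initial_private is not None:
        V = [np.asarray(v, dtype=float).copy() for v in initial_private]
        if len(V) != T or any(v.size != counts[t] for t, v in enumerate(V)):
            raise ValueError("initial_private does not match the task layout")
    elif v_init == "random-pixels":
        V = [initial_centroids(tasks[t].pixels, counts[t], seeds[t]) for t in range(T)]
    elif v_init == "public-jitter":
        span = float(pooled.max() - pooled.min())
        jitter = 0.05 * span
        V = []
        for t in range(T):
            anchor = (
                _quantile_anchor(pooled, counts[t])
                if counts[t] != D
                else _quantile_anchor(pooled, D)
            )
            rng = np.random.default_rng(seeds[t])
            V.append(anchor + rng.uniform(-jitter, jitter, size=counts[t]))
    else:
        raise ValueError(f"unknown private-centroid init: {v_init!r}")
    Z = _initial_public_centroids(tasks, V, D, z_init)
    W = np.full((D, T), 1.0 / T)
    m = config.fuzzifier
    P = [update_public_membership(V[t], Z, W[:, t], m) for t in range(T)]
    U = [update_private_membership(tasks[t], V[t], m) for t in range(T)]
    return MultitaskState(U=U, V=V, P=P, Z=Z, W=W)


def wmt_sweep(tasks: list[TaskData], state: MultitaskState, config: WmtConfig) -> None:
    """One in-place block-coordinate sweep in the order U -> P -> V -> Z -> W."""
    m, lam, gamma = config.fuzzifier, config.balance, config.entropy_coef
    for t, task in enumerate(tasks):
        state.U[t] = update_private_membership(task, state.V[t], m)
    for t in range(len(tasks)):
        state.P[t] = update_public_membership(state.V[t], state.Z, state.W[:, t], m)
    for t, task in enumerate(tasks):
        state.V[t] = update_private_centroids(
            task, state.U[t], state.P[t], state.W[:, t], state.Z, m, lam,
            prev_centroids=state.V[t],
        )
    state.Z = update_public_centroids(
        state.V, state.P, state.W, m, prev_centroids=state.Z
    )
    state.W = update_weights(state.V, state.P, state.Z, m, lam, gamma)


def run_wmt_fcm(
    tasks: list[TaskData],
    config: WmtConfig,
    *,
    initial_private: list[np.ndarray] | None = None,
    v_init: str = "public-jitter",
    z_init: str = "quantile",
) -> tuple[list[SegmentationResult], MultitaskState]:
    """Run the multitask solver to convergence.

    Sweeps stop when the absolute change of the full objective falls below
    ``config.tol`` or after ``config.max_iter`` sweeps.  Returns one hard
    segmentation per task (labels = argmax of the private memberships) and
    the final block state.

    Unless ``config.normalize_intensities`` is off, pixel intensities are
    divided by their pooled maximum before clustering and all returned
    centroids are mapped back to the original scale; the objective trace
    stays in normalized units.  γ and the stopping tolerance act on that
    normalized scale, matching the scale the recommended γ grid assumes.
    """
    if len(tasks) < 1:
        raise ValueError("need at least one task")
    scale = max(float(np.max(np.abs(t.pixels))) for t in tasks)
    if not config.normalize_intensities or scale == 0.0:
        scale = 1.0
    if scale != 1.0:
        tasks = [
            TaskData(pixels=t.pixels / scale, shape=t.shape, task_id=t.task_id)
            for t in tasks
        ]
        if initial_private is not None:
            initial_private = [np.asarray(v) / scale for v in initial_private]
    state = initialize_state(
        tasks, config, z_init=z_init, v_init=v_init, initial_private=initial_private
    )
    prev_obj = np.inf
    for _ in range(config.max_iter):
        wmt_sweep(tasks, state, config)
        obj = wmt_objective(tasks, state, config)
        state.objective_trace.append(obj)
        logger.debug(
            "sweep %d: objective=%.6g", len(state.objective_trace), obj
        )
        if abs(prev_obj - obj) < config.tol:
            break
        prev_obj = obj
    if scale != 1.0:
        state.V = [v * scale for v in state.V]
        state.Z = state.Z * scale
    results = []
    for t, task in enumerate(tasks):
        results.append(
            SegmentationResult(
                memberships=state.U[t],
                centroids=state.V[t],
                labels=np.argmax(state.U[t], axis=0),
                objective_trace=np.asarray(state.objective_trace),
                n_iter=len(state.objective_trace),
            )
        )
    return results, state
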