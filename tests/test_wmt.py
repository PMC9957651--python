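"""Multitask solver: objective, block updates, limits, driver properties."""

import numpy as np
import pytest

from wmtfcm import TaskData, WmtConfig
from wmtfcm.fcm import fcm_membership_update, fcm_objective
from wmtfcm.multitask import (
    derive_task_seeds,
    dispersion,
    initialize_state,
    run_wmt_fcm,
    update_private_centroids,
    update_private_membership,
    update_public_centroids,
    update_public_membership,
    update_weights,
    wmt_objective,
    wmt_objective_terms,
    wmt_sweep,
)

from conftest import random_simplex_state


def task(values, tid="t"):
    values = np.asarray(values, dtype=float)
    return TaskData(pixels=values, shape=(values.size,), task_id=tid)


def brute_force_objective(tasks, state, lam, gamma, m):
    """Independent triple-loop evaluation of the multitask objective."""
    total = 0.0
    for t, tk in enumerate(tasks):
        C = state.V[t].size
        for i in range(tk.n_pixels):
            for j in range(C):
                total += state.U[t][j, i] ** m * (tk.pixels[i] - state.V[t][j]) ** 2
        for d in range(state.Z.size):
            for j in range(C):
                total += (
                    lam
                    * state.W[d, t]
                    * state.P[t][j, d] ** m
                    * (state.V[t][j] - state.Z[d]) ** 2
                )
            total += gamma * state.W[d, t] * np.log(state.W[d, t])
    return total


class TestObjective:
    def test_matches_brute_force_on_tiny_instance(self, rng):
        tasks = [task(rng.random(4), "a"), task(rng.random(4), "b")]
        state = random_simplex_state(rng, tasks, [2, 2], D=2)
        cfg = WmtConfig(n_clusters=2, n_public=2, balance=3.0, entropy_coef=0.7)
        expected = brute_force_objective(tasks, state, 3.0, 0.7, 2.0)
        assert wmt_objective(tasks, state, cfg) == pytest.approx(expected, rel=1e-12)

    def test_lambda_zero_first_term_is_sum_of_fcm_objectives(self, rng):
        tasks = [task(rng.random(5), "a"), task(rng.random(6), "b")]
        state = random_simplex_state(rng, tasks, [2, 2], D=2)
        cfg = WmtConfig(n_clusters=2, n_public=2, balance=0.0)
        fidelity, coupling, _ = wmt_objective_terms(tasks, state, cfg)
        assert coupling == 0.0
        per_task = sum(
            fcm_objective(tk, state.U[t], state.V[t], 2.0)
            for t, tk in enumerate(tasks)
        )
        assert fidelity == pytest.approx(per_task, rel=1e-12)

    def test_single_task_unit_weight_has_zero_entropy(self, rng):
        tasks = [task(rng.random(4))]
        state = random_simplex_state(rng, tasks, [2], D=2)
        state.W = np.ones((2, 1))
        cfg = WmtConfig(n_clusters=2, n_public=2)
        assert wmt_objective_terms(tasks, state, cfg)[2] == 0.0

    def test_constraint_violation_rejected(self, rng):
        tasks = [task(rng.random(4))]
        state = random_simplex_state(rng, tasks, [2], D=2)
        state.U[0] = state.U[0] * 1.5
        with pytest.raises(ValueError):
            wmt_objective(tasks, state, WmtConfig(n_clusters=2, n_public=2))


class TestBlockUpdates:
    def test_private_membership_delegates_to_fcm_form(self):
        t = task([0.25])
        U = update_private_membership(t, np.array([0.0, 1.0]), m=2)
        assert np.allclose(U[:, 0], [0.9, 0.1], atol=1e-12)
        assert np.array_equal(U, fcm_membership_update(t, np.array([0.0, 1.0]), 2))

    def test_public_membership_uniform_weights_reduces_to_distance_form(self):
        P = update_public_membership(
            np.array([0.25]), np.array([0.0, 1.0]), np.array([0.5, 0.5]), m=2
        )
        assert np.allclose(P[0], [0.9, 0.1], atol=1e-12)

    def test_public_membership_single_public_cluster(self):
        P = update_public_membership(
            np.array([0.1, 0.9]), np.array([0.4]), np.array([1.0]), m=2
        )
        assert np.allclose(P, 1.0)

    def test_public_membership_favors_low_weight_at_equal_distance(self):
        # equal distances, weights (0.9, 0.1): shares invert to (0.1, 0.9)
        P = update_public_membership(
            np.array([0.5]), np.array([0.0, 1.0]), np.array([0.9, 0.1]), m=2
        )
        assert np.allclose(P[0], [0.1, 0.9], atol=1e-12)

    def test_public_membership_rows_sum_to_one_with_coincidence(self):
        P = update_public_membership(
            np.array([0.0, 0.3]), np.array([0.0, 0.0, 1.0]),
            np.array([0.2, 0.5, 0.3]), m=2,
        )
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.allclose(P[0], [0.5, 0.5, 0.0])

    def test_private_centroids_lambda_zero_is_fcm_update(self, rng):
        from wmtfcm.fcm import fcm_centroid_update

        t = task(rng.random(6))
        U = rng.random((2, 6))
        U /= U.sum(axis=0)
        P = np.full((2, 2), 0.5)
        V = update_private_centroids(
            t, U, P, np.array([0.5, 0.5]), np.array([0.2, 0.8]), 2.0, balance=0.0
        )
        assert np.allclose(V, fcm_centroid_update(t, U, 2.0))

    def test_private_centroids_dominated_by_public_at_huge_lambda(self, rng):
        t = task(rng.random(5))
        U = rng.random((2, 5))
        U /= U.sum(axis=0)
        V = update_private_centroids(
            t, U, np.ones((2, 1)), np.array([1.0]), np.array([7.0]), 2.0,
            balance=1e9,
        )
        assert np.abs(V - 7.0).max() < 1e-3

    def test_private_centroids_match_brute_ratio(self, rng):
        t = task(rng.random(4))
        state = random_simplex_state(rng, [t], [2], D=2)
        lam = 2.5
        V = update_private_centroids(
            t, state.U[0], state.P[0], state.W[:, 0], state.Z, 2.0, lam
        )
        for j in range(2):
            num = np.sum(state.U[0][j] ** 2 * t.pixels) + lam * np.sum(
                state.W[:, 0] * state.P[0][j] ** 2 * state.Z
            )
            den = np.sum(state.U[0][j] ** 2) + lam * np.sum(
                state.W[:, 0] * state.P[0][j] ** 2
            )
            assert V[j] == pytest.approx(num / den, rel=1e-12)

    def test_public_centroid_single_task_single_cluster_is_mean(self):
        V = [np.array([1.0, 3.0])]
        P = [np.ones((2, 1))]
        W = np.ones((1, 1))
        assert update_public_centroids(V, P, W, 2.0)[0] == pytest.approx(2.0)

    def test_public_centroids_weight_invariant_for_identical_tasks(self, rng):
        V = [np.array([0.1, 0.9]), np.array([0.1, 0.9])]
        P = [np.array([[0.8, 0.2], [0.3, 0.7]])] * 2
        W1 = np.array([[0.5, 0.5], [0.5, 0.5]])
        W2 = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert np.allclose(
            update_public_centroids(V, P, W1, 2.0),
            update_public_centroids(V, P, W2, 2.0),
        )

    def test_public_centroids_match_brute_weighted_mean(self, rng):
        tasks = [task(rng.random(4), "a"), task(rng.random(5), "b")]
        state = random_simplex_state(rng, tasks, [2, 3], D=2)
        Z = update_public_centroids(state.V, state.P, state.W, 2.0)
        for d in range(2):
            num = den = 0.0
            for t in range(2):
                for j in range(state.V[t].size):
                    mass = state.W[d, t] * state.P[t][j, d] ** 2
                    num += mass * state.V[t][j]
                    den += mass
            assert Z[d] == pytest.approx(num / den, rel=1e-12)


class TestWeights:
    def test_single_task_gets_unit_weight(self, rng):
        t = [task(rng.random(4))]
        s = random_simplex_state(rng, t, [2], D=3)
        W = update_weights(s.V, s.P, s.Z, 2.0, balance=5.0, entropy_coef=0.5)
        assert np.allclose(W, 1.0)

    def test_identical_tasks_share_uniformly(self):
        V = [np.array([0.2, 0.8])] * 3
        P = [np.array([[0.7, 0.3], [0.4, 0.6]])] * 3
        W = update_weights(V, P, np.array([0.3, 0.9]), 2.0, 10.0, 0.7)
        assert np.allclose(W, 1.0 / 3.0)

    def test_softmax_hand_example(self):
        """Dispersion terms 0 and ln 9 at lambda=gamma=1 give weights 0.9/0.1."""
        # task 1: private centroid sits on z (dispersion 0)
        # task 2: p=1, (v-z)^2 = ln 9
        V = [np.array([0.0]), np.array([np.sqrt(np.log(9.0))])]
        P = [np.ones((1, 1)), np.ones((1, 1))]
        Z = np.array([0.0])
        disp = dispersion(V, P, Z, 2.0)
        assert disp[0, 0] == 0.0
        assert disp[0, 1] == pytest.approx(np.log(9.0), rel=1e-12)
        W = update_weights(V, P, Z, 2.0, balance=1.0, entropy_coef=1.0)
        assert np.allclose(W[0], [0.9, 0.1], atol=1e-12)

    def test_flat_limit_large_gamma(self, rng):
        tasks = [task(rng.random(5), "a"), task(rng.random(5), "b"),
                 task(rng.random(5), "c")]
        s = random_simplex_state(rng, tasks, [2, 2, 2], D=2)
        W = update_weights(s.V, s.P, s.Z, 2.0, balance=50.0, entropy_coef=1e9)
        assert np.abs(W - 1.0 / 3.0).max() < 1e-6

    def test_sharp_limit_small_gamma(self, rng):
        tasks = [task(rng.random(5), "a"), task(rng.random(5), "b")]
        s = random_simplex_state(rng, tasks, [2, 2], D=2)
        disp = dispersion(s.V, s.P, s.Z, 2.0)
        assert np.abs(np.diff(disp, axis=1)).min() > 0  # strict ordering
        W = update_weights(s.V, s.P, s.Z, 2.0, balance=1.0, entropy_coef=1e-9)
        onehot = np.zeros_like(W)
        onehot[np.arange(2), np.argmin(disp, axis=1)] = 1.0
        assert np.allclose(W, onehot)

    def test_no_overflow_for_extreme_dispersions(self):
        V = [np.array([0.0]), np.array([1e6])]
        P = [np.ones((1, 1))] * 2
        W = update_weights(V, P, np.array([0.0]), 2.0, 100.0, 0.1)
        assert np.all(np.isfinite(W))
        assert np.allclose(W.sum(axis=1), 1.0)


class TestDriver:
    def test_simplex_constraints_after_every_sweep(self, phantom_group):
        tasks = [t for t, _ in phantom_group]
        cfg = WmtConfig(n_clusters=4, seed=0)
        scale = max(t.pixels.max() for t in tasks)
        scaled = [TaskData(t.pixels / scale, t.shape, t.task_id) for t in tasks]
        state = initialize_state(scaled, cfg)
        for _ in range(8):
            wmt_sweep(scaled, state, cfg)
            for U in state.U:
                assert np.abs(U.sum(axis=0) - 1.0).max() < 1e-9
            for P in state.P:
                assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-9
            assert np.abs(state.W.sum(axis=1) - 1.0).max() < 1e-9

    def test_objective_trace_non_increasing(self, phantom_group):
        tasks = [t for t, _ in phantom_group]
        _, state = run_wmt_fcm(tasks, WmtConfig(n_clusters=4, seed=1))
        tr = np.asarray(state.objective_trace)
        assert np.all(np.diff(tr) <= 1e-8 * np.maximum(np.abs(tr[:-1]), 1.0))

    def test_seed_determinism(self, phantom_group):
        tasks = [t for t, _ in phantom_group]
        r1, s1 = run_wmt_fcm(tasks, WmtConfig(n_clusters=4, seed=5))
        r2, s2 = run_wmt_fcm(tasks, WmtConfig(n_clusters=4, seed=5))
        assert np.array_equal(s1.Z, s2.Z)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.labels, b.labels)

    def test_lambda_zero_reduces_to_fcm_trajectories(self, phantom_group):
        """With no coupling and shared init, private blocks follow plain FCM."""
        from wmtfcm.fcm import fcm_centroid_update, initial_centroids

        tasks = [t for t, _ in phantom_group]
        seeds = derive_task_seeds(9, len(tasks))
        init = [initial_centroids(t.pixels, 4, s) for t, s in zip(tasks, seeds)]
        cfg = WmtConfig(
            n_clusters=4, balance=0.0, seed=9, normalize_intensities=False
        )
        state = initialize_state(tasks, cfg, initial_private=init)
        V_ref = [v.copy() for v in init]
        for _ in range(10):
            wmt_sweep(tasks, state, cfg)
            for t, tk in enumerate(tasks):
                U_ref = fcm_membership_update(tk, V_ref[t], 2.0)
                V_ref[t] = fcm_centroid_update(tk, U_ref, 2.0, V_ref[t])
                assert np.abs(state.U[t] - U_ref).max() <= 1e-10
                assert np.abs(state.V[t] - V_ref[t]).max() <= 1e-10

    def test_public_centroids_recover_shared_class_means(self, phantom_group):
        tasks = [t for t, _ in phantom_group]
        _, state = run_wmt_fcm(tasks, WmtConfig(n_clusters=4, seed=33))
        assert np.abs(np.sort(state.Z) - [0.0, 60.0, 120.0, 180.0]).max() < 5.0

    def test_rejects_empty_or_degenerate_input(self):
        with pytest.raises(ValueError):
            run_wmt_fcm([], WmtConfig(n_clusters=2))
        with pytest.raises(ValueError):
            run_wmt_fcm([task([1.0, 2.0])], WmtConfig(n_clusters=4))

    def test_checkpoint_is_json_serializable(self, phantom_group):
        import json

        tasks = [t for t, _ in phantom_group]
        _, state = run_wmt_fcm(tasks, WmtConfig(n_clusters=4, seed=2, max_iter=3))
        text = json.dumps(state.to_checkpoint())
        back = json.loads(text)
        assert np.allclose(back["public_centroids"], state.Z)
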