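import logging

import numpy as np
import pytest

from wmtfcm import TaskData, generate_task_group

# degenerate-cluster warnings are expected in stress tests
logging.getLogger("wmtfcm").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blob_task(rng):
    """Two tight, well-separated intensity groups at 0 and 10."""
    x = np.concatenate([rng.normal(0, 0.01, 50), rng.normal(10, 0.01, 50)])
    return TaskData(pixels=x, shape=(100,), task_id="blobs")


@pytest.fixture
def phantom_group():
    """Three related 64x64 phantom tasks at mixed noise/INU settings."""
    return generate_task_group(
        3, [(1, 20), (5, 20), (7, 0)], shape=(64, 64), seeds=[1, 2, 3],
        geometry_seed=5,
    )


def random_simplex_state(rng, tasks, counts, D):
    """A random constraint-satisfying multitask state for oracle tests."""
    from wmtfcm.types import MultitaskState

    T = len(tasks)
    U = []
    P = []
    V = []
    for t, task in enumerate(tasks):
        u = rng.random((counts[t], task.n_pixels)) + 0.1
        U.append(u / u.sum(axis=0, keepdims=True))
        p = rng.random((counts[t], D)) + 0.1
        P.append(p / p.sum(axis=1, keepdims=True))
        V.append(rng.random(counts[t]))
    W = rng.random((D, T)) + 0.1
    W = W / W.sum(axis=1, keepdims=True)
    return MultitaskState(U=U, V=V, P=P, Z=rng.random(D), W=W)
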