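"""Core data containers shared across the package.

All containers are thin dataclasses around numpy arrays; validation happens
at construction so downstream numerics can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


@dataclass
class TaskData:
    """One clustering task: a flattened grayscale image.

    Parameters
    ----------
    pixels
        1-D vector of N non-negative intensities (arbitrary units).
    shape
        Original image dimensions; ``pixels`` is the row-major flattening
        of the image and round-trips through :meth:`to_image`.
    task_id
        Free-form label used in result tables.
    """

    pixels: np.ndarray
    shape: tuple[int, ...]
    task_id: str = "task"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float).ravel()
        self.shape = tuple(int(s) for s in self.shape)
        if self.pixels.size < 1:
            raise ValueError("task needs at least one pixel")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if int(np.prod(self.shape)) != self.pixels.size:
            raise ValueError(
                f"shape {self.shape} does not match {self.pixels.size} pixels"
            )

    @classmethod
    def from_image(cls, image: np.ndarray, task_id: str = "task") -> "TaskData":
        image = np.asarray(image, dtype=float)
        return cls(pixels=image.ravel(order="C"), shape=image.shape, task_id=task_id)

    def to_image(self, values: np.ndarray | None = None) -> np.ndarray:
        """Reshape ``values`` (default: the pixels) back to the image grid."""
        v = self.pixels if values is None else np.asarray(values)
        return v.reshape(self.shape, order="C")

    @property
    def n_pixels(self) -> int:
        return self.pixels.size


@dataclass(frozen=True)
class FcmConfig:
    """Settings for classical single-task fuzzy C-means.

    ``fuzzifier`` m > 1 controls membership softness (m = 2 is the MRI
    convention), ``tol`` is the absolute objective-change stopping
    threshold and ``max_iter`` caps the alternating updates.
    """

    n_clusters: int
    fuzzifier: float = 2.0
    tol: float = 1e-4
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not self.fuzzifier > 1:
            raise ValueError("fuzzifier must be > 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class WmtConfig:
    """Settings for the weighted multitask solver.

    ``balance`` (λ ≥ 0) scales the coupling between private and public
    centroids; ``entropy_coef`` (γ > 0) is the Shannon-entropy coefficient
    of the task-weight regularizer (large γ flattens weights toward 1/T,
    small γ sharpens them toward one-hot).  ``n_public`` defaults to the
    largest per-task cluster count.  The defaults λ = 60 and γ = 0.6 are
    the midpoints of the recommended search grids {20,…,120} and
    {0.2,…,1.2}; those grids are calibrated to unit-normalized
    intensities, so by default the solver rescales the pooled intensities
    to [0, 1] internally and maps centroids back (membership updates and
    λ are scale-invariant, only γ and the tolerance are scale-sensitive).
    """

    n_clusters: int | Sequence[int] = 4
    n_public: int | None = None
    fuzzifier: float = 2.0
    balance: float = 60.0
    entropy_coef: float = 0.6
    tol: float = 1e-4
    max_iter: int = 100
    seed: int = 0
    normalize_intensities: bool = True

    def __post_init__(self) -> None:
        counts = self.clusters_for(1) if np.isscalar(self.n_clusters) else self.n_clusters
        if any(c < 1 for c in np.atleast_1d(counts)):
            raise ValueError("every per-task cluster count must be >= 1")
        if self.n_public is not None and self.n_public < 1:
            raise ValueError("n_public must be >= 1")
        if not self.fuzzifier > 1:
            raise ValueError("fuzzifier must be > 1")
        if self.balance < 0:
            raise ValueError("balance (lambda) must be >= 0")
        if not self.entropy_coef > 0:
            raise ValueError("entropy_coef (gamma) must be > 0")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def clusters_for(self, n_tasks: int) -> list[int]:
        """Per-task cluster counts, broadcasting a scalar to all tasks."""
        if np.isscalar(self.n_clusters):
            return [int(self.n_clusters)] * n_tasks
        counts = [int(c) for c in self.n_clusters]  # type: ignore[union-attr]
        if len(counts) != n_tasks:
            raise ValueError(
                f"got {len(counts)} cluster counts for {n_tasks} tasks"
            )
        return counts

    def public_count(self, n_tasks: int) -> int:
        if self.n_public is not None:
            return int(self.n_public)
        return max(self.clusters_for(n_tasks))


@dataclass
class SegmentationResult:
    """Outcome of one clustering run on one task.

    ``memberships`` is the C×N fuzzy partition (columns on the simplex),
    ``labels`` the hard argmax assignment, ``objective_trace`` the
    objective value after each iteration.
    """

    memberships: np.ndarray
    centroids: np.ndarray
    labels: np.ndarray
    objective_trace: np.ndarray
    n_iter: int

    def label_image(self, task: TaskData) -> np.ndarray:
        return task.to_image(self.labels)


@dataclass
class MultitaskState:
    """Full block state of the multitask solver.

    Per task t: private memberships ``U[t]`` (C_t×N_t), private centroids
    ``V[t]`` (C_t), public memberships ``P[t]`` (C_t×D, rows on the
    simplex).  Shared: public centroids ``Z`` (D) and the D×T weight
    matrix ``W`` whose rows (one per public cluster) sum to 1 over tasks.
    """

    U: list[np.ndarray]
    V: list[np.ndarray]
    P: list[np.ndarray]
    Z: np.ndarray
    W: np.ndarray
    objective_trace: list[float] = field(default_factory=list)

    @property
    def n_tasks(self) -> int:
        return len(self.V)

    def to_checkpoint(self) -> dict:
        """JSON-serializable snapshot of centroids and weights."""
        return {
            "private_centroids": [v.tolist() for v in self.V],
            "public_centroids": self.Z.tolist(),
            "weights": self.W.tolist(),
        }


@dataclass
class Phantom:
    """Synthetic T1-like slice with ground truth and generating parameters.

    ``truth`` labels: 0 = background, 1 = CSF, 2 = GM, 3 = WM.
    """

    image: np.ndarray
    truth: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        if self.image.shape != self.truth.shape:
            raise ValueError("image and truth must share a shape")

    def as_task(self, task_id: str | None = None) -> TaskData:
        tid = task_id or self.params.get("task_id", "phantom")
        return TaskData.from_image(self.image, task_id=tid)


@dataclass
class MetricsReport:
    """Per-tissue Dice, pooled average Dice, and segmentation accuracy."""

    dsc_per_class: Mapping[str, float]
    dsc_av: float
    sa: float
    alignment: Mapping[int, int]

    def to_row(self) -> dict:
        row = {"SA": self.sa, "DSC_av": self.dsc_av}
        for tissue, value in self.dsc_per_class.items():
            row[f"DSC_{tissue}"] = value
        return row
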