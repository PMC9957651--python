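"""Experiment protocols: grid search, noise sweep, repeated-trial stability.

All protocols run on synthetic phantom task groups (real volumes can be
segmented through the CLI instead).  The phantom group is fixed per
experiment — repeated trials vary only the clustering initialization
seed, mirroring how segmentation variability is attributed to the random
centroid initialization.  Every result row carries full provenance
(algorithm, λ, γ, seeds, phantom parameters) so it can be regenerated
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fcm import run_fcm
from .metrics import evaluate_segmentation
from .multitask import derive_task_seeds, run_wmt_fcm
from .phantoms import DEFAULT_CLASS_MEANS, STUDY_SETTINGS, generate_task_group
from .types import FcmConfig, TaskData, WmtConfig

#: recommended parameter search grids
LAMBDA_GRID = (20.0, 40.0, 60.0, 80.0, 100.0, 120.0)
GAMMA_GRID = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2)


@dataclass
class ExperimentConfig:
    """One experiment's settings (defaults mirror the study protocol)."""

    algorithm: str = "both"  # "fcm" | "wmt_fcm" | "both"
    settings: list[tuple[float, float]] = field(
        default_factory=lambda: list(STUDY_SETTINGS[:3])
    )
    class_means: tuple[float, ...] = DEFAULT_CLASS_MEANS
    shape: tuple[int, int] = (128, 128)
    lam_grid: tuple[float, ...] = LAMBDA_GRID
    gamma_grid: tuple[float, ...] = GAMMA_GRID
    balance: float = 60.0
    entropy_coef: float = 0.6
    n_clusters: int = 4
    n_public: int | None = None
    fuzzifier: float = 2.0
    tol: float = 1e-4
    max_iter: int = 100
    n_trials: int = 10
    seed: int = 0

    def wmt_config(self, seed: int, balance=None, entropy_coef=None) -> WmtConfig:
        return WmtConfig(
            n_clusters=self.n_clusters,
            n_public=self.n_public,
            fuzzifier=self.fuzzifier,
            balance=self.balance if balance is None else balance,
            entropy_coef=self.entropy_coef if entropy_coef is None else entropy_coef,
            tol=self.tol,
            max_iter=self.max_iter,
            seed=seed,
        )


def trial_seed(master_seed: int, trial: int) -> int:
    """Deterministic, independently reproducible seed for trial k."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(7, trial))
    return int(ss.generate_state(1)[0] % 2**31)


def make_group(config: ExperimentConfig) -> list[tuple[TaskData, np.ndarray]]:
    """The experiment's fixed phantom task group (seeded by ``config.seed``)."""
    n = len(config.settings)
    seeds = [
        int(np.random.SeedSequence(entropy=config.seed, spawn_key=(3, t)).generate_state(1)[0] % 2**31)
        for t in range(n)
    ]
    return generate_task_group(
        n_tasks=n,
        settings=config.settings,
        class_means=config.class_means,
        seeds=seeds,
        shape=config.shape,
        geometry_seed=config.seed,
    )


def segment_group(
    group: list[tuple[TaskData, np.ndarray]],
    config: ExperimentConfig,
    algorithm: str,
    seed: int,
    balance: float | None = None,
    entropy_coef: float | None = None,
) -> list[dict]:
    """Run one algorithm once on a task group and score every task.

    FCM segments each task independently; both algorithms draw their
    per-task initial centroids from the same split of ``seed`` so repeated
    trials compare like with like.
    """
    tasks = [t for t, _ in group]
    truths = [tr for _, tr in group]
    lam = config.balance if balance is None else balance
    gam = config.entropy_coef if entropy_coef is None else entropy_coef
    if algorithm == "wmt_fcm":
        results, _ = run_wmt_fcm(tasks, config.wmt_config(seed, lam, gam))
    elif algorithm == "fcm":
        task_seeds = derive_task_seeds(seed, len(tasks))
        results = [
            run_fcm(
                task,
                FcmConfig(
                    n_clusters=config.n_clusters,
                    fuzzifier=config.fuzzifier,
                    tol=config.tol,
                    max_iter=config.max_iter,
                    seed=task_seeds[t],
                ),
            )
            for t, task in enumerate(tasks)
        ]
    else:
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    rows = []
    for t, (task, truth, res) in enumerate(zip(tasks, truths, results)):
        report = evaluate_segmentation(res.labels.reshape(truth.shape), truth)
        noise_pct, inu_pct = config.settings[t]
        row = {
            "algorithm": algorithm,
            "task_id": task.task_id,
            "noise_pct": noise_pct,
            "inu_pct": inu_pct,
            "lambda": lam if algorithm == "wmt_fcm" else np.nan,
            "gamma": gam if algorithm == "wmt_fcm" else np.nan,
            "seed": seed,
            "n_iter": res.n_iter,
        }
        row.update(report.to_row())
        rows.append(row)
    return rows


def _algorithms(config: ExperimentConfig) -> list[str]:
    return ["fcm", "wmt_fcm"] if config.algorithm == "both" else [config.algorithm]


def run_grid_search(
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, dict]:
    """Exhaustive (λ, γ) grid search with repeated seeded trials per cell.

    Returns the full per-trial table and the best cell: the one with the
    highest mean SA, ties broken by higher mean DSC_av, then smaller λ,
    then smaller γ.
    """
    if len(config.lam_grid) == 0 or len(config.gamma_grid) == 0:
        raise ValueError("grids must not be empty")
    group = make_group(config)
    rows = []
    for lam in config.lam_grid:
        for gam in config.gamma_grid:
            for k in range(config.n_trials):
                seed = trial_seed(config.seed, k)
                for r in segment_group(
                    group, config, "wmt_fcm", seed, balance=lam, entropy_coef=gam
                ):
                    r["trial"] = k
                    rows.append(r)
    table = pd.DataFrame(rows)
    means = (
        table.groupby(["lambda", "gamma"])[["SA", "DSC_av"]].mean().reset_index()
    )
    means = means.sort_values(
        by=["SA", "DSC_av", "lambda", "gamma"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    top = means.iloc[0]
    best = {
        "lambda": float(top["lambda"]),
        "gamma": float(top["gamma"]),
        "mean_SA": float(top["SA"]),
        "mean_DSC_av": float(top["DSC_av"]),
    }
    return table, best


def run_noise_sweep(
    config: ExperimentConfig,
    noise_levels: tuple[float, ...] = (1, 3, 5, 7, 9),
    inu_pct: float = 20.0,
) -> pd.DataFrame:
    """SA / DSC_av versus noise level at fixed INU, per algorithm.

    Every task of the group is corrupted at the same noise level for each
    sweep point; curves are the per-level means over trials and tasks.
    """
    if len(noise_levels) == 0:
        raise ValueError("noise_levels must not be empty")
    rows = []
    for noise in noise_levels:
        level_cfg = replace(
            config, settings=[(noise, inu_pct)] * len(config.settings)
        )
        group = make_group(level_cfg)
        for algorithm in _algorithms(config):
            for k in range(config.n_trials):
                seed = trial_seed(config.seed, k)
                for r in segment_group(group, level_cfg, algorithm, seed):
                    r["trial"] = k
                    r["sweep_noise_pct"] = noise
                    rows.append(r)
    return pd.DataFrame(rows)


def run_stability_trials(config: ExperimentConfig) -> pd.DataFrame:
    """Repeated trials on one fixed task group; only the init seed varies.

    The per-algorithm standard deviation of SA over trials measures
    sensitivity to centroid initialization.
    """
    group = make_group(config)
    rows = []
    for algorithm in _algorithms(config):
        for k in range(config.n_trials):
            seed = trial_seed(config.seed, k)
            for r in segment_group(group, config, algorithm, seed):
                r["trial"] = k
                rows.append(r)
    return pd.DataFrame(rows)


def stability_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and std of per-trial mean SA, per algorithm."""
    per_trial = table.groupby(["algorithm", "trial"])["SA"].mean().reset_index()
    return per_trial.groupby("algorithm")["SA"].agg(["mean", "std"]).reset_index()
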