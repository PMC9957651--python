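"""BrainWeb-style synthetic phantoms.

Each phantom is a 2-D T1-like slice built from a nested-region geometry
(background ring, CSF band, GM band, WM core — concentric smoothed shapes,
sufficient for intensity-only clustering), a piecewise-constant intensity
image at the four class means, a smooth multiplicative intensity
nonuniformity (INU) field, and additive noise.

Conventions follow the BrainWeb simulator's parameterization:
- noise percent p: zero-mean Gaussian with sigma = (p/100) * brightest
  class mean (Rician available, since magnitude MR noise is Rician);
- INU percent q: multiplicative field spanning [1 - q/200, 1 + q/200]
  (20% INU => [0.9, 1.1]), applied to the clean image before noise.

The nine (noise%, INU%) study settings are exposed as STUDY_SETTINGS.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import Phantom, TaskData

#: default class means (background, CSF, GM, WM) in intensity units
DEFAULT_CLASS_MEANS = (0.0, 60.0, 120.0, 180.0)

#: the nine (noise_pct, inu_pct) image settings of the study protocol
STUDY_SETTINGS = [
    (1, 20), (5, 20), (7, 0), (1, 0), (7, 20), (9, 20), (3, 20), (3, 0), (5, 0),
]

# nested-region radii as fractions of the brain radius: WM core, GM band,
# CSF band; outside is background
_RADII = (0.45, 0.70, 0.85)


def nested_geometry(
    shape: tuple[int, int], seed: int = 0, wobble: float = 0.06
) -> np.ndarray:
    """Ground-truth label map of concentric, smoothly perturbed regions.

    The boundary radii are modulated by a seeded low-order Fourier series
    in the polar angle so the regions are not perfect ellipses; labels are
    0 = background, 1 = CSF, 2 = GM, 3 = WM.
    """
    h, w = shape
    if h < 32 or w < 32:
        raise ValueError("phantom shape must be at least 32x32")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    brain_r = 0.46 * min(h, w)
    rho = np.hypot((yy - cy), (xx - cx)) / brain_r
    theta = np.arctan2(yy - cy, xx - cx)
    bump = np.zeros_like(theta)
    for k in (2, 3, 4):
        a, b = rng.normal(0, wobble / 2, size=2)
        bump += a * np.cos(k * theta) + b * np.sin(k * theta)
    rho = rho * (1.0 + bump)
    truth = np.zeros(shape, dtype=np.int64)
    truth[rho < 1.0] = 1                # CSF outer band
    truth[rho < _RADII[1] / _RADII[2]] = 2   # GM band
    truth[rho < _RADII[0] / _RADII[2]] = 3   # WM core
    return truth


def inu_field(shape: tuple[int, int], inu_pct: float, seed: int = 0) -> np.ndarray:
    """Smooth multiplicative bias field spanning [1 - q/200, 1 + q/200].

    Low-frequency random field: white noise blurred with a Gaussian of
    sigma = min(shape)/4, then affinely rescaled so its min and max hit
    the span endpoints exactly.
    """
    if inu_pct < 0:
        raise ValueError("inu_pct must be >= 0")
    if inu_pct == 0:
        return np.ones(shape)
    rng = np.random.default_rng(seed)
    raw = gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 4.0)
    lo, hi = 1.0 - inu_pct / 200.0, 1.0 + inu_pct / 200.0
    rmin, rmax = raw.min(), raw.max()
    return lo + (raw - rmin) * (hi - lo) / (rmax - rmin)


def generate_phantom(
    shape: tuple[int, int] = (128, 128),
    class_means: tuple[float, ...] = DEFAULT_CLASS_MEANS,
    noise_pct: float = 0.0,
    inu_pct: float = 0.0,
    seed: int = 0,
    geometry: np.ndarray | None = None,
    geometry_seed: int | None = None,
    noise_model: str = "gaussian",
) -> Phantom:
    """Build one synthetic slice with ground truth.

    ``seed`` drives the INU field and the noise; ``geometry_seed``
    (default: the same seed) drives only the region shapes, so task
    groups can share anatomy while drawing independent corruption.
    A pre-made label map can be passed as ``geometry`` instead.
    Intensities are clipped at 0 after noise.
    """
    means = np.asarray(class_means, dtype=float)
    if means.size != 4 or np.any(np.diff(means) <= 0):
        raise ValueError("class_means must be 4 strictly increasing values")
    if noise_pct < 0:
        raise ValueError("noise_pct must be >= 0")
    if geometry is not None:
        truth = np.asarray(geometry, dtype=np.int64)
        if truth.shape != tuple(shape):
            raise ValueError("supplied geometry does not match shape")
    else:
        gseed = seed if geometry_seed is None else geometry_seed
        truth = nested_geometry(tuple(shape), seed=gseed)
    clean = means[truth]
    rng = np.random.default_rng(seed)
    image = clean * inu_field(tuple(shape), inu_pct, seed=int(rng.integers(2**31)))
    sigma = (noise_pct / 100.0) * means.max()
    if sigma > 0:
        if noise_model == "gaussian":
            image = image + rng.normal(0.0, sigma, size=image.shape)
        elif noise_model == "rician":
            image = np.hypot(
                image + rng.normal(0.0, sigma, size=image.shape),
                rng.normal(0.0, sigma, size=image.shape),
            )
        else:
            raise ValueError(f"unknown noise model: {noise_model!r}")
    image = np.clip(image, 0.0, None)
    return Phantom(
        image=image,
        truth=truth,
        params={
            "class_means": tuple(means.tolist()),
            "noise_pct": float(noise_pct),
            "inu_pct": float(inu_pct),
            "seed": int(seed),
            "geometry_seed": int(seed if geometry_seed is None else geometry_seed),
            "geometry": "nested" if geometry is None else "supplied",
            "noise_model": noise_model,
            "shape": tuple(int(s) for s in shape),
        },
    )


def generate_task_group(
    n_tasks: int,
    settings: list[tuple[float, float]],
    class_means: tuple[float, ...] = DEFAULT_CLASS_MEANS,
    seeds: list[int] | None = None,
    shape: tuple[int, int] = (128, 128),
    geometry_seed: int = 0,
    noise_model: str = "gaussian",
) -> list[tuple[TaskData, np.ndarray]]:
    """A group of related tasks: shared class means and anatomy, distinct noise.

    One (noise_pct, inu_pct) setting per task; ``seeds`` default to
    0..n_tasks-1.  The shared means are the common information the
    multitask solver exploits.
    """
    if len(settings) == 0:
        raise ValueError("settings must not be empty")
    if len(settings) != n_tasks:
        raise ValueError(f"need one (noise, inu) setting per task, got {len(settings)}")
    if seeds is None:
        seeds = list(range(n_tasks))
    if len(seeds) != n_tasks:
        raise ValueError("need one seed per task")
    out = []
    for t, ((noise_pct, inu_pct), seed) in enumerate(zip(settings, seeds)):
        ph = generate_phantom(
            shape=shape,
            class_means=class_means,
            noise_pct=noise_pct,
            inu_pct=inu_pct,
            seed=seed,
            geometry_seed=geometry_seed,
            noise_model=noise_model,
        )
        task = ph.as_task(task_id=f"task{t}_n{noise_pct:g}_inu{inu_pct:g}")
        out.append((task, ph.truth))
    return out
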