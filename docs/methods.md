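# Methods

## Model

Single-task FCM minimizes J = Σ_i Σ_j u_ij^m ‖x_i − v_j‖² over
memberships U (columns on the probability simplex) and centroids V by
alternating the closed-form updates

    u_ij = ‖x_i − v_j‖^(−2/(m−1)) / Σ_l ‖x_i − v_l‖^(−2/(m−1))
    v_j  = Σ_i u_ij^m x_i / Σ_i u_ij^m

The multitask extension couples T such problems through D public
centroids Z, public memberships P^(t) (one row per private centroid,
rows on the simplex over public clusters) and a weight matrix W whose
row for each public cluster is a distribution over tasks:

    J = Σ_t Σ_i Σ_j u_ij,t^m ‖x_i,t − v_j,t‖²
      + λ Σ_t Σ_d Σ_j w_d,t p_jd,t^m ‖v_j,t − z_d‖²
      + γ Σ_t Σ_d w_d,t log w_d,t

Eliminating the Lagrange multipliers of the three simplex constraints
gives closed-form block minimizers; one sweep applies them in the order
U → P → V → Z → W.  Each update is the exact minimizer of J with the
other blocks fixed, so the objective trace is non-increasing and the
stopping rule |ΔJ| < ε is well defined.  The weight update is a softmax,

    w_d,t = exp(−λ s_d,t / γ) / Σ_h exp(−λ s_d,h / γ),
    s_d,t = Σ_j p_jd,t^m ‖v_j,t − z_d‖²,

computed with the usual max-shift so it cannot overflow; γ → ∞ flattens
every weight row to 1/T and γ → 0 sharpens it to one-hot on the
smallest-dispersion task.

## Parameters

- m (fuzzifier, default 2): membership softness; 2 is the standard
  choice for MRI intensity clustering.
- λ (balance, default 60): strength of the private↔public coupling,
  dimensionless (both distance terms scale identically with intensity
  units).  Default is the midpoint of the recommended search grid
  {20, 40, 60, 80, 100, 120}.
- γ (entropy coefficient, default 0.6): temperature of the task-weight
  softmax, in units of squared *normalized* intensity.  Grid
  {0.2, 0.4, 0.6, 0.8, 1.0, 1.2}.
- ε = 1e-4 (absolute objective change on the normalized scale),
  K = 100 sweeps maximum, C = D = 4 clusters for the four tissue
  classes.

### Intensity normalization

γ and ε are scale-sensitive: the distance terms grow with the square of
the intensity units while the entropy term does not.  On raw 0–255-style
intensities λ·s/γ reaches 10⁴–10⁵, the softmax collapses to exact
one-hot, and the exact P-update then dumps all public membership onto
zero-weight clusters — the adaptive weighting degenerates.  The γ grid
above is only meaningful on unit-scaled data, so `run_wmt_fcm` divides
the pooled intensities by their maximum before clustering and maps all
centroids back afterwards (memberships and λ are scale-invariant; the
objective trace stays in normalized units).  `normalize_intensities=False`
disables this.

### Initialization

FCM initializes centroids as C distinct pixels drawn uniformly without
replacement under the seed — the standard random init whose trial-to-trial
variability the stability protocol measures.

For the multitask solver the public centroids start at the midpoints of
D equal-probability bins of the pooled intensity distribution, and the
private centroids start at those shared positions plus a small per-task
seeded jitter (5 % of the pooled range); W starts uniform and P by one
public-membership update.  This choice is deliberate: the coupling term
has total mass O(λ·D) ≈ 10² against a pixel term of O(N) ≈ 10³–10⁴ per
task, so it cannot pull a task out of a merged-cluster local optimum
after the fact — and two centroids that have merged exactly are
symmetry-locked forever.  The cross-task information therefore enters
where it is effective: at initialization.  Random-pixel private init and
a centroid-mean Z init are available as options (`v_init`, `z_init`).

## Numerical conventions

- Zero distances in any membership update: uniform split over the
  coinciding centroids (the limit of the update), deterministic.
- Inverse-power shares are computed after dividing by the slice minimum,
  so the dominant term is exactly 1 and the power never overflows.
- Zero-mass clusters (private or public): centroid frozen at its
  previous value, warning logged, never a crash.
- Weight entropy uses the convention 0·log 0 = 0 (clamp at 1e-300).
- Hard labels are the argmax over memberships; ties resolve to the
  lowest cluster index.
- Cluster-to-tissue alignment maximizes total overlap via optimal
  assignment on the contingency table; an intensity-ordering
  alternative (background < CSF < GM < WM for T1) is provided.
  Empty-vs-empty Dice is 1 by convention, empty-vs-non-empty 0.
  DSC_av pools overlaps and sizes over CSF/GM/WM before the ratio; it is
  not the arithmetic mean of the per-tissue Dice values.

## Synthetic phantoms

The generator emulates simulated T1 slices: a nested-region geometry
(background ring, CSF band, GM band, WM core; boundaries perturbed by a
seeded low-order Fourier series in the polar angle), piecewise-constant
class means (default 0, 60, 120, 180), a smooth multiplicative INU field
(blurred white noise rescaled so a q % field spans exactly
[1 − q/200, 1 + q/200], applied before noise), and additive zero-mean
Gaussian noise with σ = (p/100)·brightest mean (Rician optional, since
magnitude MR noise is Rician); intensities clip at 0.  Task groups share
geometry and class means and draw independent corruption — the shared
structure the multitask solver exploits.

What the phantoms do not emulate: anatomical shapes, partial-volume
mixing at tissue boundaries, spatially correlated noise, and multi-
sequence contrast.  Passing tests therefore demonstrate the clustering
and weighting mechanics under controlled intensity statistics, not
performance on real acquisitions.  Two inherent biases of corrupted
images are visible in the results and are not solver error: clipping at
0 lifts the effective background mean by ≈ 0.4 σ, and an INU field can
shift a region's effective mean by several percent.

## Experiment protocols and problem sizes

Grid search evaluates every (λ, γ) cell with repeated seeded trials and
selects the cell with the highest mean SA (ties: higher DSC_av, then
smaller λ, then smaller γ).  The noise sweep runs both algorithms over
increasing noise at fixed 20 % INU.  The stability protocol fixes one
task group and varies only the initialization seed; the standard
deviation of SA over trials measures initialization sensitivity.
Per-trial seeds split from the master seed through independent
`SeedSequence` spawn keys, so any trial is reproducible in isolation,
and every result row carries its full provenance.

The bundled tests and the acceptance script run on 64×64 phantoms with
three-task groups and ten repeated trials — large enough for stable
statistics (the noise-σ convention is verified at 128×128) while keeping
the whole suite in seconds.

## Known limitations

- Intensity-only clustering: no spatial regularization, so performance
  degrades faster with noise than spatially-aware variants would.
- The coupling rescues nothing after a private solver has merged two
  centroids (see Initialization); robustness to initialization comes
  from the shared starting point, with the coupling refining centroids
  and the weights selecting reliable tasks thereafter.
- λ is the sensitive parameter: very large values drag private
  centroids toward the consensus and can hurt tasks whose intensity
  profile genuinely deviates.
- Metrics assume one predicted cluster per tissue class (one-to-one
  alignment); over-segmentation requires choosing C > 4 deliberately and
  interpreting DSC per merged mask.
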