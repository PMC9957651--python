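# wmtfcm — weighted multitask fuzzy C-means for brain-MRI tissue segmentation

Segmenting a T1-weighted brain MRI slice into background, cerebrospinal
fluid (CSF), gray matter (GM) and white matter (WM) is commonly posed as
intensity clustering.  Classical fuzzy C-means (FCM) handles the fuzzy
tissue boundaries well but is sensitive to noise and to the random
initialization of its cluster centroids.  Different scans of brains,
however, share structure — their tissue intensities cluster around very
similar values — and that shared information can stabilize each
individual segmentation.

`wmtfcm` implements a weighted multitask FCM (WMT-FCM) that clusters T
related images jointly.  Each task t keeps private centroids
v<sub>j,t</sub> and memberships u<sub>ij,t</sub>; all tasks share D public
centroids z<sub>d</sub>, linked through fuzzy public memberships
p<sub>jd,t</sub> and an adaptive, entropy-regularized task-weight matrix
w<sub>d,t</sub>.  The joint objective is

```
J = Σ_t Σ_i Σ_j u_ij,t^m ‖x_i,t − v_j,t‖²
  + λ Σ_t Σ_d Σ_j w_d,t p_jd,t^m ‖v_j,t − z_d‖²
  + γ Σ_t Σ_d w_d,t log w_d,t
```

subject to Σ_j u<sub>ij,t</sub> = 1, Σ_d p<sub>jd,t</sub> = 1 and
Σ_t w<sub>d,t</sub> = 1.  Every block has a closed-form minimizer, so the
solver is plain block-coordinate descent (U → P → V → Z → W) with a
guaranteed non-increasing objective.  The optimal weights are a softmax
of the scaled negative dispersions: tasks whose private centroids sit
tightly around a public centroid earn a larger say in it.

The package also ships the classical FCM baseline, the evaluation metrics
used for tissue segmentation (per-tissue Dice, pooled average Dice over
CSF/GM/WM, and overall segmentation accuracy SA, with optimal
cluster-to-tissue alignment), a BrainWeb-style synthetic phantom
generator (four tissue classes, percentage-scaled Gaussian or Rician
noise, a smooth multiplicative intensity-nonuniformity field), and the
experiment protocols: (λ, γ) grid search, noise sweeps and
repeated-trial stability analysis.

## Worked example

Three related 128×128 phantom slices share the class means
(0, 60, 120, 180) but carry different corruption — (noise %, INU %) of
(1, 20), (5, 20) and (7, 0):

```python
import numpy as np
from wmtfcm import generate_task_group, run_wmt_fcm, WmtConfig
from wmtfcm.metrics import evaluate_segmentation

group = generate_task_group(
    3, [(1, 20), (5, 20), (7, 0)], shape=(128, 128),
    seeds=[1, 2, 3], geometry_seed=5,
)
tasks = [t for t, _ in group]
results, state = run_wmt_fcm(
    tasks, WmtConfig(n_clusters=4, balance=60, entropy_coef=0.6, seed=0)
)
print("public centroids:", np.round(np.sort(state.Z), 1))
for (task, truth), res in zip(group, results):
    r = evaluate_segmentation(res.labels.reshape(truth.shape), truth)
    print(f"{task.task_id}: SA={r.sa:.4f}  DSC_av={r.dsc_av:.4f}")
```

prints

```
public centroids: [  2.9  60.6 121.8 184.1]
task0_n1_inu20: SA=1.0000  DSC_av=1.0000
task1_n5_inu20: SA=0.9993  DSC_av=0.9991
task2_n7_inu0: SA=0.9881  DSC_av=0.9852
```

The public centroids land within a few intensity units of the shared
class means (the residual offsets reflect the intensity-nonuniformity
and noise-clipping bias of the corrupted images, not solver error), and
each task's hard segmentation matches its ground truth almost
pixel-for-pixel: SA is the fraction of correctly labeled pixels after
optimally matching clusters to tissues, and DSC_av pools the Dice
overlap of CSF, GM and WM (background excluded).

The same pipeline is available from the shell:

```bash
wmtfcm phantom --shape 128 128 --noise 5 --inu 20 --seed 2 --output ph
wmtfcm segment ph_image.png --algorithm wmt_fcm --clusters 4 --output seg/
wmtfcm evaluate --pred seg/ph_image_labels.png --truth ph_truth.png
wmtfcm gridsearch --config experiment.yaml --output grid.csv
wmtfcm sweep-noise --levels 1,3,5,7,9 --inu 20 --output sweep.csv
wmtfcm stability --trials 10 --output stability.csv
```

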