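# gapcross

Kinematic and EMG analysis of modular organization in mouse gap-crossing
jumps, with a synthetic jump-trial generator for validation against known
ground truth.

Gap-crossing jumps unfold as a stereotyped sequence — preparation,
propulsion, flight, landing — and the package quantifies that modular
structure from tracked body landmarks and hindlimb muscle recordings:

* **Phase segmentation** from hindpaw acceleration: the Savitzky–Golay
  second derivative of the paw trajectory rises sharply through
  propulsion, drops suddenly at takeoff, stays low through ballistic
  flight and spikes again at touch-down; scale-free thresholds on this
  trace recover the four phase boundaries.
* **Postural state space**: per-frame landmark coordinates are centered,
  flattened, and embedded by PCA. Stereotypy is summarized by the
  trial-to-centroid dispersion profile over takeoff-aligned time and by
  the time-by-time Euclidean similarity matrix, whose block structure is
  segmented by exact dynamic-programming changepoint detection.
* **Configuration modes and movement states**: pooled frames are
  clustered on a kNN graph by Leiden community detection at low
  resolution (postural clusters and their temporal occupancy), and the
  embedding dynamics are modeled by a sticky Gaussian AR-HMM
  `x_t | z_t=k ~ N(A_k x_{t-1..t-p} + b_k, Σ_k)` fitted by EM with scaled
  forward–backward recursions, implemented in full here.
* **EMG burst quantification**: sliding-RMS envelopes, per-phase burst
  peaks, and task-demand tuning of the pre-takeoff extensor burst with a
  random-intercept model `y_ij = β0 + β1 d_ij + u_i + ε_ij` fitted by
  REML through 1-D profiling of the variance ratio, with a Wald z test
  on the distance slope β1.
* **Closed-loop perturbation statistics**: suppression indices, pre/post
  joint-angle contrasts, movement latencies, Welch and paired t tests,
  Hedges' g with small-sample correction, timepoint-wise contrasts with
  Benjamini–Hochberg adjustment, and one-way ANOVA with Tukey HSD.

The synthetic generator (`gapcross.synth`) produces trials from a
hindpaw-rooted 2-D kinematic chain with per-phase posture templates,
ballistic flight, phase-locked amplitude-modulated-noise EMG, and
injectable stimulation effects — every analysis above can be validated
against the generator's ground truth.

## Worked example

```python
import numpy as np
from gapcross import (SynthConfig, generate_cohort, compute_acceleration,
                      segment_phases, cluster_postures)
from gapcross.posture import build_posture_matrix, fit_pca, embed

cfg = SynthConfig()                     # default study conditions
cohort = generate_cohort(cfg, n_animals=6, trials_per_condition=2, seed=0)

trial = cohort.trials[0]
seg = segment_phases(compute_acceleration(trial, "hindpaw"), trial.frame_rate)
print("boundaries:", seg.boundaries, "truth:", cohort.truths[0].phase_boundaries)

mats = [build_posture_matrix(t) for t in cohort.trials]
pca = fit_pca(mats)
pooled = np.vstack([embed(m, pca).scores for m in mats])
clus = cluster_postures(pooled, knn_k=15, resolution=0.1, seed=0)
print("clusters:", clus.n_clusters_)
```

prints

```
boundaries: (52, 78, 113) truth: (50, 80, 114)
clusters: 4
```

— the detected phase boundaries sit within two frames of the generator's
ground truth, and low-resolution community detection recovers exactly the
four postural configuration modes (crouched preparation, extended
propulsion, flexed flight, re-extended landing) that the generator
plants.

The same analyses run from the shell:

```bash
gapcross all --out results/run1 --seed 1          # full pipeline
gapcross segment --out results/seg --seed 2       # simulate + segmentation only
gapcross init-config --out my_config.yaml         # editable YAML config
```

Every run writes plain CSV/JSON artifacts plus a `manifest.json`
recording parameters and seed; reruns with the same config and seed are
bit-identical.

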