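# tramqc

Quality control and dynamic phenotyping of single-cell time-lapse tracks.

Automated segmentation-and-tracking pipelines (Harmony, CellProfiler,
Imaris, ...) fail on a sizeable fraction of cells: identities swap, nuclei
split or merge, debris gets tracked.  Those failures show up as sudden,
unusually large changes that hit several measured quantities — position,
area, shape — at the same time point, and they bias every downstream
estimate of motility, morphology or signaling kinetics.  `tramqc`
implements a two-step filter for anyone analyzing per-cell tracking tables:

1. **Incomplete-track removal** — cells without a measurement at every time
   point (mostly floating debris and border-crossers) are dropped.
2. **Aberration filtering** with the **Tracking Aberration Measure (TrAM, τ)**:

   For each track, every included time series *m<sub>i</sub>* is compared
   with its smoothed baseline *m̂<sub>i</sub>* (cubic regression spline,
   5 knots by default) in units of the population-typical frame-to-frame
   fluctuation *s<sub>i</sub>* (the median |m<sub>i,t+1</sub> −
   m<sub>i,t</sub>| across the cohort):

   z<sub>it</sub> = |m<sub>it</sub> − m̂<sub>it</sub>| / s<sub>i</sub>,  
   τ = max<sub>t</sub> [ (1/N) Σ<sub>i</sub> z<sub>it</sub><sup>p</sup> ]<sup>1/p</sup>,  p = 0.5.

   Because p < 1, a given total deviation scores highest when spread across
   *all* series simultaneously — the fingerprint of a tracking failure
   rather than real biology.  Well-tracked cells score τ of order 1.  (X, Y)
   positions enter as a single isotropic Euclidean term so the score does
   not depend on axis orientation.

The threshold τ\* is calibrated per assay from a small set of by-eye
pass/fail annotations via an ROC curve, choosing the point that maximizes
the Youden index J = sensitivity + specificity − 1 (equivalently, balanced
accuracy).  Given the failed-track prevalence *P* and the operating point's
error rates α = 1 − specificity, β = 1 − sensitivity, filter performance
follows in closed form:

> precision = (1 − P)(1 − α) / [ (1 − P)(1 − α) + P β ],  recall = 1 − α,

so the precision/throughput trade-off can be predicted before committing to
a threshold.  Downstream phenotype read-outs are included: drift-corrected
cell speed, K-means clustering of feature time courses (with a
cross-run stability score), mitosis detection from single-step nuclear-area
jumps, and threshold classification of translocation responders and dead
cells.  A built-in simulator generates cohorts with known ground truth —
random-walk motility, plate drift, simultaneous-jump artifacts, debris,
responders, phototoxic shrinkage, pre-mitotic swelling — so the whole
workflow is testable end to end.

## Worked example

```python
import numpy as np
from tramqc import (SimConfig, TramParams, simulate_trackset, split_complete,
                    estimate_global_drift, apply_drift_correction,
                    compute_tram_table, roc_curve, youden_operating_point,
                    predicted_performance, tram_filter)

# a short-term motility cohort: 1000 cells, 25 frames at 1-min increments,
# 17% simulated tracking failures, 13% debris
cfg = SimConfig.motility(seed=0, n_cells=1000)
ts, truth = simulate_trackset(cfg)

complete, incomplete, summary = split_complete(ts)
drift = estimate_global_drift(complete)
complete = apply_drift_correction(complete, drift)

params = TramParams(features=("area", "roundness"), p=0.5, n_knots=5)
taus, scales = compute_tram_table(complete, params)

# calibrate on a 100-cell annotated subsample (ground truth stands in for
# by-eye annotation here)
rng = np.random.default_rng(0)
sample = rng.choice(taus["cell_id"], size=100, replace=False)
labels = {c: ("fail" if truth.track_quality[c] == "aberrant" else "pass")
          for c in sample}
roc = roc_curve({c: t for c, t in zip(taus.cell_id, taus.tau) if c in labels},
                labels)
op = youden_operating_point(roc)
perf = predicted_performance(np.mean([v == "fail" for v in labels.values()]),
                             op.sensitivity, op.specificity)
report = tram_filter(complete, taus, op.threshold)
```

This prints (via the session's `print` statements):

```text
step 1: removed 138 incomplete tracks (14%) of 1000
drift over the course: (3.65, 2.45) um from 862 complete tracks
median tau = 1.29 over 862 tracks
ROC AUC = 1.000; Youden threshold tau* = 4.05 (sens 1.00, spec 1.00)
predicted precision 83% -> 100% at 100% recall (residual prevalence 0%)
step 2: rejected 149 of 862 tracks (17%) at tau > 4.05
```

Reading the output: 14% of tracks were debris/incomplete (the simulator's
13% plus sampling noise); the plate drifted ~3.7 μm over the half hour; the
typical track scores τ ≈ 1.3 while the injected failures score far higher,
so the ROC separates them perfectly (AUC 1.0) and the Youden threshold
τ\* = 4.05 rejects exactly the aberrant 17% of the population.  The
closed-form model predicts the precision gain of filtering (83% → 100%
here, where the artifacts are strong and cleanly separable; with the
overlapping score distributions of real data the same formula gives e.g.
83% → 98% at 85% recall for an operating point of 0.90 sensitivity / 0.85
specificity).

The same pipeline runs from the shell on exported tracking tables:

```bash
tramqc simulate --n-cells 1000 --seed 0 --out demo
tramqc filter demo_tracks.csv --features area,roundness --tau 4.05 --out-dir out/
tramqc calibrate out/tram.csv annotations.csv --out-dir out/
tramqc phenotype out/filtered_tracks.csv --what speeds --out speeds.csv
```

Input tables are delimited text with one row per (cell, time point);
column mappings for Harmony-, CellProfiler- and Imaris-style exports are
built in and user-editable via YAML (`DialectSpec.from_yaml`).

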