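# Methods

## The aberration measure

A tracked cell is a set of *n* uniformly sampled time series — (X, Y)
position plus named features such as nuclear area and roundness — on a grid
of *T* frames with increment `dt_minutes`.  Tracking failures (segmentation
swaps, identity exchanges) produce sudden, large, *simultaneous* excursions
in several of these series; genuine biology rarely does.  The Tracking
Aberration Measure scores each track by its single worst simultaneous
deviation:

```
z_it = |m_it − m̂_it| / s_i
τ    = max_t [ (1/N) Σ_i z_it^p ]^(1/p)
```

* `m̂_i` is a smoothed baseline: a least-squares cubic regression spline
  with `n_knots` knots (default 5) placed at equally spaced quantiles of
  the time index, evaluated at the original frames.  No roughness penalty
  is applied; the knot count alone controls how much temporal variability
  is considered credible.  For series shorter than `n_knots + 2` frames the
  knot count drops to `max(3, T − 2)`.  Constants and straight lines are
  reproduced exactly, so they score τ = 0.
* `s_i` is the population fluctuation scale of series *i*: the median (more
  generally, a configurable quantile) of |m_{i,t+1} − m_{i,t}| pooled over
  all complete tracks of one condition.  The median makes the scale robust
  to the minority of failed tracks, which is the point — deviations are
  expressed in units of what *well-tracked* cells do between frames.
  Scales are computed per condition (cell line × treatment) and never
  pooled across conditions, on the same time window the score uses, and on
  drift-corrected positions.  A population-constant series (s_i = 0)
  carries no fluctuation information and is dropped with a warning rather
  than divided by an arbitrary epsilon.
* The aggregation is the mean-power form with `p = 0.5` by default.  For
  p < 1 it is sub-additive: at fixed total deviation it is maximized when
  the deviation is spread evenly over all series, which is exactly the
  simultaneity signature of a tracking failure.  The `1/N` normalization
  makes τ ≈ 1 for typical tracks regardless of how many series are
  included; any fixed normalization only rescales the score, and since
  thresholds are always re-derived by ROC on the same scale the choice
  cannot affect filtering decisions.
* When positions are included they enter as one isotropic Euclidean term
  `z_xy = sqrt(((x−x̂)/s_xy)² + ((y−ŷ)/s_xy)²)` with `s_xy` the quantile of
  adjacent-frame Euclidean step lengths, because the plain p-norm is
  anisotropic for p ≠ 2 and the score should not depend on camera
  orientation.
* `argmax_time` reports the worst frame (smallest index on ties, for
  determinism).  The score may be restricted to a sub-window of the
  experiment — e.g. only the first 30 frames of a long phototoxicity
  assay, keeping the filter blind to late-occurring biology it must not
  reject.

Implementation note: for a shared grid the spline projection is a fixed
T×T hat matrix, cached per (T, n_knots), so scoring a cohort is a handful
of matrix products per track.

## Preprocessing

**Incomplete tracks.**  A track is complete iff it has a measurement at
every one of the `T_expected` frames.  Incomplete tracks (debris crossing
the focal plane, cells entering/leaving the field) are removed before any
scale or score is computed; tracks with missing values in a feature the
score uses are routed the same way, since τ needs full series.

**Global drift.**  Well plates translate slightly during thermal
equilibration.  Assuming cell motion has no net direction, the mean
displacement of complete tracks relative to frame 0 estimates the plate
path; it is subtracted from every track (incomplete ones included, at the
frames they possess) before speeds or scores are computed.  The mean is
the primary estimator; a median option exists for cohorts with wild
outliers.  There is no guard against genuinely collective migration — a
warning is logged when the apparent drift per frame exceeds the median
cell step, but no automatic fallback is applied.

## Threshold calibration and the performance model

A random sample of tracks is annotated pass/fail by eye.  The ROC curve of
τ against these labels uses every midpoint between adjacent distinct
scores plus ±∞ sentinels as candidate thresholds; a track is predicted
"fail" when τ exceeds the threshold.  The positive class is "fail", so
sensitivity is the fraction of failed tracks rejected and specificity the
fraction of good tracks kept.  AUC is the tie-corrected Mann–Whitney
statistic.  The default operating point maximizes the Youden index
J = sensitivity + specificity − 1 (equivalently balanced accuracy), with
ties broken toward the larger threshold — higher specificity preserves
throughput.  Alternative criteria (minimum-sensitivity, minimum-
specificity, prevalence-weighted accuracy) are available behind the same
interface, since positive predictive value or accuracy may better fit a
given study.

With failed-track prevalence *P* (estimated as the fail fraction of the
annotated sample), α = 1 − specificity and β = 1 − sensitivity:

```
precision (unfiltered) = 1 − P
precision (filtered)   = (1−P)(1−α) / [ (1−P)(1−α) + P·β ]
recall                 = 1 − α            (good cells kept = specificity)
residual prevalence    = 1 − precision (filtered)
```

Percentages are reported rounded half-up.  Note two readings of the Imaris
row of published operating points are internally inconsistent at the
source; the model accepts any (P, sens, spec) triple as input and takes no
position on which reading is right.

## Phenotype read-outs

* **Speed**: mean adjacent-frame Euclidean displacement over dt, on
  drift-corrected positions, over a configurable window (e.g. skipping the
  first frames affected by thermal shift).  Invariant to global
  translation and to any constant drift correction.
* **Trajectory clustering**: K-means on one feature's time courses,
  normalized to the first window frame by default so clusters reflect
  relative change (raw-value clustering by flag).  `n_runs` random
  initializations are run; the lowest-inertia run is reported together
  with a stability score (mean pairwise adjusted Rand index across runs).
  Only K values with high stability deserve interpretation; too small a K
  hides minority behaviors, too large a K fragments them.
* **Mitosis**: an event fires at frame t when the relative single-step
  area change (A_{t+1} − A_t)/A_t strictly exceeds the threshold (default
  0.182), increases only; per-hour rates are dividing cells / (cells ×
  hours observed).  Depends only on relative change, hence invariant to
  area rescaling.
* **Threshold response**: a track is "positive" when a summary statistic
  strictly exceeds a threshold — end-minus-start change for translocation
  responders (default 0.147 on the nuclear/cytoplasmic intensity ratio;
  "change" is deliberately the simplest reading of an intensity-change
  criterion), or the maximum over time for dead-cell flagging (default
  1.1 on signal/background: a cell dead at any point stays flagged).  All
  response thresholds are strict inequalities.
* Group comparisons (Welch t-test on speeds, first-order linear model on
  translocation change) are thin reporting wrappers over scipy/statsmodels,
  not re-derived statistics.

## The simulator

`SimConfig`/`simulate_trackset` generate cohorts with known ground truth:

* positions = constant per-frame plate drift + per-cell isotropic Gaussian
  random walk (component sd 0.32 μm at 1-min sampling ⇒ mean step
  ≈ 0.40 μm/min, the speed scale of the adherent cancer lines this
  workflow targets);
* features = per-cell baseline (lognormal-free Gaussian cv) + smooth
  low-frequency trend + white measurement noise; defaults model nuclear
  area (~150 μm², noise sd 4) and roundness (~0.9, noise sd 0.015);
* tracking failures (probability = `artifact.prevalence`, default 0.17): an
  additive pulse of `jump_scale` (default 10) typical adjacent-frame
  fluctuation units, applied simultaneously to the feature series *and* the
  position for `duration` frames, then reverting — the measurement is
  wrong, not the cell;
* debris (default probability 0.13): tracks truncated to a random
  sub-window, hence incomplete;
* subpopulations: logistic translocation responders (amplitude ≈ 0.6,
  midpoint 12.5 min), phototoxic nuclei shrinking smoothly over the second
  half to 0.46 of baseline, and mitotic cells swelling gently over the
  final pre-division hour and jumping +37% in area at division.  Presets
  (`motility`, `translocation`, `phototoxicity`, `mitosis`) carry the four
  assay layouts (25×1 min, 31×1 min, 61×5 min, 40×30 min).

One global seed spawns a per-cell substream, so cohorts are bit-identical
across runs and stable under reordering.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: correlated or directed migration, cell–cell
contact effects, segmentation errors that persist or drift rather than
pulse, non-Gaussian heavy-tailed measurement noise, lineage structure
across divisions (daughters are not spawned as new tracks), photobleaching
trends in intensity features, and any coupling between a cell's phenotype
and its probability of being mistracked.  Real τ distributions are
broader-tailed than simulated ones; thresholds must always be recalibrated
per assay from real annotations.

## Problem sizes and numerical choices

The validation suite runs cohorts of 200–5,000 tracks (up to 50,000
Bernoulli draws for the closed-form cross-check), chosen to make binomial
confidence bands a few percentage points wide while keeping the whole
suite and the reproduction script comfortably fast on a laptop.  The
spline fit solves least squares via pseudo-inverse (rank-tolerant for
degenerate short series); equality comparisons against the naive
reference evaluator are asserted at 1e-9 relative tolerance; ROC/Youden
computations are exact apart from a 1e-12 guard when selecting among tied
J values.

A note on the clustering validation: with a 19% shrinking subpopulation at
K = 7, the lowest-inertia K-means solution sometimes represents the dying
family with two pure centroids rather than one (the same fragmentation the
K-selection guidance warns about).  The recovery check therefore
identifies dying clusters by their signature — a terminal center value
closer to the configured terminal area fraction than to the stable level —
and requires them to contain essentially exactly the phototoxic cells at
the configured population fraction.

## Known limitations

* TrAM detects and removes aberrant tracks; it does not attempt to repair
  them.
* The incomplete-track step discards cells that divide, die or leave the
  field mid-experiment; for assays where those are the signal, window the
  analysis instead.
* Drift correction models pure translation; rotation or non-rigid plate
  deformation is out of scope.
* The closed-form performance model assumes the annotated sample is an
  unbiased draw from the cohort and that sensitivity/specificity transfer
  from the sample to the population.
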