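# Methods

## Data model

A *trajectory* is the ordered tablet stream of one subject drawing one
test block: parallel arrays `x`, `y` (device units, 100/mm, x ≤ 21000,
y ≤ 29700), `pressure` (device units, ≥ 0) and `t` (seconds).  Pressure
zero means the pen is off the paper; a *stroke* is a maximal pen-down run.
Timestamps are normalized to seconds at read time (`time_unit` declares
the raw unit per input dialect, since tablets report in different units
and the device's sampling rate is not fixed by the format).  Duplicate
timestamps keep the first sample; a decreasing timestamp is an error in
strict mode and is dropped with a log message in lenient mode, because
every derivative-based feature needs strictly increasing time.  Pen-up
samples retain their coordinates (the tablet tracks the hovering pen) but
contribute only to time accounting — never to pressure, jerk or
vector-quantization inputs, which are about writing.

Coordinates stay in device units throughout; no physical-mm conversion is
applied.  All distance-valued features are scale-consistent as long as
the reference and the scored trajectories share units.

## Kinematic features

* **Completion time** `t_last − t_first` per block.
* **Execution / preparation time**: an inter-sample interval is pen-down
  iff its *earlier* sample has pressure > 0; execution is the pen-down
  total, preparation the remainder.  The two sum to the completion time
  exactly.  Preparation is interpreted as total within-block thinking
  time; per-target latencies are deliberately out of scope.
* **Pressure mean/min/max** over pen-down samples only.  Including pen-up
  zeros would pin the minimum at 0 for any trajectory with a single pen
  lift and destroy the feature.
* **Cross-block contrasts** `T(A2) − T(B2)` and `T(A2)/T(B2)`.  A zero
  denominator (a block coded as not completed) replaces the denominator
  by −1, a sentinel that keeps the value finite at the cost of a
  discontinuity; the convention is applied exactly and only when the
  input explicitly codes a zero completion time.
* **Jerk smoothness index.**  "Jerk" fixes only the derivative order, not
  a scalar summary, so the package defines one and treats it as a
  swappable strategy: per stroke, resample `(x, y)` by linear
  interpolation onto a uniform grid at the trajectory's median sampling
  interval (robust to uneven sampling), apply the five-point central
  stencil for the third derivative, take the RMS of the jerk-vector
  magnitude, and average strokes weighted by duration.  Strokes shorter
  than five resampled points are skipped; a trajectory with no eligible
  stroke yields NaN.  The grid length uses a 1e-9 relative slack so that
  floating-point noise in timestamps cannot flip the number of grid
  points.  Linear and quadratic motion score ≈ 0 (at fp precision);
  sinusoidal tremor of amplitude A and angular frequency ω adds ≈ Aω³
  per axis, so the index rises monotonically with tremor.

Undefined features propagate as NaN into the feature table and are
imputed at model-fit time (below).

## Template-based features

The premise: every healthy-control drawing of a block contains the same
"standard answer", so one control trajectory can serve as a reference and
distance-from-reference measures abnormality.

* **Selection**: from the healthy-control pool (ordered by subject id so
  the result is caller-order-invariant), draw `subset_size = 10`
  trajectories without replacement (seeded); compute the pairwise DTW
  distance matrix over pen-down points; return the row-sum argmin, ties
  to the lowest subject id.  Within cross-validation the pool is the HC
  subjects *outside* the test fold, re-drawn per fold.
* **DTW**: exact dynamic programming with Euclidean local cost, summed
  along the optimal monotone path, unconstrained, no path-length
  normalization.  **FastDTW**: the standard multilevel scheme — halve
  both sequences recursively, align at the coarsest level, refine each
  level inside a corridor of `radius` cells around the projected coarse
  path; exact whenever the radius covers the matrix.  Both the full and
  the windowed DP are numba kernels.  Radius 1 is the production default
  (empirically within ~5% of exact on random-walk pairs while linear
  time); the exact version is used as oracle in tests and is the default
  for key-point sequences, which are short.
* **Smoothing**: the selected reference — and every trajectory entering
  quantization — is Gaussian-filtered over sample index (reflect
  boundary) with σ = 0.1.  σ is in sample-index units because no physical
  unit is defined for it; at 0.1 the filter is nearly an identity, and σ
  is exposed as a parameter.
* **Vector quantization**: k-means (scipy `kmeans2`, seeded `++` init) on
  pen-down `(x, y)` only — time is excluded by design; codebook size 40,
  capped at the number of distinct points.  An empty cluster triggers a
  restart with a shifted seed (≤ 10), after which empty clusters are
  dropped.
* **Temporal restructuring**: clusters are ordered by mean member time;
  each cluster removes member points earlier than the *previous*
  cluster's mean time or later than the *next* one's (neighbor means
  taken before any removal, one pass); emptied clusters are dropped and
  centers/mean-times re-averaged.  Because the surviving intervals of
  neighboring clusters can still overlap, a final stable sort by
  recomputed mean time — merging clusters with exactly equal means —
  enforces the strictly-increasing-time invariant.  Iterating the removal
  to a fixed point is deliberately not done: one pass is the defined
  operation.  A spatial cluster whose member times are bimodal (the pen
  revisits a region) is often emptied entirely; key-point counts well
  below the codebook size are therefore normal for self-crossing trails.
* **Distances from the reference**: DTWD between the two key-point center
  sequences; index-paired (by temporal rank, up to the shorter length m)
  mean Euclidean distance, unweighted `(1/m) Σ ‖rᵢ − kᵢ‖` and weighted
  `Σ wᵢ‖rᵢ − kᵢ‖ / Σ wᵢ` using the *scored trajectory's* relative
  weights renormalized over the paired prefix, keeping the feature a
  length-scale quantity even when restructuring dropped clusters.  An
  optional full-trajectory DTWD can be added by computing
  `dtw_distance` on raw pen-down points; key-point DTWD is the default
  feature because the key points are the method's representation.
* Templates are selected and applied independently per (part, block) —
  four references per trained model — and can be archived to JSON and
  reloaded for follow-up scoring.

## Screening model

The feature table is subjects × named columns
(`completion_A1 … jerk_B2`, `tdiff_A2B2`, `tratio_A2B2`,
`tmpl_{dtwd,vq,vqw}_{A1..B2}`, demographics, examiner-interaction
counts), with NaN for undefined entries.  Three feature sets:
*conventional* (completion times + sex/age/education + interaction
counts — the paper-based test's information), *proposed* (all kinematic,
cross-block and template features + demographics, excluding interaction
counts, to remove the caregiver dependency), and *all*.  Follow-up mode
drops sex/age/education so re-assessed subjects cannot be recognized by
identity.

* **ANOVA screen**: per feature and group pair, a one-way F-test with
  listwise NaN removal; no multiple-testing correction by default (raw
  p-values are the screen); a Benjamini–Hochberg column is available as a
  clearly-marked extension.  A pair with zero variance in both groups is
  reported NaN.
* **Cross-validation**: stratified k-fold (default 5), shuffled with a
  pinned seed; per fold the template is re-fitted from HC subjects
  outside the test fold, and all fitted transforms (median imputation
  with missing-indicator columns) are learned on the training fold only.
  Key points are template-independent and cached across folds.  Metrics
  (accuracy, AUC from probability scores or the decision function for
  SVC, sensitivity, specificity) are fold means.  The positive class is
  the more impaired group (MCI over HC, AD over everything), which fixes
  the meaning of sensitivity as impairment detection rate.
* **Models**: scikit-learn defaults with pinned seeds — SVC, AdaBoost,
  random forest (the reference model), gradient boosting — plus LightGBM.
  No tuning, by design: the features, not the learner, are under study.
* **Holdout validation**: fit on the baseline table, score an untouched
  follow-up table with matching columns; the AD-vs-others task relabels
  HC and MCI as the negative class.
* **Grouped importance**: per-feature mean absolute attribution.  For
  ensembles of classification trees, tree-path attribution: a sample's
  predicted positive-class probability is decomposed along its decision
  path, each split's value change credited to the split feature, averaged
  over trees.  For other models, seeded permutation importance.  Family
  aggregates are exact sums of member values (missing-indicator columns
  inherit their base feature's family), so family importance is additive.

## The simulator

The generator emulates the tablet stream for the four blocks of a
complete assessment.  Sheets: targets (label, circle/square, center,
radius 600 units ≈ 6 mm) rejection-sampled without overlap inside
margins; block 1 carries labels 1–8 (warm-up), block 2 labels 1–25; part
A shows each label once; part B shows every label in both shapes except
the square-only 1, and the correct order alternates shapes (odd labels
square, even circle) with the unvisited duplicates acting as distractors.

Drawing: between consecutive targets the pen optionally hovers
(pressure 0, truncated-normal pause, occasionally lengthened by a lapse),
then follows a minimum-jerk position profile
`s(τ) = 10τ³ − 15τ⁴ + 6τ⁵` — chosen because it is the smoothness-optimal
reach with a closed form, giving the jerk metric an analyzable baseline —
plus a fixed-frequency sinusoid (random phase) modeling tremor.  Pen
force is truncated-normal per pen-down sample.  All timing sits on an
exact uniform grid (pauses rounded to whole sample intervals), so the
ground-truth duration and pause totals are exact to the sample; pressure
means are exact up to sampling noise (observed means sit within ~3
standard errors of the programmed means, with the binomially expected
rate of slightly larger excursions across hundreds of blocks).

Group profiles (units/s, s, device units, Hz; 50 Hz sampling):

| group | speed | pause μ/σ | pressure μ/σ | tremor A/f | lapse |
|-------|------:|----------:|-------------:|-----------:|------:|
| HC    |  9000 | 0.15/0.05 |     1650/120 |     15/5.0 |  0.02 |
| MCI   |  6200 | 0.55/0.20 |     1380/150 |     30/5.5 |  0.08 |
| AD    |  4200 | 1.10/0.40 |      900/180 |     45/6.0 |  0.20 |

The ordering reproduces the *directions* clinical cohorts show — slower,
pausier, lighter-pressure, more tremulous drawing with impairment — with
magnitudes chosen once so a block lasts roughly 10–70 s (speeds of
40–90 mm/s are ordinary drawing speeds); the profiles are not calibrated
to any clinical cohort's means and make no such claim.  Subject-level
lognormal random effects (σ 0.06–0.15) jitter speed, pause, pressure and
tremor.  Demographics are drawn from group-dependent normals;
examiner-interaction counts are zero unless error simulation is enabled,
in which case they are Poisson draws — connection errors themselves are
not enacted in the trajectory.

What the simulator does *not* emulate: visual search and
decision-making (paths go target-to-target without exploration), wrong
connections or corrections, drift of the hovering pen, device
quantization noise, and within-subject session effects.  Passing tests on
synthetic cohorts therefore demonstrate the pipeline's mechanics —
feature recovery, leakage-free validation, calibration, determinism — not
clinical accuracy; the near-perfect synthetic classification metrics
reflect the programmed group separation, and no clinical performance is
claimed.

## Numerical and design notes

* All randomness flows through named integer seeds; per-subject seeds are
  CRC32-derived from the subject id so results are independent of record
  order.  Identical seeds give identical reports, feature tables and
  serialized cohorts (byte-level).
* CSV round-trips are bit-exact: floats are written with shortest
  round-trip repr and parsed with round-trip precision.
* Degenerate inputs yield NaN markers, not failures: all-pen-up blocks
  (no pressure/jerk), strokes too short for the jerk stencil, zero
  variance in an ANOVA pair, missing blocks in the feature table.
* Test and acceptance problem sizes — cohorts of 24–180 subjects at
  50 Hz, DTW oracles at lengths ≤ 6 (exhaustive) and 100 (exact DP) —
  were chosen as the smallest sizes at which each property is
  meaningfully exercised.

## Known limitations

* The jerk scalar and several conventions the underlying method leaves
  open (DTW normalization, whose VQ weights, pairing of unequal key-point
  counts) are fixed here as documented choices; alternatives plug in at
  the named functions.
* FastDTW is an upper bound on the exact distance; at radius 1 errors of
  a few percent are possible and asymmetric pathological cases exist.
* Tree-path attribution approximates Shapley-style attribution; it is
  exact in the additive-decomposition sense along each path but not
  game-theoretically symmetric.  The permutation fallback measures a
  different (global) quantity.
* The simulator's interaction counts are label-correlated draws, not
  behaviorally generated; the conventional feature set on synthetic data
  is therefore only a plumbing check.
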