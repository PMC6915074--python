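# Methods

This note documents the models, defaults and design choices behind
`somatobci`, and what the synthetic-data tests do and do not establish.

## Experimental design being modelled

A classifier-training run is a pseudorandom sequence of nine left-foot
and nine right-hand somatosensory-imagery trials of 18 s, each followed
by a 16, 18 or 20 s rest, at TR = 2 s. An answer run contains five
trials of a single class encoding a yes (hand) or no (foot) answer.
Stated volume counts are 340 per training run and 96 per answer run; the
sources give the trial and rest durations but not the lead-in/trailing
rest, so the generator uses a 16 s lead-in and 16 s trailing rest for
training runs and a 12 s lead-in for answer runs — the unique simple
reconciliation that makes the volume counts exact. Rest durations are
drawn without replacement from a balanced multiset (six each of
16/18/20 s for 18 trials); the sources list the three durations but not
their frequencies, so balance is assumed. Both choices are
config-exposed (`DesignSpec`).

Event times are seconds from the first retained volume; any discarding
of initial volumes is a preprocessing concern outside this package, so
the generator emits already-trimmed runs and `read_run` never trims.

## Coordinate convention

World x is positive toward the subject's right (Talairach-like). The
left-foot representation is medial/right-hemisphere (positive x), the
right-hand representation lateral/left-hemisphere (negative x); the
layout invariant `foot_centroid_x > hand_centroid_x` encodes this, and
all somatotopy summaries default to the x axis, where the hand–foot
separation is most pronounced. The dual native (1.5 mm) / normalised
(2 mm) resolution handling of a real scanner pipeline is collapsed to
one fixed grid.

## Hemodynamic model

A double-gamma HRF: positive lobe peaking at 5 s, undershoot at 15 s,
peak:undershoot 6:1, 32 s kernel, zero at t = 0, normalised to unit
peak (`HrfModel`). The sources specify only "canonical"; these are
conventional values. Gamma shapes are chosen so the lobe modes fall
exactly at the stated delays (shape = delay + 1, scale 1 s). Regressors
are built by convolving the trial boxcar with the kernel on a 0.1 s grid
and interpolating to volume times; causality makes the pre-cue sample
exactly zero.

## Synthetic signal and noise

Voxel time series = 100 (baseline) + amplitude × selectivity-weighted
HRF-convolved class boxcars + drift + Gaussian noise.

* **S1 clusters** — spheres of radius 8 mm (default grid) around the
  foot (+10 mm) and hand (−30 mm) centroids, with a Gaussian spatial
  falloff (σ = radius/2). A foot-cluster voxel responds to foot blocks
  with weight `s1_selectivity` (default 0.9) and to hand blocks with the
  complement.
* **S2 cluster** — one weaker cluster (`s2_selectivity` 0.4) whose class
  preference alternates on a voxel checkerboard (`s2_mixing` 0.5),
  giving the spatially mixed, less decodable code expected of secondary
  cortex.
* **Noise** — i.i.d. Gaussian (σ default 1.0, in the same arbitrary
  units as amplitude) plus a per-voxel random-phase sinusoid of period
  128 s (< 0.01 Hz) and amplitude 0.5, standing in for slow scanner
  drift. The GLM intercept absorbs it at the trial-window scale; an
  optional linear-trend column is available.

Masks are nested cylinders around region core lines parallel to x, with
the radius shrinking linearly in the probability level — this mirrors
the atlas property that higher-probability masks are smaller and makes
nesting and S1/S2 disjointness structural. On the default 40×40×20 grid
(2 mm voxels) the lowest-level masks hold several thousand voxels and
the >90% masks drop below 500, so the strictly-greater-than-500-voxel
inclusion rule used in the region comparison is exercisable.

What the generator does **not** emulate: physiological noise spectra,
motion, spatial autocorrelation of noise, distortions, inter-subject
anatomical variability, and hemodynamic nonlinearity. Passing tests
therefore establish the correctness of the analysis machinery and its
behaviour under a controlled somatotopic signal, not performance on real
recordings.

## Feature extraction

The peri-trial window is 1 + 1 + 14 = 16 volumes (−2 s to +28 s around
the cue). The sources describe this as a "30 s" window although 16
samples at TR 2 span 32 s inclusive; the volume-count reading is taken
as authoritative. Each trial is fitted separately by OLS on [intercept,
regressor]; t uses window − 2 degrees of freedom (the trial-wise
residual df; a full-design residual df would require the joint model the
trial-wise procedure deliberately avoids). Adjacent trials' hemodynamic
tails are ignored — an inherited simplification of the trial-wise
approach. Zero-residual (perfect) fits are capped at a sentinel t of
1e6 with a warning so downstream z-scoring stays finite. The real-time
variant differs from the offline one only in a 4 mm FWHM volume-wise
Gaussian smoothing before fitting.

## Decoding

Linear C-SVM (libsvm via scikit-learn), C = 1, tolerance 1e-4 — the
dual problem is deterministic, so repeated fits are identical. Training
features are z-scored per voxel with training-set statistics; the same
statistics are reused at test time (leakage-free; whether the original
analysis pooled statistics is unknowable, and the train-only choice is
the defensible one). Zero-variance voxels are removed from the decision
function. Decision ties at exactly 0 go to hand (−1). The answer call
is the majority class over a run's five trials mapped to yes (hand) / no
(foot); with five trials a tie is impossible, and majority is the
minimal rule consistent with the reported behaviour. Weight maps are
the element-wise mean of split weight vectors, z-scored across mask
voxels (positive = foot evidence).

## Inference

* **Permutation test** — labels re-shuffled independently within each
  run (preserving per-run class balance; an unstratified mode is
  provided as a sensitivity toggle), the full CV re-run per permutation,
  `p = (#{null error ≤ observed} + 1)/(N + 1)`, floor 1/(N+1). The
  reported null band is the empirical 2.5–97.5 percentile interval.
* **rm-ANOVA** — fully-within designs via orthonormal contrast
  transforms: per effect, the classical univariate F with its own
  subject-by-effect error term; Greenhouse–Geisser epsilon from the
  covariance of the contrast scores (exactly 1 for 2-level effects;
  Huynh–Feldt is not implemented). Degenerate (ceiling) data yield an
  infinite/NaN F with a warning rather than an exception, since
  saturated synthetic cohorts hit this routinely. Verified against
  direct-formula evaluation, pingouin and statsmodels in the tests.
* **Polynomial contrasts** — orthonormal polynomials over equally
  spaced levels; per order a one-sample F (= t²) on the per-subject
  contrast scores.
* **Wilcoxon signed-rank** — normal approximation with midranks,
  tie-corrected variance, zero differences dropped; continuity
  correction off by default (both modes exposed — the continuity-
  corrected p is the one that tracks exact enumeration within 0.02 at
  n = 10, as the tests verify).
* **Spearman** — midrank Pearson correlation; permutation p (exhaustive
  for n ≤ 7, seeded Monte-Carlo otherwise, asymptotic on request).
* **Answer-table aggregation** — proportions are averaged within
  subject, then across subjects. This two-stage rule reproduces the
  published overall row of the answer-run table exactly; trial-pooled
  averaging does not.

## Problem sizes in tests and the acceptance script

The unit and acceptance suites run the full pipeline at reduced problem
sizes chosen as the package's own desk-scale defaults: a 16×16×8 grid
(2 mm voxels) with the layout geometry scaled proportionally, 200
permutations where the formula's behaviour (not its resolution) is under
test, 50–100 subjects for rate estimates, and the full 40×40×20 default
grid for the single high-SNR parameter-recovery subject so the top-200
weight rule applies unchanged. The quantities asserted — rates, medians,
exact arithmetic — are scale-free, so the downscaling changes runtime,
not meaning. On the tiny grid the signal clusters hold only ~7 voxels,
so somatotopy summaries there use a proportionally smaller top-k; the
median of a top-k set is only an unbiased centroid estimate while k does
not exceed the cluster size.

## Known limitations

* The generator's noise is white; real fMRI noise is temporally and
  spatially autocorrelated, which would widen permutation nulls and
  slow the growth of accuracy with training data.
* Trial-wise GLM fitting ignores overlap between adjacent trials'
  responses; with 16–20 s rests the bias is small but nonzero.
* The region comparison assumes the S1/S2 dichotomy of the synthetic
  layout; atlas subarea granularity (areas 3a/3b/1/2, OP1–OP4) is out
  of scope.
* Real-time emulation replays prerecorded runs; no scanner streaming,
  motion correction or incremental realignment is implemented.
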