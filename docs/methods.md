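# Methods

## Problem and model

EEG features recorded from the same subject on different days are
differently distributed: background (emotion-irrelevant) activity is
fairly regular within a day but shifts between days, so a classifier
trained on earlier days transfers poorly to a later one. The working
assumption of this package is that within one trial's feature matrix
`X` (features × time windows) the background occupies a low-dimensional
subspace while emotion-related oscillations are deviant and sparse.
That assumption is operationalized by principal component pursuit:

    min ‖L‖* + λ‖S‖₁  s.t.  X = L + S

Classification then consumes the per-trial, trial-averaged sparse
component (RPCA-S), with the low-rank component (RPCA-L) and the
undecomposed features (Original) as comparators.

## Solver

The program is solved by inexact augmented Lagrange multipliers:
alternately apply singular-value thresholding (for `L`) and elementwise
soft thresholding (for `S`) to the residual-augmented matrix, update
the dual variable, and grow the penalty `μ`. The input is normalized
to unit spectral norm internally and the decomposition rescaled on
return, so the solution is exactly equivariant under `X → cX`.
Defaults (on the normalized scale): `μ₀ = 1.25`, growth factor
`ρ = 1.5`, stop when `‖X − L − S‖_F/‖X‖_F ≤ 1e-7`, at most 1000
iterations. The penalty grows only when the S-step has settled at the
current level (`μ‖S_k − S_{k−1}‖_F/‖X‖_F < 1e-2`); growing it
unconditionally stalls the iterate short of the optimum on harder
inputs (rank ~5 with ~10% corruption). The synthetic benchmark relaxes
the stopping tolerance to `1e-5` — far below the trial noise floor,
and roughly 25% cheaper per decomposition on dense-noise matrices —
while recovery oracles keep `1e-7`. Non-convergence is reported in the
result object, not raised.

Two caveats worth knowing:

* **Objective behavior.** ALM iterates are infeasible, and their raw
  objective `‖L‖* + λ‖S‖₁` approaches the optimum from below, i.e.
  increases. The recorded `objective_history` is the objective of the
  feasible completion `(L_k, S_k + (X − L_k − S_k))`, which decreases
  overall and ends at its minimum, but can rise transiently by order
  1e-3 relative in the early, strongly infeasible phase. No
  per-iteration quantity of this solver family (raw objective,
  feasible completion, augmented Lagrangian) is strictly monotone.
* **Support of S.** A convex solver leaves numerically-zero residue on
  non-support entries; `numerical_support` declares support above
  `1e-4 × max|S|`.

### The two λ rules

`default_lambda` implements `paper` (`1/max(m, n)`) and `sqrt`
(`1/√max(m, n)`). The sqrt rule is the scaling under which exact
recovery of incoherent low-rank + sparse matrices is guaranteed, and
it recovers the synthetic ground truth to ~1e-7. At the 110×73 size
used here the `1/max(m, n)` rule makes the ℓ₁ penalty so cheap that
essentially the whole matrix moves into `S` (rank of `L` drops to 0),
which makes RPCA-S indistinguishable from Original. `PipelineConfig`
keeps `paper` as its default for fidelity; the synthetic benchmark and
the recovery tests use `sqrt`, and any quantitative claim should state
the rule used.

## Feature extraction

* High-pass FIR: Hamming-window linear-phase design, two
  sampling-rates' worth of taps rounded to odd (257 at 128 Hz), tap
  mean removed so DC gain is exactly zero, applied on reflect-padded
  data with exact group-delay compensation. This meets ≥ 20 dB
  attenuation at 0.2 Hz with < 0.1 dB ripple above 2 Hz; a
  one-sampling-rate design does not.
* STFT: 1-s Hamming window, 50% overlap, FFT length = window length.
  A band's value is the mean PSD over bins with center frequency
  inside the band, edges inclusive (1-Hz bin spacing at 128 Hz). A
  37-s trial yields 73 windows.
* MESH: for each band, 12 per-channel rows, then 6 laterality rows
  (left − right: AF3–AF4, F7–F8, F3–F4, FC5–FC6, P7–P8, O1–O2), then 4
  caudality rows (frontal − posterior: AF3–O1, F7–P7, AF4–O2, F8–P8);
  band-major ordering, 110 rows total. The asymmetry operator is the
  plain power difference; `ratio` and `log_ratio` variants sit behind
  a config switch since the original asymmetry formula is defined only
  in earlier work. Asymmetries are computed before normalization and
  may be negative.
* Min-max normalization maps each feature row to [0, 1]; constant rows
  map to zero. The default scope is per feature, per day, over that
  day's music-listening windows — each day, including a test day, uses
  its own min/max, so no scale information leaks across days. Whether
  the original analysis normalized per trial, per session or per day
  is not recorded; the scope is switchable (`trial`, `day`, `none`).

## Feature selection and classification

F-scores are the one-way ANOVA ratio `MS_between/MS_within` with
df (1, n−2) p-values. Degenerate features are made deterministic:
zero within-class variance with separated means gives the largest
finite F (p = 0); a fully constant feature gives F = 0 (p = 1). No
multiple-testing correction is applied — raw p < 0.05 mirrors the
analysis being reproduced, deliberately.

The GNB uses per-class sample means and variances with a variance
floor of `1e-9 ×` the largest pooled per-feature variance, log-space
densities, and posterior ties broken to the lexicographically first
class. It is implemented in-package because the add-feature-in search
needs per-feature log likelihoods accumulated along the F-score
ranking: one cumulative sum evaluates all 110 candidate feature counts
per fold at once, which keeps a full ADI run with 100 repetitions
cheap. scikit-learn's GaussianNB serves as an independent cross-check
in the tests, not as the implementation.

## Add-day-in validation

For each condition (train days 1..D, test day D+1): features are
ranked once on the full, unbalanced training pool; the feature count
d* is the smallest count attaining the maximum of the CV-accuracy
curve averaged over `reps` class-balanced subsamples × stratified
`folds`-fold splits; the deployed model is refit on *all* training
trials with priors forced to (0.5, 0.5) — equal priors reproduce the
balancing intent without discarding data, since which balanced model
the original analysis deployed is unstated. All randomness derives
from named substreams of the master seed (`"balance", rep` and
`"folds", rep`), so every one of the `reps × folds` fits is
reproducible in isolation. Baseline-segment trials inherit the label
of their paired music trial.

## Synthetic data generator

Feature-level mode emulates one subject of a five-day music-listening
protocol: per day, 12 trials per class (happiness/sadness), each a
110 × 73 matrix

    X = background + sparse + noise
    background = U_d V'ᵀ + b_d 1ᵀ   (rank r = 4, scale 1)
    sparse     = class-signed events on k = 10 support rows
    noise      = i.i.d. N(0, noise_sd²)

`U_d` is a common orthonormal basis perturbed per day (QR of
`U₀ + day_drift·G/√m`, columns sign-aligned so drift → 0 is
continuous) and `b_d ~ N(0, day_drift²)` is a per-day, per-feature
offset — together they produce the across-day cluster translation that
breaks cross-day classifiers. The support rows and their signs are
drawn once and shared by all days (the class signal is day-stable).

The class component is sparse in features *and* time: each support row
carries events at `event_rate = 0.15` of the windows with amplitude
`±effect_size/(2·event_rate)`, so the per-trial row-mean class gap is
exactly `effect_size`. A component constant across a trial's windows —
the more obvious choice — is rank ≤ 1 as a matrix, and the nuclear/ℓ₁
geometry then assigns it to `L` (at 110 × 73,
`‖a‖√n ≪ λn‖a‖₁`), which would erase the very phenomenon under study;
temporal sparsity is what makes the class signal genuinely "sparse" to
the decomposition.

Generated matrices stand in for MESH matrices at the point where RPCA
consumes them, so the feature-level benchmark feeds them to the
decomposition directly, without min-max normalization (a per-day
min-max would itself cancel a pure additive day offset; real
extraction-pipeline runs still normalize raw-signal data as described
above).

What the generator does *not* emulate: volume conduction and channel
correlation structure, artifacts (EMG/EOG), non-Gaussian heavy tails,
within-day nonstationarity, and any physiological basis for the class
effect. Passing benchmarks therefore show that the pipeline behaves
correctly *when the low-rank + sparse assumption holds*, not that the
assumption holds for real EEG.

### Calibration of the defaults

No quantitative magnitude of inter-day drift is published, so the
defaults were calibrated, as the generator's own design choice, to the
qualitative study conditions: drift strong enough that the Original
manner tests near chance across days, while within-day structure stays
intact. With `day_drift = 3.0`, `effect_size = 0.6`, `noise_sd = 1.0`
(10 dataset seeds, 10 repetitions): Original tests at 0.50 in the
Days 1–4 vs Day 5 condition; RPCA-S at 0.89 there and 0.83 in Day 1 vs
Day 2, with the selected feature count growing from ~4 to ~13; all
baseline-segment controls fall in 0.50–0.51. These numbers are
recomputed, not asserted, by the acceptance suite and
`scripts/acceptance.py`.

Raw-signal mode generates 12-channel sums of one sinusoid per band
(random phases) plus 1/f noise, with alpha/gamma amplitudes modulated
oppositely by class on six frontal channels — a stylized class effect
for exercising the extraction chain end to end, with ground-truth
amplitudes attached.

## Evaluation utilities

* `discriminant_project`: axis 1 solves the shrinkage-regularized
  within-class scatter against the mean difference (shrinkage 0.1
  toward the diagonal; trials ≪ features makes the raw scatter
  singular). A two-class problem has only one discriminant direction,
  so axis 2 is defined as the leading variance direction orthogonal to
  axis 1 — an explicit substitute, not a claim about how the original
  figures were produced. Axes are unit-norm with first nonzero
  loading positive. The conceptual decision boundary passes through
  the midpoint of the class centroids, perpendicular to their
  difference.
* Importance maps are F-score vectors; maps compared within a day are
  min-max normalized jointly over their concatenation; dissimilarity
  is the Euclidean distance.
* The Wilcoxon signed-rank test drops zero differences and uses the
  exact null for ≤ 25 untied pairs, the normal approximation
  otherwise.

## Problem sizes used by tests and the acceptance script

Structural and oracle checks run at their natural sizes (110 × 73
matrices, 20 solver seeds, 10⁴ GNB samples, 1000 null features). The
cross-day benchmark runs the full five-day, 12-trials-per-class
dataset with 10 add-feature-in repetitions (instead of 100) per
condition; the repetition average is already stable at 10, and the
selected sizes keep a complete run in the minutes range on one core.
The acceptance script averages the benchmark over 10 dataset seeds;
the acceptance test suite uses 20.

## Known limitations

* The published group accuracies (58.31 ± 12.33% → 64.03 ± 8.40% etc.)
  were computed on a private 12-subject dataset and cannot be
  reproduced here; the synthetic benchmark reproduces the qualitative
  phenomenon (Original at chance, sparse component restoring cross-day
  transfer, gain growing with training days), not those numbers.
* Per-trial RPCA assumes the background subspace is stable within a
  trial; slow within-trial drift would smear into `S`.
* The add-feature-in curve is evaluated on nested top-d sets of a
  single global ranking; interactions that only appear for non-nested
  subsets are invisible to it.
* EDF export is not implemented (EDF read is available via the
  optional `mne` extra); synthetic raw data is written as TSV.
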