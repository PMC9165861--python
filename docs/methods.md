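# Methods

This note records the models, conventions and parameter choices behind
`surgskill`, the reasoning where the design was genuinely open, and what
the synthetic validation does and does not demonstrate.

## Recording model

A recording unit is one (subject, skill, task, trial, muscle, side)
combination with a single sEMG channel (default 2000 Hz, µV), a triaxial
accelerometer (default 100 Hz, g), a resting baseline EMG segment, and a
positive MVC reference in envelope units. Six bilateral muscle sites are
modeled (biceps, triceps, deltoid, extensor carpi ulnaris, flexor carpi
ulnaris, thenar eminence) over three tasks (knot tying, pegboard
transfer, robotic suturing), with at least three trials per task. The
default cohort is 10 novice / 11 intermediate / 5 expert subjects; the
published study design reports these group sizes inconsistently in
different places (11/12/3 elsewhere), so the counts are configurable and
the default simply documented rather than presented as authoritative.

## EMG preprocessing

Six steps, in order: linear detrend; 4th-order Butterworth band-pass
20–500 Hz; IIR notch at 60 Hz; 6-sample windowed RMS; 4th-order
Butterworth low-pass at 5 Hz; division by MVC. Choices the protocol
leaves open, and how they were fixed:

- **Zero-phase filtering.** All IIR filters run forward–backward
  (`filtfilt`), so activation-onset timing is unbiased. This doubles the
  effective order; the stated orders refer to the designed filter.
- **Detrending** removes a least-squares linear trend. Plain "bias
  removal" would be mean subtraction; linear detrending is strictly more
  general and reduces to it for trend-free signals.
- **RMS window alignment.** The 6-sample window (3 ms at 2000 Hz) is
  centered, with edge truncation (shorter effective windows at the
  boundaries). The windowed RMS *is* the rectification step; no separate
  absolute-value pass is applied.
- **Notch quality factor** defaults to Q = 30 (≈2 Hz bandwidth), wide
  enough to remove mains interference without touching the 50 Hz or
  70 Hz neighborhood. Attenuation contracts are verified on interior
  samples of long tones, away from the filter's edge transients.
- **Band edge at low rates.** At fs < 1100 Hz the upper band edge is
  clamped to 0.45·fs with a logged warning; at the native 2000 Hz the
  500 Hz edge is Nyquist/4 and needs no adjustment.
- The envelope is clipped at zero after the low-pass (smoothing ringing
  must not produce negative "activity") and carries an ordered
  provenance list of every applied step.

## EMG features

- `CMW` — trapezoidal time integral of the MVC-normalized envelope over
  the full task; additive over segments.
- `AWS` — CMW divided by *performance time*, taken as the whole-trial
  duration (the protocol reports task completion time separately from
  activation time; an activation-time denominator is available by
  argument).
- `TotalTime` — activity threshold = baseline mean + 5·SD, with the
  sample SD (n−1 denominator; the protocol says only "SD"). Onset is the
  first sample strictly above threshold, cessation the last; total time
  is their difference, a single span rather than a sum of episodes
  (matching the "onset and cessation points" phrasing). Never-active
  recordings yield 0 with onset/cessation flagged absent. No debounce by
  default.
- `RMS`, `Range` — computed on the normalized envelope.
- `DominantFreq` — computed on the detrended, band-passed,
  notch-filtered signal (the 5 Hz envelope cannot carry a firing
  spectrum): zero-pad to the next power of two, squared FFT modulus,
  argmax over positive frequencies with the DC bin excluded and ties
  broken toward the lowest frequency. An all-zero signal has no dominant
  frequency and is flagged, not reported as 0 Hz.

## Nonlinear features

All operate on the resultant acceleration magnitude. Estimator
conventions:

- **ApEn / SampEn**: Chebyshev template distance; ApEn includes
  self-matches (Φ_m − Φ_{m+1}), SampEn excludes them (−ln(A/B) over the
  common N−m templates). A = 0 or B = 0 raises an undefined-result
  error; nothing substitutes infinity silently. Template counting uses a
  KD-tree in the Chebyshev norm and is tested for exact agreement with
  O(N²) brute-force counting.
- **MSE**: coarse-graining by non-overlapping window means (length
  ⌊N/τ⌋); the tolerance r stays fixed at 0.2·SD of the *original* series
  across all scales (the standard convention; per-scale r is available).
  Scales with undefined SampEn are flagged NaN and excluded from the
  reported mean and (population) variance, with a log entry.
- **Correlation dimension**: correlation sum with *strict* inequality
  (pairs at distance exactly r do not count), Euclidean norm. The slope
  is a least-squares fit of log C(r) vs log r over a geometric radius
  grid between the 2nd and 25th percentiles of the pairwise-distance
  distribution — low enough to probe the scaling region, high enough
  that C(r) never vanishes for non-degenerate clouds. Series are
  embedded at m = 3 and evenly subsampled to ≤1500 points to bound the
  pair count. A constant series returns 0 (single-point attractor, by
  convention, logged); vanishing correlation sums over the whole region
  raise an undefined-result error.
- **Rosenstein Lyapunov**: delay embedding (m = 3; lag from the first
  minimum of the 16-bin average mutual information, falling back to the
  first autocorrelation zero crossing); nearest neighbor constrained by
  a temporal separation larger than the mean period (reciprocal of the
  power-weighted mean frequency). The exponent is the degree-1
  least-squares slope of the mean log-divergence curve over the
  expansion range [k_min, k_max], divided by the sample period; the
  default window is [1, fs] samples, and for benchmark recovery the
  range should be placed in the visually linear region of the curve
  (past the early neighbor-relaxation transient, before saturation), as
  the method prescribes. Short- and long-range exponents are the same
  fit over [1, ½ mean period] and [½, 2 mean periods], the convention
  used in movement-variability work.
- **Numerical resolution floor**: neighbors closer than 10⁻⁸ of the
  attractor extent are treated as duplicates and skipped. Noise-free
  periodic signals reproduce state-space points to machine precision;
  without the floor the divergence curve of a perfect sinusoid is pure
  rounding noise.
- **Wolf Lyapunov**: fiducial-trajectory tracking with nearest-neighbor
  replacement; the separation evolves one sample per step and the
  neighbor is replaced when it exceeds 0.2 of the attractor extent
  (both configurable). No angular constraint is applied at replacement —
  the nearest admissible point is taken — which is the common simplified
  variant. Validated within 30% of ln 2 on the logistic map and ≈0 on
  periodic signals; on noise-dominated signals it saturates high, which
  is informative as a feature but not meaningful as a physical exponent.
- **Generalized Hurst**: the series is treated as increments — mean
  centered and cumulatively summed — then H(q) is the slope of
  log K_q(Δ) = log E|y(t+Δ)−y(t)|^q against log Δ over lags 1–19,
  divided by q (default q = 2). Under this convention iid noise scores
  H ≈ 0.5, a linear ramp exactly 1, and an integrated random walk
  saturates toward 1.

Per-trial features are emitted as `Apen`, `Sample_Entropy`, `MSE` (mean
over scales), `Var_MSE` (variance over scales), `Rosenstein_Lye`,
`Short_Lye`, `Long_Lye`, `Wolf_Lye`, `Correlation_Dimension`,
`Generalized_Hurst_Exp`; aggregation across trials within
(subject, task, muscle, side) produces the reporting names (`Mean_Apen`,
…, with `Var_MSE` keeping its name since it is already a variance).
Whether sides should also pool is left to a flag (default: kept
separate). Any estimator undefined for an input yields NaN — an explicit
missing value — never a silent zero.

## Feature selection

- **Correlation filter (CFS)**: pairs with |ρ| at or above the threshold
  (default 0.9) are resolved by dropping the member with the weaker
  absolute Pearson association to the ordinal skill label (novice = 0,
  intermediate = 1, expert = 2 — the three-class analogue of a
  point-biserial association); ties drop the later column, logged. Pairs
  are processed in descending |ρ| order until no kept pair meets the
  threshold, which makes the post-condition (no kept pair ≥ threshold)
  structural. The protocol's description of which member to drop is
  incomplete; keeping the more label-associated member preserves
  predictive signal and matches the filter's stated supervised intent.
- **RFE**: one feature eliminated per iteration under a 100-tree random
  forest (the importance-bearing model of the reported priority table);
  ranks record elimination order (1 = survived), weights are the final
  fit's importances normalized to sum 1. The combined default
  (`cfs+rfe`, target 10) mirrors the reported 26 → 10 reduction.

## Classification protocol

Stratified 70/30 train/test split, subject-level by default (no
subject's trials span the split; the source protocol is silent and
likely row-level, which remains available by flag for fidelity runs).
Models: random forest (100 trees, seeded), SVM with RBF kernel, Gaussian
naive Bayes. Median imputation is fit on the training set for all
models; standardization (zero mean, unit variance, train-fit) is
additionally applied for the SVM and naive Bayes. Two printed formulas
in the source protocol cannot be taken literally and are corrected with
the deviation recorded in every report footer: precision is implemented
as TP/(TP+FP) (the printed version repeats the recall denominator), and
the "RBF kernel" attributed to naive Bayes is read as the SVM's kernel
(naive Bayes has no kernel). Headline multi-class metrics are macro
averages over the three one-vs-rest problems; per-class values are
always emitted so any other averaging convention can be recovered. Zero
denominators flag the affected metric NaN and exclude it from the macro
with a log entry. ROC curves are one-vs-rest per class from class
probabilities (decision values for the SVM), AUC by trapezoid.

For muscle-set evaluation, the trial table is restricted to the set's
sensors and widened to one row per (subject, task, trial) with
`<muscle>_<side>_<feature>` columns — left/right sensors contribute
concatenated features rather than pooled rows (pooling available).

## Synthetic cohort generator

The generator encodes the group differences the analysis is meant to
detect; its defaults are the study conditions, not tuning knobs.

- **EMG**: a unit-variance Gaussian carrier band-passed to 20–450 Hz
  (inside the analysis band, so preprocessing preserves it) multiplied
  by a burst envelope of Hann-shaped bumps with Poisson count, uniform
  centers and jittered durations/amplitudes; overlaps take the pointwise
  maximum. Skill templates: novices burst more often (0.60/s vs 0.42/s),
  longer (1.2 s vs 0.8 s) and harder (0.55 vs 0.30 of MVC) than experts,
  with intermediates between. Baseline noise 8 µV on all groups.
- **MVC reference**: 2× the subject's maximum task-envelope amplitude
  (the protocol never describes the MVC trial numerically); the multiple
  is configurable.
- **Accelerometer**: each axis is amplitude · (w_p · sinusoid + w_c ·
  peak-normalized Lorenz-63 component + w_n · peak-normalized white
  noise) with weights summing to 1, base frequency 1.5 Hz, default
  amplitude 0.5 g. The Lorenz flow (σ=10, ρ=28, β=8/3) is integrated by
  fixed-step RK4 at dt = 0.01 per output sample with a 1000-step
  transient discarded, giving a known positive largest exponent
  (≈0.906 per unit flow time) as a validation target. Skill weights:
  novice (0.20, 0.35, 0.45), intermediate (0.40, 0.35, 0.25), expert
  (0.60, 0.30, 0.10) — novice movement is noise-dominated, expert
  movement smooth and repeatable.
- **Task durations** (s), chosen once as plausible completion times:
  knot tying 50/48/45 for novice/intermediate/expert (all groups
  similar), pegboard 110/85/70, robotic suturing 100/75/65 (novices
  markedly slower).
- **Between-subject variation**: multiplicative log-normal jitter
  (relative SD 0.08) on activation parameters and durations, additive
  renormalized jitter on complexity weights, log-normal (SD 0.15) on the
  subject's MVC scale.
- **Planted-signal cohorts**: `informative_muscles` restricts the
  skill-dependent structure to a subset of muscles; the rest use a
  skill-independent (intermediate) profile. This supports localization
  checks (e.g., only the ECU carries signal, so the ECU should top the
  per-muscle accuracy ranking).
- **Determinism**: all draws descend from `numpy` seed sequences spawned
  from the config seed, keyed by subject and unit indices, so any
  sub-cohort is reproducible and two runs of one config are
  bit-identical.
- **Serialization**: per-unit CSV channel files (17 significant digits,
  so text round-trips floats exactly) plus a YAML manifest; a manifest
  entry whose channel file is missing raises a corrupt-dataset error
  naming the file.

What the generator does **not** emulate: real motor-unit action
potentials (the carrier is Gaussian, not a physiological MUAP train),
electrode artifacts, ECG contamination, cross-talk between sites,
actual task biomechanics or robot kinematics, gravity orientation in the
accelerometer (components are zero-mean mixtures), or vendor file
formats. Passing tests therefore show that the pipeline recovers the
*kind* of structure these sensors carry — amplitude/duration workload
differences and regularity/complexity differences — not that it
reproduces any particular human dataset's numbers, which are not
publicly available.

## Pipeline and provenance

Stages `simulate → preprocess → features → select → train → report` each
write plain-text artifacts plus a provenance record (stage, derived
seed, configuration hash, package version). Stage seeds derive from the
single global seed by SHA-256 of `"<seed>:<stage>"` modulo 2³¹, so
independently re-run stages agree with full-pipeline runs. Running a
stage without its upstream artifacts raises an error naming the missing
stage. The descriptive group summary reports per-(skill, task) means,
SDs and counts for every feature plus the ordering of group means;
inferential statistics (MANOVA, post-hoc comparisons) are deliberately
out of scope.

## Problem sizes

Validation and the acceptance script use scaled-down cohorts chosen as
the package's own desk-scale problem sizes: an 8/8/8-subject, one-task,
two-muscle cohort (~25–30 s trials) for the separated-structure and
shuffled-label checks, a 6/6/6-subject six-muscle cohort (~15–22 s
trials) for planted-signal localization, and 2/2/2 subjects for the
determinism round trip. The full 10/11/5 × 3 tasks × 3 trials × 6
muscles × 2 sides design (2808 units) remains the generator default and
runs the same code paths.

## Known limitations

- Lyapunov and correlation-dimension estimates on short, noisy windows
  are biased; they are used as *relative* discriminative features, and
  their absolute values are only validated on the benchmark systems.
- The Wolf estimator saturates on noise-dominated series (divergence is
  immediate), so its magnitude is not interpretable there.
- The generator's group differences are, by design, stronger than what
  wearable studies typically report, so the end-to-end accuracies on
  synthetic cohorts exceed what the same pipeline would achieve on real
  recordings.
- The average-mutual-information lag selector uses a fixed 16-bin
  histogram; for very short series it can return an early spurious
  minimum. The lag is always available as an explicit parameter.
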