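# Methods

## Problem and pipeline

Obstructive sleep apnea syndrome (OSAS) is graded by the apnea–hypopnea
index (AHI): apneic events (obstructive, central and mixed apneas plus
hypopneas) per hour of sleep, with the clinical class bands normal
(AHI < 5), mild (5–15), moderate (15–30) and severe (≥ 30). The package
estimates AHI and severity from a single bed-sensor ballistocardiogram
(BCG) sampled at 125 Hz, using deliberately cheap algorithms: instead of
classifying the whole night, a variance change-point detector first
pre-identifies *apnea-suspected episodes*, and only those are featurised
and classified. Features are computed from the BCG directly — no heartbeat
localisation, no derived respiration or heart-rate series.

## Signal conditioning

Band-pass Butterworth, 0.05–3 Hz, order 7, applied forward–backward
(`sosfiltfilt`). Zero-phase filtering doubles the effective order but
keeps event onsets un-shifted, which matters because episode labels are
assigned by temporal overlap. After z-scoring (population SD), motion
artifacts are flagged per non-overlapping 30 s RMS window when the window
RMS strictly exceeds mean + 1 SD over windows. The rule is one-sided:
movement raises RMS, while apneas *lower* it, and a two-sided rule would
discard the episodes of interest (a `two_sided` config flag exists for
sensitivity experiments). Flagged windows are excluded wholesale; signal
is never repaired. "SD" is the population (ddof = 0) convention
throughout the package.

## Change-point episode pre-identification

Segment cost is the Gaussian variance cost
`C(i, j) = (j − i) · log(max(var x[i:j], 1e-12))`. The default search is
greedy recursive binary segmentation with minimum-improvement stopping: a
split is accepted only when it reduces its segment's total cost by
strictly more than the threshold (default 50, on the conditioned,
z-scored signal). An exact penalized dynamic program
(`mode="exact"`, minimising total cost + threshold × #splits, O(n²)) is
provided and is verified against exhaustive enumeration in the tests.

Numerical choices:

- **Minimum segment length.** The variance-log cost is unbounded below
  for near-constant micro-segments, so a minimum segment length is
  required. The low-level function defaults to 10 samples (enough to keep
  pure-noise inputs split-free at realistic lengths); the pipeline uses
  `cp_min_size = 375` samples (3 s at 125 Hz), below which local variance
  fluctuations within a single breathing cycle (~4 s at 15 breaths/min)
  masquerade as change points and shred the night into sub-10 s
  fragments.
- Detection runs separately on each contiguous artifact-free block, so
  masked samples never contribute to a segment.
- Every inter-change-point segment is a candidate episode. Durations
  < 10 s (strict) are excluded as too short to be apneas or hypopneas;
  durations > 120 s (`max_episode_s`, an artifact bound the source
  method leaves open) are excluded because unbounded quiescent stretches
  would swamp the classifier with trivial negatives.

An episode is labelled positive when its half-open interval has a
nonzero-length intersection with any annotated event. All intervals in
the package are half-open `[start, end)` seconds, making boundary-touching
cases deterministic.

## Features (38 per episode)

Time domain: mean square power, SD, zero-crossing rate, Fisher kurtosis,
skewness; mean and SD of the Teager energy
ψ[n] = x[n]² − x[n−1]·x[n+1]; sample entropy SampEn(m = 2,
r = 0.2·SD, Chebyshev distance, self-matches excluded, Richman–Moorman
counting); intercept, slope and RMS residual of an OLS fit against time
(default on the raw samples; an envelope mode fitting the 1 s RMS
envelope is available since the motivating signature is an amplitude
trend); 15 Burg-method AR coefficients (convention
x[n] = Σ aₖ x[n−k] + e[n]; Burg is stable on short segments, Yule–Walker
adds nothing here).

Frequency domain, from a Welch PSD (8 s Hann segments, 50 % overlap,
zero-padded to a ≤ 0.01 Hz grid, per-segment mean detrend) normalised to
unit total power: dominant frequency and its normalised peak power in
0–0.5 Hz (respiration, DF1/SP1) and 0.8–1.8 Hz (cardiac fundamental,
DF2/SP2); mean and SD of normalised PSD bins in 0–3 Hz and 3–10 Hz; band
powers VLF [0, 0.05], LF (0.05, 0.15], HF (0.15, 0.5] Hz and the LF/HF
ratio (HF floored at 1e-12). SP1/SP2 are peak bin values, not integrated
band powers — the cheaper and sharper choice where the source is
ambiguous; SPL/SPH statistics use normalised power uniformly. The 3–10 Hz
statistics are computed on the band-passed signal exactly as the stage
order dictates (only filter roll-off energy remains there); a
`sph_on_raw` switch computes them on the pre-filter z-scored signal
instead.

Episodes longer than 30 s are anti-alias decimated to ≤ 2000 points
before SampEn only (the one O(n²) feature); all features are rates or
normalised quantities, so they are insensitive to episode length, which
the tests verify on stationary cuts. Any single-feature failure (e.g., a
constant segment) invalidates the episode; invalid episodes are dropped
and counted.

## Classification and cross-validation

One fold per subject (leave-one-subject-out): the test subject's episodes
never appear in training or validation — the audit is part of the test
suite. Within each fold, four training subjects (one per severity class,
drawn from the fold's deterministic seed) form a validation set;
hyperparameters are tuned by seeded random search (default budget 30
draws; the study-scale runs in this repository use budget 10, see
"Problem sizes") maximising validation F1, then the model is refit on all
31 training subjects. Random forest is the default (trees 50–500, minimum
leaf 1–50, positive class prior 0.1–0.9 via class weights); RBF-SVM
(C 1e-2–1e2, γ 1e-3–1e1) and logistic regression (C 1e-3–1e3), both
behind a standardising pipeline, are alternatives.

Pooled event metrics: sensitivity = true events overlapped by ≥ 1
positively-predicted episode / all true events; precision =
positively-predicted episodes overlapping ≥ 1 true event / all
positively-predicted episodes; F1 is their harmonic mean. With zero
positive predictions precision is reported as 0 and flagged.

## AHI, severity and boundary calibration

Estimated AHI = positive episodes per hour of **total recording time**
(i.e., a respiratory event index — sleep staging is out of scope), while
the reference AHI uses annotated sleep time when available; missed events
and the larger denominator both bias the estimate low. Severity classes
use inclusive lower bounds. Boundary calibration grid-searches ordered
triples (b1 ∈ {0.5, 1, …, 10}, b2 ∈ {b1+0.5, …, 20} step 0.5,
b3 ∈ {b2+1, …, 40} step 1 — a grid containing both the clinical
(5, 15, 30) and coarse integer triples) maximising 4-class accuracy on
the training subjects' (estimated AHI, true class) pairs, with ties
broken by higher kappa, then smallest L1 distance to (5, 15, 30), then
lexicographically — fully deterministic and auditable. Per-fold triples
are aggregated by component-wise median (lower median for even counts, so
the result stays on the grid). Because the grid contains (5, 15, 30),
calibration can never reduce training accuracy below the nominal
boundaries'.

Agreement statistics: Spearman correlation of estimated vs reference AHI;
Bland–Altman mean difference (estimated − reference) with ±1.96 SD limits;
4-class and collapsed 2-class (normal+mild vs moderate+severe, applied to
both label sets) confusion matrices with overall accuracy and unweighted
Cohen's kappa. The correlation between per-subject underestimation
(reference − estimated AHI) and hypopnea index (hypopneas per recording
hour) is reported, returning NaN when either variable is constant.

## Synthetic cohort

The generator emulates what the pipeline needs to see, not hemodynamics:

- cardiac pulse train: a damped 8 Hz oscillation (decay 0.15 s) plus a
  slow Gaussian recoil bump, so the heart-rate fundamental survives the
  0.05–3 Hz band-pass; inter-beat interval Gaussian with 5 % jitter
  around 60/HR (default HR 70 bpm);
- respiration: sinusoid at 15 breaths/min with 3 % slow frequency
  jitter, both amplitude-modulating the pulses (depth 0.5) and adding a
  baseline (amplitude 0.4 relative to unit pulse amplitude);
- events: count = round(target AHI × hours) exactly, durations uniform
  10–60 s, minimum gap 15 s, 30 s edge margins, placed by uniform
  stick-breaking (an error suggests a longer recording when they cannot
  fit); apneas suppress the respiratory modulation and baseline to 0.05,
  hypopneas to a per-event uniform 0.3–0.7; each event is followed by
  5–10 s of 1.5× amplitude overshoot (recovery breaths); hypopnea
  probability 0.33 per event (roughly the clinical subtype mix), the
  remainder obstructive — central/mixed share the obstructive phenotype
  and are not separately modelled;
- noise: white Gaussian at 0.1 of the clean-signal SD; motion artifacts:
  Poisson bursts (default 2/h, 2–6 s, 6× signal SD, low-pass shaped into
  the analysis band), kept clear of annotated events so event ground
  truth stays unambiguous.

Per-subject target AHIs are drawn uniformly inside the class band, 0.5
events/h away from the edges so the rounded realised count stays in band.
Cohorts draw per-subject seeds deterministically from one cohort seed.

What the generator does **not** emulate: real BCG morphology and its
inter-subject variability, posture changes, sleep–wake structure, gradual
event onsets, central-apnea cardiac signatures, sensor drift. Passing
end-to-end tests therefore demonstrates that the pipeline's machinery is
correct and recovers known ground truth under its own model of the
signal — not clinical-grade performance; on this high-signal cohort,
detection metrics are far above what heterogeneous clinical data yields,
and the AHI bias is small, so calibrated boundaries stay near (5, 15, 30)
unless under-detection is injected.

## Problem sizes and determinism

Default verification scales, chosen so the whole suite runs comfortably
on one CPU: the study-scale cohort is 32 subjects (8 per class) at 1 h
per recording with tuning budget 10; module tests use an 8-subject,
half-hour cohort with budget 5. Every stochastic element — simulator,
validation-subject draws, random search, forest — is seeded from a single
seed, and refitting with the same seed reproduces predictions, AHIs and
boundaries exactly. The systematic-under-detection check thins each
subject's detected events to round(0.6 · n) before re-estimating AHI,
which drags all three calibrated boundaries strictly below (5, 15, 30).

## Known limitations

- The change-point threshold (50) is taken at face value for the
  variance-log cost on z-scored data; its interaction with a different
  cost algebra or un-normalised units is not modelled (it is
  config-exposed).
- AHI from total recording time systematically underestimates sleep-time
  AHI; boundary calibration compensates on average but cannot correct
  per-subject sleep-efficiency differences.
- EDF support is a minimal single-channel reader/writer (16-bit, 1 s
  records, trailing partial second dropped on write); CSV is the primary
  interchange format.
- `aggregate_boundaries` checks median ordering defensively, but the
  violation is unreachable for valid per-fold boundaries (order
  statistics preserve strict pairwise domination).
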