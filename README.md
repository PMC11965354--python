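# bcgapnea

Cost-effective monitoring of obstructive sleep apnea syndrome (OSAS) from a
single-channel **ballistocardiogram** (BCG) — the micro-movement signal a
piezoelectric bed sensor records from heartbeats and breathing.

Polysomnography (PSG), the clinical gold standard, requires a sleep
laboratory. A bed sensor is non-obtrusive and cheap, but embedded hardware
cannot afford to run heavy feature extraction over a whole night of signal.
This package implements a pipeline built around that constraint:

1. **Conditioning** — 7th-order Butterworth band-pass (0.05–3 Hz, zero
   phase), z-score normalisation, and exclusion of motion artifacts as
   30 s windows whose RMS amplitude exceeds one SD above the mean.
2. **Episode pre-identification** — fast variance change-point detection
   (segment cost `C(i,j) = (j−i)·log var(x[i:j])`, greedy binary
   segmentation, minimum cost improvement 50) isolates *apnea-suspected
   episodes*; segments shorter than 10 s are too short to be apneas or
   hypopneas and are discarded. Only these episodes are processed further.
3. **Features** — 38 BCG-only features per episode (power, SD,
   zero-crossing rate, kurtosis/skewness, Teager energy, sample entropy,
   linear trend, 15 Burg AR coefficients, dominant respiratory/cardiac
   frequencies and normalised band powers incl. VLF/LF/HF), with no
   heartbeat localisation anywhere.
4. **Classification** — a random forest (SVM and logistic regression as
   alternatives) labels each episode apneic/non-apneic under strictly
   subject-independent leave-one-subject-out cross-validation, with
   per-fold seeded random-search hyperparameter tuning on a 4-subject
   validation split (one subject per severity class).
5. **Assessment** — the apnea–hypopnea index (AHI) is estimated as
   positive episodes per hour of recording (a respiratory event index),
   severity is graded as normal / mild / moderate / severe
   (AHI < 5 / 5–15 / 15–30 / ≥ 30), and because missed events bias the AHI
   low, the three class boundaries are recalibrated by grid search on the
   training folds and aggregated by median. Agreement is quantified with
   confusion matrices, accuracy, Cohen's kappa, Spearman correlation and
   Bland–Altman limits.

Clinical BCG cohorts are rarely shareable, so the package ships a
synthetic-cohort generator (`bcgapnea.simulate`) producing BCG-like signals
— a cardiac pulse train amplitude-modulated by respiration, with apneas,
hypopneas, recovery breaths and motion artifacts — plus exact ground-truth
annotations, so the whole pipeline is testable end to end.

## Worked example

```python
import bcgapnea as bg

cfg = bg.PipelineConfig(tune_budget=6)
model = bg.BcgCohortModel.from_simulation(n_per_class=2, duration_h=1.0,
                                          seed=7, config=cfg)
res = model.fit()
print(res.summary())
```

prints (8 synthetic subjects, two per severity class, 1 h each):

```
BCG-based OSAS assessment — cohort results
==========================================================
subjects: 8    episodes: 223    positive predictions: 150

Apneic event detection (pooled over LOSO folds)
  sensitivity  0.916   precision  0.960   F1  0.937
  true events 154   captured 141

AHI agreement (estimated vs reference)
  Spearman r  0.970   mean difference   -0.50 events/h
  95% limits of agreement [-4.66, 3.66]

Severity boundaries: nominal (5, 15, 30) -> adjusted (5, 15, 30)
  4-class accuracy / kappa:  nominal  87.5% / 0.83   adjusted  87.5% / 0.83
  2-class accuracy / kappa:  nominal  87.5% / 0.75   adjusted  87.5% / 0.75
```

Reading it: 154 apneic events were annotated in the ground truth; 141 were
overlapped by a positively-classified episode (pooled sensitivity 0.92,
precision 0.96). Estimated AHI ranks the subjects almost perfectly
(Spearman 0.97) with a mean bias of −0.5 events/h, and severity grading
agrees with the reference for 7 of 8 subjects. On this high-signal
synthetic cohort the AHI bias is small, so boundary calibration keeps the
clinical thresholds; under heavier under-detection it pulls them down.

`res.plot_ahi_scatter()`, `res.plot_bland_altman()` and
`res.plot_fold_boundaries()` draw the standard agreement figures, and
`res.save_report(path)` writes a JSON report.

The same pipeline is scriptable from a shell:

```sh
bcgapnea simulate --out cohort/ --n-per-class 8 --duration-h 1 --seed 1
bcgapnea assess --cohort cohort/ --out report.json --seed 1
```

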