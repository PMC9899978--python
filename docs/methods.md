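# Methods

`arimap` analyses multi-lead unipolar epicardial electrograms and surface
ECG recorded at fixed snapshots around the onset of a coronary occlusion,
and associates the resulting repolarization measures with early
("phase 1A") ventricular fibrillation.  This note documents the models, the
parameter choices that are genuinely open, the numerical conventions, what
the synthetic cohort does and does not emulate, and the known limitations.

## 1. Fiducial detection

**Derivative estimation.** All fiducials are extrema of the first
derivative of the low-pass-smoothed signal.  Smoothing is a zero-phase
Gaussian kernel parameterized by its half-power cutoff; the derivative is
the central difference of the smoothed samples, in signal units per ms.
Raw finite differences at 4 kHz are noise-dominated, and a symmetric kernel
guarantees that smoothing cannot displace the extremum of a symmetric
deflection.  Cutoffs:

| stage | cutoff | rationale |
| --- | --- | --- |
| QRS onset, AT | 40 Hz | the intrinsic deflection is fast and large; heavy smoothing would let neighbouring waves bias its position |
| RT (Wyatt) | 20 Hz | the T upstroke is slow and shallow; at 40 Hz its derivative extremum jitters by ~2 ms under realistic noise, at 20 Hz by ~0.5 ms while the noiseless extremum moves < 0.02 ms |
| ECG T apex / T end | 15 Hz | the tangent method needs a stable slope estimate on a low-frequency wave |

The isoelectric level for ECG T-wave work is the mean of the 40 ms PR
segment preceding the QRS onset, taken on the 40 Hz (not the 15 Hz) signal:
the heavier smoothing smears QRS energy back into the PR segment and would
bias the tangent intersection asymmetrically for positive vs negative T
waves.

**QRS onset** is the first instant at which the rectified smoothed
derivative exceeds 10% of its beat maximum, where "first" means the
earliest crossing that is preceded by at least 10 ms of sub-threshold
signal.  The quiet-stretch requirement skips the brief sub-threshold dip
between the far-field R wave and the local intrinsic deflection without
being fooled by the silent ST gap between them.  The crossing is linearly
interpolated between samples, so the onset has sub-sample resolution; the
rule is invariant to amplitude scaling and constant offsets.

**AT** is the dV/dt minimum within the QRS window (onset to onset + 80 ms);
**RT** is the dV/dt maximum within the T window (AT + 100 ms to 90% of the
RR interval, in beat time).  The Wyatt maximum-upslope rule is polarity
independent by construction.  Ties break to the earliest sample.  The
window bounds are configurable; the defaults are package decisions — no
standard exists for them.

**ECG T end** uses the tangent method: the line through the steepest
returning slope after the T apex, intersected with the isoelectric level.
The same formula serves positive and negative T waves; a biphasic T yields
the dominant deflection's apex.

**Rate correction** is Bazett's, `x / sqrt(RR in s)`, applied identically
to ARI, QT and QTp using the same beat's preceding RR.

A lead on which any detector fails is recorded as missing and excluded per
metric downstream; nothing is imputed.

## 2. Zone classification and summaries

A lead belongs to the **core ischemic zone** when its AT exceeds its own
baseline value by strictly more than 5 ms at *any* of the 1, 2.5 or 5 min
snapshots.  The threshold is absolute by default; a relative mode (> 20% of
the baseline AT) is available because the defining criterion can be read
either way.  The **border zone** is the 4-neighborhood adjacency frontier
of the core on the electrode grid (8-neighborhood by option); everything
else is remote.

Per animal and time-point the package reports cross-lead extrema (maximal
AT, minimal/mean/maximal ARIc, maximal QT/QTc, minimal QTp/QTp_c), the
dispersion of repolarization DOR = max RT − min RT (natural RT by default;
whether rate-corrected RT was ever used for DOR is not standardized), the
global Tpeak–Tend span, and the **early-prolongation flag**: true iff
maximal ARIc rose by strictly more than 10 ms above baseline at 1 and/or
2.5 min.

## 3. Outcome statistics

All association analyses are univariate, matching the scale of an 18-animal
experiment.  Repeated time-points enter regressions either pooled (one row
per animal per time-point within the 1–10 min phase-1A window; animal-level
clustering is flagged in every report, not modeled) or reduced to one
per-animal maximum — both modes ship because the correct choice is not
derivable for this design, and no replication of any specific coefficient
is claimed.

* Logistic and linear fits come from statsmodels (ML logit, OLS); odds
  ratios carry Wald 95% intervals symmetric on the log scale.  Complete or
  quasi-complete separation is flagged, never silently reported.
* The ROC AUC is computed from ranks as the Mann–Whitney pairwise
  concordance with ties counted ½ — exactly the all-pairs count — with the
  asymptotic rank-test p-value.  Cutoffs follow the "covariate > c predicts
  event" convention over observed values; the optimal cutoff maximizes
  Youden's J, ties resolved to the lower cutoff.
* Cox fits use lifelines (Efron tie handling).  Kaplan–Meier curves come
  from lifelines; the two-sample log-rank chi-square is computed in-package
  from the summed observed-minus-expected events with hypergeometric
  variance terms, and is cross-checked against lifelines in the tests.
  Non-event animals are censored at 10 min, the end of the phase-1A window.
* The occlusion-site comparison is a Pearson chi-square without continuity
  correction (the convention that reproduces the printed statistic for a
  5/9-vs-4/9 table, 0.222).

A note on a tempting invariance: duplicating every subject leaves
Kaplan–Meier curves unchanged and exactly doubles the summed O−E, but the
pooled log-rank statistic more than doubles, because duplication creates
tied event times whose variance factor (n−d)/(n−1) is not additive.  The
tests assert the exact closed form.

## 4. The synthetic cohort

The generator emulates the study design: `n_animals` (default 18, half LAD
/ half LCX occlusion), 32–64 unipolar epicardial leads on a rectangular
plate (default 48 on 6×8) at 4 kHz, 12 surface-ECG leads at 1028 Hz, one
representative beat per lead at snapshots 0/1/2.5/5/10 min (multi-beat
snapshots by option).

**Beat model.** Every waveform is a sum of smooth Gaussian steps
(`h·Φ((t−μ)/σ)`).  Only four properties are contractual: the smoothed
derivative minimum inside the QRS window falls at the requested AT, the
smoothed derivative maximum inside the T window at AT + ARI, the ST plateau
equals the requested shift, and T polarity is selectable (50/50 mixed by
default on epicardial leads) without moving either extremum.  Component
spacings were chosen so that neighbouring steps displace each extremum by
< 0.1 ms — below the 0.25 ms sample period — which makes the placement
itself the ground truth.  Two feasibility floors follow from the
morphology: AT ≥ 24 ms from onset (closer would merge the intrinsic
deflection into the far-field R wave) and RR large enough to contain the
T wave plus margins; sampled values are clipped to these floors.

**Electrophysiology.** Per-lead baseline AT and ARI are normal with an
animal-level random effect; occlusion adds profile values per time-point:
an AT delay reaching ~25 ms and an ARIc shortening in the core, and a
biphasic ARI course in the border (+24 ms at 1 and 2.5 min — the reported
group median of border-zone prolongation, used as a parameter, not a
reproduced statistic — turning negative by 5–10 min).  Core leads also gain
a 0.2 mV ST elevation.  The variance components are calibrated to the
study's descriptive table: a within-animal ARIc lead SD of ~15 ms (from the
~34 ms gap between maximal and average ARIc over ~48 leads, consistent with
the reported DOR) and a between-animal SD of ~23 ms natural units; RR is
lognormal between animals (534 ± 97 ms) with a small (2% CV) within-animal
drift across snapshots, since the reported group means drift by only ~1–2%.
Fully independent per-snapshot RR draws would make Bazett-corrected
intervals jump by ±18 ms between time-points, contradicting the table.
Small per-snapshot jitters (0.5 ms AT, 3 ms ARI) stand in for biological
beat-to-beat variation.

**ECG and outcome.** Each ECG lead's QT targets the maximal epicardial RT
plus a lead-specific offset (20 ± 8 ms), which builds in the expected
coupling between maximal ARIc and maximal QTc; the recorded ECG ground
truth is not the target but the analytic fiducials (onset, apex, tangent
T-end) of the noiseless waveform on a 0.05 ms grid, evaluated with the same
rules and smoothing bands the detectors use.  VF is Bernoulli with
logit P(VF) = β₀ + β₁·(true maximal QTc at 2.5 min); the default slope
corresponds to an odds ratio of 1.024 per ms centred to give ~50% incidence,
and VF times are uniform on 1–8 min (only the range is reported), non-VF
animals censored at 10 min.

With `signals=False` the generator produces the ground-truth tables and
outcomes without waveform synthesis — the cohort-level model — which is the
path used for large statistical simulations such as the 500-replicate Wald
coverage study (100,000 animals would otherwise require ~6 million
waveforms).  The coverage property concerns the logistic outcome model on
the covariate the VF model actually uses, so nothing is lost by skipping
synthesis there.

**Determinism.** All randomness flows from one `SeedSequence`; per animal,
separate spawned streams drive structure, waveform noise and outcomes.
Identical configs regenerate bit-identical datasets, and the pipeline's
manifest digests make run-level determinism checkable.

**What the generator does not emulate.** No ionic-current dynamics, no
restitution (ARI is generated independently of RR, so ARIc inherits RR
drift that real, rate-adapted ARIs would partly compensate), no spatial
autocorrelation of baseline properties beyond the zone structure, no VF
waveforms, no ectopy, no drifting baselines or powerline artifacts, and no
body-surface forward model (ECG beats are the same parametric model with
their own ground truth).  Passing tests therefore demonstrate correctness
of the measurement and statistics chain under this generative model — not
detector performance on real electrograms.

## 5. Simulation scale of the test suite

The suite validates the fiducial oracle equivalence on 1,000 noiseless
beats, noise robustness on 500 matched polarity pairs at 20 dB SNR, zone
recovery on 50 noiseless animals, the prolongation flag on 2 × 200 animals
at default noise, ROC identities on 100 random cohorts, and Wald coverage
on 500 cohorts of 200 animals in ground-truth mode.  These sizes keep the
whole suite within a few minutes on one CPU while leaving the Monte-Carlo
error of each check well inside its asserted band.

## 6. Known limitations

* **The prolongation flag's operating characteristics are bounded by the
  cohort's own dispersion.**  With the within-animal ARIc lead spread
  calibrated to the study table (~15 ms SD), injecting the median border
  prolongation (+24 ms natural, ≈ +33 ms ARIc) raises the *border* maximum,
  but the flag compares the *all-lead* maximum across time: in ~10–13% of
  animals the baseline all-lead maximum exceeds the elevated border maximum
  by more than the margin, so the true flag rate plateaus near 87–90% no
  matter how accurate the detectors are, and measurement noise adds ~5
  percentage points of false positives on the null side.  This mirrors the
  real experiment, where only 11 of 18 animals showed >10 ms prolongation.
  A detection experiment demanding ≥90%/≤10% operating characteristics is
  therefore not achievable under table-calibrated dispersion; the package
  reports the flag as defined rather than tuning the cohort to make it look
  sharper.
* Wald intervals and the asymptotic rank test are used at n = 18 where
  exact methods could differ; the package matches the original analysis
  conventions instead of improving on them.
* Repeated time-points pooled into univariate regressions ignore
  within-animal correlation; the per-animal-maximum mode is the
  conservative alternative, and every report names its mode.
* The tangent T-end and all window defaults are reasonable conventions,
  not validated against manual annotations.
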