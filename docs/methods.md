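# Methods

This package implements the computation of task-induced frontal alpha
asymmetry (FAA) and its emotional-modulation index (eFAA) from epoched EEG,
together with the group comparisons and questionnaire correlations used to
evaluate eFAA as a candidate biomarker of mild traumatic brain injury
(mTBI).  Because the clinical EEG underlying the published group statistics
is not redistributable, the package ships a synthetic cohort generator that
reproduces the study's task structure and configured effect sizes; every
pipeline stage is exercised and validated against that generator.

## Indices

With `P(e, c)` the subject's mean alpha-band (8–12 Hz) power at electrode
`e` in condition `c`:

```
FAA(c)  = ln P(F4, c) − ln P(F3, c)
eFAA    = FAA(threat) − FAA(neutral)
```

Lower FAA means relatively more right-frontal cortical activity (alpha is
inversely related to activation).  eFAA isolates the effect of threat
content by subtracting an emotionally neutral but otherwise identical
condition, and thereby also cancels each subject's baseline asymmetry.
Per-subject condition means are computed per Emotion × Relevance cell; the
overall FAA is the unweighted mean of the four cell values (cell-means
logic, matching the ANOVA), and scalar eFAA is the mean of the per-Relevance
differences.  Go/NoGo is generated and marked but pooled before averaging,
since the asymmetry analyses carry only Emotion and Relevance factors.

## Preprocessing chain

The chain is fixed and recorded in provenance metadata:

1. zero-phase Butterworth band-pass 0.01–70 Hz (4th order, forward–backward);
2. decimation 500 → 250 Hz (anti-aliased, zero-phase);
3. ocular correction: Gratton-style regression of each EEG channel on the
   vertical EOG, with the propagation coefficient estimated over
   blink-active samples (3×MAD threshold on the EOG).  Regression replaces
   interactive ICA-based correction because it is deterministic and exactly
   testable against synthetic blinks of known propagation; an ICA hook can
   be added without touching the chain;
4. re-reference to Cz (reference retained as an all-zero channel; the
   operation is idempotent);
5. band-pass 0.1–30 Hz;
6. segmentation into 2-s epochs starting at the stimulus (triangle) onset
   marker, half-open `[onset, onset + 500)` samples at 250 Hz;
7. baseline correction by the mean of the first 200 ms;
8. amplitude rejection: a segment is discarded when any sample on any EEG
   analysis channel is strictly beyond ±80 µV.  Exactly ±80.0 µV is kept;
   the EOG channel is never in the rejection scope.  Rejection is
   whole-segment and applied to all EEG channels (scope configurable).

## Spectral estimation

Each 2-s, 250 Hz epoch yields a Hann-tapered one-sided periodogram with the
window power compensated, so the density (µV²/Hz) integrates to the epoch's
mean square (Parseval-consistent).  The 0.5 Hz grid hits the band edges
8.0 and 12.0 Hz exactly; band power is the trapezoidal integral over
[8, 12] Hz, endpoints included.  Per subject × electrode × condition the
per-epoch band AUCs are averaged over retained epochs and the natural log
is taken of the mean (log after average, matching the published order of
operations: power averaged per condition, then log-transformed).  The AUC
is floored at 1e-12 µV² before the log to guard degenerate input.  Cells
with fewer than `min_segments` (default 10) epochs are marked missing and
the subject is excluded from ANOVA input, with the exclusion logged.

## Outlier rule

Outliers are screened by mean ± k·SD with k = 2.5, computed on the pooled
sample across groups (the published analysis reports a single pooled mean
−0.14 and SD 0.41, giving bounds −1.165 / 0.885).  Removal is single pass
with strict exceedance (a value exactly at a bound survives).  The rule is
applied per analysis — once for the FAA ANOVA, once for the eFAA ANOVA, and
to both members of each correlation pair — mirroring the per-analysis
removals of the original study.  A per-group variant exists but is off by
default.

## Statistical battery

The mixed-design ANOVA (one between factor of 2–3 unbalanced groups × up to
two 2-level within factors) is implemented from the univariate
sums-of-squares partition using orthonormal within-subject contrasts: the
between stratum is a one-way ANOVA on subject means; each within effect and
its Group interaction are tested in the stratum of the corresponding
contrast scores with subjects-within-group error.  With unequal group
sizes, within main effects test the unweighted average of group means
(sum-to-zero / Type III estimable functions, the convention of the R
repeated-measures ANOVA packages this mirrors).  Two-level within factors
need no sphericity correction.  Generalized eta squared places all error
strata in the denominator: η²_G = SS_effect / (SS_effect + Σ SS_error).
The implementation is verified against an independent statsmodels
general-linear-hypothesis oracle on random unbalanced designs (agreement to
1e-8 relative) and against pingouin where conventions coincide.

Post-hoc group contrasts are Welch t tests (Satterthwaite fractional df)
with step-down Holm correction across the three pairs.  Homogeneity is
confirmed with the Brown–Forsythe variant of Levene's test (deviations from
group medians) and significant results with rank tests on the original,
outliers-in data (Wilcoxon rank-sum for two groups — exact for small n,
tie-corrected normal approximation otherwise — and Kruskal–Wallis for
three).  Questionnaire couplings use Spearman correlation (midranks).  The
depression-sensitivity re-analysis excludes subjects with BDI ≥ 10 (mild
depressive symptoms) and repeats the two-group FAA ANOVA.

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions:

* **Groups.** 17 controls, 12 non-symptomatic mTBI, 15 symptomatic mTBI.
  Group × emotion FAA targets default to the published means (Control
  +0.057/+0.060, NonSymp −0.215/−0.194, Symp −0.135/−0.154 for
  neutral/threat), applied to both relevance levels.
* **Task.** 16 blocks × 64 trials; four response rules, each governing four
  whole blocks (rules 1–2 attend the colour cue → the emotional figure is
  irrelevant; rules 3–4 attend the figure → relevant); emotion and go/nogo
  balanced 32/32 within block; inter-trial interval uniform 2.5–3.5 s
  (the pacing is not published; these values are configurable defaults,
  not inferred ones).
* **Signal.** 500 Hz on a minimal montage {F3, F4, Fz, Cz, VEOG} — only
  F3/F4/Cz enter the analysis.  During each trial's 2-s window, F3/F4 carry
  a 10 Hz sinusoid with per-trial random phase and a Tukey (Hann-edged,
  10 % ramps) taper; the taper's mean square is compensated exactly so the
  epoch band AUC equals the requested power (a sinusoid of amplitude A
  carries A²/2).  A full Hann envelope would scale epoch power by 3/8 and
  was rejected for that reason.
* **Subject variability.** Per subject, a baseline asymmetry offset
  (SD 0.30, the published between-subject FAA spread) shifts all four
  cells; an eFAA offset (SD 0.03) splits threat vs neutral; independent
  per-cell jitter (SD 0.02) keeps every ANOVA stratum non-degenerate.
* **Noise and its compensation.** Independent 1/f pink noise per channel
  (default 5 µV RMS, density flat below 0.5 Hz).  Its alpha-band AUC ν is
  known in closed form from the synthesis PSD; re-referencing adds Cz's
  independent noise, so the pipeline sees 2ν per electrode.  Cell powers
  are solved from (P4 + 2ν)/(P3 + 2ν) = e^FAA with P3 fixed at the base
  power (5 µV²), so the pipeline recovers target ln-ratios unbiasedly with
  noise on; with noise off this reduces to P4 = P3·e^FAA.
* **Blinks.** Poisson events (12/min) as 300-ms Hann bumps: full amplitude
  (400 µV) on VEOG, ×0.3 on frontal channels, none on Cz.  The per-trial
  artifact log records, for each epoch, the peak absolute frontal artifact
  after subtracting its own 200-ms baseline mean — exactly what the
  rejection stage will see — and is the ground truth for artifact tests.
* **Questionnaires.** A Gaussian copula couples each score to the subject's
  latent eFAA: latent ranks are mapped to normal scores, mixed at Pearson
  ρ = 2·sin(π·ρ_s/6) so the *Spearman* correlation hits the configured
  target (BDI −0.52, RPQ −0.34, PTA +0.41), then pushed through skewed
  marginals — BDI as a rounded Gamma(1.2) scaled so ~15 % of subjects reach
  the ≥10 cut-off; RPQ zero by definition for NonSymp, ≥1 for Symp; PTA
  (< 24 h) and months post-injury for mTBI subjects only; ages from the
  groups' published moments.  Rounding-induced ties attenuate the realised
  Spearman by well under 0.01 at these marginals.

What the generator does *not* emulate: event-related potentials, reaction
times or response errors, volume conduction/head geometry, non-stationary
alpha (beyond per-trial phase), line noise, or channel-specific artifacts.
Passing tests therefore demonstrate correctness of the computational chain
and calibration of the inference battery under a plausible signal model —
not clinical validity on real recordings.

## Numerical choices and problem sizes

* Filters: 4th-order Butterworth, SOS form, `sosfiltfilt`; band validity
  checked against Nyquist.  Decimation via zero-phase IIR.
* Trial onsets are rounded to even samples at 500 Hz so epoch boundaries
  survive the ÷2 decimation exactly.
* Degenerate-variance ANOVA cells report F = 0 with a flag rather than
  NaN; the band-AUC log floor is 1e-12 µV².
* Simulation sizes in tests and analysis scripts are chosen for fast,
  stable estimates: single-subject recovery checks use 4 blocks × 16
  trials (16 epochs per Emotion × Relevance cell); the cohort analysis in
  `analysis/` uses 4 blocks × 64 trials (64 epochs per cell); calibration
  studies use the scores-only fast path (latent per-subject scores without
  EEG synthesis), which is the appropriate level for calibrating the
  statistical battery itself.  The generator's task default remains the
  full 16 × 64 design.
* With scaled-down epoch counts, measurement noise adds to the latent
  eFAA spread (observed SD ≈ 0.06–0.08 at 64 epochs/cell vs 0.03 latent),
  so small-cohort eFAA contrasts are noisier than the published ones; at
  the full task size the measurement component shrinks by half.

## Known limitations

* The mixed ANOVA supports at most two within factors, each with two
  levels — exactly the designs used here; no sphericity machinery.
* Ocular regression assumes a linear, stationary blink propagation; it is
  exact for the synthetic blinks and an approximation for real EEG.
* The published F values for the clinical cohort cannot be reproduced from
  synthetic data; the package instead verifies the arithmetic identities
  of the published summary table and the calibration of each statistical
  component.
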