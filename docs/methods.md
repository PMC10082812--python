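# Methods

This note documents the models, conventions and numerical choices behind
`photom`, the assumptions they rest on, and what the synthetic-data tests do
and do not establish about recorded data.

## Signal model and ΔF/F correction

The measurement model is two fluorescence channels sharing their artifact
components:

    F465(t) = F0_465 · (1 + dff(t)) + s465·B(t) + g465·m(t) + ε465(t)
    F405(t) = F0_405              + s405·B(t) + g405·m(t) + ε405(t)

where `B(t)` is a double-exponential photobleaching baseline, `m(t)` sparse
motion/fiber-bending transients, and `dff(t)` the calcium signal, present
only at 465 nm. Because `B` and `m` enter both channels through the same
waveforms, an affine map of F405 predicts the calcium-independent part of
F465 exactly in the noiseless limit; the OLS fit estimates that map and

    ΔF/F = (F465 − fitted) / fitted

removes it. Consequences worth knowing:

* **Correction is only as good as the shared-waveform assumption.** Channel
  wavelength-dependent artifacts (hemodynamic absorption, autofluorescence)
  are outside the model and are not removed.
* **Both channels are smoothed identically before the regression**
  (centered moving average, default 0.25 s, configurable). Filtering only
  the regressor would leave the unfiltered fast component of common-mode
  artifacts in the numerator: with a smoothed-405-only chain we measured
  |corr(ΔF/F, motion)| up to ~0.3 on simulated sessions, versus ~0.04 when
  both channels pass the same filter, which cancels shared components
  exactly for any linear filter. A 405-only mode (`smooth_465=False`)
  remains available. The 0.25 s default preserves the energy of fast
  indicator transients (~0.05 s rise / ~0.5 s decay); a 1 s window blurs
  them enough to cost ~10 % of ground-truth correlation.
* **The ΔF/F denominator is the fitted curve**, so the effective gain varies
  with the bleaching level: a transient occurring while the baseline is
  still elevated reads slightly smaller. With the session template's 10 min
  habituation most bleaching has decayed by the first stimulus and the
  residual compression is ~1–3 %.
* **Artifact removal** flags samples with |x − median| > k·MAD (raw MAD,
  k = 8 by default) and linearly interpolates them. A global median/MAD rule
  presumes (i) stationary measurement noise to calibrate the threshold and
  (ii) artifacts large against the signal's overall spread. On a noiseless
  signal every genuine transient is unboundedly many MADs out, so
  zero-noise validation runs disable the detector (`artifact_mad_k` large);
  on strongly trending signals the trend inflates the MAD and the rule is
  conservative. Flagging > 10 % of samples warns; > 50 % refuses the
  session.

## Peri-event conventions

Windows are half-open `[onset − 5 s, onset + 10 s)`; the onset sample opens
post bin 0 (the post-stimulus axis of binned plots runs 0–20). Trials are
averaged pointwise per subject *before* binning; bins take
`round(b·bin_s·fs)` sample boundaries, so non-integer samples-per-bin
resolve by nearest-boundary assignment and no sample is dropped.
Baseline normalization subtracts the mean of the 10 pre bins from all 30
bins exactly once (double normalization raises). Summaries: peak point
= max of the 20 post bins; post mean = their mean.

## Bootstrap band

Resampling draws whole subject traces (one index per subject per iteration),
preserving within-subject correlation across bins; per-bin independent
resampling is available behind `resample_unit="per_bin"` for sensitivity
analysis. Bounds are linear-interpolation empirical percentiles of the
iteration means; significance is strict (`lower > 0`) and one-sided
positive, post bins only.

**Calibration caveat (measured, not hypothetical).** The plain percentile
bootstrap is narrow at photometry group sizes: for n = 8 i.i.d. normal
subject traces, P(lower 99 % bound > 0 | null) ≈ P(t₇ > 2.576·√(7/8))
≈ 0.023 rather than the nominal 0.005 (we measure ≈ 0.029 including
percentile-interpolation effects). The band should be read as a descriptive
envelope with an anti-conservative tail at small n; run-length rules or
studentized intervals, which mitigate this, are deliberately out of scope.

## Cohort statistics

* The repeated-measures unit of the group-level ANOVAs is the **post-stimulus
  bin of the group-mean trace** (20 rows), not the animal — the reference
  design, which the printed degrees of freedom force (within-group error
  df = ε·(k−1)·19; between design 2 × 20 rows → df 1, 38). This is
  statistically unusual and is stated prominently because of its
  consequences (below).
* RM-ANOVA and the split-plot two-way ANOVA are fit via pingouin;
  Greenhouse–Geisser ε is computed from the double-centered condition
  covariance and clamped to [1/(k−1), 1] (ε = 1 exactly for k = 2 and under
  compound symmetry). The within factor reports ε-corrected dfs; between and
  interaction terms report uncorrected dfs.
* Dunnett comparisons use t = (x̄ⱼ − x̄_baseline)/√(2·MSE/n) with the RM error
  df; the family-wise p integrates the equicorrelated (ρ = ½) multivariate
  t rectangle by seeded quasi-Monte-Carlo (absolute accuracy ~1e-4;
  reduces to the plain two-sided t for a single comparison). Dunn
  comparisons are Bonferroni-scaled rank z-tests; the family defaults to
  vs-baseline (mirroring Dunnett) with an all-pairs option.
* Šidák contrasts compare the groups at each timepoint with a pooled
  two-sample t (df n₁+n₂−2) and adjust p → 1 − (1−p)^m over the m
  timepoints. Adjusted p never falls below unadjusted p, for any procedure.
* Degenerate inputs resolve explicitly: zero residual variance in the RM
  design returns F = 0 (no effect) or F = ∞ (deterministic effect) rather
  than 0/0; a paired t on a constant nonzero difference raises
  `DegenerateStatisticError`; Fisher tables with a zero margin give p = 1.

**Known limitation of the bins-as-rows design.** The design assumes the 20
bins are exchangeable replicates. Any session-coherent variability — the
regression-gain error of each session, per-subject amplitude effects,
trial-to-trial response scaling — moves all bins of a curve together, so the
bin-level residual underestimates the sampling variance of a group-mean
curve and the interaction F is anti-conservative. On simulated null cohorts
(no group differences) the interaction rejects at far above nominal rate
regardless of generator settings with nonzero session-level noise. The
package reproduces the design faithfully for comparability, and its tests
therefore calibrate the ANOVA machinery on exchangeable-unit nulls (where
sizes are correct: measured 0.038–0.06 at α = 0.05) while treating
cohort-level detections as directional, not size-calibrated, evidence.

## Behavior

Active = a darting bout *starting* within the post-puff window (default
10 s, matching the photometry window; a sensitivity parameter). Passive =
immobility covering ≥ 50 % of the window (configurable fraction). Darting
takes precedence when both occur; anything else is unclassified and excluded
from contingency tables with a warning. Durations are exact interval
overlaps, additive over disjoint intervals.

## Synthetic sessions and cohorts

The generator exists to give every stage a known ground truth. Defaults
(chosen once, for realism at the study's scale):

| parameter | default | note |
|---|---|---|
| raw sampling rate | 200 Hz | downsampled to ~100 Hz in preprocessing |
| F0 465 / 405 | 100 / 80 a.u. | baseline fluorescence |
| bleach (A₁,τ₁,A₂,τ₂) | 20 a.u., 60 s; 8 a.u., 300 s | shared shape, channel scales 1.0/0.8; mostly decayed within the 10 min habituation |
| motion | 0.02 s⁻¹, 5 a.u., gains 1.0/0.8 | slow transients (0.1 s rise, 2 s decay), fiber-bending-like |
| transient kernel | 0.05 s rise, 0.5 s decay | unit peak, fast indicator |
| evoked response | 0.05 ΔF/F peak, 0.1 s latency, 0.02 s jitter | drive declines exponentially over 8 s: distinct early peak, sustained tail |
| spontaneous events | 0.05 s⁻¹, mean 0.015 ΔF/F | exponential amplitudes |
| noise | 0.3 a.u. per channel | white |

Session templates mirror the study protocol: 10 min habituation then two
stimuli at 5 min ISI (air puff) or 3 min ISI (auditory-only). Cohort
simulation uses the study group sizes (female 9/7, male 10/11
vehicle/psilocin), a log-normal per-subject amplitude multiplier
(σ = 0.15) held fixed across timepoints, and effect multipliers per
(sex, treatment, timepoint); the defaults program the study's directional
findings — doubling of the evoked amplitude in psilocin-treated females
acutely (×2.0 at injection, ×1.3 at day 2) and a persistent reduction in
psilocin-treated males (×0.4 at days 2/6/28). Responder type is a subject
trait (active probability 0.8 for females, 0.5 for males); active subjects
dart within 2 s of each puff, passive ones remain immobile through the
window. Everything derives from one seed; cohorts written twice with the
same seed are byte-identical.

**What the generator does not emulate:** wavelength-specific artifacts,
hemodynamic or autofluorescence confounds, biophysical calcium buffering,
non-stationary noise, electrical dropouts, or behavioral scoring noise.
Passing tests show the pipeline recovers what this model injects; they do
not certify recordings whose artifacts violate the shared-waveform
assumption.

## Validation problem sizes

Replicated simulations scale the session template down (20 s habituation,
25 s ISI at 100 Hz) so that hundreds of full cohorts run in minutes;
accuracy-oriented checks (amplitude recovery, motion rejection, ground-truth
fidelity) use the full-length 16 min template. Recovery is assessed on
sessions with the evoked transient plus bleach/motion/noise but without
spontaneous transients: those are a second genuine signal, and their
amplitude tail would otherwise land on peak bins and read as (spurious)
recovery error. Measured under these conditions: per-session peak error
within ±13 %, mean bias ≈ −1 to −3 % (bin-averaging of the peak plus
residual bleach compression), ground-truth correlation > 0.99 at zero noise,
|corr(ΔF/F, motion)| < 0.1 with raw-signal motion correlation > 0.98.
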