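# photom

Fiber-photometry peri-event analysis for stimulus-reactivity studies:
isosbestic-corrected ΔF/F, air-puff-locked trial averaging and 500 ms
binning, subject-resampling bootstrap significance bands, cohort-level
statistics, and threat-response classification — plus a synthetic
two-channel session generator with programmable ground truth so the whole
pipeline is testable end to end without recorded data.

The package is written for researchers analyzing two-channel GCaMP
recordings (465 nm calcium-dependent, 405 nm isosbestic control) around
discrete aversive stimuli — e.g. central-amygdala reactivity to an air puff
across treatment groups, sexes and follow-up timepoints.

## The analysis

**ΔF/F.** Photobleaching, fiber bending and motion contaminate both
excitation channels, while calcium dynamics appear only at 465 nm. After
artifact removal (median/MAD rule with linear interpolation), block-mean
downsampling to ~100 Hz and moving-average smoothing, the isosbestic channel
is regressed onto the GCaMP channel by ordinary least squares,

&nbsp;&nbsp;&nbsp;&nbsp;F̂₄₀₅(t) = β̂₁ F₄₀₅(t) + β̂₀,&nbsp;&nbsp;&nbsp;
ΔF/F(t) = (F₄₆₅(t) − F̂₄₀₅(t)) / F̂₄₀₅(t),

so any component shared by the two channels cancels.

**Peri-event binning.** ΔF/F is collected in half-open windows
[onset − 5 s, onset + 10 s), the two trials of a session are averaged
pointwise per subject, and the mean trace is reduced to 30 × 500 ms bins
(10 pre, 20 post; the onset sample opens post bin 0). Each trace is
baseline-normalized by subtracting its 10-pre-bin mean. Per-subject
summaries are the *peak point* (max post bin) and the mean of the 20 post
bins.

**Bootstrap band.** For a group of n subjects, n subject traces are drawn
with replacement and averaged per bin; over 1000 iterations the 0.5th/99.5th
percentiles of the resampled means form a 99 % band. A post bin is a
significant increase when the *lower* bound exceeds zero (strict,
one-sided-positive; pre bins are never tested).

**Cohort statistics.** Within-group timepoint effects: one-way
repeated-measures ANOVA with Greenhouse–Geisser-corrected degrees of freedom
(ε clamped to [1/(k−1), 1]) and Dunnett comparisons against baseline, or a
Friedman test with Dunn comparisons where normality fails. Between groups: a
mixed (split-plot) two-way ANOVA — treatment between, timepoint within —
with Šidák-adjusted per-timepoint contrasts. Peak points across sessions:
paired t. Active (darting) vs passive (immobile) threat-response
proportions: Fisher's exact test on 2×2 tables. Following the reference
design, the repeated-measures rows of the group-level ANOVAs are the 20
post-stimulus group-mean bins; see `docs/methods.md` for why that matters.

## Worked example

```python
import photom as ph

# one synthetic air-puff session: 10 min habituation, two puffs, 5 min ISI
events, duration = ph.air_puff_events()
params = ph.SignalParams(seed=7)
session, truth = ph.simulate_session(params, events)

trace = ph.preprocess_session(session)
binned = ph.perievent_pipeline(trace)
summary = ph.summarize_subject(binned)
print(f"isosbestic fit: slope={trace.fit[0]:.3f}, intercept={trace.fit[1]:.2f}")
print(f"programmed evoked amplitude: {params.evoked_amplitude:.3f} dF/F")
print(f"recovered peak point:        {summary.peak_point:.4f} dF/F")
print(f"post-stimulus mean (20 bins): {summary.post_mean:.4f} dF/F")

# a small group of subjects -> 99% bootstrap band
group = []
for i in range(8):
    s, _ = ph.simulate_session(ph.SignalParams(seed=100 + i), events)
    group.append(ph.perievent_pipeline(ph.preprocess_session(s)))
boot = ph.bootstrap_ci(group, ph.BootstrapParams(n_iter=1000, ci_level=99, seed=0))
sig = "".join("*" if b else "." for b in boot.sig_mask)
print(f"significant post bins (lower 99% bound > 0): {sig}")
```

prints

```
isosbestic fit: slope=1.283, intercept=-2.54
programmed evoked amplitude: 0.050 dF/F
recovered peak point:        0.0492 dF/F
post-stimulus mean (20 bins): 0.0302 dF/F
significant post bins (lower 99% bound > 0): ********************
```

The regression recovers the shared bleach/motion relation between the
channels (slope ≈ 1.28 reflects the programmed channel scales); the peak
point lands within 2 % of the programmed 5 % ΔF/F transient; and with eight
subjects carrying a sustained evoked response, every post-stimulus bin's
lower 99 % bound clears zero.

A `photom` command-line tool wraps the same stages for shell use
(`photom simulate | ingest | preprocess | perievent | bootstrap | behavior`);
run `photom --help`.

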