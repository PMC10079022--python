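# Methods

## Analysis model

The unit of analysis is the *arousal event*, pooled across recordings
(no subject-level random effects; events are treated as independent,
matching the pooled design the statistics reproduce). For each retained
event the autonomic response is summarised by four time-domain HRV
statistics — SDNN, RMSSD, pNN50 and mean heart rate — computed on three
consecutive 25-s ECG segments (*pre*, *intra*, *post*). Ultra-short-term
windows of 25 s are long enough for stable time-domain estimates and
short enough that the pre and post windows of one event do not reach into
its neighbours (the generator enforces > 61 s between onsets for exactly
this reason: 61 s is the smallest spacing at which two 75-s triplets
cannot overlap when peaks sit inside their events).

### Conventions and tie-breaks

- All times are seconds from recording start, 0-based; every interval is
  half-open `[start, start + duration)`. A peak exactly on a window's end
  boundary belongs to the next window.
- Binarization uses the strict predicate `score > threshold`; duration
  and gap rules are strict as well (`> 3 s` to keep, gap `> 11 s` to stay
  separate). Ties in the threshold score are broken toward the smaller
  (more sensitive) threshold; ties in the within-event probability
  maximum toward the earliest second.
- The intra window is centred on the peak-probability second with a
  −12/+13 split, keeping that second inside the window. Centering (rather
  than onset-anchoring) keeps a lagged autonomic response inside *intra*.
- The etiology lookback is anchored at the detected event's onset
  (configurable to the matched scored arousal's onset via
  `lookback_anchor`), and "happened in the window" means interval
  *overlap* with the lookback window — an event may start before the
  window or end inside it. Within one priority level the latest-ending
  candidate is the cause. The secondary (UOD) search considers only
  respiratory events: desaturations are respiratory phenomena, so a limb
  movement before a desaturation is not its cause.
- Stage is the stage of the 30-s epoch containing the onset; events
  starting in a Wake epoch are excluded from stage-stratified analyses
  with reason `wake` rather than dropped silently.

### HRV formulas

With n RR intervals in a segment (n+1 R peaks; at least 3 peaks are
required so every statistic is defined):

- SDNN: sample standard deviation of the intervals (ddof = 1);
- RMSSD: root mean square of the n−1 successive differences (the
  `rmssd_denominator="intervals"` flag divides the squared-difference sum
  by n instead, for comparison with sources that print that variant);
- pNN50: percentage of successive differences *strictly* greater than
  50 ms in absolute value, out of the n−1 differences;
- HR: 60000 / mean RR (ms).

RR intervals < 400 ms or > 2000 ms anywhere in a triplet exclude the whole
event (the strict inequalities leave exactly-400/2000 ms intervals in the
normal range). These are exclusions, not corrections — no interpolation of
ectopic beats is attempted.

### QRS detection

Pan-Tompkins with the classic free parameters: Butterworth band-pass
5–15 Hz (order 3, zero-phase), five-point derivative, squaring, 150-ms
moving-window integration, adaptive signal/noise levels with update
coefficient 0.125, threshold `NPK + 0.25 (SPK − NPK)`, RR-based
search-back at 1.66× the running average RR against the halved threshold,
and a 200-ms refractory period. Fiducial marks are refined to the local
band-passed maximum within ±50 ms. All parameters sit in
`PanTompkinsConfig`. Flatline input yields an empty peak list, not an
error.

### Statistics

Shapiro–Wilk normality is computed per metric × segment and *reported*
in the run report; it never switches the pipeline to nonparametric tests
— the t-tests are run regardless, mirroring the design this package
reproduces. Paired t-tests compare segment pairs within an etiology
(pre/intra, intra/post, and pre/post as a sanity row); Welch t-tests
(Student's pooled variant behind `independent_test="student"`) compare
gender and stage strata per segment. Every raw p is multiplied by the
fixed Bonferroni factor 200 (configurable; the multiplier is deliberately
a constant rather than the realised comparison count — the run report
logs the realised count so the two can be reconciled), capped at 1, and
significance requires adjusted p < 0.05 strictly. Cohen's d is
mean(diff)/sd(diff) for paired and pooled-SD standardised mean difference
for independent comparisons. Identical paired samples return t = 0,
p = 1; zero-variance samples with a nonzero mean difference are signalled
as degenerate and the row is flagged, never silently filled.

## Synthetic data: what it emulates, what it does not

The generator is RR-first: ground truth for HRV lives on the RR series,
so parameter-recovery targets have closed forms, and the ECG waveform
(stereotyped Gaussian P-QRS-T templates plus white noise) exists only to
exercise the QRS detector. Defaults describe one night-scale recording:
40 min, 23 arousals with the etiology mix roughly proportional to the
published distribution (UOD and spontaneous arousals dominating), arousal
durations ~N(9.08, 5.95²) s clipped to [4, 20], baseline 60 bpm with
SDNN 50 ms, an 8 bpm intra-arousal surge with SDNN 70 ms starting at
onset and lasting 15 s, 20% REM epochs, probability plateaus 0.05/0.8
with a unique 0.95 peak second and Gaussian noise (SD 0.05) truncated to
[0, 1], and 15% of UOD arousals reclassifiable (most published UODs
remained UOD after the secondary search). Arousal onsets and durations
are integer seconds so that zero-noise probability traces binarize back
to the true intervals exactly.

Not emulated: realistic PQRST morphology, ectopy, respiration or SpO2
waveforms, stage-dependent autonomic tone, inter-subject variability, or
correlated detector errors. Passing tests therefore demonstrate that the
*pipeline* is correct and well-calibrated under its stated assumptions —
not that a particular detector model performs well on clinical ECG.

### Surge recovery and window attenuation

The 15-s surge only partly overlaps the 25-s intra window, so the raw
intra-minus-pre heart-rate difference understates the programmed surge
(≈ 4.9 of 8 bpm at the defaults). `estimate_hr_surge` inverts the
mixture: with `T_s` seconds of surge in the window, the window holds
`T_s/RR_s + (25 − T_s)/RR_b` beats, which given the measured intra and
pre mean RR solves for the surge RR per event; averaging over events
recovers the programmed amplitude to within a few percent. The same
mixing *inflates* intra SDNN above the programmed 70 ms (between-regime
mean separation adds variance); the directional claims the tests make
(intra > pre, intra > post) are unaffected.

## Problem sizes

The bundled studies run at desk scale: the detector-accuracy check uses
one 10-min recording at 256 Hz with noise SD at 10% of the R amplitude;
the surge-recovery cohort uses 14 recordings (322 analyzed arousals) with
ground-truth R peaks feeding the pipeline downstream of QRS detection,
so the statistical machinery is exercised on hundreds of events while the
detector is validated separately; the null study repeats a 4-recording,
no-surge cohort over 50 seeds and counts replicates with any significant
pre-vs-intra row (expected ≈ 0 under the ×200 adjustment).

## Known limitations

- The EDF writer is minimal (single channel, 1-s records, 16-bit): a
  write/read cycle is idempotent but quantized, so round-trips are exact
  only after the first quantization pass.
- Desaturation depth is carried for provenance and never thresholded;
  linkage of desaturations to arousals is purely temporal.
- The ROC is computed on the per-second grid; sub-second arousal onsets
  are ceiling-mapped onto seconds when building labels.
- With `gap_rule="drop"` (the alternative reading of the 11-s rule) the
  later of two close events is discarded instead of merged; the default
  merges, since two arousals separated by ≤ 11 s cannot both satisfy the
  10-s-of-intervening-sleep scoring requirement.
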