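# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic benchmarks demonstrate.

## Signal model of the synthetic generator

The generator's job is to produce paired ECG/PPG recordings whose beat
structure, ictal dynamics and contamination are fully known, so every stage
of the extraction and detection chain can be scored against ground truth.
It is a fiducial-level simulator, not a physiological model.

**Rate trajectory.** The programmed heart rate is a constant baseline plus,
per seizure event, a response that rises (or falls) linearly to
`delta_hr` bpm over `ramp_time` seconds, holds until the later of ramp end
and seizure offset, and then relaxes back exponentially with time constant
`recovery_tau` (default 60 s — post-ictal recovery is visible in clinical
traces but not parameterised anywhere, so the constant is a package
choice). Responses come in three kinds, mirroring the clinical spectrum:
`increase` (the common, detectable case — ictal tachycardia), `decrease`,
and `none`. The 20 bpm detector threshold makes increases below that
magnitude undetectable by design.

**Beats.** Beats are laid down sequentially: at each beat the instantaneous
rate is the trajectory value plus an independent Gaussian perturbation of
SD `hr_jitter_sd` bpm (default 2 bpm, a quiet resting sinus arrhythmia),
clamped to the 30–220 bpm physiological band; the next beat follows after
60/rate seconds. Independent per-interval jitter was chosen over an AR
model because it directly controls the baseline-SD feature the classifier
consumes.

**Waveforms.** ECG beats are a narrow Gaussian R-wave (σ = 12 ms) with
small Q/S dips and P/T bumps; the R-wave dominates every other local
extremum ≥ 3×, so the beat fiducial is unambiguous. PPG pulses are
gamma-shaped, `p(τ) ∝ τ² e^(−τ/b)` with b = 60 ms: exactly zero before the
foot, an abrupt monotone upslope to a rounded peak at 120 ms, and a tail
that has decayed to ~2 % of peak by the next pulse at 100 bpm. The pulse
foot sits at beat time + `pulse_transit_delay` (default 0.25 s, a typical
wrist lag). The generator stores the analytic 50 %-crossing offset of the
template, so the PPG ground truth is the exact medium-amplitude-point time
per pulse.

**Artifacts.** Four kinds, each confined to declared intervals: 50 Hz
power-line and 12 Hz narrowband tones (amplitude relative to the clean
peak-to-peak), motion bursts (0.5–8 Hz band-limited noise scaled to a
relative peak-to-peak; the band overlaps the pulse-upslope band on
purpose), and dropouts (zeroed samples). No amplitude statistics for
real-device motion artifacts are available, so burst amplitude is a free,
documented parameter (cohort default 2× the clean peak-to-peak, enough to
bury the pulse but not always the rate — which matches the clinical
observation that detectors sometimes ride through, or even alarm because
of, motion).

**Determinism.** One integer seed drives a single PCG64 stream; cohort
sub-streams are spawned per patient via `SeedSequence`, so identical
(config, seed) gives bit-identical records.

## ECG beat detection

Constants the method needs but that are not fixed by its description, with
the package defaults:

| parameter | default | rationale |
|---|---|---|
| epoch length | 60 s | processing unit; threshold statistics per epoch |
| envelope window | 100 ms | QRS-scale: bridges intra-QRS oscillation, keeps F peaked |
| adaptive threshold | max(0.4 × P95(F), 3 × median(F)) | relative to the epoch's own F, hence amplitude-invariant and drift-robust |
| refractory | 250 ms | 240 bpm ceiling, standard Pan-Tompkins practice |
| refinement window | ±50 ms | R-wave search around an F peak |
| notch | second-order IIR, Q = 30, zero-phase | ≥ 20 dB at 50 Hz, < 1 dB in the 5–15 Hz QRS band |

Refinement takes the extremum of *largest absolute amplitude*, which makes
beat times invariant to lead inversion. Epoch boundaries are handled by
detecting on a 1 s context-padded slice and keeping only beats inside the
epoch proper, then deduplicating within the refractory across boundaries
(keep the earlier); without the padding, beats whose QRS straddles a
boundary can be lost to edge truncation in both epochs. Envelope edges use
truncated (not padded) windows — implemented via edge-replicating max/min
filters, which are provably identical for sliding extrema.

## PPG pulse detection

The FIR low-pass differentiator is a type-III (odd-length, antisymmetric)
equiripple design, ~fs/2 taps, passband edge 7 Hz, stopband 11 Hz — pulse
upslope energy lives below ~8 Hz — with taps rescaled so the passband gain
matches the true derivative 2πf; the group delay is an exact integer
number of samples and is removed by shifting, so no filter-induced fiducial
offset remains. The adaptive threshold is 0.5 × an exponentially weighted
mean (decay 0.125 ≈ the last 8 peaks) of accepted upslope-peak heights,
initialised from the 90th percentile of the first 10 s and re-initialised
from the trailing 3 s after 3 s without detections — this is what lets
detection resume after an amplitude step or a motion burst. The threshold
is applied to the positive filtered signal, since upslopes are
positive-derivative events. Foot and maximum are searched within 400 ms of
the upslope peak (refractory 300 ms, a 200 bpm ceiling); pulses missing
either landmark (e.g. truncated at the record edge) are discarded. The
medium-amplitude point is linearly interpolated between the bracketing
samples of the 50 % level; with multiple crossings the earliest is taken.
All fiducial times are invariant to positive amplitude scaling.

## Detector

The rule stage is necessarily this package's own definition (the original
rule set is not restated anywhere public); every constant is configurable:
rise ≥ 20 bpm over the baseline, completing within 60 s, sustained ≥ 10 s,
60 s event refractory, median filter of 5 samples. Two choices deserve
explanation:

* **Delayed baseline.** The baseline at time t is the mean rate over
  [t − 120 s, t − 60 s) — the 60 s window that ended where the fastest
  admissible ramp could have begun. Using the immediately trailing window
  would let the ramp contaminate its own baseline and raise the effective
  threshold well above 20 bpm for slower ramps.
* **Causal confirmation.** The event is confirmed at the first sample that
  is ≥ 10 s past the crossing and no longer above the running maximum; that
  sample is the alarm time and supplies HRpeak. Nothing after the alarm
  time is consulted, which gives the strict online property: truncating the
  rate series at any time and re-running reproduces exactly the alarms up
  to that time (with the causal median variant; the default centred median
  is for offline use).

Features are time-windowed on the unevenly sampled beat-time grid (no
resampling), with the population-SD convention; events with fewer than 5
baseline samples are discarded. The SVM uses z-standardised features, an
RBF kernel with the median-pairwise-distance width heuristic and C = 1;
the standardisation and width are stored in the model file, so scoring
round-trips bit-exactly. The shipped training cohort is synthetic: ictal
rises (22–45 bpm, quiet baseline) against exercise-like rises (20–32 bpm,
restless baseline with 5–9 bpm jitter), so the classes separate mainly on
baseline variability — a clean large rise is classified positive whether
or not it is ictal, which is the behaviour that produces false alarms
during light exercise in practice.

## Evaluation

Detection window [onset − 30 s, onset + 90 s], closed at both ends (the
conservative reading); an alarm eligible for two seizures goes to the
earlier one; each seizure claims its earliest unclaimed in-window alarm;
matched alarms are TP, all others FP, so TP + missed = seizures and
TP + FP = merged alarms on every recording. Zero-seizure patients
contribute FP/h but are excluded from sensitivity averaging. Percentages
and rates are rounded (half-up) only at presentation.

One caveat discovered in testing and worth stating precisely: the claim
that Se(τ) is non-increasing in the classifier threshold holds for alarm
streams whose spacing respects the detector's 60 s refractory (then the
1 min merge is a no-op and raising τ only removes alarms). For arbitrarily
dense alarm streams it can fail: removing a low-score alarm that had
absorbed a later alarm during merging can resurrect that alarm into a
detection window. The property tests therefore generate refractory-spaced
streams — the only kind the detector emits.

Missed-seizure attribution (decrease / no change / small increase / motion
/ interference) requires generator ground truth and is only defined on
synthetic data; the precedence is artifact-overlap first (motion bursts
and dropouts → MA, tones → Interf), then the programmed response, with
|Δ| < 5 bpm counted as "no change" and 0 < Δ < 20 bpm as "small increase".
FP coincidence between modalities uses a ±60 s tolerance by default — the
same constant as alarm merging; the tolerance is not fixed by any external
source and is configurable.

## File formats

ECG is written as single-channel 16-bit EDF (physical unit mV, 1 s data
records, final record zero-padded) by a minimal writer implemented here,
and read back through MNE — the independent reader doubles as a check on
the writer; round-trip error is bounded by one 16-bit quantisation step.
PPG uses the Empatica export dialect (row 1 start epoch, row 2 sampling
rate, one sample per row). Rates, alarms and annotations are two-column
CSV; ground truth and reports are JSON. Recording-system clock offsets are
user-supplied; alignment crops all modalities to their common span and
subtracts declared interruptions from the evaluated duration, so every
system is scored on the same data.

## Benchmark problem sizes

The shipped benchmarks use desk-scale cohorts: 10 clean 300 s records for
fiducial recovery, two 20-record 600 s cohorts (clean and PPG-motion) for
end-to-end behaviour, and a 420 s-record training cohort of 40 + 40 events.
These sizes give stable statistics (≥ 3 500 beats per recovery suite, 20
seizures per cohort) while keeping the full suite in the tens of seconds.

## What passing tests do and do not show

The synthetic benchmarks demonstrate internal correctness: the extractors
recover known fiducials (≥ 99 % ECG within ±10 ms, ≥ 98 % PPG within
±30 ms on clean signals), the detector recovers programmed +30 bpm
seizures with essentially no false alarms under quiet baselines, and
motion bursts over the PPG seizure windows reproduce the direction of the
central clinical finding (PPG sensitivity drops below ECG). They do not
demonstrate clinical performance: real ECG morphology varies (ectopy,
conduction abnormalities, electrode artifacts), real PPG motion artifacts
are structured rather than band-limited noise, real baselines drift with
posture and sleep state, and the substitute classifier is trained on
synthetic features, not the original patient cohort. The published
clinical aggregates bundled in `ictalhr.published` are reproduced as
arithmetic consistency checks of the evaluation module, not as a
re-analysis of the (non-public) recordings.

## Known limitations

* No ectopic beats, respiration coupling or baseline wander in the
  generator; no accelerometer-aided artifact removal.
* The EDF writer supports exactly one channel and integer sampling rates.
* The PPG chain consumes a single exported channel; proprietary multi-LED
  fusion is out of scope.
* Patient-adaptive thresholds and classifiers are out of scope.
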