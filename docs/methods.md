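# Methods

This note documents the models, parameters and design decisions behind
`endostress`: what the pipeline computes, what the synthetic-data generator
does and does not emulate, and the numerical choices that were genuinely
open.

## The measurement model

Procedural stress is read from four autonomic channels recorded at
2,048 Hz: facial EMG at two sites (corrugator supercilii — negative
affect; zygomaticus major — the headline stress feature in this setting),
ECG, skin conductance level, and fingertip temperature. The analysis
reduces each session to one scalar per channel per procedure time point
(start of examination, cecum reached, end of examination), then compares
the two study arms nonparametrically. Nothing in the pipeline estimates a
latent "stress" construct; the features are physical window means (µV, µS,
°C) and beats/min.

## Conditioning chains

All channels are decimated 2,048 → 512 Hz first (anti-alias Butterworth
low-pass at 0.8 × the target Nyquist, then every 4th sample; decimation
precedes all conditioning). Per modality:

* **fEMG** — band-pass 20–250 Hz, Hilbert magnitude, low-pass 4 Hz. The
  Hilbert magnitude of a narrowband oscillation is its instantaneous
  amplitude; the 4 Hz low-pass leaves the slow envelope whose window mean
  is the feature.
* **SCL** — low-pass 8 Hz.
* **ECG** — n = 67 centred moving average plus linear detrend, kept as the
  display/inspection trace. R-peak detection deliberately runs on the
  *unsmoothed* 512 Hz ECG: a 131 ms moving average would blunt exactly the
  QRS energy an energy-based detector needs. This is an interpretation —
  the source analysis lists the smoothing among the processing steps
  without saying which trace fed the detector.
* **TMP** — n = 513 centred moving average.

Open numerical choices, fixed as follows:

* Filter order was unstated → order 4, applied forward–backward
  (zero-phase, effective order 8). Zero phase matters because windows are
  event-anchored: group delay would shift features relative to the marks.
  The realised amplitude response is therefore the squared one-pass
  Butterworth magnitude, and the test-suite oracle checks measured
  sinusoid gains against exactly that.
* Moving-average alignment unstated → centred, window shrinking at the
  edges (length-preserving, no delay, constants pass through).
* "Detrended" unstated → least-squares straight line, the standard
  reading for short records.
* Hilbert edge effects: the first/last second of a conditioned channel is
  unreliable; all analysis windows are interior by construction (event
  marks at least 2 s inside the recording).

## QRS detection

Hamilton–Tompkins energy scheme: band-pass 8–16 Hz (order 2, zero-phase),
derivative, rectification, 80 ms moving-window integration; candidate
peaks are integrated-energy maxima at 200 ms minimum spacing (the spacing
also suppresses band-pass ringing sidelobes next to a QRS burst);
adaptive threshold = noise + 0.3125 × (signal − noise), with signal/noise
levels the running means of the last eight peaks of each class; a
search-back pass rescues a beat when the gap since the last accepted QRS
exceeds 1.5 × the running RR mean, at half the threshold; accepted peaks
are refined to the local raw-signal maximum within ±40 ms. All constants
are module-level and surfaced in the config. Thresholds are derived from
the data only, so detection is exactly invariant under positive rescaling.

Window heart rate is 60 × (number of complete RR intervals inside the
window) / (their total duration); fewer than two peaks in a window yields
a missing value.

## Windows and screening

Windows are half-open, 0-based sample ranges, 60 × fs samples exactly:
start → [t₀, t₀+60), cecum → [t_c−30, t_c+30), end → [t_end−60, t_end);
marks in seconds are floored to the sample grid. A session without a cecum
mark (failed cecal intubation) simply contributes no cecum windows.

The study screened artifacts visually; reproducibility requires an
automated surrogate, so explicit criteria are applied to the *raw
decimated* excerpt (artifacts live in the recorded signal; screening after
conditioning would let filters smear them):

* discard when > 5 % of samples sit at the channel rails (rails estimated
  as the 0.1/99.9 % channel quantiles — robust to anti-alias ringing
  around clipped segments — with "at the rail" meaning within 0.25 % of
  the channel range: clipped samples land essentially exactly on the rail,
  whereas a quiet baseline that happens to be a channel's minimum, as for
  tonic skin conductance, stays well clear of that band), when the excerpt
  is flat, or when > 10 % of samples fall outside
  median ± 8 × 1.4826 × MAD of the whole channel;
* correct isolated spikes (< 0.5 % of samples outside the robust bound)
  by linear interpolation — the repaired samples are written back before
  conditioning so features see the corrected data;
* otherwise keep.

ECG and SCL are exempt from the outlier/spike rules: QRS complexes and
phasic skin-conductance responses are legitimate fast transients, not
artifacts (saturation and flatness still apply). On long channels the
order statistics are estimated from a uniform stride-4 subsample — the
same quantities at a quarter of the sort cost.

## Group statistics

The primary comparison is a one-sided Mann–Whitney U test per
(channel, anchor) cell, stratified all / female / male. Directions are
declared a priori per feature — music lower for fEMG, SCL and BPM (the
stress-reduction hypothesis), music *higher* for TMP (peripheral
vasodilation under relaxation) — and never inferred from the data. The
exact U distribution is used when the combined sample size is ≤ 12 with no
ties; otherwise the normal approximation with tie and continuity
corrections. Significance is flagged at one-sided p ≤ 0.05 with no
multiple-testing adjustment (a Holm option exists, off by default),
mirroring the analysis being reproduced. Cohort characteristics use plain
Pearson χ² without continuity correction — this choice reproduces the
published sex / outpatient / abdominal-surgery p-values (0.886, 0.646,
0.489) from their printed counts, with "no information" rows excluded —
plus Fisher's exact test and Student's/Welch's t where appropriate.

## The synthetic-session generator

What it emulates, and the defaults (all on `SessionSpec`/`CohortSpec`):

* **fEMG** — zero-mean Gaussian noise band-limited to 20–250 Hz (the
  analysis band, so the conditioning chain is an unbiased demodulator and
  envelope recovery is an exact oracle), multiplied by a smooth positive
  envelope. The envelope is parameterised on the *rectified-envelope
  scale* — the quantity the pipeline reports in µV — by exploiting that
  the analytic magnitude of unit-variance Gaussian noise is Rayleigh with
  mean √(π/2): the carrier is scaled by envelope/√(π/2). The envelope is
  constant over each analysis window (so the window mean equals the
  segment value exactly) with linear ramps between windows; the
  within-session time course between anchors is otherwise unknown, so
  linear interpolation is an explicit assumption. Default segment means
  are the study's control-arm values (corrugator 8.15/6.86/7.23 µV,
  zygomaticus 7.70/4.82/5.17 µV) with the published between-patient SDs.
* **ECG** — a P-QRS-T template (sum of Gaussian bumps, 1 mV R amplitude,
  0.1 mV noise) at RR = 60/bpm plus Gaussian jitter, resampled below the
  0.25 s floor; exact R times returned. An optional 0.3 Hz baseline-wander
  sinusoid exercises detector robustness. Default 70 bpm, 30 ms jitter.
* **SCL** — tonic level (2 µS) plus Poisson-arriving phasic responses
  (4/min; rise τ 0.7 s, decay τ 3 s, amplitudes 0.1–0.5 µS) plus 0.01 µS
  noise, clipped at zero.
* **TMP** — baseline 32 °C + linear drift (0.05 °C/min) + slow noise
  (0.05 °C knots at 1 s, linearly interpolated).
* **Cohorts** — per-patient parameters are drawn around the base spec:
  fEMG segment means from normals truncated at zero (envelope means are
  positive) with the published between-patient SDs, heart rate ±8 bpm,
  tonic SCL ±0.8 µS, baseline TMP ±0.8 °C; sexes assigned 50/50. The music
  arm multiplies the fEMG envelope means by `music_femg_scale` (scalar or
  per-anchor). Missingness is emulated by injecting rail-to-rail
  saturation into flagged windows (probability `missing_window_prob` per
  channel × anchor) rather than deleting data, so the QC screener is
  exercised; the whole channel is then clipped to the rails as a real ADC
  would. Everything derives from one seed via spawned generator streams,
  so cohorts are bit-reproducible.

What it does **not** emulate: realistic ECG morphology variation
(arrhythmia, ectopy), sedation pharmacology, movement/electrode artifacts
other than saturation and spikes, any coupling between channels, or
non-stationarity beyond the segment-level envelope course. Passing tests
therefore demonstrate that the *pipeline* is correct and calibrated under
the stated statistical structure — not that real recordings satisfy that
structure.

## Monte-Carlo checks and problem sizes

* **Null calibration** — 200 cohorts of 30+30 with no group effect are run
  through the complete signal-level pipeline (generation → decimation →
  QC → conditioning → windowing → features → one-sided U tests); the
  pooled rejection rate at α = 0.05 must lie in [0.02, 0.09]. Calibration
  sessions are generated directly at 512 Hz and kept minimal — 126 s with
  the start and end anchors only — since the test's level depends on
  neither session length nor anchor count; cecum-window handling is
  covered by its own tests.
* **Power** — at the study's zygomaticus start-anchor conditions
  (7.70 ± 5.56 µV vs 4.82 ± 3.33 µV, n = 65/84) per-patient window means
  are drawn from the generator's truncated-normal between-patient model
  and U-tested, 200 replicates. This feature-level shortcut is justified
  by the conditioning oracles: the signal chain recovers per-patient
  envelope means with < 1 % mean relative error (measured over 50
  sessions), so signal-level simulation would add cost, not information.
* **QRS oracle** — 100 sessions spanning 45–120 bpm with jitter and
  2 mV wander on every third session; F1 against generator truth at 75 ms
  matching tolerance, plus BPM error on clean sessions.

## Known limitations

* The automated QC thresholds are stand-ins for the original visual
  screening; per-cell Ns of the in-vivo tables are not reproducible and
  missingness is a free simulation parameter.
* The two-sided Fisher test ("sum of no-more-probable tables") and
  Pearson χ² can disagree by ~0.1 in p even for well-filled tables; the
  tests assert close agreement on average, not tablewise.
* The in-vivo group means and p-values of the physiological comparisons
  require the original recordings; the Monte-Carlo calibration and power
  checks are their desk-scale surrogates.
* EDF reading is a thin optional wrapper (`mne`) and is not exercised by
  fixtures, since the interchange format for all tested paths is CSV.
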