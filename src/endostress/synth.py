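"""Synthetic colonoscopy-session generator.

Emulates the statistical structure the downstream analysis assumes, with
ground truth attached so every stage can be tested against a known answer:

* facial EMG — band-limited (20–250 Hz) Gaussian noise amplitude-modulated
  by a smooth positive envelope. The envelope is parameterised on the
  *rectified-envelope scale*: the value the conditioning chain (band-pass,
  Hilbert magnitude, 4 Hz low-pass) recovers as the window mean, i.e. the
  quantity reported in uV in the study tables. Segment values are held on
  plateaus covering each analysis window with linear ramps in between, so
  the window mean equals the specified segment mean exactly.
* ECG — a concatenated P-QRS-T beat template (sum of Gaussian bumps,
  1 mV R amplitude) with Gaussian beat-to-beat jitter on the RR interval,
  optional 0.3 Hz baseline wander, and the exact R-peak times returned.
* skin conductance — tonic level plus Poisson-arriving phasic responses
  (fast rise, exponential decay) plus low-amplitude noise, never negative.
* finger temperature — baseline plus linear drift plus slow smoothed noise.

Cohorts draw per-patient parameters (fEMG segment means, heart rate, tonic
SCL, baseline temperature) from between-patient distributions; the music
arm scales the fEMG envelope means by a configurable factor. Everything is
reproducible bit-for-bit from the cohort seed. Flagged windows receive
rail-to-rail saturation artifacts so the QC screener is exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .conditioning import butter_sos
from .signals import ANCHORS, CHANNEL_UNITS, EventMarks, Recording, Signal

#: E|analytic signal| of unit-variance Gaussian noise (Rayleigh mean).
RAYLEIGH_MEAN = math.sqrt(math.pi / 2.0)

#: Ratio by which the rail level exceeds the clean channel's peak amplitude.
SATURATION_RAIL_FACTOR = 1.5

#: Fraction of a flagged window driven to the rails.
SATURATION_FRACTION = 0.30

FEMG_SITES = ("corrugator", "zygomaticus")

# Study-scale defaults for the fEMG envelope, uV, per (start, cecum, end)
# segment: control-arm group means of the two recording sites.
DEFAULT_FEMG_MEANS = {
    "corrugator": (8.15, 6.86, 7.23),
    "zygomaticus": (7.70, 4.82, 5.17),
}
DEFAULT_FEMG_SDS = {
    "corrugator": (7.72, 5.46, 5.87),
    "zygomaticus": (5.56, 3.42, 3.80),
}


def default_anchors(duration_s: float) -> EventMarks:
    """Plausible event marks for a session of the given length: start and
    end anchors just inside the recording, cecum midway when its window
    fits between the other two."""
    margin = 2.0 if duration_s < 300 else 30.0
    t0 = margin
    te = duration_s - margin
    mid = (t0 + te) / 2.0
    has_room = (mid - 30.0 >= t0 + 60.0) and (mid + 30.0 <= te - 60.0)
    return EventMarks(t0, te, cecum=mid if has_room else None)


def _as_triple(x) -> tuple:
    """Broadcast a scalar to a per-anchor (start, cecum, end) triple."""
    if np.isscalar(x):
        return (float(x),) * 3
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected scalar or length-3 per-anchor value, got {x!r}")
    return t


@dataclass
class SessionSpec:
    """Ground-truth parameters for one simulated session."""

    duration_s: float = 600.0
    fs: float = 2048.0
    anchors: EventMarks = field(default_factory=lambda: EventMarks(60.0, 540.0, cecum=300.0))
    femg_envelope_mean: dict = field(default_factory=lambda: {k: v for k, v in DEFAULT_FEMG_MEANS.items()})
    femg_envelope_sd: dict = field(default_factory=lambda: {k: v for k, v in DEFAULT_FEMG_SDS.items()})
    ecg_mean_bpm: float = 70.0
    ecg_rr_jitter_sd: float = 0.03
    ecg_noise_sd_mv: float = 0.1
    ecg_baseline_wander_mv: float = 0.0  # 0.3 Hz sinusoid amplitude; 0 disables
    scl_tonic: float = 2.0
    scl_scr_rate: float = 4.0  # phasic responses per minute
    scl_noise_sd: float = 0.01
    tmp_baseline: float = 32.0
    tmp_drift: float = 0.05  # degC per minute
    tmp_noise_sd: float = 0.05
    missing_window_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s < 120:
            raise ValueError("session duration must be >= 120 s")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        m = self.anchors
        marks = [m.exam_start] + ([m.cecum] if m.cecum is not None else []) + [m.exam_end]
        if any(b - a < 60 for a, b in zip(marks, marks[1:])):
            raise ValueError("event anchors must be >= 60 s apart")
        m.validate_within(self.duration_s)
        self.femg_envelope_mean = {s: _as_triple(v) for s, v in self.femg_envelope_mean.items()}
        self.femg_envelope_sd = {s: _as_triple(v) for s, v in self.femg_envelope_sd.items()}
        for d, what in ((self.femg_envelope_mean, "mean"), (self.femg_envelope_sd, "sd")):
            for site, vals in d.items():
                if site not in FEMG_SITES:
                    raise ValueError(f"unknown fEMG site {site!r}")
                if what == "sd" and any(v < 0 for v in vals):
                    raise ValueError("envelope SDs must be >= 0")
                if what == "mean" and any(v < 0 for v in vals):
                    raise ValueError("envelope means must be >= 0")
        if not 30 <= self.ecg_mean_bpm <= 200:
            raise ValueError(f"mean heart rate {self.ecg_mean_bpm} bpm outside [30, 200]")
        for name in ("ecg_rr_jitter_sd", "ecg_noise_sd_mv", "scl_noise_sd", "tmp_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.scl_tonic < 0:
            raise ValueError("tonic skin conductance must be >= 0 uS")
        if self.scl_scr_rate < 0:
            raise ValueError("phasic response rate must be >= 0 per minute")
        if not 20 <= self.tmp_baseline <= 40:
            raise ValueError("baseline temperature must lie in [20, 40] degC")
        if not 0 <= self.missing_window_prob <= 1:
            raise ValueError("missing_window_prob must lie in [0, 1]")

    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class CohortSpec:
    """A two-arm cohort: shared base session plus the music-arm fEMG effect."""

    n_control: int = 98
    n_music: int = 98
    base: SessionSpec = field(default_factory=SessionSpec)
    music_femg_scale: object = 1.0  # scalar or per-anchor (start, cecum, end) triple, > 0
    bpm_between_sd: float = 8.0
    scl_between_sd: float = 0.8
    tmp_between_sd: float = 0.8
    cecum_missing_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_music < 1:
            raise ValueError("each arm needs at least one patient")
        self.music_femg_scale = _as_triple(self.music_femg_scale)
        if any(v <= 0 for v in self.music_femg_scale):
            raise ValueError("music_femg_scale must be > 0")
        for name in ("bpm_between_sd", "scl_between_sd", "tmp_between_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.cecum_missing_prob <= 1:
            raise ValueError("cecum_missing_prob must lie in [0, 1]")


@dataclass
class SimulatedSession:
    """One generated session with its ground truth."""

    recording: Recording
    marks: EventMarks
    truth: dict  # envelopes per site, r_peak times, corrupted (channel, anchor) flags


# ---------------------------------------------------------------------------
# Envelope construction


def _window_spans(marks: EventMarks) -> dict:
    spans = {"start": (marks.exam_start, marks.exam_start + 60.0),
             "end": (marks.exam_end - 60.0, marks.exam_end)}
    if marks.cecum is not None:
        spans["cecum"] = (marks.cecum - 30.0, marks.cecum + 30.0)
    return spans


def envelope_trace(spec: SessionSpec, site: str) -> np.ndarray:
    """Ground-truth rectified-scale envelope: constant over each analysis
    window (so the window mean equals the segment value exactly), linear
    ramps across the gaps between windows, held flat outside."""
    means = spec.femg_envelope_mean[site]
    spans = _window_spans(spec.anchors)
    segments = sorted((spans[a], v) for a, v in zip(ANCHORS, means) if a in spans)
    n = spec.n_samples()
    fs = spec.fs
    env = np.empty(n)
    first_a = int(segments[0][0][0] * fs)
    env[:first_a] = segments[0][1]
    for k, ((a_s, b_s), value) in enumerate(segments):
        a, b = int(a_s * fs), min(int(b_s * fs), n)
        env[a:b] = value
        if k + 1 < len(segments):  # ramp across the gap to the next plateau
            nxt_a = int(segments[k + 1][0][0] * fs)
            nxt_v = segments[k + 1][1]
            if nxt_a > b:
                env[b:nxt_a] = np.linspace(value, nxt_v, nxt_a - b, endpoint=False)
        else:
            env[b:] = value
    return env


# ---------------------------------------------------------------------------
# Channel synthesizers


def synth_femg(spec: SessionSpec, site: str, rng: np.random.Generator):
    """Synthesize one fEMG channel.

    Returns ``(Signal, envelope)`` where ``envelope`` is the ground-truth
    rectified-scale amplitude trace in uV. The carrier is zero-mean Gaussian
    noise band-limited to 20–250 Hz and scaled so that the Hilbert-magnitude
    demodulator recovers the envelope (unit-variance Gaussian noise has a
    Rayleigh-distributed analytic magnitude with mean sqrt(pi/2)).
    """
    if site not in FEMG_SITES:
        raise ValueError(f"unknown fEMG site {site!r}")
    if spec.fs < 512:
        raise ValueError(f"fs {spec.fs} Hz cannot carry the 20-250 Hz band")
    env = envelope_trace(spec, site)
    n = spec.n_samples()
    if np.all(env == 0):
        samples = np.zeros(n)
    else:
        white = rng.standard_normal(n)
        sos = butter_sos(4, (20.0, 250.0), "bandpass", float(spec.fs))
        carrier = sps.sosfiltfilt(sos, white)
        carrier /= carrier.std()
        samples = (env / RAYLEIGH_MEAN) * carrier
    sig = Signal(samples, spec.fs, unit="uV", channel=f"femg_{site}")
    return sig, env


def _beat_template(fs: float) -> tuple[np.ndarray, int]:
    """P-QRS-T beat as a sum of Gaussian bumps; returns (template, r_index)."""
    t = np.arange(-0.30, 0.45, 1.0 / fs)
    bumps = [(-0.20, 0.15, 0.040),   # P
             (-0.025, -0.15, 0.010), # Q
             (0.0, 1.00, 0.012),     # R
             (0.028, -0.25, 0.010),  # S
             (0.22, 0.30, 0.050)]    # T
    wave = np.zeros_like(t)
    for mu, amp, width in bumps:
        wave += amp * np.exp(-0.5 * ((t - mu) / width) ** 2)
    return wave, int(np.argmin(np.abs(t)))


def synth_ecg(spec: SessionSpec, rng: np.random.Generator):
    """Synthesize the ECG channel; returns ``(Signal, r_peak_times_s)``.

    RR intervals are 60/bpm plus Gaussian jitter, resampled whenever they
    fall below the 0.25 s floor so non-positive intervals are never emitted.
    """
    if not 30 <= spec.ecg_mean_bpm <= 200:
        raise ValueError(f"mean heart rate {spec.ecg_mean_bpm} bpm outside [30, 200]")
    n = spec.n_samples()
    mean_rr = 60.0 / spec.ecg_mean_bpm
    beat_times = []
    t = 0.5  # first beat
    while t < spec.duration_s - 0.5:
        beat_times.append(t)
        rr = mean_rr + spec.ecg_rr_jitter_sd * rng.standard_normal()
        while rr < 0.25:
            rr = mean_rr + spec.ecg_rr_jitter_sd * rng.standard_normal()
        t += rr
    template, r_idx = _beat_template(spec.fs)
    samples = np.zeros(n)
    for bt in beat_times:
        start = int(round(bt * spec.fs)) - r_idx
        a, b = max(start, 0), min(start + template.size, n)
        if a < b:
            samples[a:b] += template[a - start: b - start]
    if spec.ecg_noise_sd_mv > 0:
        samples = samples + spec.ecg_noise_sd_mv * rng.standard_normal(n)
    if spec.ecg_baseline_wander_mv > 0:
        tt = np.arange(n) / spec.fs
        samples = samples + spec.ecg_baseline_wander_mv * np.sin(
            2 * np.pi * 0.3 * tt + rng.uniform(0, 2 * np.pi))
    # snap ground truth to the sample grid the template was laid on
    r_times = np.array([round(bt * spec.fs) / spec.fs for bt in beat_times])
    return Signal(samples, spec.fs, unit="mV", channel="ecg"), r_times


def synth_scl(spec: SessionSpec, rng: np.random.Generator) -> Signal:
    """Tonic level + Poisson-arriving phasic responses + low-amplitude noise."""
    if spec.scl_tonic < 0:
        raise ValueError("tonic skin conductance must be >= 0 uS")
    n = spec.n_samples()
    samples = np.full(n, spec.scl_tonic)
    n_events = rng.poisson(spec.scl_scr_rate * spec.duration_s / 60.0)
    if n_events:
        # phasic response: fast rise (tau 0.7 s), exponential decay (tau 3 s)
        kt = np.arange(0, 10.0, 1.0 / spec.fs)
        kernel = np.exp(-kt / 3.0) - np.exp(-kt / 0.7)
        kernel /= kernel.max()
        for t0 in np.sort(rng.uniform(0, spec.duration_s, n_events)):
            amp = rng.uniform(0.1, 0.5)
            start = int(t0 * spec.fs)
            b = min(start + kernel.size, n)
            samples[start:b] += amp * kernel[: b - start]
    if spec.scl_noise_sd > 0:
        samples = samples + spec.scl_noise_sd * rng.standard_normal(n)
    return Signal(np.maximum(samples, 0.0), spec.fs, unit="uS", channel="scl")


def synth_tmp(spec: SessionSpec, rng: np.random.Generator) -> Signal:
    """Baseline + linear drift + slow noise (1 s knots, linearly interpolated)."""
    if not 20 <= spec.tmp_baseline <= 40:
        raise ValueError("baseline temperature must lie in [20, 40] degC")
    n = spec.n_samples()
    t = np.arange(n) / spec.fs
    samples = spec.tmp_baseline + spec.tmp_drift * t / 60.0
    if spec.tmp_noise_sd > 0:
        knots_t = np.arange(0, spec.duration_s + 1.0, 1.0)
        knots = spec.tmp_noise_sd * rng.standard_normal(knots_t.size)
        samples = samples + np.interp(t, knots_t, knots)
    return Signal(samples, spec.fs, unit="degC", channel="tmp")


# ---------------------------------------------------------------------------
# Sessions and cohorts


def _inject_saturation(sig: Signal, spans: dict, flagged: Sequence[tuple],
                       rng: np.random.Generator) -> Signal:
    """Drive a contiguous chunk of each flagged window to the rails.

    Rails sit at +/- SATURATION_RAIL_FACTOR x the clean channel's peak
    deviation from its median, emulating an amplifier hitting its limits;
    the whole channel is then clipped to the rails, as a real ADC would.
    """
    windows = [spans[a] for (ch, a) in flagged if ch == sig.channel and a in spans]
    if not windows:
        return sig
    x = sig.samples.copy()
    mid = float(np.median(x))
    half_range = float(np.max(np.abs(x - mid))) or 1.0
    lo = mid - SATURATION_RAIL_FACTOR * half_range
    hi = mid + SATURATION_RAIL_FACTOR * half_range
    for a_s, b_s in windows:
        a, b = int(a_s * sig.fs), int(b_s * sig.fs)
        span = b - a
        chunk = int(SATURATION_FRACTION * span)
        start = a + int(rng.integers(0, span - chunk))
        half = chunk // 2
        x[start:start + half] = hi
        x[start + half:start + chunk] = lo
    return sig.with_samples(np.clip(x, lo, hi))


def generate_session(spec: SessionSpec, rng: np.random.Generator,
                     patient_id: str = "P000", group: str = "control",
                     sex: str = "female",
                     corrupt: Sequence[tuple] = ()) -> SimulatedSession:
    """Generate one five-channel session with ground truth.

    ``corrupt`` lists (channel, anchor) windows to receive saturation
    artifacts; the QC screener is expected to discard them downstream.
    """
    envelopes = {}
    channels = {}
    for site in FEMG_SITES:
        sig, env = synth_femg(spec, site, rng)
        channels[sig.channel] = sig
        envelopes[site] = env
    ecg, r_times = synth_ecg(spec, rng)
    channels["ecg"] = ecg
    channels["scl"] = synth_scl(spec, rng)
    channels["tmp"] = synth_tmp(spec, rng)
    spans = _window_spans(spec.anchors)
    if corrupt:
        for name in list(channels):
            channels[name] = _inject_saturation(channels[name], spans, corrupt, rng)
    rec = Recording(channels, spec.fs, patient_id=patient_id, group=group, sex=sex)
    truth = {"envelopes": envelopes, "r_peak_times": r_times,
             "corrupt": tuple(corrupt), "spec": spec}
    return SimulatedSession(rec, spec.anchors, truth)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float = 0.0) -> float:
    """Draw from N(mean, sd) conditioned on exceeding ``lower`` (resampling)."""
    if sd == 0:
        return max(mean, lower)
    for _ in range(1000):
        x = mean + sd * rng.standard_normal()
        if x > lower:
            return float(x)
    return max(mean, lower)  # pathological spec; fall back to the mean


def patient_spec(base: SessionSpec, rng: np.random.Generator,
                 femg_scale: tuple = (1.0, 1.0, 1.0),
                 bpm_sd: float = 0.0, scl_sd: float = 0.0,
                 tmp_sd: float = 0.0, cecum_missing: bool = False) -> SessionSpec:
    """Draw one patient's session parameters around the cohort base spec."""
    means = {site: tuple(_truncated_normal(rng, m * s, sd, lower=0.05)
                         for m, s, sd in zip(base.femg_envelope_mean[site],
                                             femg_scale,
                                             base.femg_envelope_sd[site]))
             for site in base.femg_envelope_mean}
    anchors = base.anchors
    if cecum_missing and anchors.cecum is not None:
        anchors = EventMarks(anchors.exam_start, anchors.exam_end, cecum=None)
    return replace(
        base,
        anchors=anchors,
        femg_envelope_mean=means,
        ecg_mean_bpm=float(np.clip(base.ecg_mean_bpm + bpm_sd * rng.standard_normal(), 40, 150)),
        scl_tonic=_truncated_normal(rng, base.scl_tonic, scl_sd, lower=0.2),
        tmp_baseline=float(np.clip(base.tmp_baseline + tmp_sd * rng.standard_normal(), 20.5, 39.5)),
    )


def iter_cohort(cohort: CohortSpec):
    """Yield the two-arm cohort one session at a time (bit-reproducible
    from the seed); use this for large cohorts to keep memory flat."""
    n_total = cohort.n_control + cohort.n_music
    seq = np.random.SeedSequence(cohort.seed)
    meta_rng = np.random.Generator(np.random.PCG64(seq.spawn(1)[0]))
    session_seqs = seq.spawn(n_total + 1)[1:]
    spans = _window_spans(cohort.base.anchors)
    for i in range(n_total):
        is_music = i >= cohort.n_control
        group = "music" if is_music else "control"
        idx = (i - cohort.n_control if is_music else i) + 1
        pid = f"{'M' if is_music else 'C'}{idx:03d}"
        rng = np.random.Generator(np.random.PCG64(session_seqs[i]))
        scale = cohort.music_femg_scale if is_music else (1.0, 1.0, 1.0)
        cecum_missing = bool(meta_rng.random() < cohort.cecum_missing_prob)
        spec = patient_spec(cohort.base, rng, femg_scale=scale,
                            bpm_sd=cohort.bpm_between_sd,
                            scl_sd=cohort.scl_between_sd,
                            tmp_sd=cohort.tmp_between_sd,
                            cecum_missing=cecum_missing)
        corrupt = [(ch, a) for ch in CHANNEL_UNITS for a in spans
                   if meta_rng.random() < cohort.base.missing_window_prob]
        sex = "female" if meta_rng.random() < 0.5 else "male"
        yield generate_session(spec, rng, patient_id=pid, group=group,
                               sex=sex, corrupt=corrupt)


def generate_cohort(cohort: CohortSpec) -> list[SimulatedSession]:
    """Materialised :func:`iter_cohort` (fine for small cohorts and tests)."""
    return list(iter_cohort(cohort))
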