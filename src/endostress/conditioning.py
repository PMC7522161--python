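"""Per-modality signal conditioning chains.

All channels are first decimated from the acquisition rate (2,048 Hz) to
512 Hz, then conditioned per modality:

* facial EMG — Butterworth band-pass 20–250 Hz, Hilbert-magnitude
  demodulation, 4 Hz low-pass: a non-negative slow amplitude envelope in uV;
* skin conductance — 8 Hz low-pass;
* ECG — centred moving average (n = 67 samples) then linear detrend
  (retained for inspection; R-peak detection runs on the unsmoothed trace);
* skin temperature — centred moving average (n = 513 samples).

Filters are Butterworth order 4 applied forward–backward (zero phase), so
the realised amplitude response is the squared magnitude of the one-pass
design. All operations preserve length, sampling rate, and unit labels.
"""

from __future__ import annotations

from dataclasses import dataclass

from functools import lru_cache

import numpy as np
from scipy import signal as sps
from scipy.fft import irfft, next_fast_len, rfft

from .signals import Signal

#: Chain constants (defaults mirror the analysis pipeline).
FEMG_BAND_HZ = (20.0, 250.0)
FEMG_ENVELOPE_LOWPASS_HZ = 4.0
SCL_LOWPASS_HZ = 8.0
ECG_SMOOTH_N = 67
TMP_SMOOTH_N = 513
FILTER_ORDER = 4
TARGET_FS = 512.0
DECIMATE_GUARD = 0.8  # anti-alias corner at 0.8 x target Nyquist


@lru_cache(maxsize=64)
def butter_sos(order: int, corners_hz: tuple, btype: str, fs: float):
    """Cached Butterworth design in second-order sections."""
    nyq = fs / 2.0
    wn = [c / nyq for c in corners_hz]
    return sps.butter(order, wn if len(wn) > 1 else wn[0], btype=btype, output="sos")


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter: band-pass or low-pass, optionally zero-phase."""

    kind: str  # "bandpass" | "lowpass"
    corners_hz: tuple  # (low, high) for bandpass, (cut,) for lowpass
    order: int = FILTER_ORDER
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        corners = tuple(self.corners_hz)
        if self.kind == "bandpass":
            if len(corners) != 2 or not 0 < corners[0] < corners[1]:
                raise ValueError(f"bandpass needs 0 < low < high, got {corners}")
        elif len(corners) != 1 or corners[0] <= 0:
            raise ValueError(f"lowpass needs one positive corner, got {corners}")

    def sos(self, fs: float):
        nyq = fs / 2.0
        if max(self.corners_hz) >= nyq:
            raise ValueError(
                f"corner {max(self.corners_hz)} Hz >= Nyquist {nyq} Hz at fs={fs}"
            )
        return butter_sos(self.order, tuple(self.corners_hz), self.kind, float(fs))

    def gain(self, f_hz, fs: float):
        """Analytic amplitude response at ``f_hz`` (squared if zero-phase)."""
        w = 2 * np.pi * np.atleast_1d(np.asarray(f_hz, dtype=float)) / fs
        _, h = sps.sosfreqz(self.sos(fs), worN=w)
        g = np.abs(h)
        if self.zero_phase:
            g = g ** 2
        return g if np.ndim(f_hz) else float(g[0])


def apply_filter(s: Signal, spec: FilterSpec) -> Signal:
    """Filter a signal; zero-phase (filtfilt) by default. Length-preserving."""
    sos = spec.sos(s.fs)
    if spec.zero_phase:
        out = sps.sosfiltfilt(sos, s.samples)
    else:
        out = sps.sosfilt(sos, s.samples)
    return s.with_samples(out)


def decimate_signal(s: Signal, target_fs: float = TARGET_FS) -> Signal:
    """Downsample by an integer factor with an anti-alias low-pass first.

    The low-pass corner sits at ``DECIMATE_GUARD`` x the target Nyquist;
    every ``factor``-th sample is then kept, so the output has
    ``ceil(n / factor)`` samples.
    """
    if target_fs <= 0 or s.fs % target_fs != 0:
        raise ValueError(
            f"fs {s.fs} Hz is not an integer multiple of target {target_fs} Hz; "
            "decimation requires an integer factor"
        )
    factor = int(s.fs // target_fs)
    if factor == 1:
        return s.with_samples(s.samples.copy())
    aa = FilterSpec("lowpass", (DECIMATE_GUARD * target_fs / 2.0,))
    filtered = sps.sosfiltfilt(aa.sos(s.fs), s.samples)
    return s.with_samples(filtered[::factor], fs=target_fs)


def hilbert_envelope(s: Signal) -> Signal:
    """Magnitude of the analytic signal (amplitude demodulation).

    The first/last second is edge-affected; analysis windows are interior
    by construction so this is not corrected here.
    """
    if s.n < 2:
        raise ValueError("hilbert_envelope needs at least 2 samples")
    # |x + i*H(x)| with H(x) via real FFTs (cheaper than the complex-FFT
    # analytic signal, identical result up to rounding)
    nfft = next_fast_len(s.n)
    spectrum = rfft(s.samples, nfft)
    spectrum[1: (nfft + 1) // 2] *= -1j
    spectrum[0] = 0.0
    if nfft % 2 == 0:
        spectrum[-1] = 0.0
    quadrature = irfft(spectrum, nfft)[: s.n]
    return s.with_samples(np.hypot(s.samples, quadrature))


def moving_average(s: Signal, n: int) -> Signal:
    """Centred moving average; edge windows shrink, so constants pass through."""
    if n < 1:
        raise ValueError("moving-average window must be >= 1 sample")
    if n > s.n:
        raise ValueError(f"window n={n} exceeds signal length {s.n}")
    n = int(n)
    # sliding sums via cumulative sums: O(length), window centred with the
    # extra sample on the right for even n
    left, right = (n - 1) // 2, n // 2
    csum = np.concatenate(([0.0], np.cumsum(s.samples)))
    out = np.empty(s.n)
    out[left: s.n - right] = (csum[n:] - csum[:-n]) / n
    for i in range(min(left, s.n)):  # shrinking windows at the edges
        out[i] = csum[min(i + right + 1, s.n)] / min(i + right + 1, s.n)
    for i in range(max(s.n - right, 0), s.n):
        lo = max(i - left, 0)
        out[i] = (csum[s.n] - csum[lo]) / (s.n - lo)
    return s.with_samples(out)


def detrend_linear(s: Signal) -> Signal:
    """Remove the least-squares straight line (zero mean, zero slope after)."""
    if s.n < 2:
        raise ValueError("detrend needs at least 2 samples")
    return s.with_samples(sps.detrend(s.samples, type="linear"))


# ---------------------------------------------------------------------------
# Modality chains


def condition_femg(s: Signal,
                   band_hz: tuple = FEMG_BAND_HZ,
                   envelope_lowpass_hz: float = FEMG_ENVELOPE_LOWPASS_HZ,
                   order: int = FILTER_ORDER) -> Signal:
    """fEMG chain: band-pass, Hilbert magnitude, envelope low-pass.

    Yields the slow rectified-envelope trace in uV whose window means are
    the fEMG features. Requires fs >= 2 x the upper band edge.
    """
    if s.fs < 2 * band_hz[1]:
        raise ValueError(
            f"fs {s.fs} Hz cannot carry the {band_hz[1]} Hz band edge"
        )
    out = apply_filter(s, FilterSpec("bandpass", band_hz, order=order))
    out = hilbert_envelope(out)
    return apply_filter(out, FilterSpec("lowpass", (envelope_lowpass_hz,), order=order))


def condition_scl(s: Signal, lowpass_hz: float = SCL_LOWPASS_HZ,
                  order: int = FILTER_ORDER) -> Signal:
    """Skin-conductance chain: 8 Hz zero-phase low-pass."""
    return apply_filter(s, FilterSpec("lowpass", (lowpass_hz,), order=order))


def condition_ecg(s: Signal, n: int = ECG_SMOOTH_N) -> Signal:
    """ECG display chain: n=67 centred moving average, then linear detrend.

    Note: this heavy smoothing blunts QRS energy, so R-peak detection runs
    on the pre-smoothing 512 Hz trace (see :mod:`endostress.cardiac`).
    """
    return detrend_linear(moving_average(s, n))


def condition_tmp(s: Signal, n: int = TMP_SMOOTH_N) -> Signal:
    """Temperature chain: n=513 centred moving average."""
    return moving_average(s, n)


#: channel -> conditioning callable, applied after decimation to 512 Hz.
CONDITIONERS = {
    "femg_corrugator": condition_femg,
    "femg_zygomaticus": condition_femg,
    "ecg": condition_ecg,
    "scl": condition_scl,
    "tmp": condition_tmp,
}
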