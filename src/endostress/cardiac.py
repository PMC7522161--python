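"""R-peak detection (Hamilton–Tompkins) and heart-rate features.

The detector follows the classic energy-based scheme: band-pass the ECG to
the QRS band (8–16 Hz), differentiate, rectify, integrate over an 80 ms
moving window, then walk the integrated peaks with adaptive signal/noise
thresholds (running averages of the last eight peaks of each class), a
200 ms refractory period, and a search-back pass that rescues beats when
the gap since the last accepted QRS exceeds 1.5x the running RR average.
Accepted detections are refined to the local raw-signal maximum within
+/- 40 ms. Because every threshold is derived from the data, detection is
invariant to positive rescaling of the input.

Detection runs on the decimated (512 Hz) ECG *before* the n=67 moving
average of the display chain: that smoothing would blunt the QRS energy
the detector relies on.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .conditioning import butter_sos
from .signals import Signal

REFRACTORY_S = 0.200
QRS_BAND_HZ = (8.0, 16.0)
INTEGRATION_S = 0.080
THRESHOLD_COEF = 0.3125     # detection threshold sits this far from noise toward signal
SEARCHBACK_RR_FACTOR = 1.5  # trigger search-back beyond this multiple of mean RR
SEARCHBACK_THRESHOLD = 0.5  # fraction of the threshold accepted during search-back
REFINE_S = 0.040            # half-width for raw-peak refinement
MIN_DURATION_S = 5.0


@dataclass
class PeakTrain:
    """Detected R-peak times, strictly increasing, refractory-separated."""

    peak_times: np.ndarray  # seconds from recording start
    fs: float
    source_channel: str = "ecg"

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=np.float64)
        if self.peak_times.size > 1:
            gaps = np.diff(self.peak_times)
            if np.any(gaps <= 0):
                raise ValueError("peak times must be strictly increasing")
            if np.any(gaps < REFRACTORY_S - 1e-9):
                raise ValueError(f"peaks closer than the {REFRACTORY_S*1e3:.0f} ms refractory period")

    @property
    def n(self) -> int:
        return self.peak_times.size

    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.peak_times)


def _integrated_energy(x: np.ndarray, fs: float) -> np.ndarray:
    sos = butter_sos(2, QRS_BAND_HZ, "bandpass", float(fs))
    filtered = sps.sosfiltfilt(sos, x)
    rectified = np.abs(np.gradient(filtered))
    n_int = max(int(round(INTEGRATION_S * fs)), 1)
    return np.convolve(rectified, np.ones(n_int) / n_int, mode="same")


def detect_r_peaks(s: Signal) -> PeakTrain:
    """Detect R-peaks in a (decimated, unsmoothed) ECG signal."""
    if s.duration_s < MIN_DURATION_S:
        raise ValueError(f"ECG shorter than {MIN_DURATION_S} s cannot be analysed")
    x = s.samples
    if np.ptp(x) == 0:
        return PeakTrain(np.empty(0), s.fs, s.channel or "ecg")

    fs = s.fs
    energy = _integrated_energy(x, fs)
    # candidate peaks at refractory spacing: keeps the largest peak when the
    # band-pass ringing puts sidelobes next to a QRS burst
    cand_idx, _ = sps.find_peaks(energy, distance=max(int(REFRACTORY_S * fs), 1))
    if cand_idx.size == 0:
        return PeakTrain(np.empty(0), s.fs, s.channel or "ecg")
    cand_amp = energy[cand_idx]

    # threshold state: running averages over the last 8 peaks of each class
    init = energy[: int(2 * fs)]
    qrs_peaks: deque = deque([float(init.max())], maxlen=8)
    noise_peaks: deque = deque([float(np.median(init))], maxlen=8)
    rr_hist: deque = deque(maxlen=8)

    def threshold() -> float:
        nq = sum(noise_peaks) / len(noise_peaks)
        return nq + THRESHOLD_COEF * (sum(qrs_peaks) / len(qrs_peaks) - nq)

    accepted: list[int] = []
    rejected: list[int] = []  # candidate positions (indices into cand_idx)

    def accept(ci: int) -> None:
        idx = int(cand_idx[ci])
        if accepted:
            rr_hist.append((idx - accepted[-1]) / fs)
        accepted.append(idx)
        qrs_peaks.append(float(cand_amp[ci]))

    for ci in range(cand_idx.size):
        idx = int(cand_idx[ci])
        if accepted and (idx - accepted[-1]) / fs < REFRACTORY_S:
            continue
        if cand_amp[ci] > threshold():
            accept(ci)
        else:
            noise_peaks.append(float(cand_amp[ci]))
            rejected.append(ci)
        # search-back: gap since the last QRS grew past 1.5x the mean RR
        if accepted and len(rr_hist) >= 2:
            mean_rr = sum(rr_hist) / len(rr_hist)
            if (idx - accepted[-1]) / fs > SEARCHBACK_RR_FACTOR * mean_rr:
                window = [cj for cj in rejected
                          if accepted[-1] < cand_idx[cj] < idx
                          and (cand_idx[cj] - accepted[-1]) / fs >= REFRACTORY_S]
                if window:
                    best = max(window, key=lambda cj: cand_amp[cj])
                    if cand_amp[best] > SEARCHBACK_THRESHOLD * threshold():
                        # splice the rescued beat in (it precedes the cursor)
                        idx_b = int(cand_idx[best])
                        rr_hist.append((idx_b - accepted[-1]) / fs)
                        accepted.append(idx_b)
                        qrs_peaks.append(float(cand_amp[best]))
                        rejected.remove(best)

    # refine to the local raw maximum within +/- 40 ms
    half = int(round(REFINE_S * fs))
    refined = []
    for idx in sorted(accepted):
        a, b = max(idx - half, 0), min(idx + half + 1, x.size)
        refined.append((a + int(np.argmax(x[a:b]))) / fs)
    # enforce the refractory invariant after refinement (keep earlier peak)
    times: list[float] = []
    for t in sorted(refined):
        if not times or t - times[-1] >= REFRACTORY_S:
            times.append(t)
    return PeakTrain(np.asarray(times), s.fs, s.channel or "ecg")


def heart_rate_bpm(peaks: PeakTrain, window_s: tuple) -> float:
    """Mean heart rate over a window, from RR intervals fully inside it.

    BPM = 60 x (number of complete RR intervals) / (their total duration).
    Returns NaN when fewer than two peaks fall inside the window.
    """
    a, b = window_s
    inside = peaks.peak_times[(peaks.peak_times >= a) & (peaks.peak_times < b)]
    if inside.size < 2:
        return float("nan")
    return 60.0 * (inside.size - 1) / float(inside[-1] - inside[0])


def match_peaks(detected: np.ndarray, truth: np.ndarray, tol_s: float = 0.075):
    """Greedy one-to-one matching of detected vs true peak times.

    Returns (n_matched, n_detected, n_truth); F1 etc. derive from these.
    """
    detected = np.sort(np.asarray(detected, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    i = j = matched = 0
    while i < detected.size and j < truth.size:
        dt = detected[i] - truth[j]
        if abs(dt) <= tol_s:
            matched += 1
            i += 1
            j += 1
        elif dt < 0:
            i += 1
        else:
            j += 1
    return matched, detected.size, truth.size
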