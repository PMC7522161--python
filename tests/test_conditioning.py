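"""Signal-conditioning tests against analytic and spectral oracles."""

import numpy as np
import pytest

from endostress.conditioning import (FilterSpec, apply_filter, condition_femg,
                                     condition_tmp, decimate_signal,
                                     detrend_linear, hilbert_envelope,
                                     moving_average)
from endostress.signals import Signal


def sine(freq, fs, duration, amp=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return Signal(amp * np.sin(2 * np.pi * freq * t + phase), fs)


def fitted_amplitude(sig, freq, skip_s=1.0):
    """Least-squares amplitude of a known-frequency sinusoid (interior)."""
    n0 = int(skip_s * sig.fs)
    x = sig.samples[n0: sig.n - n0]
    t = np.arange(n0, sig.n - n0) / sig.fs
    design = np.column_stack([np.sin(2 * np.pi * freq * t),
                              np.cos(2 * np.pi * freq * t),
                              np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(np.hypot(coef[0], coef[1]))


# ---------------------------------------------------------------------------
# decimation


def test_decimate_2048_to_512_lengths():
    s = Signal(np.random.default_rng(0).standard_normal(8192), 2048.0)
    out = decimate_signal(s, 512.0)
    assert out.fs == 512.0 and out.n == 2048


def test_decimate_preserves_dc():
    s = Signal(np.full(4096, 3.7), 2048.0)
    out = decimate_signal(s, 512.0)
    assert np.allclose(out.samples, 3.7, atol=1e-9)


def test_decimate_preserves_in_band_tone():
    """A 50 Hz tone survives 2048->512 Hz decimation within 2 % amplitude."""
    s = sine(50.0, 2048.0, 8.0, amp=1.3)
    out = decimate_signal(s, 512.0)
    spectrum = np.abs(np.fft.rfft(out.samples * np.hanning(out.n)))
    freqs = np.fft.rfftfreq(out.n, 1 / out.fs)
    assert abs(freqs[np.argmax(spectrum)] - 50.0) < 0.2
    assert fitted_amplitude(out, 50.0) == pytest.approx(1.3, rel=0.02)


def test_decimate_rejects_non_integer_factor():
    s = Signal(np.zeros(100), 1000.0)
    with pytest.raises(ValueError, match="integer"):
        decimate_signal(s, 512.0)


# ---------------------------------------------------------------------------
# Butterworth filtering


def test_bandpass_removes_dc():
    s = Signal(np.ones(4096), 512.0)
    out = apply_filter(s, FilterSpec("bandpass", (20, 250)))
    assert np.max(np.abs(out.samples[512:-512])) < 0.01


def test_bandpass_passes_midband_tone():
    out = apply_filter(sine(100, 512.0, 8.0), FilterSpec("bandpass", (20, 250)))
    assert 0.95 <= fitted_amplitude(out, 100.0) <= 1.05


def test_bandpass_rejects_out_of_band_tone():
    out = apply_filter(sine(5, 512.0, 8.0), FilterSpec("bandpass", (20, 250)))
    assert fitted_amplitude(out, 5.0) < 0.01


@pytest.mark.parametrize("freq", [5, 15, 25, 50, 100, 180, 240])
def test_measured_gain_matches_analytic_magnitude(freq):
    """Sinusoid gain equals the (squared, zero-phase) Butterworth response."""
    spec = FilterSpec("bandpass", (20, 250))
    out = apply_filter(sine(freq, 512.0, 12.0), spec)
    analytic = spec.gain(freq, 512.0)
    measured = fitted_amplitude(out, freq, skip_s=2.0)
    if analytic >= 0.05:
        assert measured == pytest.approx(analytic, rel=0.02)
    else:
        assert abs(measured - analytic) < 0.02


def test_filter_homogeneity():
    rng = np.random.default_rng(1)
    s = Signal(rng.standard_normal(2048), 512.0)
    spec = FilterSpec("lowpass", (8.0,))
    once = apply_filter(s, spec).samples
    scaled = apply_filter(s.with_samples(3.5 * s.samples), spec).samples
    assert np.allclose(scaled, 3.5 * once, rtol=1e-12, atol=1e-12)


def test_corner_at_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        apply_filter(Signal(np.zeros(100), 512.0), FilterSpec("lowpass", (256.0,)))


# ---------------------------------------------------------------------------
# Hilbert envelope


def test_hilbert_zero_signal():
    out = hilbert_envelope(Signal(np.zeros(512), 512.0))
    assert np.all(out.samples == 0)


def test_hilbert_recovers_tone_amplitude():
    out = hilbert_envelope(sine(50, 512.0, 4.0, amp=2.0))
    interior = out.samples[512:-512]
    assert np.allclose(interior, 2.0, rtol=0.01)


def test_hilbert_demodulates_am_signal():
    """AM envelope recovered after 4 Hz low-pass correlates r > 0.99."""
    fs, dur = 512.0, 8.0
    t = np.arange(int(fs * dur)) / fs
    modulator = 1 + 0.5 * np.sin(2 * np.pi * 1.0 * t)
    s = Signal(modulator * np.sin(2 * np.pi * 50.0 * t), fs)
    env = apply_filter(hilbert_envelope(s), FilterSpec("lowpass", (4.0,)))
    sl = slice(512, -512)
    r = np.corrcoef(env.samples[sl], modulator[sl])[0, 1]
    assert r > 0.99


# ---------------------------------------------------------------------------
# moving average / detrend


def test_moving_average_preserves_constant():
    out = moving_average(Signal(np.full(1000, 2.5), 512.0), 67)
    assert np.allclose(out.samples, 2.5, atol=1e-12)


def test_moving_average_impulse_plateau():
    x = np.zeros(500)
    x[250] = 1.0
    out = moving_average(Signal(x, 512.0), 67)
    covering = out.samples[250 - 33: 250 + 34]
    assert np.allclose(covering, 1 / 67, atol=1e-12)
    assert np.allclose(out.samples[:216], 0.0) and np.allclose(out.samples[285:], 0.0)


def test_moving_average_noise_variance_reduction():
    """n=513 box filter divides white-noise variance by ~513."""
    rng = np.random.default_rng(2)
    ratios = []
    for _ in range(100):
        x = rng.standard_normal(4096)
        out = moving_average(Signal(x, 512.0), 513)
        ratios.append(np.var(out.samples[513:-513]) / np.var(x))
    assert np.mean(ratios) == pytest.approx(1 / 513, rel=0.2)


def test_moving_average_rejects_bad_window():
    with pytest.raises(ValueError):
        moving_average(Signal(np.zeros(10), 512.0), 0)
    with pytest.raises(ValueError):
        moving_average(Signal(np.zeros(10), 512.0), 11)


def test_detrend_removes_ramp_exactly():
    out = detrend_linear(Signal(np.linspace(0, 1, 1000), 512.0))
    assert np.max(np.abs(out.samples)) < 1e-9


def test_detrend_constant_gives_zeros():
    out = detrend_linear(Signal(np.full(100, 5.0), 512.0))
    assert np.allclose(out.samples, 0.0, atol=1e-9)


def test_detrend_keeps_oscillation():
    """Removing the line from sin + trend leaves the sin's own least-squares
    residual (independent polyfit oracle) to within 1 % RMS."""
    fs, dur = 512.0, 4.0
    t = np.arange(int(fs * dur)) / fs
    wave = np.sin(2 * np.pi * 10 * t)
    out = detrend_linear(Signal(wave + 0.3 * t, fs))
    slope, intercept = np.polyfit(t, wave, 1)
    expected = wave - (slope * t + intercept)
    rms_err = np.sqrt(np.mean((out.samples - expected) ** 2))
    assert rms_err < 0.01 * np.sqrt(np.mean(wave ** 2))


# ---------------------------------------------------------------------------
# modality chains


def test_condition_femg_zero_input():
    out = condition_femg(Signal(np.zeros(2048), 512.0, unit="uV"))
    assert np.allclose(out.samples, 0.0)


def test_condition_femg_homogeneous():
    rng = np.random.default_rng(3)
    s = Signal(rng.standard_normal(4096), 512.0, unit="uV")
    assert np.allclose(condition_femg(s.with_samples(2 * s.samples)).samples,
                       2 * condition_femg(s).samples, rtol=1e-10, atol=1e-10)


def test_condition_femg_rejects_low_rate():
    with pytest.raises(ValueError, match="band"):
        condition_femg(Signal(np.zeros(1000), 256.0))


def test_condition_femg_recovers_constant_envelope(rng):
    """A 6 uV constant-envelope simulated fEMG yields a ~6 uV window mean."""
    from endostress.signals import EventMarks
    from endostress.synth import SessionSpec, synth_femg

    spec = SessionSpec(duration_s=186.0, fs=512.0,
                       anchors=EventMarks(2.0, 182.0, cecum=92.0),
                       femg_envelope_mean={"corrugator": 6.0},
                       femg_envelope_sd={"corrugator": 0.0})
    sig, env = synth_femg(spec, "corrugator", rng)
    out = condition_femg(sig)
    a, b = int(2 * 512), int(62 * 512)
    assert np.mean(out.samples[a:b]) == pytest.approx(6.0, rel=0.10)


def test_condition_tmp_preserves_drift_slope():
    """n=513 smoothing leaves a 0.1 degC/min drift slope within 2 %."""
    fs, dur = 512.0, 600.0
    t = np.arange(int(fs * dur)) / fs
    s = Signal(32.0 + (0.1 / 60.0) * t, fs, unit="degC", channel="tmp")
    out = condition_tmp(s)
    sl = slice(1024, -1024)
    slope = np.polyfit(t[sl], out.samples[sl], 1)[0] * 60.0
    assert slope == pytest.approx(0.1, rel=0.02)


def test_chains_preserve_length_fs_unit():
    rng = np.random.default_rng(4)
    s = Signal(rng.standard_normal(4096), 512.0, unit="uV", channel="femg_corrugator")
    out = condition_femg(s)
    assert (out.n, out.fs, out.unit, out.channel) == (s.n, s.fs, s.unit, s.channel)
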