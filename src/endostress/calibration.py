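"""Monte-Carlo calibration and power studies of the full analysis.

Two levels of simulation:

* :func:`null_rejection_rate` — the *signal-level* check: whole synthetic
  cohorts with no group effect are pushed through decimation, QC,
  conditioning, windowing, feature extraction and the one-sided U test,
  and the fraction of significant cells is compared with alpha. Sessions
  are kept short (two-to-three-minute recordings at 512 Hz) since the
  test's level does not depend on session length.
* :func:`feature_level_power` — the *feature-level* check: per-patient
  window means are drawn directly from the generator's between-patient
  model (normal, truncated at zero — envelope means are positive) and
  compared with the one-sided U test. This is how detection power at
  study-scale group sizes is estimated; the signal chain's fidelity in
  recovering those means is established separately by the conditioning
  oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import PipelineConfig
from .pipeline import run_pipeline
from .signals import EventMarks
from .stats import mann_whitney_u
from .synth import CohortSpec, SessionSpec, iter_cohort


def short_session_spec(fs: float = 512.0, include_cecum: bool = False) -> SessionSpec:
    """A minimal-duration session for calibration runs, generated directly
    at 512 Hz.

    By default only the start and end anchors are present (126 s session):
    the test's level does not depend on the anchor, so the Monte Carlo
    omits the cecum window to stay desk-scale. ``include_cecum=True`` gives
    the three-anchor 186 s variant.
    """
    if include_cecum:
        return SessionSpec(duration_s=186.0, fs=fs,
                           anchors=EventMarks(2.0, 182.0, cecum=92.0))
    return SessionSpec(duration_s=126.0, fs=fs,
                       anchors=EventMarks(2.0, 122.0, cecum=None))


@dataclass
class CalibrationResult:
    rejection_rate: float
    n_tests: int
    n_replicates: int
    alpha: float
    per_cell: dict  # (channel, anchor) -> rejection rate


def null_rejection_rate(n_replicates: int = 200,
                        n_per_group: int = 30,
                        alpha: float = 0.05,
                        seed: int = 0,
                        base: SessionSpec | None = None,
                        config: PipelineConfig | None = None) -> CalibrationResult:
    """Type-I error of the full pipeline under no group effect.

    Each replicate generates a fresh null cohort (music_femg_scale = 1),
    runs the complete signal pipeline, and counts the significant
    (channel, anchor) cells in the 'all' stratum at one-sided ``alpha``.
    """
    base = base or short_session_spec()
    config = config or PipelineConfig(alpha=alpha)
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2 ** 31)
    hits: dict = {}
    totals: dict = {}
    for rep in range(n_replicates):
        cohort = CohortSpec(n_control=n_per_group, n_music=n_per_group,
                            base=base, music_femg_scale=1.0, seed=int(seeds[rep]))
        _, comparison, _ = run_pipeline(iter_cohort(cohort), config)
        cells = comparison[comparison["stratum"] == "all"]
        for _, row in cells.iterrows():
            if not np.isfinite(row["p_one_sided"]):
                continue
            key = (row["channel"], row["anchor"])
            totals[key] = totals.get(key, 0) + 1
            hits[key] = hits.get(key, 0) + int(row["p_one_sided"] <= alpha)
    n_tests = sum(totals.values())
    n_hits = sum(hits.values())
    per_cell = {k: hits.get(k, 0) / totals[k] for k in totals}
    return CalibrationResult(rejection_rate=n_hits / n_tests if n_tests else float("nan"),
                             n_tests=n_tests, n_replicates=n_replicates,
                             alpha=alpha, per_cell=per_cell)


def qrs_detection_score(n_sessions: int = 100, seed: int = 0,
                        bpm_range: tuple = (45.0, 120.0),
                        jitter_max: float = 0.05,
                        wander_every: int = 3,
                        duration_s: float = 126.0) -> dict:
    """Aggregate R-peak F1 (75 ms match tolerance) and clean-signal BPM
    error over simulated sessions spanning the physiological rate range,
    with beat-to-beat jitter and periodic 2 mV baseline wander."""
    from .cardiac import detect_r_peaks, heart_rate_bpm, match_peaks
    from .synth import synth_ecg

    rng = np.random.default_rng(seed)
    anchors = EventMarks(2.0, duration_s - 4.0, cecum=None)
    tm = td = tt = 0
    bpm_errors = []
    for i in range(n_sessions):
        bpm = rng.uniform(*bpm_range)
        jitter = rng.uniform(0.0, jitter_max)
        wander = 2.0 if (wander_every and i % wander_every == 0) else 0.0
        spec = SessionSpec(duration_s=duration_s, fs=512.0, anchors=anchors,
                           ecg_mean_bpm=bpm, ecg_rr_jitter_sd=jitter,
                           ecg_baseline_wander_mv=wander)
        sig, truth = synth_ecg(spec, rng)
        peaks = detect_r_peaks(sig)
        m, nd, nt = match_peaks(peaks.peak_times, truth, tol_s=0.075)
        tm, td, tt = tm + m, td + nd, tt + nt
        if wander == 0 and jitter < 0.01:
            win = (2.0, 62.0)
            in_w = truth[(truth >= win[0]) & (truth < win[1])]
            true_bpm = 60.0 * (in_w.size - 1) / (in_w[-1] - in_w[0])
            bpm_errors.append(abs(heart_rate_bpm(peaks, win) - true_bpm))
    precision = tm / td if td else 0.0
    recall = tm / tt if tt else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"f1": f1, "sensitivity": recall, "ppv": precision,
            "bpm_max_error": max(bpm_errors) if bpm_errors else float("nan"),
            "n_sessions": n_sessions}


def envelope_recovery_error(n_sessions: int = 50, seed: int = 0) -> dict:
    """Mean absolute relative error between the conditioned fEMG window
    mean and the generator's specified envelope mean, across sessions with
    envelope levels drawn over the study's range."""
    from .conditioning import condition_femg
    from .synth import synth_femg

    rng = np.random.default_rng(seed)
    base = short_session_spec()
    errors = []
    for _ in range(n_sessions):
        level = float(rng.uniform(2.0, 12.0))
        spec = replace(base, femg_envelope_mean={"zygomaticus": level},
                       femg_envelope_sd={"zygomaticus": 0.0})
        sig, _ = synth_femg(spec, "zygomaticus", rng)
        env = condition_femg(sig)
        for a_s, b_s in ((2.0, 62.0), (62.0, 122.0)):
            a, b = int(a_s * spec.fs), int(b_s * spec.fs)
            errors.append(abs(float(np.mean(env.samples[a:b])) - level) / level)
    return {"mean_abs_rel_error": float(np.mean(errors)),
            "max_abs_rel_error": float(np.max(errors)),
            "n_sessions": n_sessions}


def _truncated_normal_sample(rng: np.random.Generator, mean: float, sd: float,
                             size: int, lower: float = 0.0) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        draw = draw[draw > lower]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def feature_level_power(mean_control: float, sd_control: float,
                        mean_music: float, sd_music: float,
                        n_control: int, n_music: int,
                        n_replicates: int = 200,
                        alpha: float = 0.05,
                        alternative: str = "less",
                        seed: int = 0) -> float:
    """Fraction of replicates with a significant one-sided U test when
    per-patient window means follow the two groups' truncated-normal
    between-patient distributions."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        ctrl = _truncated_normal_sample(rng, mean_control, sd_control, n_control)
        music = _truncated_normal_sample(rng, mean_music, sd_music, n_music)
        res = mann_whitney_u(music, ctrl, alternative=alternative)
        hits += int(res.p_one_sided <= alpha)
    return hits / n_replicates
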