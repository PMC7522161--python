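"""End-to-end session processing: decimate, screen, condition, featurise.

Per session the order is:

1. decimate every channel to the analysis rate (512 Hz);
2. cut the event-anchored raw windows and screen them (artifacts are
   visible on the raw trace; corrected excerpts are written back so the
   conditioning sees the repaired data);
3. condition each full-length channel per modality;
4. detect R-peaks on the unsmoothed 512 Hz ECG;
5. reduce each non-discarded window to its feature (conditioned-trace
   mean, or BPM for the ECG channel).

`run_pipeline` maps this over a cohort and appends the group comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from . import conditioning as cond
from .cardiac import detect_r_peaks
from .config import PipelineConfig
from .features import FEATURE_UNITS, bpm_feature, build_feature_table, window_mean
from .signals import ANCHORS, EventMarks, Recording
from .stats import ComparisonPlan, compare_groups
from .windowing import (QC_CORRECTED, QC_DISCARDED, AnalysisWindow,
                        channel_screen_stats, extract_window, screen_window)

log = logging.getLogger("endostress")


@dataclass
class ProcessedSession:
    patient_id: str
    feature_rows: list
    qc_rows: list


def _condition_channel(name, sig, config: PipelineConfig):
    if name.startswith("femg"):
        return cond.condition_femg(sig, band_hz=config.femg_band_hz,
                                   envelope_lowpass_hz=config.femg_envelope_lowpass_hz,
                                   order=config.filter_order)
    if name == "scl":
        return cond.condition_scl(sig, lowpass_hz=config.scl_lowpass_hz,
                                  order=config.filter_order)
    if name == "ecg":
        return cond.condition_ecg(sig, n=config.ecg_smooth_n)
    if name == "tmp":
        return cond.condition_tmp(sig, n=config.tmp_smooth_n)
    return sig


def process_session(rec: Recording, marks: EventMarks,
                    config: Optional[PipelineConfig] = None) -> ProcessedSession:
    """Run one session through decimation, QC, conditioning and features."""
    config = config or PipelineConfig()
    marks.validate_within(rec.duration_s)

    decimated = {name: cond.decimate_signal(sig, config.target_fs)
                 if sig.fs > config.target_fs else sig
                 for name, sig in rec.channels.items()}

    feature_rows, qc_rows = [], []
    for name, raw in decimated.items():
        screened: dict[str, AnalysisWindow] = {}
        repaired = raw
        stats = channel_screen_stats(raw, config.screen)
        for anchor in ANCHORS:
            w = extract_window(repaired, marks, anchor)
            if w is None:
                continue
            w = screen_window(w, stats, config.screen)
            if w.qc == QC_CORRECTED:
                patched = repaired.samples.copy()
                a, b = w.sample_range
                patched[a:b] = w.data.samples
                repaired = repaired.with_samples(patched)
            screened[anchor] = w
            qc_rows.append({"patient_id": rec.patient_id, "channel": name,
                            "anchor": anchor, "qc": w.qc, "qc_reason": w.qc_reason})

        feature_channel = "bpm" if name == "ecg" else name
        if name == "ecg":
            # the ECG feature is BPM from the unsmoothed trace; the n=67
            # smoothed/detrended display chain is not needed here
            peaks = detect_r_peaks(repaired)
        else:
            conditioned = _condition_channel(name, repaired, config)

        for anchor, w in screened.items():
            if w.qc == QC_DISCARDED:
                value = float("nan")
            elif name == "ecg":
                value = bpm_feature(peaks, w)
            else:
                a, b = w.sample_range
                cw = AnalysisWindow(name, anchor, (a, b),
                                    conditioned.with_samples(conditioned.samples[a:b]),
                                    qc=w.qc, qc_reason=w.qc_reason)
                value = window_mean(cw)
            feature_rows.append({"patient_id": rec.patient_id, "group": rec.group,
                                 "sex": rec.sex, "channel": feature_channel,
                                 "anchor": anchor, "value": value,
                                 "unit": FEATURE_UNITS[feature_channel],
                                 "qc": w.qc})
    return ProcessedSession(rec.patient_id, feature_rows, qc_rows)


def run_pipeline(sessions: Iterable, config: Optional[PipelineConfig] = None):
    """Process a cohort of (Recording, EventMarks) pairs end to end.

    ``sessions`` yields ``(Recording, EventMarks)`` tuples or objects with
    ``.recording`` / ``.marks`` (e.g. simulated sessions). Returns
    ``(features, comparison, qc_report)`` DataFrames. Failures in one
    session are logged and skipped; the run continues.
    """
    config = config or PipelineConfig()
    all_features, all_qc, failures = [], [], []
    for item in sessions:
        rec, marks = (item.recording, item.marks) if hasattr(item, "recording") else item
        try:
            processed = process_session(rec, marks, config)
        except Exception as exc:  # keep going; report at the end
            log.error("session %s failed: %s", rec.patient_id, exc)
            failures.append((rec.patient_id, str(exc)))
            continue
        all_features.extend(processed.feature_rows)
        all_qc.extend(processed.qc_rows)
    features = build_feature_table(all_features)
    plan = ComparisonPlan(directions=dict(config.directions),
                          alpha=config.alpha, holm=config.holm)
    comparison = compare_groups(features, plan) if len(features) else pd.DataFrame()
    qc_report = pd.DataFrame(all_qc, columns=["patient_id", "channel", "anchor",
                                              "qc", "qc_reason"])
    n_disc = int((qc_report["qc"] == QC_DISCARDED).sum()) if len(qc_report) else 0
    log.info("pipeline: %d feature rows, %d windows discarded, %d sessions failed",
             len(features), n_disc, len(failures))
    if failures:
        qc_report.attrs["failures"] = failures
    return features, comparison, qc_report
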