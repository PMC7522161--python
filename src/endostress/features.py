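"""Window features and the cohort feature table.

Each kept (or corrected) window reduces to one scalar: the arithmetic mean
of the conditioned excerpt for fEMG (uV), SCL (uS) and TMP (degC), and the
mean heart rate in beats/min derived from the detected R-peak train for
the ECG channel. The feature table is long-format: one row per
(patient, channel, anchor), carrying the group and sex covariates and the
window's QC status; discarded windows contribute no value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cardiac import PeakTrain, heart_rate_bpm
from .signals import ANCHORS
from .windowing import QC_DISCARDED, AnalysisWindow

#: Feature channels and their units (BPM replaces the raw ECG trace).
FEATURE_UNITS = {
    "femg_corrugator": "uV",
    "femg_zygomaticus": "uV",
    "scl": "uS",
    "tmp": "degC",
    "bpm": "bpm",
}

FEATURE_COLUMNS = ["patient_id", "group", "sex", "channel", "anchor",
                   "value", "unit", "qc"]


def window_mean(w: AnalysisWindow) -> float:
    """Arithmetic mean of a non-discarded window; NaN when discarded."""
    if w.qc == QC_DISCARDED:
        return float("nan")
    return float(np.mean(w.data.samples))


def bpm_feature(peaks: PeakTrain, w: AnalysisWindow) -> float:
    """Heart rate over a window's time span (NaN with < 2 peaks inside)."""
    if w.qc == QC_DISCARDED:
        return float("nan")
    a, b = w.sample_range
    return heart_rate_bpm(peaks, (a / w.data.fs, b / w.data.fs))


def build_feature_table(rows: list) -> pd.DataFrame:
    """Assemble per-window feature rows into the cohort feature table.

    ``rows`` are dicts with the :data:`FEATURE_COLUMNS` keys. Rows are
    sorted deterministically by (patient, channel, anchor); duplicate
    (patient, channel, anchor) cells and unknown groups are rejected.
    """
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if len(table):
        bad_groups = set(table["group"]) - {"control", "music"}
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
        keys = table[["patient_id", "channel", "anchor"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValueError(f"duplicate feature cell: {tuple(dup)}")
        table["anchor"] = pd.Categorical(table["anchor"], categories=list(ANCHORS))
        table = table.sort_values(["patient_id", "channel", "anchor"]).reset_index(drop=True)
        table["anchor"] = table["anchor"].astype(str)
    return table


def write_feature_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return table[FEATURE_COLUMNS]
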