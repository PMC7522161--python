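"""Recording serialization: CSV interchange format plus sidecar metadata.

A session is stored as ``<name>.csv`` with a ``time_s`` column followed by
one column per channel, suffixed with its unit (``femg_corrugator_uV``,
``ecg_mV``, ...), and a JSON sidecar ``<name>.meta`` holding the sampling
rate, patient metadata and the event marks. EDF recordings can be read
(not written) through the optional ``mne`` dependency.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import CHANNEL_UNITS, EventMarks, Recording, Signal


def _column_name(channel: str) -> str:
    return f"{channel}_{CHANNEL_UNITS[channel]}"


def write_recording(rec: Recording, marks: EventMarks, path,
                    float_format: str = "%.6f") -> None:
    """Write the CSV interchange file and its ``.meta`` sidecar."""
    path = Path(path)
    data = {"time_s": np.arange(rec.n) / rec.fs}
    for name in CHANNEL_UNITS:
        if name in rec.channels:
            data[_column_name(name)] = rec.channels[name].samples
    pd.DataFrame(data).to_csv(path, index=False, float_format=float_format)
    meta = {"fs": rec.fs, "patient_id": rec.patient_id, "group": rec.group,
            "sex": rec.sex,
            "marks": {"exam_start": marks.exam_start, "exam_end": marks.exam_end,
                      **({"cecum": marks.cecum} if marks.cecum is not None else {})}}
    path.with_suffix(".meta").write_text(json.dumps(meta, indent=1))


def read_recording(path) -> tuple:
    """Read a CSV session and its sidecar; returns (Recording, EventMarks)."""
    path = Path(path)
    sidecar = path.with_suffix(".meta")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar {sidecar} is missing")
    meta = json.loads(sidecar.read_text())
    table = pd.read_csv(path)
    if "time_s" not in table.columns:
        raise ValueError("interchange CSV must contain a time_s column")
    t = table["time_s"].to_numpy()
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time_s must be strictly increasing")
    fs = float(meta["fs"])
    if t.size > 1:
        fs_from_time = 1.0 / float(np.median(np.diff(t)))
        if abs(fs_from_time - fs) / fs > 0.01:
            raise ValueError(
                f"sampling rate mismatch: sidecar says {fs} Hz, "
                f"time column implies {fs_from_time:.1f} Hz")
    channels = {}
    for name, unit in CHANNEL_UNITS.items():
        col = _column_name(name)
        if col in table.columns:
            channels[name] = Signal(table[col].to_numpy(), fs, unit=unit, channel=name)
    if not channels:
        raise ValueError(f"no recognised channel columns in {path.name}; "
                         f"expected e.g. {_column_name('ecg')!r}")
    m = meta.get("marks", {})
    if "exam_start" not in m or "exam_end" not in m:
        raise ValueError("sidecar marks must include exam_start and exam_end")
    marks = EventMarks(float(m["exam_start"]), float(m["exam_end"]),
                       cecum=float(m["cecum"]) if "cecum" in m else None)
    rec = Recording(channels, fs, patient_id=str(meta.get("patient_id", "")),
                    group=str(meta.get("group", "")), sex=str(meta.get("sex", "")))
    marks.validate_within(rec.duration_s)
    return rec, marks


def read_recording_edf(path, channel_map: dict, marks: EventMarks,
                       patient_id: str = "", group: str = "", sex: str = "") -> tuple:
    """Read an EDF file, mapping EDF channel labels to pipeline channels.

    ``channel_map`` maps EDF labels to canonical names, e.g.
    ``{"EMG1": "femg_corrugator", "ECG": "ecg"}``. Requires ``mne``.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError("EDF support requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    channels = {}
    for label, name in channel_map.items():
        if name not in CHANNEL_UNITS:
            raise ValueError(f"unknown target channel {name!r}")
        if label not in raw.ch_names:
            raise ValueError(f"EDF file has no channel {label!r}")
        data = raw.get_data(picks=[label])[0]
        channels[name] = Signal(data, fs, unit=CHANNEL_UNITS[name], channel=name)
    rec = Recording(channels, fs, patient_id=patient_id, group=group, sex=sex)
    marks.validate_within(rec.duration_s)
    return rec, marks


def write_peak_train(peaks, path) -> None:
    """Two-column CSV export of a detected R-peak train."""
    pd.DataFrame({"time_s": peaks.peak_times,
                  "sample_index": np.round(peaks.peak_times * peaks.fs).astype(int)}
                 ).to_csv(path, index=False)
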