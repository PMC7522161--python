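"""Core in-memory containers for multi-channel physiological recordings.

A session is a :class:`Recording` — five uniformly sampled channels sharing
one sampling rate — plus :class:`EventMarks` giving the three procedure
anchors (examination start, cecum reached, examination end) in seconds from
the start of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Canonical channel names and their units.
CHANNEL_UNITS = {
    "femg_corrugator": "uV",
    "femg_zygomaticus": "uV",
    "ecg": "mV",
    "scl": "uS",
    "tmp": "degC",
}

CHANNELS = tuple(CHANNEL_UNITS)

#: Window anchors, in procedure order.
ANCHORS = ("start", "cecum", "end")


@dataclass
class Signal:
    """A uniformly sampled single-channel trace.

    Parameters
    ----------
    samples : ndarray
        Sample values in the channel's physical unit.
    fs : float
        Sampling rate in Hz.
    unit : str
        Physical unit label (``uV``, ``mV``, ``uS``, ``degC``).
    channel : str
        Channel label, normally one of :data:`CHANNELS`.
    """

    samples: np.ndarray
    fs: float
    unit: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Signal samples must be one-dimensional")
        if self.samples.size < 1:
            raise ValueError("Signal must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"Sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based)."""
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, fs: Optional[float] = None) -> "Signal":
        """Copy of this signal with new samples (and optionally a new rate)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64),
                       fs=self.fs if fs is None else fs)


@dataclass
class EventMarks:
    """Procedure anchors in seconds from recording start.

    ``cecum`` may be ``None``: cecal intubation is not always achieved, in
    which case the mid-procedure window is simply absent for that session.
    """

    exam_start: float
    exam_end: float
    cecum: Optional[float] = None

    def __post_init__(self) -> None:
        if self.exam_start < 0:
            raise ValueError("exam_start must be >= 0")
        if self.cecum is not None and not (self.exam_start < self.cecum < self.exam_end):
            raise ValueError(
                f"event marks must be ordered exam_start < cecum < exam_end, got "
                f"{self.exam_start}, {self.cecum}, {self.exam_end}"
            )
        if not self.exam_start < self.exam_end:
            raise ValueError("exam_start must precede exam_end")

    def validate_within(self, duration_s: float) -> None:
        if self.exam_end > duration_s:
            raise ValueError(
                f"exam_end {self.exam_end} s exceeds recording duration {duration_s} s"
            )


@dataclass
class Recording:
    """One session's multi-channel signals at a common sampling rate."""

    channels: dict[str, Signal]
    fs: float
    patient_id: str = ""
    group: str = ""
    sex: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("Recording needs at least one channel")
        lengths = {s.n for s in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channels must share a sample count, got {sorted(lengths)}")
        for name, sig in self.channels.items():
            if sig.fs != self.fs:
                raise ValueError(f"channel {name!r} fs {sig.fs} != recording fs {self.fs}")
            expected = CHANNEL_UNITS.get(name)
            if expected is not None and sig.unit != expected:
                raise ValueError(f"channel {name!r} unit {sig.unit!r}, expected {expected!r}")

    @property
    def n(self) -> int:
        return next(iter(self.channels.values())).n

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def __getitem__(self, channel: str) -> Signal:
        return self.channels[channel]
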