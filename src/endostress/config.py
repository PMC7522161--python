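"""Pipeline configuration: every tunable constant in one validated object.

Defaults reproduce the analysis chain exactly: decimation to 512 Hz,
fEMG 20–250 Hz band-pass + Hilbert magnitude + 4 Hz low-pass, SCL 8 Hz
low-pass, ECG n=67 / TMP n=513 moving averages, 60 s event-anchored
windows, one-sided U tests at alpha = 0.05. Configs round-trip through
YAML; unknown keys are rejected on load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .stats import DEFAULT_DIRECTIONS
from .windowing import ScreenCriteria


@dataclass
class PipelineConfig:
    target_fs: float = 512.0
    filter_order: int = 4
    femg_band_hz: tuple = (20.0, 250.0)
    femg_envelope_lowpass_hz: float = 4.0
    scl_lowpass_hz: float = 8.0
    ecg_smooth_n: int = 67
    tmp_smooth_n: int = 513
    screen: ScreenCriteria = field(default_factory=ScreenCriteria)
    directions: dict = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    alpha: float = 0.05
    holm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.femg_band_hz = tuple(float(c) for c in self.femg_band_hz)
        if not (0 < self.femg_band_hz[0] < self.femg_band_hz[1] < self.target_fs / 2):
            raise ValueError("fEMG band corners must satisfy 0 < low < high < Nyquist")
        for name in ("femg_envelope_lowpass_hz", "scl_lowpass_hz"):
            if not 0 < getattr(self, name) < self.target_fs / 2:
                raise ValueError(f"{name} must lie inside (0, Nyquist)")
        if self.ecg_smooth_n < 1 or self.tmp_smooth_n < 1:
            raise ValueError("moving-average lengths must be >= 1")
        if self.filter_order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for ch, d in self.directions.items():
            if d not in ("less", "greater"):
                raise ValueError(f"direction for {ch!r} must be 'less' or 'greater'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["femg_band_hz"] = list(self.femg_band_hz)
        d["screen"]["outlier_exempt_channels"] = list(self.screen.outlier_exempt_channels)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "screen" in data and isinstance(data["screen"], dict):
            sdata = dict(data["screen"])
            sknown = {f.name for f in dataclasses.fields(ScreenCriteria)}
            sunknown = set(sdata) - sknown
            if sunknown:
                raise ValueError(f"unknown screen-criteria keys: {sorted(sunknown)}")
            if "outlier_exempt_channels" in sdata:
                sdata["outlier_exempt_channels"] = tuple(sdata["outlier_exempt_channels"])
            data["screen"] = ScreenCriteria(**sdata)
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
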