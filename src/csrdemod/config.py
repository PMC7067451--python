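"""Pipeline configuration: every tunable in one validated record.

Defaults reproduce the published operating point: envelope resampled at
1 Hz, 2-minute estimation windows with 80% overlap, oscillation threshold
h0 = 0.12 with the [8, 30] mHz pathological band, one-minute zone
persistence and the 10-min / 6-min classification durations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]

_RANGES = {
    "fs_env": (0.1, 100.0),
    "slope_min": (0.0, 1.0),
    "min_section_s": (0.0, 60.0),
    "gap_factor": (1.0, 100.0),
    "detrend_window_s": (1.0, 600.0),
    "penalty_scale": (0.0, 1e6),
    "window_s": (30.0, 3600.0),
    "overlap": (0.0, 0.999),
    "pencil_ratio": (0.01, 0.99),
    "order": (1, 10),
    "amplitude_floor_frac": (0.0, 1.0),
    "h0": (0.0, 10.0),
    "f_low": (0.0, 1.0),
    "f_high": (0.0, 1.0),
    "min_zone_s": (0.0, 3600.0),
    "total_min_s": (0.0, 86400.0),
    "episode_min_s": (0.0, 86400.0),
    "h_apnea": (0.0, 10.0),
    "min_cover_s": (0.0, 60.0),
}


@dataclass(frozen=True)
class PipelineConfig:
    # envelope stage
    fs_env: float = 1.0
    slope_min: float = 1e-3
    min_section_s: float = 1.0
    gap_factor: float = 3.0
    detrend_window_s: float = 30.0
    penalty_scale: float = 6.0
    cpa_beta: float | None = None  # None -> automatic BIC-like penalty
    # estimation stage
    window_s: float = 120.0
    overlap: float = 0.8
    pencil_ratio: float = 1.0 / 3.0
    order: int = 3
    amplitude_floor_frac: float = 0.01
    # detection stage
    h0: float = 0.12
    f_low: float = 0.008
    f_high: float = 0.030
    min_zone_s: float = 60.0
    total_min_s: float = 600.0
    episode_min_s: float = 360.0
    h_apnea: float = 1.0
    # evaluation
    min_cover_s: float = 30.0
    # simulation / reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ValueError(
                    f"config field {name}={val} outside valid range [{lo}, {hi}]"
                )
        if self.cpa_beta is not None and self.cpa_beta < 0:
            raise ValueError("cpa_beta must be >= 0 or null")
        if not self.f_low < self.f_high:
            raise ValueError("f_low must be below f_high")

    @property
    def f_band(self) -> tuple[float, float]:
        return (self.f_low, self.f_high)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a YAML mapping")
        return cls.from_dict(raw)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
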