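"""Core containers shared across the pipeline.

Everything downstream operates on uniformly sampled signals; ``TimeSeries``
enforces that contract once so the envelope, estimation and detection stages
never have to re-check it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "CSRParams",
    "Segment",
    "SyntheticRecording",
    "BreathSegmentation",
    "EnvelopeSignal",
    "WindowEstimate",
    "EstimateTrack",
    "OscillationZone",
    "Diagnosis",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Sample ``i`` sits at ``start_time + i / sampling_rate`` seconds. All
    values must be finite.
    """

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if not np.isfinite(values).all():
            raise ValueError("TimeSeries values must be finite (no NaN/Inf)")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Length of the sampled interval in seconds (n / fs)."""
        return len(self.values) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.sampling_rate


@dataclass(frozen=True)
class CSRParams:
    """Parameters of the amplitude-modulation model of ventilation.

    The envelope is ``A_c * (1 + h * cos(2*pi*f_m*t + phi_m))`` riding on a
    carrier (breathing) at ``f_c``. ``h`` is the modulation index: 0 for a
    flat envelope, (0, 1] for periodic breathing, > 1 for over-modulation
    whose clipped envelope produces central apneas.
    """

    a_c: float = 1.0
    f_c: float = 0.3
    h: float = 0.0
    f_m: float = 0.015
    phi_m: float = 0.0

    def __post_init__(self) -> None:
        if not self.a_c > 0:
            raise ValueError(f"carrier amplitude a_c must be > 0, got {self.a_c}")
        if self.h < 0:
            raise ValueError(f"modulation index h must be >= 0, got {self.h}")
        if self.f_m < 0:
            raise ValueError(f"modulation frequency f_m must be >= 0, got {self.f_m}")
        if not self.f_c > 0:
            raise ValueError(f"carrier frequency f_c must be > 0, got {self.f_c}")


@dataclass(frozen=True)
class Segment:
    """A schedule entry: constant model parameters on [start_s, end_s)."""

    start_s: float
    end_s: float
    params: CSRParams

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"segment end ({self.end_s}) must be after start ({self.start_s})"
            )

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SyntheticRecording:
    """A simulated ventilation recording plus its ground truth.

    ``truth_minutes`` holds one label per minute, ``"oscillating"`` or
    ``"normal"``; a minute is oscillating when at least 30 s of it lies in a
    schedule segment with pathological modulation. ``breath_peaks`` are the
    true inspiration-peak times of every breath actually present in the
    signal (breaths suppressed by envelope clipping are absent).
    """

    signal: TimeSeries
    schedule: tuple[Segment, ...]
    truth_minutes: tuple[str, ...]
    breath_peaks: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass(frozen=True)
class BreathSegmentation:
    """Breath-cycle detection output on one recording.

    ``change_points`` are the retained section boundaries (seconds);
    ``peak_times``/``peak_amps`` the kept breath maxima; ``gaps`` the
    ventilation interruptions, each longer than three times the median
    inter-peak spacing.
    """

    change_points: np.ndarray
    peak_times: np.ndarray
    peak_amps: np.ndarray
    gaps: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        cps = np.asarray(self.change_points, dtype=float)
        object.__setattr__(self, "change_points", cps)
        object.__setattr__(self, "peak_times", np.asarray(self.peak_times, dtype=float))
        object.__setattr__(self, "peak_amps", np.asarray(self.peak_amps, dtype=float))
        if len(cps) > 1 and not (np.diff(cps) > 0).all():
            raise ValueError("change points must be strictly increasing")


@dataclass(frozen=True)
class EnvelopeSignal:
    """Reconstructed ventilation envelope, uniform and non-negative."""

    series: TimeSeries
    source_peaks: int = 0

    def __post_init__(self) -> None:
        if (self.series.values < 0).any():
            raise ValueError("envelope values must be non-negative")


@dataclass(frozen=True)
class WindowEstimate:
    """Model-parameter estimates on one analysis window.

    ``valid`` is False when the DC amplitude is below the floor (the
    modulation-index ratio is then meaningless) or no DC-like component was
    found.
    """

    t_center: float
    a_c_hat: float
    h_hat: float
    f_m_hat: float
    phi_hat: float
    valid: bool = True


@dataclass(frozen=True)
class EstimateTrack:
    """Per-window estimates from a sliding analysis of the envelope."""

    estimates: tuple[WindowEstimate, ...]
    window_s: float
    overlap: float

    def __len__(self) -> int:
        return len(self.estimates)

    def __iter__(self):
        return iter(self.estimates)

    @property
    def hop_s(self) -> float:
        return self.window_s * (1.0 - self.overlap)

    @property
    def t_centers(self) -> np.ndarray:
        return np.array([e.t_center for e in self.estimates])

    @property
    def h_hats(self) -> np.ndarray:
        return np.array([e.h_hat for e in self.estimates])

    @property
    def f_m_hats(self) -> np.ndarray:
        return np.array([e.f_m_hat for e in self.estimates])


@dataclass(frozen=True)
class OscillationZone:
    """A detected interval of pathological envelope oscillation."""

    start_s: float
    end_s: float
    mean_h: float
    max_h: float

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


#: Three-class patient labels.
CSR_CSA = "CSR_CSA"
PB = "PB"
NON_CSR = "NON_CSR"

DIAGNOSIS_LABELS = (CSR_CSA, PB, NON_CSR)


@dataclass(frozen=True)
class Diagnosis:
    """Final per-recording classification with its supporting statistics."""

    label: str
    total_oscillation_s: float
    longest_episode_s: float
    h_bar: float

    def __post_init__(self) -> None:
        if self.label not in DIAGNOSIS_LABELS:
            raise ValueError(f"unknown diagnosis label {self.label!r}")
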