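"""Synthetic ventilation signals under the amplitude-modulation model.

Ventilation during Cheyne-Stokes respiration (CSR) is modelled as an
amplitude-modulated carrier: the carrier is the breath-by-breath airflow
oscillation (0.25--0.33 Hz in adults) and the modulation signal is the slow
crescendo--decrescendo envelope (8--30 mHz).  The modulated signal is

    y(t) = env(t) * H(env(t)) * c(t),
    env(t) = A_c * (1 + h * cos(2*pi*f_m*t + phi_m)),

with ``H`` the Heaviside step.  For modulation index ``h <= 1`` the clipping
is inactive; for ``h > 1`` (over-modulation) the envelope is clipped at zero
and produces central apneas whose duration follows in closed form from
``h`` and ``f_m``.

The carrier ``c(t)`` is either a pure cosine or a breath-shaped waveform
(fast half-sine inspiration, slower and shallower expiration) with optional
cycle-to-cycle period jitter, which makes the breath-segmentation problem
realistically hard.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .types import CSRParams, Segment, SyntheticRecording, TimeSeries

__all__ = [
    "modulate",
    "apnea_duration",
    "build_recording",
    "fig1_schedule",
    "write_signal_csv",
    "write_truth_csv",
    "write_schedule_json",
    "read_schedule_yaml",
]

#: Pathological modulation-frequency band (Hz) used for ground-truth labels.
F_BAND = (0.008, 0.030)

#: Modulation-index threshold separating flat from oscillating envelopes.
H0_DEFAULT = 0.12

#: Fraction of the breath cycle spent on inspiration for the breath-shaped
#: carrier; expiration fills the rest at reduced depth so each cycle has
#: zero mean.
_INSP_FRACTION = 0.4


def envelope_of(params: CSRParams, t: np.ndarray) -> np.ndarray:
    """Unclipped model envelope ``A_c * (1 + h cos(2 pi f_m t + phi_m))``."""
    return params.a_c * (
        1.0 + params.h * np.cos(2.0 * np.pi * params.f_m * t + params.phi_m)
    )


def modulate(
    params: CSRParams, duration_s: float, fs: float, start_time: float = 0.0
) -> TimeSeries:
    """Sample the amplitude-modulated ventilation model with a cosine carrier.

    Returns ``env(t) * H(env(t)) * cos(2 pi f_c t)`` on ``duration_s``
    seconds at rate ``fs``.  The Heaviside clipping only bites for
    ``h > 1``, in which case the signal contains one apnea (exact-zero run)
    per modulation period.
    """
    if not duration_s > 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    if not fs > 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    if fs < 4.0 * params.f_c:
        raise ValueError(
            f"fs={fs} Hz cannot resolve carrier f_c={params.f_c} Hz (need >= 4*f_c)"
        )
    n = int(round(duration_s * fs))
    t = start_time + np.arange(n) / fs
    env = envelope_of(params, t)
    clipped = np.where(env > 0, env, 0.0)
    y = clipped * np.cos(2.0 * np.pi * params.f_c * t)
    return TimeSeries(values=y, sampling_rate=fs, start_time=start_time)


def apnea_duration(h: float, f_m: float) -> float:
    """Closed-form duration (s) of the apnea produced by over-modulation.

    The envelope ``1 + h cos(theta)`` is negative (hence clipped to zero) on
    an arc of width ``2*(pi - arccos(-1/h))`` per cycle, giving

        delta = (pi - arccos(-1/h)) / (pi * f_m).

    For ``h <= 1`` the envelope never goes negative and the duration is 0.
    As ``h`` grows the apnea approaches half the modulation period.
    """
    if not f_m > 0:
        raise ValueError(f"f_m must be > 0, got {f_m}")
    if h < 0:
        raise ValueError(f"h must be >= 0, got {h}")
    if h <= 1.0:
        return 0.0
    return (math.pi - math.acos(-1.0 / h)) / (math.pi * f_m)


def _breath_cycle_starts(
    duration_s: float, f_c: float, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Start times of consecutive breath cycles covering [0, duration_s]."""
    nominal = 1.0 / f_c
    starts = [0.0]
    while starts[-1] < duration_s:
        period = nominal * (1.0 + jitter * rng.uniform(-1.0, 1.0))
        starts.append(starts[-1] + period)
    return np.asarray(starts)


def _breath_waveform(phase: np.ndarray) -> np.ndarray:
    """Breath-shaped carrier over one cycle, ``phase`` in [0, 1).

    A raised half-sine inspiration on the first ``_INSP_FRACTION`` of the
    cycle followed by a longer, shallower expiration half-sine; the
    expiration depth balances the inspiration lobe so each cycle integrates
    to zero and the signal is baseline-centred.
    """
    d = _INSP_FRACTION
    depth = d / (1.0 - d)
    out = np.where(
        phase < d,
        np.sin(np.pi * phase / d),
        -depth * np.sin(np.pi * (phase - d) / (1.0 - d)),
    )
    return out


def _validate_schedule(schedule: Sequence[Segment]) -> None:
    if not schedule:
        raise ValueError("schedule must contain at least one segment")
    for prev, cur in zip(schedule, schedule[1:]):
        if cur.start_s < prev.end_s:
            raise ValueError(
                f"schedule segments overlap or are unsorted at t={cur.start_s}"
            )
        if cur.start_s != prev.end_s:
            raise ValueError(
                f"schedule has a hole between t={prev.end_s} and t={cur.start_s}"
            )
    if schedule[0].start_s != 0.0:
        raise ValueError("schedule must start at t=0")


def _segment_phases(schedule: Sequence[Segment]) -> list[float]:
    """Starting modulation phase of each segment, chosen for continuity.

    The first segment uses its own ``phi_m``.  At every boundary the next
    segment's phase is picked so the envelope value is continuous whenever
    the new parameters can reach the outgoing value (the new phase starts
    on the rising limb, i.e. a crescendo onset); when they cannot — e.g. a
    drop back to a flat envelope mid-swing — the nearest attainable value
    is used and the envelope steps, as a genuine regime change does.
    """
    phases = [schedule[0].params.phi_m]
    for prev, cur in zip(schedule, schedule[1:]):
        p_prev, p_cur = prev.params, cur.params
        theta_end = phases[-1] + 2.0 * np.pi * p_prev.f_m * prev.duration
        env_end = p_prev.a_c * (1.0 + p_prev.h * math.cos(theta_end))
        if p_cur.h > 0:
            c = (env_end / p_cur.a_c - 1.0) / p_cur.h
            phases.append(-math.acos(min(1.0, max(-1.0, c))))
        else:
            phases.append(0.0)
    return phases


def _schedule_envelope(schedule: Sequence[Segment], t: np.ndarray) -> np.ndarray:
    """Piecewise model envelope, continuous across regime boundaries.

    Within each segment the envelope follows that segment's parameters;
    segment starting phases come from :func:`_segment_phases`.  Samples at
    or beyond the final boundary extrapolate the last segment.
    """
    env = np.zeros_like(t)
    phases = _segment_phases(schedule)
    for seg, phase in zip(schedule, phases):
        p = seg.params
        mask = (t >= seg.start_s) & (t < seg.end_s)
        theta = phase + 2.0 * np.pi * p.f_m * (t[mask] - seg.start_s)
        env[mask] = p.a_c * (1.0 + p.h * np.cos(theta))
    last, phase = schedule[-1], phases[-1]
    mask = t >= last.end_s
    if mask.any():
        p = last.params
        theta = phase + 2.0 * np.pi * p.f_m * (t[mask] - last.start_s)
        env[mask] = p.a_c * (1.0 + p.h * np.cos(theta))
    return env


def _params_at(schedule: Sequence[Segment], t: float) -> CSRParams:
    for seg in schedule:
        if seg.start_s <= t < seg.end_s:
            return seg.params
    return schedule[-1].params


def _truth_minutes(
    schedule: Sequence[Segment], duration_s: float, h0: float
) -> tuple[str, ...]:
    """Per-minute labels: oscillating iff >= 30 s of the minute is pathological."""
    n_minutes = int(duration_s // 60.0)
    labels = []
    for m in range(n_minutes):
        m0, m1 = 60.0 * m, 60.0 * (m + 1)
        covered = 0.0
        for seg in schedule:
            p = seg.params
            if p.h >= h0 and F_BAND[0] <= p.f_m <= F_BAND[1]:
                covered += max(0.0, min(m1, seg.end_s) - max(m0, seg.start_s))
        labels.append("oscillating" if covered >= 30.0 else "normal")
    return tuple(labels)


def build_recording(
    schedule: Sequence[Segment],
    fs: float = 25.0,
    noise_sd: float = 0.0,
    breath_jitter: float = 0.0,
    seed: int = 0,
    carrier: Literal["cosine", "breath"] = "cosine",
    h0: float = H0_DEFAULT,
) -> SyntheticRecording:
    """Simulate a multi-regime ventilation recording with ground truth.

    The schedule is a contiguous, sorted list of constant-parameter
    segments starting at t=0.  The envelope is built with modulation-phase
    continuity across segment boundaries and clipped at zero
    (over-modulation -> apneas); the carrier is either a pure cosine or a
    jittered breath-shaped waveform; zero-mean Gaussian noise of the given
    SD is added last.  Output is a pure function of the arguments and seed.
    """
    _validate_schedule(schedule)
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if not 0.0 <= breath_jitter < 0.5:
        raise ValueError(f"breath_jitter must be in [0, 0.5), got {breath_jitter}")

    rng = np.random.default_rng(seed)
    duration_s = schedule[-1].end_s
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    env = _schedule_envelope(schedule, t)
    env_clipped = np.where(env > 0, env, 0.0)

    peak_times: list[float] = []
    if carrier == "cosine":
        # carrier phase continuity across possible f_c changes
        phase = np.zeros(n)
        theta0 = 0.0
        for seg in schedule:
            mask = (t >= seg.start_s) & (t < min(seg.end_s, duration_s))
            phase[mask] = theta0 + 2.0 * np.pi * seg.params.f_c * (
                t[mask] - seg.start_s
            )
            theta0 += 2.0 * np.pi * seg.params.f_c * seg.duration
        car = np.cos(phase)
        # true breath peaks: carrier maxima (phase = 2*pi*k) with open airway
        theta0 = 0.0
        for seg in schedule:
            f_c = seg.params.f_c
            k0 = math.ceil((theta0 / (2 * math.pi)) - 1e-9)
            k = k0
            while True:
                tp = seg.start_s + ((2 * math.pi * k) - theta0) / (2 * math.pi * f_c)
                if tp >= seg.end_s - 1e-9 or tp >= duration_s:
                    break
                if tp >= seg.start_s - 1e-9:
                    peak_times.append(tp)
                k += 1
            theta0 += 2.0 * np.pi * f_c * seg.duration
    elif carrier == "breath":
        starts = _breath_cycle_starts(
            duration_s, schedule[0].params.f_c, breath_jitter, rng
        )
        car = np.zeros(n)
        for c0, c1 in zip(starts, starts[1:]):
            mask = (t >= c0) & (t < c1)
            phase = (t[mask] - c0) / (c1 - c0)
            car[mask] = _breath_waveform(phase)
            tp = c0 + _INSP_FRACTION / 2.0 * (c1 - c0)
            if tp < duration_s:
                peak_times.append(tp)
    else:
        raise ValueError(f"unknown carrier {carrier!r}")

    y = env_clipped * car
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)

    # a breath only exists where the airway is open at its peak
    kept = [
        tp
        for tp in peak_times
        if _schedule_envelope(schedule, np.array([tp]))[0] > 1e-9
    ]

    return SyntheticRecording(
        signal=TimeSeries(values=y, sampling_rate=fs),
        schedule=tuple(schedule),
        truth_minutes=_truth_minutes(schedule, duration_s, h0),
        breath_peaks=np.asarray(kept),
    )


def fig1_schedule(
    f_m: float = 0.01, f_c: float = 0.3, a_c: float = 1.0
) -> tuple[Segment, ...]:
    """Reference 15-minute scenario: normal, then mild (h=0.5), then severe
    over-modulated (h=1.5) Cheyne-Stokes respiration."""
    return (
        Segment(0.0, 120.0, CSRParams(a_c=a_c, f_c=f_c, h=0.0, f_m=f_m)),
        Segment(120.0, 660.0, CSRParams(a_c=a_c, f_c=f_c, h=0.5, f_m=f_m)),
        Segment(660.0, 900.0, CSRParams(a_c=a_c, f_c=f_c, h=1.5, f_m=f_m)),
    )


# ---------------------------------------------------------------------------
# writers / schedule IO


def write_signal_csv(ts: TimeSeries, path: str | Path) -> None:
    """Two-column CSV ``time_s,value`` with header."""
    import pandas as pd

    # %.17g preserves IEEE doubles exactly, so reading back is bitwise
    pd.DataFrame({"time_s": ts.times, "value": ts.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_truth_csv(rec: SyntheticRecording, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "minute_index": np.arange(len(rec.truth_minutes)),
            "label": list(rec.truth_minutes),
        }
    ).to_csv(path, index=False)


def write_schedule_json(schedule: Sequence[Segment], path: str | Path) -> None:
    payload = [
        {
            "start_s": seg.start_s,
            "end_s": seg.end_s,
            "a_c": seg.params.a_c,
            "f_c": seg.params.f_c,
            "h": seg.params.h,
            "f_m": seg.params.f_m,
            "phi_m": seg.params.phi_m,
        }
        for seg in schedule
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_schedule_yaml(path: str | Path) -> tuple[Segment, ...]:
    """Load a schedule from YAML: a list of mappings with start_s, end_s and
    model parameters (a_c, f_c, h, f_m, phi_m; missing ones take defaults)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list):
        raise ValueError("schedule YAML must be a list of segments")
    segments = []
    for entry in raw:
        params = CSRParams(
            a_c=float(entry.get("a_c", 1.0)),
            f_c=float(entry.get("f_c", 0.3)),
            h=float(entry.get("h", 0.0)),
            f_m=float(entry.get("f_m", 0.015)),
            phi_m=float(entry.get("phi_m", 0.0)),
        )
        segments.append(Segment(float(entry["start_s"]), float(entry["end_s"]), params))
    return tuple(segments)
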