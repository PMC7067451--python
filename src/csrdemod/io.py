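"""Signal and artifact readers/writers.

The interchange format is a two-column CSV ``time_s,value`` with a header;
timestamps must be uniform (checked to 1e-6 s).  Single channels of EDF
recordings can be read when ``mne`` is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BreathSegmentation,
    Diagnosis,
    EnvelopeSignal,
    EstimateTrack,
    OscillationZone,
    TimeSeries,
)

__all__ = [
    "read_signal",
    "read_signal_csv",
    "read_signal_edf",
    "read_annotations_csv",
    "write_peaks_csv",
    "write_gaps_csv",
    "write_envelope_csv",
    "write_track_csv",
    "write_zones_csv",
    "write_diagnosis_json",
]

_UNIFORMITY_TOL_S = 1e-6


def read_signal_csv(path: str | Path) -> TimeSeries:
    """Read a uniform two-column ``time_s,value`` CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    # round_trip parsing keeps values bitwise-identical to what was written
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.max(np.abs(dt - dt[0])) > _UNIFORMITY_TOL_S or dt[0] <= 0:
        raise ValueError(
            f"{path}: non-uniform sampling (timestamps must be evenly spaced "
            f"to within {_UNIFORMITY_TOL_S} s and increasing)"
        )
    return TimeSeries(
        values=df["value"].to_numpy(dtype=float),
        sampling_rate=1.0 / dt[0],
        start_time=float(t[0]),
    )


def read_signal_edf(path: str | Path, channel: str) -> TimeSeries:
    """Read one named channel of an EDF file (requires ``mne``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "EDF input requires the optional dependency 'mne' "
            "(pip install csrdemod[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(
            f"{path}: channel {channel!r} not found; available: {raw.ch_names}"
        )
    data = raw.get_data(picks=[channel])[0]
    return TimeSeries(values=data, sampling_rate=float(raw.info["sfreq"]))


def read_signal(
    path: str | Path, fmt: str | None = None, channel: str | None = None
) -> TimeSeries:
    """Dispatch on format (csv/edf), inferring from the suffix when absent."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt == "csv":
        return read_signal_csv(path)
    if fmt == "edf":
        if channel is None:
            raise ValueError("EDF input requires a channel name")
        return read_signal_edf(path, channel)
    raise ValueError(f"unknown signal format {fmt!r}")


def read_annotations_csv(path: str | Path) -> list[str]:
    """Per-minute expert annotation CSV ``minute_index,label``."""
    df = pd.read_csv(path)
    for col in ("minute_index", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.sort_values("minute_index")
    idx = df["minute_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        raise ValueError(f"{path}: minute_index must be contiguous from 0")
    return [str(v) for v in df["label"]]


def write_peaks_csv(seg: BreathSegmentation, path: str | Path) -> None:
    pd.DataFrame({"time_s": seg.peak_times, "amplitude": seg.peak_amps}).to_csv(
        path, index=False
    )


def write_gaps_csv(seg: BreathSegmentation, path: str | Path) -> None:
    pd.DataFrame(
        {
            "start_s": [g[0] for g in seg.gaps],
            "end_s": [g[1] for g in seg.gaps],
        }
    ).to_csv(path, index=False)


def write_envelope_csv(env: EnvelopeSignal, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": env.series.times, "env": env.series.values}
    ).to_csv(path, index=False)


def write_track_csv(track: EstimateTrack, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_center_s": [e.t_center for e in track.estimates],
            "h_hat": [e.h_hat for e in track.estimates],
            "f_m_hat": [e.f_m_hat for e in track.estimates],
            "A_c_hat": [e.a_c_hat for e in track.estimates],
            "valid": [int(e.valid) for e in track.estimates],
        }
    ).to_csv(path, index=False)


def write_zones_csv(zones: list[OscillationZone], path: str | Path) -> None:
    pd.DataFrame(
        {
            "start_s": [z.start_s for z in zones],
            "end_s": [z.end_s for z in zones],
            "mean_h": [z.mean_h for z in zones],
            "max_h": [z.max_h for z in zones],
        }
    ).to_csv(path, index=False)


def write_diagnosis_json(diag: Diagnosis, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "label": diag.label,
                "total_oscillation_s": diag.total_oscillation_s,
                "longest_episode_s": diag.longest_episode_s,
                "h_bar": diag.h_bar,
            },
            indent=2,
        )
    )
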