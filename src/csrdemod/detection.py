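"""Oscillation-zone detection and three-class patient classification.

A window is flagged pathological when its estimate is valid, the modulation
index reaches the oscillation threshold ``h0`` and the modulation frequency
falls in the Cheyne-Stokes band [8, 30] mHz — both conditions are required:
a deep modulation outside the band, or an in-band frequency with a flat
envelope, is not an oscillation zone.  Runs of flagged windows persisting
for at least one minute become zones (the persistence rule suppresses
artifact-triggered short false positives).

The final per-recording diagnosis follows sleep-medicine duration rules:
more than 10 minutes of total oscillation with at least one 6-minute
episode makes the recording pathological — Cheyne-Stokes respiration with
central apneas (CSR-CSA) when the mean modulation index over the zones
exceeds 1 (over-modulation, i.e. true apneas), periodic breathing (PB,
early-stage CSR) otherwise; anything less is non-CSR.  The mean modulation
index doubles as a degree-of-certainty indicator.
"""

from __future__ import annotations

import numpy as np

from .types import CSR_CSA, NON_CSR, PB, Diagnosis, EstimateTrack, OscillationZone

__all__ = ["flag_windows", "build_zones", "classify_patient"]

#: Oscillation threshold on the modulation index (set by ROC analysis
#: against expert minute annotations).
H0 = 0.12

#: Pathological modulation-frequency band, Hz.
F_BAND = (0.008, 0.030)

#: Minimum zone span (persistence rule), seconds.
MIN_ZONE_S = 60.0

#: Classification durations: total oscillation and longest single episode.
TOTAL_MIN_S = 600.0
EPISODE_MIN_S = 360.0

#: Over-modulation threshold separating apneic CSR from periodic breathing.
H_APNEA = 1.0


def flag_windows(
    track: EstimateTrack,
    h0: float = H0,
    f_band: tuple[float, float] = F_BAND,
) -> np.ndarray:
    """Boolean flag per window: valid, h_hat >= h0 and f_m_hat in the band.

    Both threshold comparisons are inclusive.
    """
    flags = np.array(
        [
            e.valid and e.h_hat >= h0 and f_band[0] <= e.f_m_hat <= f_band[1]
            for e in track.estimates
        ],
        dtype=bool,
    )
    return flags


def build_zones(
    flags: np.ndarray,
    track: EstimateTrack,
    min_zone_s: float = MIN_ZONE_S,
) -> list[OscillationZone]:
    """Convert flagged-window runs into oscillation zones.

    A maximal run of flagged windows spans [first window start, last window
    end); runs shorter than ``min_zone_s`` are discarded, and zones whose
    separation is smaller than one hop (adjacent up to estimation
    granularity) are merged.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(track.estimates):
        raise ValueError("flags and track must have equal length")
    half = track.window_s / 2.0
    hop = track.hop_s

    runs: list[tuple[int, int]] = []  # [i, j) in window indices
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j < len(flags) and flags[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1

    zones: list[OscillationZone] = []
    for i, j in runs:
        start = track.estimates[i].t_center - half
        end = track.estimates[j - 1].t_center + half
        if end - start < min_zone_s:
            continue
        hs = np.array([track.estimates[k].h_hat for k in range(i, j)])
        zones.append(
            OscillationZone(
                start_s=start, end_s=end,
                mean_h=float(hs.mean()), max_h=float(hs.max()),
            )
        )

    merged: list[OscillationZone] = []
    for z in zones:
        if merged and z.start_s - merged[-1].end_s < hop:
            prev = merged[-1]
            w_prev = prev.end_s - prev.start_s
            w_cur = z.end_s - z.start_s
            merged[-1] = OscillationZone(
                start_s=prev.start_s,
                end_s=z.end_s,
                mean_h=(prev.mean_h * w_prev + z.mean_h * w_cur) / (w_prev + w_cur),
                max_h=max(prev.max_h, z.max_h),
            )
        else:
            merged.append(z)
    return merged


def classify_patient(
    zones: list[OscillationZone],
    total_min_s: float = TOTAL_MIN_S,
    episode_min_s: float = EPISODE_MIN_S,
    h_apnea: float = H_APNEA,
) -> Diagnosis:
    """Three-class diagnosis from the detected oscillation zones.

    With total oscillation T, longest episode E and duration-weighted mean
    modulation index h_bar over the zones: CSR-CSA when T > 10 min,
    E >= 6 min and h_bar > 1; PB when only the duration conditions hold;
    non-CSR otherwise.
    """
    total = float(sum(z.duration for z in zones))
    longest = float(max((z.duration for z in zones), default=0.0))
    if total > 0:
        h_bar = float(
            sum(z.mean_h * z.duration for z in zones) / total
        )
    else:
        h_bar = 0.0
    if total > total_min_s and longest >= episode_min_s:
        label = CSR_CSA if h_bar > h_apnea else PB
    else:
        label = NON_CSR
    return Diagnosis(
        label=label,
        total_oscillation_s=total,
        longest_episode_s=longest,
        h_bar=h_bar,
    )
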