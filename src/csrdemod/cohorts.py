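"""Reference synthetic cohorts for validating the detection pipeline.

No clinical recordings ship with the package, so validation runs on
simulated cohorts that mirror the profiles seen in CSR screening studies:

* severe CSR — over-modulated oscillation (h = 1.5) sustained through the
  whole recording, as severe patients typically present;
* periodic breathing — a long mild-oscillation episode (h = 0.5) after a
  normal start;
* normal breathing — no envelope modulation, but with the slow ~±15%
  tidal-volume wander real subjects show (perfectly flat normals would make
  any tiny threshold look adequate);
* short-oscillation normals — a burst of oscillation too brief to qualify
  as CSR or PB.

All cohorts use 30-minute recordings at 25 Hz with the breath-shaped
carrier, 10% breath-period jitter and additive noise of SD 0.05 (in units
of the carrier amplitude) — the package's standard simulated operating
conditions.
"""

from __future__ import annotations

import numpy as np

from .simulator import build_recording
from .types import CSRParams, Segment, SyntheticRecording

__all__ = ["variable_normal_schedule", "study_cohort", "roc_cohort"]

#: Standard simulated operating conditions.
NOISE_SD = 0.05
BREATH_JITTER = 0.1
FS = 25.0
DURATION_S = 1800.0

#: Modulation frequencies (Hz) assigned across the severe-CSR recordings,
#: spanning the pathological band.
CSR_F_MS = (0.010, 0.0125, 0.016, 0.020)


def _p(h: float = 0.0, f_m: float = 0.0125, a_c: float = 1.0) -> CSRParams:
    return CSRParams(a_c=a_c, f_c=0.3, h=h, f_m=f_m)


def variable_normal_schedule(
    seed: int, duration_s: float = DURATION_S
) -> tuple[Segment, ...]:
    """Normal breathing with slow amplitude wander.

    Random-length stretches (1-3 min) whose carrier amplitude varies in
    [0.85, 1.15], emulating the spontaneous tidal-volume variability of
    healthy subjects.
    """
    rng = np.random.default_rng(seed)
    segs, t = [], 0.0
    while t < duration_s:
        end = min(t + rng.uniform(60.0, 180.0), duration_s)
        segs.append(Segment(t, end, _p(a_c=rng.uniform(0.85, 1.15))))
        t = end
    return tuple(segs)


def study_cohort(
    seed: int = 1,
    noise_sd: float = NOISE_SD,
    breath_jitter: float = BREATH_JITTER,
) -> list[tuple[str, SyntheticRecording]]:
    """Fifteen 30-minute recordings: 4 severe CSR, 1 PB, 10 non-CSR.

    Returns (designed label, recording) pairs.  The non-CSR group holds
    eight variable normals and two recordings with a 4-minute oscillation
    burst (too short to classify as pathological).
    """
    specs: list[tuple[str, tuple[Segment, ...]]] = []
    for f_m in CSR_F_MS:
        specs.append(
            ("CSR_CSA", (Segment(0.0, DURATION_S, _p(h=1.5, f_m=f_m)),))
        )
    specs.append(
        (
            "PB",
            (
                Segment(0.0, 600.0, _p()),
                Segment(600.0, DURATION_S, _p(h=0.5, f_m=0.0125)),
            ),
        )
    )
    for k in range(8):
        specs.append(("NON_CSR", variable_normal_schedule(seed + 1000 + k)))
    for k in range(2):
        specs.append(
            (
                "NON_CSR",
                (
                    Segment(0.0, 600.0, _p()),
                    Segment(600.0, 840.0, _p(h=0.6, f_m=0.015)),
                    Segment(840.0, DURATION_S, _p()),
                ),
            )
        )
    return [
        (
            label,
            build_recording(
                sched,
                fs=FS,
                noise_sd=noise_sd,
                breath_jitter=breath_jitter,
                seed=seed + i,
                carrier="breath",
            ),
        )
        for i, (label, sched) in enumerate(specs)
    ]


def roc_cohort(
    seed: int = 1,
    noise_sd: float = NOISE_SD,
    breath_jitter: float = BREATH_JITTER,
    positive_hs: tuple[float, ...] = (0.3, 0.5, 0.8, 1.0, 1.2, 1.5),
    n_negative: int = 4,
) -> list[tuple[SyntheticRecording, list[str]]]:
    """Cohort for threshold (ROC) analysis.

    One recording per positive modulation index, oscillating throughout,
    plus variable-normal negatives.  Returns (recording, per-minute
    reference labels) pairs using the annotation vocabulary
    (``csr_pb`` / ``normal``).
    """
    out = []
    for i, h in enumerate(positive_hs):
        rec = build_recording(
            (Segment(0.0, DURATION_S, _p(h=h)),),
            fs=FS,
            noise_sd=noise_sd,
            breath_jitter=breath_jitter,
            seed=seed + i,
            carrier="breath",
        )
        ref = [
            "csr_pb" if m == "oscillating" else "normal" for m in rec.truth_minutes
        ]
        out.append((rec, ref))
    for k in range(n_negative):
        rec = build_recording(
            variable_normal_schedule(seed + 50 + k),
            fs=FS,
            noise_sd=noise_sd,
            breath_jitter=breath_jitter,
            seed=seed + 50 + k,
            carrier="breath",
        )
        out.append((rec, ["normal"] * int(DURATION_S // 60)))
    return out
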