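"""Per-minute scoring, ROC threshold selection and cohort confusion matrix.

Detections are compared with expert-style annotations minute by minute.
The reference annotation uses three classes — CSR/PB, no abnormal pattern,
and erratic breathing possibly PB — and binary scoring is defined on the
first two only: erratic minutes are excluded from the sensitivity /
specificity counts and tallied separately.

Two "specificity" variants are reported side by side.  The formula printed
with the method's original performance figures, ``TP / (TP + FP)``, is the
conventional positive predictive value; the conventional specificity is
``TN / (TN + FP)``.  Both are computed (``sp_as_printed`` and
``specificity_conventional``); ROC analysis uses the conventional one,
since an ROC axis requires a true-negative-based rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import build_zones, flag_windows
from .types import DIAGNOSIS_LABELS, EstimateTrack, OscillationZone

__all__ = [
    "PerformanceReport",
    "minutes_from_zones",
    "se_sp",
    "roc_select_threshold",
    "confusion_matrix",
    "OSC", "NORMAL", "REF_POSITIVE", "REF_NEGATIVE", "REF_ERRATIC",
]

#: Predicted minute labels.
OSC = "oscillation"
NORMAL = "normal"

#: Reference minute labels.
REF_POSITIVE = "csr_pb"
REF_NEGATIVE = "normal"
REF_ERRATIC = "erratic"

#: Minimum zone coverage (s) for a minute to be called an oscillation.
MIN_COVER_S = 30.0


@dataclass(frozen=True)
class PerformanceReport:
    """Minute-level detection performance counts and rates (percent)."""

    tp: int
    fp: int
    fn: int
    tn: int
    excluded: int = 0

    @property
    def se(self) -> float:
        """Sensitivity TP/(TP+FN), percent."""
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def sp_as_printed(self) -> float:
        """TP/(TP+FP) in percent — the positive predictive value."""
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def specificity_conventional(self) -> float:
        """TN/(TN+FP), percent."""
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else float("nan")

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "excluded_erratic": self.excluded,
            "Se": self.se,
            "sp_as_printed": self.sp_as_printed,
            "specificity_conventional": self.specificity_conventional,
        }


def minutes_from_zones(
    zones: list[OscillationZone],
    n_minutes: int,
    min_cover_s: float = MIN_COVER_S,
) -> list[str]:
    """Predicted per-minute labels: oscillation iff zones cover >= 30 s of
    the minute (majority rule)."""
    if n_minutes < 1:
        raise ValueError(f"n_minutes must be >= 1, got {n_minutes}")
    labels = []
    for m in range(n_minutes):
        m0, m1 = 60.0 * m, 60.0 * (m + 1)
        covered = sum(
            max(0.0, min(m1, z.end_s) - max(m0, z.start_s)) for z in zones
        )
        labels.append(OSC if covered >= min_cover_s else NORMAL)
    return labels


def se_sp(pred: list[str], ref: list[str]) -> PerformanceReport:
    """Minute-level TP/FP/FN/TN against the reference annotation.

    A true positive is a minute the detector marks as oscillation that the
    reference labels CSR/PB; erratic reference minutes are excluded from
    the counts.
    """
    if len(pred) != len(ref):
        raise ValueError(
            f"prediction ({len(pred)}) and reference ({len(ref)}) lengths differ"
        )
    tp = fp = fn = tn = excl = 0
    for p, r in zip(pred, ref):
        if r == REF_ERRATIC:
            excl += 1
            continue
        if r not in (REF_POSITIVE, REF_NEGATIVE):
            raise ValueError(f"unknown reference label {r!r}")
        if p not in (OSC, NORMAL):
            raise ValueError(f"unknown predicted label {p!r}")
        positive = p == OSC
        if r == REF_POSITIVE:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return PerformanceReport(tp=tp, fp=fp, fn=fn, tn=tn, excluded=excl)


@dataclass(frozen=True)
class RocPoint:
    h0: float
    se: float
    sp: float

    @property
    def youden(self) -> float:
        return self.se + self.sp - 100.0


@dataclass(frozen=True)
class RocResult:
    h0: float
    curve: tuple[RocPoint, ...] = field(default_factory=tuple)


def roc_select_threshold(
    tracks: list[EstimateTrack],
    references: list[list[str]],
    grid: np.ndarray,
    f_band: tuple[float, float] = (0.008, 0.030),
    min_zone_s: float = 60.0,
    min_cover_s: float = MIN_COVER_S,
) -> RocResult:
    """Youden-optimal modulation-index threshold over a candidate grid.

    For each candidate ``h0`` the full zone machinery is re-run on every
    recording's estimate track, minutes are pooled across recordings, and
    sensitivity plus conventional specificity are computed.  Returns the
    smallest grid value maximizing the Youden index Se + Sp - 100, with the
    whole curve.
    """
    if len(tracks) != len(references):
        raise ValueError("need one reference label track per estimate track")
    flat = [r for ref in references for r in ref if r != REF_ERRATIC]
    if not flat or all(r == flat[0] for r in flat):
        raise ValueError(
            "reference annotations are single-class; ROC analysis is undefined"
        )
    grid = np.sort(np.asarray(grid, dtype=float))
    points = []
    for h0 in grid:
        preds, refs = [], []
        for track, ref in zip(tracks, references):
            flags = flag_windows(track, h0=h0, f_band=f_band)
            zones = build_zones(flags, track, min_zone_s=min_zone_s)
            preds.extend(
                minutes_from_zones(zones, len(ref), min_cover_s=min_cover_s)
            )
            refs.extend(ref)
        rep = se_sp(preds, refs)
        points.append(RocPoint(h0=float(h0), se=rep.se, sp=rep.specificity_conventional))
    youden = np.array([p.youden for p in points])
    best = int(np.flatnonzero(youden == youden.max())[0])
    return RocResult(h0=points[best].h0, curve=tuple(points))


def confusion_matrix(
    predicted: list[str], reference: list[str]
) -> pd.DataFrame:
    """3x3 recording-level confusion matrix.

    Rows are predicted classes, columns the expert reference classes, in
    the order (CSR-CSA, PB, non-CSR); counts sum to the number of
    recordings.
    """
    if len(predicted) != len(reference):
        raise ValueError("predicted and reference label lists differ in length")
    for lab in list(predicted) + list(reference):
        if lab not in DIAGNOSIS_LABELS:
            raise ValueError(f"unknown diagnosis label {lab!r}")
    mat = pd.DataFrame(
        0, index=list(DIAGNOSIS_LABELS), columns=list(DIAGNOSIS_LABELS), dtype=int
    )
    for p, r in zip(predicted, reference):
        mat.loc[p, r] += 1
    return mat
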