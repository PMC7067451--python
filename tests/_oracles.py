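"""Independent oracles used to cross-check the implementation.

These deliberately re-derive expected results by routes independent of the
library code paths they validate: exhaustive dynamic programming for the
penalized segmentation, numerical Fourier quadrature for the clipped
envelope, and direct interval arithmetic for minute labelling.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad


def dp_segmentation(x: np.ndarray, beta: float, min_size: int = 3) -> list[int]:
    """Exhaustive O(n^2) penalized segmentation (no pruning).

    Minimizes sum of per-section straight-line RSS plus ``beta`` per change
    point, considering every admissible split; returns interior breakpoint
    indices.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = np.arange(n, dtype=float)
    z = np.zeros(1)
    ct = np.concatenate([z, np.cumsum(m)])
    cy = np.concatenate([z, np.cumsum(x)])
    ctt = np.concatenate([z, np.cumsum(m * m)])
    cty = np.concatenate([z, np.cumsum(m * x)])
    cyy = np.concatenate([z, np.cumsum(x * x)])

    def rss(i: np.ndarray, j: int) -> np.ndarray:
        k = j - i.astype(float)
        st, sy = ct[j] - ct[i], cy[j] - cy[i]
        stt, sty, syy = ctt[j] - ctt[i], cty[j] - cty[i], cyy[j] - cyy[i]
        a = stt - st * st / k
        b = sty - st * sy / k
        c = syy - sy * sy / k
        with np.errstate(divide="ignore", invalid="ignore"):
            out = c - np.where(a > 0, b * b / np.maximum(a, 1e-300), 0.0)
        return np.maximum(out, 0.0)

    f = np.full(n + 1, np.inf)
    f[0] = -beta
    last = np.zeros(n + 1, dtype=int)
    for s in range(min_size, n + 1):
        ts = np.arange(0, s - min_size + 1)
        ts = ts[(ts == 0) | (ts >= min_size)]
        vals = f[ts] + rss(ts, s) + beta
        b = int(np.argmin(vals))
        f[s] = vals[b]
        last[s] = ts[b]
    out = []
    s = n
    while s > 0:
        t = int(last[s])
        if t > 0:
            out.append(t)
        s = t
    return out[::-1]


def clipped_h_ratio(h: float) -> float:
    """Fundamental-to-DC Fourier coefficient ratio of max(0, 1 + h cos)."""

    def g(theta: float) -> float:
        return max(0.0, 1.0 + h * np.cos(theta))

    c0 = quad(g, 0, 2 * np.pi, limit=200)[0] / (2 * np.pi)
    c1 = quad(lambda th: g(th) * np.cos(th), 0, 2 * np.pi, limit=200)[0] / np.pi
    return c1 / c0


def minute_labels_from_intervals(
    intervals: list[tuple[float, float]], n_minutes: int, min_cover_s: float = 30.0
) -> list[str]:
    """Direct interval-overlap minute labelling."""
    labels = []
    for m in range(n_minutes):
        lo, hi = 60.0 * m, 60.0 * (m + 1)
        cov = sum(max(0.0, min(hi, b) - max(lo, a)) for a, b in intervals)
        labels.append("oscillation" if cov >= min_cover_s else "normal")
    return labels


def match_events(
    detected: np.ndarray, truth: np.ndarray, tol_s: float = 0.5
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of event times; returns (tp, fn, fp)."""
    truth = np.asarray(truth, dtype=float)
    used = np.zeros(len(truth), dtype=bool)
    tp = 0
    for d in np.asarray(detected, dtype=float):
        if len(truth) == 0:
            break
        i = int(np.argmin(np.abs(truth - d)))
        if abs(truth[i] - d) <= tol_s and not used[i]:
            used[i] = True
            tp += 1
    return tp, len(truth) - tp, len(detected) - tp
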