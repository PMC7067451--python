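"""Matrix Pencil demodulation of the ventilation envelope.

On each analysis window the envelope is modelled as a three-term sum of
complex exponentials,

    env(t) = a1 + a2 exp(j 2 pi f_m t) + a3 exp(-j 2 pi f_m t),

with ``a1 = A_c`` and ``a2 = conj(a3) = (A_c h / 2) exp(j phi_m)``.  The
Matrix Pencil method recovers the frequencies from the generalized
eigenvalues of a pair of shifted Hankel matrices built from the window
samples, after truncating their SVD to the model order; the complex
amplitudes follow from a linear least-squares fit.  The modulation index is
then ``h_hat = 2 |a2| / |a1|`` (or ``(|a2|+|a3|)/|a1|`` when the conjugate
pair is resolved asymmetrically under noise) and ``f_m_hat`` is the paired
frequency magnitude.

Estimates are produced over a sliding window, 2 min long with 80% overlap
by default: long enough for the sinusoidal model with locally constant
parameters to hold, short enough to track regime changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .types import EnvelopeSignal, EstimateTrack, TimeSeries, WindowEstimate

__all__ = [
    "PencilResult",
    "matrix_pencil",
    "window_params",
    "sliding_estimate",
]

logger = logging.getLogger(__name__)

#: Default model order: DC plus one conjugate pair.
ORDER = 3

#: Pencil parameter as a fraction of the window length (noise-robust range
#: is N/3 .. N/2).
PENCIL_RATIO = 1.0 / 3.0

#: Singular values below this ratio of the largest are treated as rank
#: collapse and the model order is reduced accordingly.
RANK_TOL = 1e-8

#: A DC component must sit within this band (Hz) of zero frequency.
DC_MAX_FREQ = 0.005


@dataclass(frozen=True)
class PencilResult:
    """Poles, frequencies (Hz) and complex amplitudes from one window."""

    poles: np.ndarray
    freqs: np.ndarray
    amps: np.ndarray
    reduced_order: bool


def matrix_pencil(
    window: TimeSeries,
    order: int = ORDER,
    pencil_ratio: float = PENCIL_RATIO,
) -> PencilResult:
    """Estimate ``order`` complex exponentials from one uniform window.

    Builds the Hankel matrix with pencil parameter ``L = round(ratio * N)``,
    truncates its SVD to ``order`` (fewer if the numerical rank collapses,
    flagged via ``reduced_order``), solves the shifted-subspace eigenvalue
    problem for the poles and a least-squares system for the amplitudes.
    Pole damping is discarded: frequencies are ``|angle(z)| / (2 pi dt)``
    signed by the angle, matching the undamped envelope model.
    """
    x = np.asarray(window.values, dtype=float)
    n = len(x)
    if n < 3 * order:
        raise ValueError(f"window of {n} samples is too short for order {order}")
    if not 0 < pencil_ratio < 1:
        raise ValueError(f"pencil_ratio must be in (0, 1), got {pencil_ratio}")
    if not np.any(x != 0.0):
        return PencilResult(
            poles=np.array([]), freqs=np.array([]), amps=np.array([]),
            reduced_order=True,
        )

    ell = int(round(pencil_ratio * n))
    ell = min(max(ell, order), n - order - 1)
    # Hankel data matrix of size (n - ell) x (ell + 1)
    y = scipy.linalg.hankel(x[: n - ell], x[n - ell - 1 :])
    _, svals, vh = np.linalg.svd(y, full_matrices=False)
    rank = int(np.sum(svals >= RANK_TOL * svals[0]))
    m = min(order, rank)
    reduced = m < order
    v = vh[:m, :].conj().T  # (ell + 1) x m right singular vectors
    v1 = v[:-1, :]
    v2 = v[1:, :]
    poles = np.linalg.eigvals(np.linalg.pinv(v1) @ v2)
    dt = window.dt
    freqs = np.angle(poles) / (2.0 * np.pi * dt)
    # undamped amplitudes from least squares on the unit-modulus poles
    z = np.exp(1j * np.angle(poles))
    vand = z[None, :] ** np.arange(n)[:, None]
    amps, *_ = np.linalg.lstsq(vand, x.astype(complex), rcond=None)
    # re-reference amplitudes from the window start to absolute time zero
    amps = amps * np.exp(-1j * 2.0 * np.pi * freqs * window.start_time)
    return PencilResult(poles=poles, freqs=freqs, amps=amps, reduced_order=reduced)


def window_params(
    result: PencilResult,
    t_center: float = 0.0,
    amplitude_floor: float = 0.0,
    dc_max_freq: float = DC_MAX_FREQ,
) -> WindowEstimate:
    """Convert pencil output to model parameters for one window.

    The DC term is the pole of smallest |frequency|; the remaining poles are
    a (possibly asymmetric) conjugate pair whose mean |frequency| gives
    ``f_m_hat``.  The estimate is invalid when no DC-like pole exists
    (min |f| above ``dc_max_freq``) or the DC amplitude is below
    ``amplitude_floor`` — the modulation index is a ratio and degenerates
    as the DC amplitude vanishes.
    """
    if len(result.freqs) == 0:
        return WindowEstimate(
            t_center=t_center, a_c_hat=0.0, h_hat=0.0, f_m_hat=0.0,
            phi_hat=0.0, valid=False,
        )
    order = np.argsort(np.abs(result.freqs))
    dc = order[0]
    if np.abs(result.freqs[dc]) > dc_max_freq:
        return WindowEstimate(
            t_center=t_center, a_c_hat=0.0, h_hat=0.0, f_m_hat=0.0,
            phi_hat=0.0, valid=False,
        )
    a1 = float(np.abs(result.amps[dc]))
    rest = order[1:]
    if len(rest) == 0:
        h_hat, f_m_hat, phi_hat = 0.0, 0.0, 0.0
    else:
        pair_amps = np.abs(result.amps[rest])
        pair_freqs = np.abs(result.freqs[rest])
        if len(rest) >= 2:
            h_num = float(pair_amps[0] + pair_amps[1])
            f_m_hat = float(np.mean(pair_freqs[:2]))
        else:
            h_num = 2.0 * float(pair_amps[0])
            f_m_hat = float(pair_freqs[0])
        pos = rest[np.argmax(result.freqs[rest])]
        phi_hat = float(np.angle(result.amps[pos]))
        h_hat = h_num / a1 if a1 > 0 else 0.0
    valid = a1 >= amplitude_floor and a1 > 0
    return WindowEstimate(
        t_center=t_center,
        a_c_hat=a1,
        h_hat=h_hat,
        f_m_hat=f_m_hat,
        phi_hat=phi_hat,
        valid=valid,
    )


def sliding_estimate(
    env: EnvelopeSignal | TimeSeries,
    window_s: float = 120.0,
    overlap: float = 0.8,
    order: int = ORDER,
    pencil_ratio: float = PENCIL_RATIO,
    amplitude_floor_frac: float = 0.01,
) -> EstimateTrack:
    """Sliding-window demodulation of the envelope.

    The hop is ``window_s * (1 - overlap)`` (24 s by default); each full
    window is passed to the pencil estimator as-is (no detrending — the DC
    term is part of the model), a trailing partial window is skipped, and
    validity uses an amplitude floor of ``amplitude_floor_frac`` times the
    recording's median envelope.
    """
    series = env.series if isinstance(env, EnvelopeSignal) else env
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    fs = series.sampling_rate
    n_win = int(round(window_s * fs))
    hop = max(1, int(round(window_s * (1.0 - overlap) * fs)))
    if len(series) < n_win:
        logger.warning(
            "envelope (%d samples) shorter than one %g-s window; empty track",
            len(series), window_s,
        )
        return EstimateTrack(estimates=(), window_s=window_s, overlap=overlap)
    floor = amplitude_floor_frac * float(np.median(series.values))
    estimates = []
    for start in range(0, len(series) - n_win + 1, hop):
        chunk = TimeSeries(
            values=series.values[start : start + n_win],
            sampling_rate=fs,
            start_time=series.start_time + start / fs,
        )
        t_center = chunk.start_time + window_s / 2.0
        result = matrix_pencil(chunk, order=order, pencil_ratio=pencil_ratio)
        estimates.append(
            window_params(result, t_center=t_center, amplitude_floor=floor)
        )
    return EstimateTrack(
        estimates=tuple(estimates), window_s=window_s, overlap=overlap
    )
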