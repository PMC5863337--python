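"""PW-Doppler envelope extraction and velocity summary indices."""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.signal import find_peaks, medfilt

from sonoquant.datatypes import RenalIndices, Spectrogram, VelocityTrace
from sonoquant.errors import EnvelopeError, PeakCountError

__all__ = [
    "extract_envelope",
    "find_cycle",
    "velocity_indices",
    "renal_indices",
    "mitral_ea",
]


def extract_envelope(
    spec: Spectrogram,
    percentile: float = 0.95,
    median_bins: int = 5,
    empty_rel_threshold: float = 1e-4,
    max_empty_fraction: float = 0.3,
) -> VelocityTrace:
    """Trace the velocity envelope of a spectrogram.

    Per time bin the envelope is the largest velocity whose cumulative
    power reaches ``percentile`` of the bin total, taken on the dominant
    side of the baseline with the sign preserved, then median filtered.
    Bins with essentially no power are interpolated; more than
    ``max_empty_fraction`` empty bins raises :class:`EnvelopeError`.
    """
    if not 0 < percentile < 1:
        raise ValueError("percentile must be in (0,1)")
    power = spec.power
    v = spec.velocity_axis
    totals = power.sum(axis=1)
    if totals.max() <= 0:
        raise EnvelopeError("spectrogram contains no power")
    empty = totals < empty_rel_threshold * totals.max()
    if empty.mean() > max_empty_fraction:
        raise EnvelopeError(
            f"{empty.mean():.0%} of time bins are empty")

    pos_power = float(power[:, v > 0].sum())
    neg_power = float(power[:, v < 0].sum())
    dominant_positive = pos_power >= neg_power

    env = np.full(totals.size, np.nan)
    cum = np.cumsum(power, axis=1)
    for i in np.flatnonzero(~empty):
        # mirror the percentile for down-going flow so the envelope always
        # hugs the high-|velocity| edge of the dominant band
        if dominant_positive:
            target = percentile * totals[i]
            j = int(min(np.searchsorted(cum[i], target), v.size - 1))
        else:
            target = (1.0 - percentile) * totals[i]
            # last bin whose *remaining* cumulative power still reaches the
            # percentile, i.e. first bin where cum crosses from below
            j = int(min(np.searchsorted(cum[i], target), v.size - 1))
        env[i] = v[j]

    idx = np.arange(env.size)
    good = np.isfinite(env)
    env = np.interp(idx, idx[good], env[good])
    if median_bins > 1 and env.size >= median_bins:
        env = medfilt(env, kernel_size=median_bins | 1)
    return VelocityTrace(time=spec.time_axis, velocity=env)


def dominant_period_bins(x: np.ndarray, min_bins: int = 10) -> Optional[int]:
    """Dominant periodicity of a 1-D signal in samples, or None."""
    detr = x - x.mean()
    power = float(np.dot(detr, detr))
    if power < 1e-12 or x.size < 2 * min_bins:
        return None
    n = x.size
    ac = np.correlate(detr, detr, mode="full")[n - 1:]
    # unbiased normalization, else the shrinking overlap drags peaks early
    max_lag = int(0.75 * n) + 1
    ac = ac[:max_lag] / (n - np.arange(max_lag))
    lags, _ = find_peaks(ac, height=0.2 * ac[0])
    lags = lags[lags >= min_bins]
    return int(lags[0]) if lags.size else None


def find_cycle(trace: VelocityTrace, min_bins: int = 10) -> tuple[int, int]:
    """Locate one complete cardiac cycle of a pulsatile envelope.

    The cycle spans one dominant period starting at the first systolic
    peak (its indices are half-open); a constant or aperiodic envelope
    yields the whole trace as one cycle.
    """
    vel = trace.velocity
    sign = 1.0 if np.nanmean(vel) >= 0 else -1.0
    x = sign * vel
    span = x.max() - x.min()
    if span < 1e-9 * max(abs(x).max(), 1.0) or x.size < min_bins:
        return 0, int(x.size)
    period = dominant_period_bins(x, min_bins)
    if period is None:
        return 0, int(x.size)
    peaks, _ = find_peaks(x, prominence=0.3 * span, distance=max(int(0.6 * period), 1))
    start = int(peaks[0]) if peaks.size else 0
    if start + period > x.size:
        start = max(int(x.size) - period, 0)
    return start, start + period


def velocity_indices(
    trace: VelocityTrace,
    cycle: Optional[tuple[int, int]] = None,
    edv_window_fraction: float = 0.2,
    min_bins: int = 10,
) -> tuple[float, float, float]:
    """(PSV, EDV, MV) over one cardiac cycle of an envelope trace.

    PSV is the cycle maximum, MV the cycle mean, and EDV the envelope
    minimum in the ``edv_window_fraction`` of the cycle preceding the
    systolic upstroke (tolerant of dicrotic notches).  ``cycle`` is a
    half-open index range; by default the first detected full cycle.
    """
    if cycle is None:
        cycle = trace.cycle_bounds or find_cycle(trace, min_bins)
    a, b = cycle
    if b - a < min_bins:
        raise EnvelopeError(f"cycle has {b - a} bins; need >= {min_bins}")
    seg = trace.velocity[a:b]
    sign = 1.0 if np.mean(seg) >= 0 else -1.0
    x = sign * seg
    psv = float(x.max())
    mv = float(x.mean())
    if x.max() - x.min() < 1e-12:
        edv = psv
    else:
        # end diastole: the window just before the upstroke foot, where the
        # foot is the last sub-threshold sample of the cycle (the cycle may
        # start at a systolic peak, so diastole sits at its tail)
        thresh = x.min() + 0.1 * (x.max() - x.min())
        below = np.flatnonzero(x <= thresh)
        foot = int(below[-1]) if below.size else int(np.argmin(x))
        w = max(int(round(edv_window_fraction * x.size)), 1)
        lo = max(foot - w, 0)
        edv = float(x[lo:foot + 1].min())
    return sign * psv, sign * edv, sign * mv


def renal_indices(psv: float, edv: float, mv: float) -> RenalIndices:
    """Resistivity and pulsatility indices of a renal Doppler waveform.

    RI = (PSV - EDV) / PSV and PI = (PSV - EDV) / MV.
    """
    if psv <= 0:
        raise ValueError("PSV must be positive")
    if mv <= 0:
        raise ValueError("MV must be positive")
    return RenalIndices(ri=(psv - edv) / psv, pi=(psv - edv) / mv)


def mitral_ea(
    trace: VelocityTrace,
    cycle: Optional[tuple[int, int]] = None,
    prominence_fraction: float = 0.2,
) -> tuple[float, float, Optional[float]]:
    """E and A filling peaks and their ratio from a transmitral envelope.

    The two prominent peaks within one cycle are returned in temporal
    order (E first).  A single detected peak is reported as an E-A fusion:
    ``(peak, nan, None)``.  Any other peak count raises
    :class:`PeakCountError`.
    """
    if cycle is None:
        cycle = trace.cycle_bounds
    multi_cycle = cycle is None
    a, b = cycle if cycle is not None else (0, trace.velocity.size)
    seg = trace.velocity[a:b]
    sign = 1.0 if np.mean(seg) >= 0 else -1.0
    x = sign * seg
    if x.max() <= 0:
        raise PeakCountError("no inflow signal in cycle")
    peaks, _ = find_peaks(x, prominence=prominence_fraction * x.max())
    if peaks.size == 1:
        return float(sign * x[peaks[0]]), float("nan"), None
    if peaks.size > 2 and multi_cycle:
        # periodic multi-cycle trace ... E A E A ...: pick one E-A pair; the
        # within-cycle E-to-A gap is shorter than the A-to-next-E gap
        gaps = np.diff(peaks)
        peaks = peaks[:2] if gaps[0] <= gaps[1] else peaks[1:3]
    if peaks.size != 2:
        raise PeakCountError(f"expected 1 or 2 inflow peaks, found {peaks.size}")
    e = float(sign * x[peaks[0]])
    a_pk = float(sign * x[peaks[1]])
    return e, a_pk, e / a_pk
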