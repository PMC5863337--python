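"""Vascular biomarkers: distension, loop-based PWV, pulse pressure, shear.

The local pulse wave velocity is estimated from the diameter-velocity
loop: over the reflection-free early-systolic limb the blood velocity is
linear in ln(diameter) with slope 2*PWV (water-hammer relation with the
area expressed through the diameter), so a least-squares fit of V against
ln(D) on that limb yields PWV = slope / 2.

Pulse pressure comes from inverting the Bramwell-Hill relation between
PWV, blood density and fractional distension.  Because the distension may
be read as a diameter strain or an area strain, three conventions are
provided (see :func:`pulse_pressure`); they disagree by roughly a factor
of two at physiological distensions, and the choice is surfaced rather
than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from sonoquant.datatypes import DiameterTrace, VelocityTrace
from sonoquant.errors import LoopFitError
from sonoquant.vessel import segment_beats

__all__ = [
    "BLOOD_DENSITY_KG_M3",
    "MMHG_PER_PA",
    "PP_CONVENTIONS",
    "LoopFit",
    "VascularSummary",
    "relative_distension",
    "pwv_loop",
    "pulse_pressure",
    "wall_shear_rate",
    "vascular_summary",
]

BLOOD_DENSITY_KG_M3 = 1059.0
MMHG_PER_PA = 1.0 / 133.322
PP_CONVENTIONS = ("literal", "linearized_area", "exact_area")


@dataclass(frozen=True)
class LoopFit:
    """Result of the diameter-velocity loop regression."""

    pwv_m_s: float
    slope: float  # mm/s per unit ln(D); pwv = slope / 2 / 1000
    window: tuple[int, int]  # index range of the early-systolic limb
    r2: float


@dataclass
class VascularSummary:
    """One vessel's biomarker row (units as commonly tabulated)."""

    dm_mm: float
    reld_pct: float
    pwv_m_s: float  # NaN when the loop fit failed
    pp_pa: float
    pp_mmhg: float
    wsr_per_s: float
    convention: str
    pwv_error: Optional[str] = None


def relative_distension(ds_mm: float, dd_mm: float) -> float:
    """Relative distension 100 * (Ds - Dd) / Dd, in percent."""
    if dd_mm <= 0:
        raise ValueError("Dd must be positive")
    if ds_mm < dd_mm - 1e-12:
        raise ValueError("Ds must be >= Dd (beat segmentation fault upstream)")
    return 100.0 * (ds_mm - dd_mm) / dd_mm


def _upstroke_window(v: np.ndarray, peak: int, lookback: int) -> tuple[int, int]:
    """Early-systolic limb: intersecting-tangents foot to 80% of the V peak."""
    lo = max(peak - lookback, 0)
    seg = v[lo:peak + 1]
    if seg.size < 3:
        return lo, peak + 1
    dv = np.gradient(seg)
    i_ms = int(np.argmax(dv))  # max-slope sample
    baseline = float(seg.min())
    slope = dv[i_ms]
    if slope <= 0:
        return lo, peak + 1
    # intersection of the max-slope tangent with the diastolic baseline
    foot = i_ms - (seg[i_ms] - baseline) / slope
    foot_i = lo + int(np.clip(np.floor(foot), 0, seg.size - 1))
    thresh = baseline + 0.8 * (v[peak] - baseline)
    above = np.flatnonzero(v[foot_i:peak + 1] >= thresh)
    end = foot_i + (int(above[0]) if above.size else seg.size)
    return foot_i, max(end, foot_i + 2)


def pwv_loop(
    dtrace: DiameterTrace,
    vtrace: VelocityTrace,
    min_window: int = 5,
    min_r2: float = 0.8,
) -> LoopFit:
    """Estimate local PWV from the diameter-velocity loop.

    Both traces are linearly resampled onto the denser time axis over
    their common span; per detected beat the early-systolic limb of V(t)
    is selected and V is regressed on ln(D).  The reported fit is the
    median over per-beat fits.  Raises :class:`LoopFitError` (with
    diagnostics attached) for windows shorter than ``min_window``, fits
    with R^2 below ``min_r2``, or a diameter too static for ln(D) to
    carry information.
    """
    t0 = max(dtrace.time[0], vtrace.time[0])
    t1 = min(dtrace.time[-1], vtrace.time[-1])
    if t1 <= t0:
        raise LoopFitError("traces do not overlap in time")
    rate_d = (dtrace.time.size - 1) / (dtrace.time[-1] - dtrace.time[0])
    rate_v = (vtrace.time.size - 1) / (vtrace.time[-1] - vtrace.time[0])
    n = int(np.floor((t1 - t0) * max(rate_d, rate_v))) + 1
    t = np.linspace(t0, t1, n)
    d = np.interp(t, dtrace.time, dtrace.diameter)
    v = np.interp(t, vtrace.time, vtrace.velocity)

    if np.std(np.log(d)) < 1e-6:
        raise LoopFitError("diameter is static: ln(D) carries no information",
                           ln_d_std=float(np.std(np.log(d))))

    span = v.max() - v.min()
    peaks, _ = find_peaks(v, prominence=0.5 * span) if span > 0 else (np.array([], int), {})
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(v))])
    med_gap = int(np.median(np.diff(peaks))) if peaks.size > 1 else n
    lookback = max(min(med_gap, n) // 2, min_window + 2)

    fits = []
    diags = []
    for pk in peaks:
        a, b = _upstroke_window(v, int(pk), lookback)
        if b - a < min_window:
            diags.append({"window": (a, b), "reason": "short window"})
            continue
        x = np.log(d[a:b])
        y = v[a:b]
        if np.ptp(x) < 1e-9:
            diags.append({"window": (a, b), "reason": "flat ln(D)"})
            continue
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
        fits.append(LoopFit(pwv_m_s=slope / 2.0 / 1000.0, slope=float(slope),
                            window=(a, b), r2=float(r2)))

    good = [f for f in fits if f.r2 >= min_r2 and f.window[1] - f.window[0] >= min_window]
    if not good:
        raise LoopFitError("no reliable early-systolic loop fit",
                           attempted=len(fits), rejected=diags,
                           r2=[f.r2 for f in fits])
    pwvs = np.array([f.pwv_m_s for f in good])
    best = good[int(np.argsort(pwvs)[pwvs.size // 2])]
    return LoopFit(pwv_m_s=float(np.median(pwvs)), slope=float(np.median(pwvs)) * 2000.0,
                   window=best.window, r2=float(np.median([f.r2 for f in good])))


def pulse_pressure(
    pwv_m_s: float,
    reld_pct: float,
    convention: str = "literal",
    rho_kg_m3: float = BLOOD_DENSITY_KG_M3,
) -> tuple[float, float]:
    """Pulse pressure (Pa, mmHg) from PWV and relative distension.

    Conventions for the distension term, with ``x = relD / 100``:

    * ``literal``          : PP = PWV^2 * rho * x        (distension read
      as a diameter strain, used verbatim)
    * ``linearized_area``  : PP = PWV^2 * rho * 2x       (area strain of a
      circular lumen, linearized: dA/A ~= 2 dD/D)
    * ``exact_area``       : PP = PWV^2 * rho * ((1+x)^2 - 1)

    At physiological distensions the area conventions give roughly twice
    the literal value; see the package README for why both are offered.
    """
    if convention not in PP_CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; use one of {PP_CONVENTIONS}")
    if pwv_m_s <= 0:
        raise ValueError("PWV must be positive")
    if reld_pct < 0:
        raise ValueError("relative distension must be nonnegative")
    x = reld_pct / 100.0
    factor = {"literal": x,
              "linearized_area": 2.0 * x,
              "exact_area": (1.0 + x) ** 2 - 1.0}[convention]
    pp_pa = pwv_m_s ** 2 * rho_kg_m3 * factor
    return pp_pa, pp_pa * MMHG_PER_PA


def wall_shear_rate(v_mean_mm_s: float, dd_mm: float) -> float:
    """Poiseuille-type wall shear rate 4 * Vmean / Dd, in 1/s."""
    if dd_mm <= 0:
        raise ValueError("Dd must be positive")
    return 4.0 * v_mean_mm_s / dd_mm


def vascular_summary(
    dtrace: DiameterTrace,
    vtrace: VelocityTrace,
    convention: str = "literal",
    ecg=None,
) -> VascularSummary:
    """Assemble one vessel's biomarker row from its two traces.

    Dd/Ds (hence relD) come from the ensemble-averaged beat; Dm is the
    time average of the full trace; the mean velocity for the shear rate
    is the envelope cycle mean.  A failed loop fit is reported as
    ``pwv_m_s = NaN`` with the reason in ``pwv_error`` (and PP only when
    relD is zero), never as a silent number.
    """
    from sonoquant.doppler import velocity_indices

    if not dtrace.beats or dtrace.ensemble is None:
        dtrace = segment_beats(dtrace, ecg=ecg)
    _, ens = dtrace.ensemble
    dd, ds = float(ens.min()), float(ens.max())
    reld = relative_distension(ds, dd)

    psv, edv, mv = velocity_indices(vtrace)
    wsr = wall_shear_rate(abs(mv), dd)

    pwv_error = None
    try:
        fit = pwv_loop(dtrace, vtrace)
        pwv = fit.pwv_m_s
    except LoopFitError as exc:
        pwv = float("nan")
        pwv_error = str(exc)

    if np.isfinite(pwv):
        pp_pa, pp_mmhg = pulse_pressure(pwv, reld, convention)
    elif reld < 1e-9:
        pp_pa, pp_mmhg = 0.0, 0.0
    else:
        pp_pa, pp_mmhg = float("nan"), float("nan")

    return VascularSummary(dm_mm=dtrace.dm_mm, reld_pct=reld, pwv_m_s=pwv,
                           pp_pa=pp_pa, pp_mmhg=pp_mmhg, wsr_per_s=wsr,
                           convention=convention, pwv_error=pwv_error)
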