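"""Ground-truth parameter specs and analytic waveforms for synthetic data.

Every synthetic artifact is generated from a :class:`PhantomTruth`, which
fully determines the output together with the seed (identical spec + seed
gives bit-identical arrays).  Reference traces are analytic evaluations of
the waveform specs, so downstream estimators can be checked against exact
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "DiameterWaveform",
    "PulsatileWaveform",
    "MitralWaveform",
    "NoiseSpec",
    "PhantomTruth",
    "make_ecg",
    "speckle_field",
]

BLOOD_DENSITY_KG_M3 = 1059.0


@dataclass(frozen=True)
class DiameterWaveform:
    """Periodic vessel diameter D(t): raised-cosine upstroke then recovery.

    ``D`` rises from ``dd_mm`` to ``ds_mm`` over ``upstroke_fraction`` of the
    period and relaxes back with a second raised cosine, so the waveform is
    C1-smooth and exactly periodic.
    """

    dd_mm: float = 1.0
    ds_mm: float = 1.2
    period_s: float = 0.2
    upstroke_fraction: float = 0.25

    def __post_init__(self):
        if not (self.ds_mm >= self.dd_mm > 0):
            raise ValueError("need Ds >= Dd > 0")
        if self.period_s <= 0:
            raise ValueError("period must be positive")
        if not 0 < self.upstroke_fraction < 1:
            raise ValueError("upstroke fraction must lie in (0,1)")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        phase = np.mod(t, self.period_s)
        up = self.upstroke_fraction * self.period_s
        amp = self.ds_mm - self.dd_mm
        rising = 0.5 * (1.0 - np.cos(np.pi * phase / up))
        falling = 0.5 * (1.0 + np.cos(np.pi * (phase - up) / (self.period_s - up)))
        d = self.dd_mm + amp * np.where(phase < up, rising, falling)
        return d

    def upstroke_window(self, beat_start_s: float = 0.0) -> tuple[float, float]:
        """Time span of the systolic upstroke of the beat starting at t0."""
        return beat_start_s, beat_start_s + self.upstroke_fraction * self.period_s

    def coupled_velocity(self, t, pwv_m_s: float) -> np.ndarray:
        """Velocity (mm/s) satisfying V = 2 * PWV * ln(D/Dd) everywhere.

        On the upstroke this is the reflection-free loop relation; past the
        upstroke the same expression decays smoothly back to zero, keeping
        the loop a single line so PWV recovery is well posed.
        """
        d = self(t)
        return 2.0 * pwv_m_s * 1000.0 * np.log(d / self.dd_mm)


@dataclass(frozen=True)
class PulsatileWaveform:
    """Arterial/renal-type velocity waveform hitting PSV/EDV/MV targets.

    A systolic pulse with raised-cosine rise/fall edges and (when the mean
    target requires it) a flat top, on an end-diastolic baseline.  The edge
    and plateau widths are solved so the cycle mean equals ``mv_mm_s``
    exactly; with ``mv_mm_s=None`` a default pulse width is used.
    """

    psv_mm_s: float = 120.0
    edv_mm_s: float = 40.0
    mv_mm_s: Optional[float] = None
    period_s: float = 0.2
    onset_fraction: float = 0.05
    max_edge_fraction: float = 0.15

    def __post_init__(self):
        if self.psv_mm_s < self.edv_mm_s:
            raise ValueError("PSV must be >= EDV")
        if self.period_s <= 0:
            raise ValueError("period must be positive")
        mv = self.mv_mm_s
        if mv is not None and self.psv_mm_s > self.edv_mm_s:
            if not (self.edv_mm_s < mv < self.psv_mm_s):
                raise ValueError("MV target must lie strictly between EDV and PSV")
            if self._mean_fraction > 0.95 - self.onset_fraction - self.max_edge_fraction:
                raise ValueError("MV target too close to PSV for one systolic pulse")

    @property
    def _mean_fraction(self) -> float:
        """Target pulse mean as a fraction of (PSV - EDV)."""
        if self.psv_mm_s == self.edv_mm_s or self.mv_mm_s is None:
            return 0.3
        return (self.mv_mm_s - self.edv_mm_s) / (self.psv_mm_s - self.edv_mm_s)

    @property
    def _pulse_widths(self) -> tuple[float, float]:
        """(edge width e, plateau width p), phase fractions; mean = e + p."""
        m = self._mean_fraction
        e = min(self.max_edge_fraction, m)
        return e, m - e

    @property
    def mean_mm_s(self) -> float:
        if self.mv_mm_s is not None:
            return self.mv_mm_s
        return self.edv_mm_s + (self.psv_mm_s - self.edv_mm_s) * self._mean_fraction

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        phase = np.mod(t, self.period_s) / self.period_s
        if self.psv_mm_s == self.edv_mm_s:
            return np.full_like(phase, float(self.psv_mm_s))
        e, p = self._pulse_widths
        x = phase - self.onset_fraction
        pulse = np.zeros_like(phase)
        rise = (x >= 0) & (x < e)
        flat = (x >= e) & (x < e + p)
        fall = (x >= e + p) & (x < 2 * e + p)
        with np.errstate(invalid="ignore", divide="ignore"):
            pulse[rise] = 0.5 * (1 - np.cos(np.pi * x[rise] / e)) if e > 0 else 0.0
            pulse[flat] = 1.0
            if e > 0:
                pulse[fall] = 0.5 * (1 + np.cos(np.pi * (x[fall] - e - p) / e))
        return self.edv_mm_s + (self.psv_mm_s - self.edv_mm_s) * pulse


@dataclass(frozen=True)
class MitralWaveform:
    """Transmitral inflow with an early (E) and a late (A) filling bump."""

    e_mm_s: float = 800.0
    a_mm_s: float = 400.0
    period_s: float = 0.2
    e_center: float = 0.35  # phase fractions
    a_center: float = 0.78
    bump_width: float = 0.22

    def __post_init__(self):
        if self.e_mm_s <= 0 or self.a_mm_s <= 0:
            raise ValueError("E and A peaks must be positive")
        if not 0 < self.e_center < self.a_center < 1:
            raise ValueError("E bump must precede A bump within the cycle")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        phase = np.mod(t, self.period_s) / self.period_s
        out = np.zeros_like(phase)
        for peak, center in ((self.e_mm_s, self.e_center), (self.a_mm_s, self.a_center)):
            x = (phase - center) / (self.bump_width / 2.0)
            out += peak * np.where(np.abs(x) < 1, 0.5 * (1 + np.cos(np.pi * x)), 0.0)
        return out


@dataclass(frozen=True)
class NoiseSpec:
    """Speckle and sensor-noise levels for synthetic images.

    ``speckle`` scales a low-pass-filtered Rayleigh field applied
    multiplicatively (0 disables it); ``additive`` is the std of white
    sensor noise in gray levels; ``correlation_px`` is the speckle cell
    size (Gaussian low-pass sigma in pixels).
    """

    speckle: float = 0.0
    additive: float = 0.0
    correlation_px: float = 1.5

    def __post_init__(self):
        if self.speckle < 0 or self.additive < 0 or self.correlation_px <= 0:
            raise ValueError("noise levels must be nonnegative, correlation positive")

    @property
    def is_noiseless(self) -> bool:
        return self.speckle == 0.0 and self.additive == 0.0


@dataclass(frozen=True)
class PhantomTruth:
    """Everything needed to generate one synthetic dataset and grade it."""

    seed: int = 0
    diameter: DiameterWaveform = field(default_factory=DiameterWaveform)
    true_pwv_m_s: float = 2.0
    true_strain: Optional[dict] = None  # direction -> peak fraction
    velocity: Optional[PulsatileWaveform | MitralWaveform] = None
    gray_means: tuple[float, float] = (120.0, 100.0)  # (liver, kidney)
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self):
        if self.true_pwv_m_s <= 0:
            raise ValueError("true PWV must be positive")
        lo, hi = min(self.gray_means), max(self.gray_means)
        if lo < 0 or hi > 255:
            raise ValueError("gray means must lie in [0, 255]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["velocity_kind"] = type(self.velocity).__name__ if self.velocity else None
        return d


def make_ecg(duration_s: float, hr_bpm: float, sample_rate: float = 1000.0) -> "np.ndarray":
    """Impulse-train ECG: unit R waves every 60/HR seconds starting at t=0."""
    from sonoquant.datatypes import Ecg

    n = int(math.floor(duration_s * sample_rate)) + 1
    samples = np.zeros(n)
    rr = 60.0 / hr_bpm
    t_r = 0.0
    while t_r <= duration_s + 1e-9:
        samples[int(round(t_r * sample_rate))] = 1.0
        t_r += rr
    return Ecg(samples=samples, sample_rate=sample_rate)


def speckle_field(shape: tuple[int, int], rng: np.random.Generator,
                  correlation_px: float = 1.5) -> np.ndarray:
    """Unit-mean multiplicative speckle: low-passed Rayleigh texture.

    First-order B-mode speckle approximation; the Gaussian low-pass sets the
    apparent speckle cell size.
    """
    from scipy.ndimage import gaussian_filter

    raw = rng.rayleigh(scale=1.0, size=shape)
    smooth = gaussian_filter(raw, sigma=correlation_px, mode="reflect")
    return smooth / smooth.mean()
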