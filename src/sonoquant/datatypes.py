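"""Core data containers shared across the pipeline.

All images are grayscale ``float`` arrays on a 0-255 intensity scale; axial is
the first image axis (rows), lateral the second (columns).  Distances are
millimetres, times seconds, velocities mm/s, unless a field name says
otherwise.  Containers validate their invariants at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Ecg",
    "CineLoop",
    "Spectrogram",
    "Beat",
    "DiameterTrace",
    "VelocityTrace",
    "RenalIndices",
    "LVTrace",
    "StrainResult",
]

VIEWS = (
    "aorta-long-axis",
    "carotid-long-axis",
    "PLAX",
    "SAX",
    "liver-kidney",
    "mitral",
    "renal",
)


@dataclass
class Ecg:
    """A sampled ECG trace (arbitrary units, impulse-like R waves)."""

    samples: np.ndarray
    sample_rate: float  # Hz

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("ECG needs at least two samples")
        if self.sample_rate <= 0:
            raise ValueError("ECG sample rate must be positive")

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass
class CineLoop:
    """A calibrated grayscale frame stack.

    Parameters
    ----------
    frames
        ``(T, H, W)`` intensities in [0, 255].
    pixel_spacing
        ``(axial mm/px, lateral mm/px)``.
    frame_rate
        Frames per second.
    ecg
        Optional ECG covering at least the loop duration.
    view
        One of :data:`VIEWS`.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    frame_rate: float
    ecg: Optional[Ecg] = None
    view: str = "aorta-long-axis"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (T>=2, H, W)")
        ax, lat = self.pixel_spacing
        if ax <= 0 or lat <= 0:
            raise ValueError("pixel spacings must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        if self.ecg is not None and self.ecg.duration < self.duration - 1e-9:
            raise ValueError("ECG must span the loop duration")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class Spectrogram:
    """PW-Doppler power as a time x velocity image.

    ``power`` has shape ``(len(time_axis), len(velocity_axis))`` with
    nonnegative entries; ``velocity_axis`` is signed with the baseline at 0.
    """

    power: np.ndarray
    time_axis: np.ndarray
    velocity_axis: np.ndarray
    prf: float  # Hz
    angle_correction: float = 60.0  # degrees, stored, not re-applied

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.velocity_axis = np.asarray(self.velocity_axis, dtype=float)
        if self.power.shape != (self.time_axis.size, self.velocity_axis.size):
            raise ValueError("power shape must match axes")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")
        for ax in (self.time_axis, self.velocity_axis):
            if ax.size < 2 or np.any(np.diff(ax) <= 0):
                raise ValueError("axes must be strictly increasing")
        if self.prf <= 0:
            raise ValueError("PRF must be positive")

    @property
    def velocity_bin(self) -> float:
        """Velocity-axis bin width (mm/s)."""
        return float(np.mean(np.diff(self.velocity_axis)))


@dataclass
class Beat:
    """Per-beat diameter extrema; ``start``/``stop`` index into the trace."""

    dd_mm: float
    ds_mm: float
    start: int
    stop: int

    def __post_init__(self):
        if self.dd_mm <= 0:
            raise ValueError("Dd must be positive")
        if self.ds_mm < self.dd_mm - 1e-12:
            raise ValueError("Ds must be >= Dd within a beat")


@dataclass
class DiameterTrace:
    """Instantaneous vessel diameter over time plus per-beat summaries."""

    time: np.ndarray  # s, strictly increasing
    diameter: np.ndarray  # mm, positive
    beats: list[Beat] = field(default_factory=list)
    quality: Optional[np.ndarray] = None  # per-frame confidence in [0,1]
    ensemble: Optional[tuple[np.ndarray, np.ndarray]] = None  # (phase, mm)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.time.shape != self.diameter.shape or self.time.ndim != 1:
            raise ValueError("time and diameter must be 1-D and equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.diameter <= 0):
            raise ValueError("diameter must be positive everywhere")
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=float)
            if self.quality.shape != self.time.shape:
                raise ValueError("quality must align with time")

    @property
    def dm_mm(self) -> float:
        """Time-averaged mean diameter (trapezoidal)."""
        return float(np.trapezoid(self.diameter, self.time) / (self.time[-1] - self.time[0]))


@dataclass
class VelocityTrace:
    """Doppler envelope over time plus single-cycle summary velocities."""

    time: np.ndarray  # s
    velocity: np.ndarray  # mm/s, signed envelope
    psv: Optional[float] = None
    edv: Optional[float] = None
    mv: Optional[float] = None
    cycle_bounds: Optional[tuple[int, int]] = None  # half-open index range

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.time.shape != self.velocity.shape or self.time.ndim != 1:
            raise ValueError("time and velocity must be 1-D and equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class RenalIndices:
    ri: float
    pi: float


@dataclass
class LVTrace:
    """Per-frame LV contours in a PLAX or SAX plane.

    ``endo``/``epi`` are lists (one entry per frame) of ``(N, 2)`` point
    arrays in mm, ordered along the contour; the point count is constant
    across frames.  ``long_axis_mm`` may be given per frame (PLAX); when
    absent it is derived from the endocardial contour.
    """

    time: np.ndarray
    endo: Sequence[np.ndarray]
    epi: Optional[Sequence[np.ndarray]] = None
    long_axis_mm: Optional[np.ndarray] = None
    view: str = "PLAX"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if len(self.endo) != self.time.size:
            raise ValueError("one endocardial contour per frame required")
        self.endo = [np.asarray(c, dtype=float) for c in self.endo]
        npts = self.endo[0].shape[0]
        if any(c.shape != (npts, 2) for c in self.endo):
            raise ValueError("contour point count must be constant across frames")
        if self.epi is not None:
            self.epi = [np.asarray(c, dtype=float) for c in self.epi]
            if len(self.epi) != self.time.size:
                raise ValueError("one epicardial contour per frame required")
        if self.long_axis_mm is not None:
            self.long_axis_mm = np.asarray(self.long_axis_mm, dtype=float)
            if self.long_axis_mm.shape != self.time.shape:
                raise ValueError("long_axis_mm must align with time")


@dataclass
class StrainResult:
    """Per-segment strain (%) and strain rate (1/s) for one direction."""

    direction: str  # longitudinal | radial | circumferential
    time: np.ndarray
    segment_strain: np.ndarray  # (6, T) percent, strain[:, 0] == 0
    segment_strain_rate: np.ndarray  # (6, T) 1/s
    segment_peaks: np.ndarray  # (6,) signed peak strain per segment
    segment_rate_peaks: np.ndarray  # (6,) signed peak strain rate
    global_strain: float  # mean of the 6 segmental strain peaks
    global_strain_rate: float  # mean of the 6 segmental rate peaks
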