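"""Synthetic pulsating-vessel cine loops with exact ground truth.

The vessel appears as two bright horizontal wall bands (Gaussian axial
profiles rendered at sub-pixel positions) on a dark lumen; the band-center
separation follows the prescribed diameter waveform exactly.  Optional
multiplicative speckle and additive sensor noise per :class:`NoiseSpec`.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from sonoquant.datatypes import Beat, CineLoop, DiameterTrace, Spectrogram, VelocityTrace
from sonoquant.errors import SizingError
from sonoquant.phantom.truth import PhantomTruth, make_ecg, speckle_field
from sonoquant.phantom.doppler import render_spectrogram, required_prf

__all__ = ["make_vessel_cine", "make_coupled_vessel", "DEFAULT_VESSEL_NOISE"]

# default speckle level used by recovery experiments and the cohort generator
from sonoquant.phantom.truth import NoiseSpec

DEFAULT_VESSEL_NOISE = NoiseSpec(speckle=0.35, additive=2.0, correlation_px=1.5)


def _reference_trace(truth: PhantomTruth, times: np.ndarray) -> DiameterTrace:
    d = truth.diameter(times)
    beats = []
    period = truth.diameter.period_s
    duration = times[-1]
    k = 0
    while (k + 1) * period <= duration + 1e-9:
        start = int(np.searchsorted(times, k * period))
        stop = int(np.searchsorted(times, (k + 1) * period, side="right"))
        beats.append(Beat(dd_mm=truth.diameter.dd_mm, ds_mm=truth.diameter.ds_mm,
                          start=start, stop=stop))
        k += 1
    return DiameterTrace(time=times, diameter=d, beats=beats,
                         quality=np.ones_like(times))


def make_vessel_cine(
    truth: PhantomTruth,
    n_beats: int = 3,
    image_shape: tuple[int, int] = (160, 128),
    pixel_mm: tuple[float, float] = (0.02, 0.02),
    frame_rate: float = 700.0,
    wall_thickness_mm: float = 0.12,
    background: float = 12.0,
    wall_amplitude: float = 200.0,
    view: str = "aorta-long-axis",
    with_ecg: bool = True,
) -> tuple[CineLoop, DiameterTrace]:
    """Render a pulsating-vessel long-axis loop and its reference trace.

    Returns the cine loop and the analytic diameter trace sampled at frame
    times.  Raises :class:`SizingError` when the systolic diameter plus wall
    bands would not fit in the image.
    """
    H, W = image_shape
    ax_mm, _ = pixel_mm
    sigma_px = wall_thickness_mm / 2.355 / ax_mm  # FWHM -> Gaussian sigma
    ds_px = truth.diameter.ds_mm / ax_mm
    if ds_px + 8.0 * sigma_px >= H:
        raise SizingError(
            f"systolic diameter {truth.diameter.ds_mm} mm does not fit in "
            f"{H} px at {ax_mm} mm/px")

    period = truth.diameter.period_s
    n_frames = int(round(n_beats * period * frame_rate)) + 1
    times = np.arange(n_frames) / frame_rate
    d_px = truth.diameter(times) / ax_mm
    c0 = (H - 1) / 2.0
    rows = np.arange(H, dtype=float)

    rng = truth.rng()
    frames = np.empty((n_frames, H, W))
    for i in range(n_frames):
        near = c0 - d_px[i] / 2.0
        far = c0 + d_px[i] / 2.0
        profile = background + wall_amplitude * (
            np.exp(-0.5 * ((rows - near) / sigma_px) ** 2)
            + np.exp(-0.5 * ((rows - far) / sigma_px) ** 2)
        )
        frame = np.repeat(profile[:, None], W, axis=1)
        if truth.noise.speckle > 0:
            s = speckle_field((H, W), rng, truth.noise.correlation_px)
            frame = frame * (1.0 + truth.noise.speckle * (s - 1.0))
        if truth.noise.additive > 0:
            frame = frame + rng.normal(0.0, truth.noise.additive, size=(H, W))
        frames[i] = np.clip(frame, 0.0, 255.0)

    ecg = None
    if with_ecg:
        ecg = make_ecg(times[-1] + 1.0 / frame_rate, hr_bpm=60.0 / period)
    loop = CineLoop(frames=frames, pixel_spacing=pixel_mm, frame_rate=frame_rate,
                    ecg=ecg, view=view)
    return loop, _reference_trace(truth, times)


def make_coupled_vessel(
    truth: PhantomTruth,
    n_beats: int = 3,
    prf: Optional[float] = None,
    spectrogram_dt: float = 1e-3,
    **cine_kwargs,
) -> tuple[CineLoop, Spectrogram, DiameterTrace, VelocityTrace]:
    """Vessel cine plus a Doppler spectrogram coupled through the loop model.

    The velocity waveform is ``V(t) = 2 * PWV_true * ln(D(t)/Dd)`` so the
    early-systolic diameter-velocity loop has slope ``2 * PWV_true`` by
    construction.  With ``prf=None`` the PRF is chosen large enough to keep
    the waveform below the Nyquist velocity.
    """
    loop, dtrace = make_vessel_cine(truth, n_beats=n_beats, **cine_kwargs)

    def vfun(t):
        return truth.diameter.coupled_velocity(t, truth.true_pwv_m_s)

    duration = dtrace.time[-1]
    v_peak = float(np.max(np.abs(vfun(dtrace.time))))
    if prf is None:
        prf = required_prf(1.3 * max(v_peak, 1.0))
    spec = render_spectrogram(vfun, duration=duration, prf=prf, dt=spectrogram_dt,
                              seed=truth.seed + 1, noise=truth.noise)
    vt = spec.time_axis
    v_ref = vfun(vt)
    period = truth.diameter.period_s
    cyc = (int(np.searchsorted(vt, 0.0)), int(np.searchsorted(vt, period, side="right")))
    in_cyc = vfun(np.linspace(0, period, 2049))
    vtrace = VelocityTrace(time=vt, velocity=v_ref,
                           psv=float(in_cyc.max()), edv=float(in_cyc.min()),
                           mv=float(in_cyc.mean()), cycle_bounds=cyc)
    return loop, spec, dtrace, vtrace
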