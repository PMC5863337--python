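"""Synthetic PW-Doppler spectrograms with a known envelope.

Power is concentrated in a narrow Gaussian band (sigma = one velocity bin)
centered on the prescribed waveform, with a weak spectral-broadening fill
between the baseline and the band and a faint noise floor.  The
cumulative-power-percentile envelope of a noiseless rendering therefore
tracks the prescribed waveform to within two velocity bins.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from sonoquant.datatypes import Spectrogram, VelocityTrace
from sonoquant.errors import AliasingError
from sonoquant.phantom.truth import MitralWaveform, NoiseSpec, PulsatileWaveform

__all__ = [
    "nyquist_velocity",
    "required_prf",
    "render_spectrogram",
    "make_doppler_trace",
]

SOUND_SPEED_M_S = 1540.0
DEFAULT_F0_HZ = 24e6  # 24 MHz probe
DEFAULT_ANGLE_DEG = 60.0


def nyquist_velocity(prf: float, f0_hz: float = DEFAULT_F0_HZ,
                     angle_deg: float = DEFAULT_ANGLE_DEG) -> float:
    """Largest unaliased velocity (mm/s) for a given PRF.

    From the Doppler equation v = c * fd / (2 * f0 * cos(theta)) with
    fd = PRF/2.
    """
    cos_t = np.cos(np.deg2rad(angle_deg))
    return SOUND_SPEED_M_S * (prf / 2.0) / (2.0 * f0_hz * cos_t) * 1000.0


def required_prf(v_mm_s: float, f0_hz: float = DEFAULT_F0_HZ,
                 angle_deg: float = DEFAULT_ANGLE_DEG) -> float:
    """Smallest PRF whose Nyquist velocity covers ``v_mm_s``."""
    cos_t = np.cos(np.deg2rad(angle_deg))
    return 2.0 * (abs(v_mm_s) / 1000.0) * 2.0 * f0_hz * cos_t / SOUND_SPEED_M_S


def render_spectrogram(
    waveform: Callable[[np.ndarray], np.ndarray],
    duration: float,
    prf: float,
    dt: float = 1e-3,
    n_velocity_bins: int = 512,
    seed: int = 0,
    noise: Optional[NoiseSpec] = None,
    band_power: float = 1000.0,
    band_sigma_bins: float = 0.8,
    fill_amplitude: float = 0.1,
    floor_amplitude: float = 0.01,
    f0_hz: float = DEFAULT_F0_HZ,
    angle_deg: float = DEFAULT_ANGLE_DEG,
) -> Spectrogram:
    """Render the spectrogram of a velocity waveform (mm/s over seconds).

    Raises :class:`AliasingError` when the waveform exceeds the PRF-implied
    Nyquist velocity; aliasing is deliberately not simulated.
    """
    noise = noise or NoiseSpec()
    vmax = nyquist_velocity(prf, f0_hz, angle_deg)
    t_axis = np.arange(0.0, duration + dt / 2, dt)
    v_axis = np.linspace(-vmax, vmax, n_velocity_bins)
    dv = v_axis[1] - v_axis[0]

    v_true = np.asarray(waveform(t_axis), dtype=float)
    if np.max(np.abs(v_true)) >= vmax:
        raise AliasingError(
            f"waveform peak {np.max(np.abs(v_true)):.1f} mm/s exceeds Nyquist "
            f"velocity {vmax:.1f} mm/s at PRF {prf:.0f} Hz")

    band = np.exp(-0.5 * ((v_axis[None, :] - v_true[:, None]) / (band_sigma_bins * dv)) ** 2)
    band *= band_power / band.sum(axis=1, keepdims=True)

    lo = np.minimum(0.0, v_true)[:, None]
    hi = np.maximum(0.0, v_true)[:, None]
    fill = fill_amplitude * ((v_axis[None, :] >= lo) & (v_axis[None, :] <= hi))

    power = band + fill + floor_amplitude
    if not noise.is_noiseless:
        rng = np.random.default_rng(seed)
        if noise.speckle > 0:
            s = rng.rayleigh(scale=1.0, size=power.shape)
            power = power * (1.0 + noise.speckle * (s / s.mean() - 1.0))
        if noise.additive > 0:
            # weak broadband clutter, scaled well below the band power
            power = power + rng.uniform(0.0, noise.additive * floor_amplitude,
                                        size=power.shape)
    power = np.clip(power, 0.0, None)
    return Spectrogram(power=power, time_axis=t_axis, velocity_axis=v_axis,
                       prf=prf, angle_correction=angle_deg)


def make_doppler_trace(
    waveform: PulsatileWaveform | MitralWaveform,
    seed: int = 0,
    n_cycles: int = 3,
    prf: Optional[float] = None,
    noise: Optional[NoiseSpec] = None,
    dt: float = 1e-3,
    **render_kwargs,
) -> tuple[Spectrogram, VelocityTrace]:
    """Spectrogram plus exact reference envelope for a parametric waveform.

    With ``prf=None`` a PRF with 30% Nyquist headroom is chosen; an explicit
    PRF that clips the waveform raises :class:`AliasingError`.
    """
    duration = n_cycles * waveform.period_s
    probe = waveform(np.linspace(0.0, waveform.period_s, 4096, endpoint=False))
    if prf is None:
        prf = required_prf(1.3 * max(float(np.max(np.abs(probe))), 1.0))
    spec = render_spectrogram(waveform, duration=duration, prf=prf, dt=dt,
                              seed=seed, noise=noise, **render_kwargs)
    t = spec.time_axis
    v_ref = np.asarray(waveform(t), dtype=float)
    cyc = (0, int(np.searchsorted(t, waveform.period_s, side="right")))
    if isinstance(waveform, PulsatileWaveform):
        psv, edv, mv = waveform.psv_mm_s, waveform.edv_mm_s, waveform.mean_mm_s
    else:
        psv, edv = max(waveform.e_mm_s, waveform.a_mm_s), float(np.min(probe))
        mv = float(np.mean(probe))
    trace = VelocityTrace(time=t, velocity=v_ref, psv=float(psv), edv=float(edv),
                          mv=float(mv), cycle_bounds=cyc)
    return spec, trace
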