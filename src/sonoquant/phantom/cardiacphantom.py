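"""Synthetic left-ventricle loops with analytically prescribed deformation.

Two phantom families:

* :func:`make_lv_cine` renders speckle-textured SAX (annulus) or PLAX
  (elliptical annulus) loops in which the tissue texture is advected by a
  closed-form displacement field, so true strain per direction is known
  exactly at every frame.
* :func:`make_lv_contour_trace` builds border tracings (no images) of an
  ellipse whose area-length volume follows a prescribed EDV/ESV cycle, for
  testing the chamber-metric formulas against closed-form ellipsoid volumes.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from sonoquant.datatypes import CineLoop, LVTrace
from sonoquant.errors import SizingError
from sonoquant.phantom.truth import PhantomTruth, make_ecg, speckle_field

__all__ = ["make_lv_cine", "make_lv_contour_trace", "LVCinePhantom"]


def _cycle_bump(phase: np.ndarray) -> np.ndarray:
    """0 at cycle ends, 1 at mid-cycle, C1-smooth."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))


class LVCinePhantom:
    """Result bundle for :func:`make_lv_cine` (loop, contours, true strain)."""

    def __init__(self, loop: CineLoop, contours: dict, true_strain: dict,
                 frame_strain: dict):
        self.loop = loop
        #: dict with "endo", "mid", "epi": list over frames of (P, 2) mm arrays
        self.contours = contours
        #: direction -> true peak strain, percent (signed)
        self.true_strain = true_strain
        #: direction -> per-frame true strain curve, percent
        self.frame_strain = frame_strain


def make_lv_cine(
    truth: PhantomTruth,
    view: str = "SAX",
    image_shape: tuple[int, int] = (128, 128),
    pixel_mm: float = 0.05,
    frame_rate: float = 250.0,
    period_s: float | None = None,
    n_points: int = 48,
    r_endo_mm: float = 1.0,
    r_epi_mm: float = 2.2,
    plax_axes_mm: tuple[float, float] = (2.6, 1.4),
    contour_inset_mm: float = 0.3,
    background_factor: float = 0.8,
    texture_correlation_px: float = 1.0,
    with_ecg: bool = True,
) -> LVCinePhantom:
    """Render one cardiac cycle of a deforming LV phantom.

    ``truth.true_strain`` prescribes peak deformation fractions, e.g.
    ``{"radial": 0.30}`` (wall thickening), ``{"circumferential": -0.20}``
    (shortening) for SAX, ``{"longitudinal": -0.15}`` for PLAX (isotropic
    in-plane shrink, so every in-plane length strain equals the prescribed
    value).  True per-frame strain is returned in closed form.
    """
    if view not in ("SAX", "PLAX"):
        raise ValueError("view must be SAX or PLAX")
    strain_spec = dict(truth.true_strain or {})
    a_pk = float(strain_spec.get("radial", 0.0))
    c_pk = float(strain_spec.get("circumferential", 0.0))
    l_pk = float(strain_spec.get("longitudinal", 0.0))
    period = period_s if period_s is not None else truth.diameter.period_s

    H, W = image_shape
    # frames span exactly one period with an even interval count, so both
    # cycle ends and the mid-cycle deformation peak are sampled exactly
    n_frames = max(2 * int(round(period * frame_rate / 2.0)) + 1, 9)
    times = np.linspace(0.0, period, n_frames)
    frame_rate = (n_frames - 1) / period
    g = _cycle_bump(times / period)

    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    dy_mm = (yy - cy) * pixel_mm
    dx_mm = (xx - cx) * pixel_mm

    rng = truth.rng()
    # material texture on the reference grid; tissue carries it while deforming
    texture = speckle_field((H, W), rng, texture_correlation_px)

    r_mid = 0.5 * (r_endo_mm + r_epi_mm)
    edge_mm = 2.0 * pixel_mm  # soft mask edge for sub-pixel rendering

    def soft_band(r, lo, hi):
        inner = 0.5 * (1.0 + np.tanh((r - lo) / edge_mm))
        outer = 0.5 * (1.0 + np.tanh((hi - r) / edge_mm))
        return inner * outer

    frames = np.empty((n_frames, H, W))
    contours = {"endo": [], "mid": [], "epi": []}
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)

    if view == "SAX":
        max_r = (r_mid + (r_epi_mm - r_mid) * (1 + max(a_pk, 0.0))) * (1 + max(c_pk, 0.0))
        if max_r + 4 * edge_mm > min(cy, cx) * pixel_mm:
            raise SizingError("deformed annulus does not fit in the frame")
        r_pix = np.hypot(dy_mm, dx_mm)
        for i in range(n_frames):
            a, c = a_pk * g[i], c_pk * g[i]
            # inverse of r(R) = (r_mid + (R - r_mid)(1+a)) (1+c)
            R = r_mid + (r_pix / (1.0 + c) - r_mid) / (1.0 + a)
            R = np.maximum(R, 0.0)
            scale = np.where(r_pix > 1e-9, R / np.maximum(r_pix, 1e-9), 1.0)
            ry = cy + dy_mm * scale / pixel_mm
            rx = cx + dx_mm * scale / pixel_mm
            tex = map_coordinates(texture, [ry, rx], order=3, mode="nearest")
            wall = soft_band(R, r_endo_mm, r_epi_mm)
            # background_factor < 1 keeps the wall visible while damping the
            # wall/cavity edge, whose motion differs from nearby tissue and
            # would otherwise bias block matching toward it
            frame = 15.0 + 185.0 * (wall + background_factor * (1.0 - wall)) * tex
            if truth.noise.additive > 0:
                frame = frame + rng.normal(0.0, truth.noise.additive, size=(H, W))
            frames[i] = np.clip(frame, 0.0, 255.0)
            for name, R0 in (("endo", r_endo_mm + contour_inset_mm),
                             ("mid", r_mid),
                             ("epi", r_epi_mm - contour_inset_mm)):
                r_t = (r_mid + (R0 - r_mid) * (1.0 + a)) * (1.0 + c)
                pts = np.column_stack([r_t * np.cos(theta), r_t * np.sin(theta)])
                contours[name].append(pts)
        thick = (1.0 + a_pk * g) * (1.0 + c_pk * g) - 1.0
        frame_strain = {"radial": 100.0 * thick, "circumferential": 100.0 * c_pk * g}
    else:  # PLAX: isotropic in-plane scaling by (1 + l(t))
        ax_a, ax_b = plax_axes_mm
        s_extreme = 1.0 + (l_pk if l_pk > 0 else 0.0)
        if (ax_a * s_extreme + 4 * edge_mm > cx * pixel_mm
                or ax_b * s_extreme + 4 * edge_mm > cy * pixel_mm):
            raise SizingError("deformed ellipse does not fit in the frame")
        wall = 0.5
        for i in range(n_frames):
            s = 1.0 + l_pk * g[i]
            Ry = cy + dy_mm / s / pixel_mm
            Rx = cx + dx_mm / s / pixel_mm
            tex = map_coordinates(texture, [Ry, Rx], order=3, mode="nearest")
            # elliptical radius in reference coordinates
            rho = np.hypot(dx_mm / s / ax_a, dy_mm / s / ax_b)
            band = soft_band(rho, 1.0 - wall / ax_b, 1.0)
            frame = 15.0 + 185.0 * (band + background_factor * (1.0 - band)) * tex
            if truth.noise.additive > 0:
                frame = frame + rng.normal(0.0, truth.noise.additive, size=(H, W))
            frames[i] = np.clip(frame, 0.0, 255.0)
            for name, f in (("endo", 1.0 - wall / ax_b + 0.08), ("mid", 1.0 - 0.5 * wall / ax_b),
                            ("epi", 1.0 - 0.08)):
                pts = np.column_stack([s * ax_a * f * np.cos(theta),
                                       s * ax_b * f * np.sin(theta)])
                contours[name].append(pts)
        frame_strain = {"longitudinal": 100.0 * l_pk * g}

    true_strain = {}
    for name, curve in frame_strain.items():
        idx = int(np.argmax(np.abs(curve)))
        true_strain[name] = float(curve[idx])

    ecg = make_ecg(times[-1] + 1.0 / frame_rate, hr_bpm=60.0 / period) if with_ecg else None
    loop = CineLoop(frames=frames, pixel_spacing=(pixel_mm, pixel_mm),
                    frame_rate=frame_rate, ecg=ecg, view=view)
    return LVCinePhantom(loop, contours, true_strain, frame_strain)


def make_lv_contour_trace(
    edv_ul: float = 50.0,
    esv_ul: float = 25.0,
    period_s: float = 0.2,
    frame_rate: float = 250.0,
    n_cycles: int = 1,
    n_points: int = 64,
    wall_thickness_mm: float = 0.6,
    elongation: float = 2.0,
) -> LVTrace:
    """Elliptical PLAX tracings whose area-length volume is prescribed.

    The endocardial border is an ellipse with semi-axes ``(a, b)``,
    ``a = elongation * b``; for an ellipse the monoplane area-length volume
    ``8 A^2 / (3 pi L)`` equals the prolate-ellipsoid volume
    ``4/3 pi a b^2``, so EDV/ESV are exact by construction.  Volumes follow
    ``V(t) = EDV + (ESV - EDV) * bump(t)`` via isotropic scaling.
    """
    if not (edv_ul > esv_ul > 0):
        raise ValueError("need EDV > ESV > 0")
    n_frames = int(round(n_cycles * period_s * frame_rate)) + 1
    times = np.arange(n_frames) / frame_rate
    phase = np.mod(times, period_s) / period_s
    vol = edv_ul + (esv_ul - edv_ul) * _cycle_bump(phase)

    b0 = (edv_ul / (4.0 / 3.0 * np.pi * elongation)) ** (1.0 / 3.0)
    a0 = elongation * b0
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    endo, epi, laxis = [], [], []
    for v in vol:
        s = (v / edv_ul) ** (1.0 / 3.0)
        a, b = a0 * s, b0 * s
        endo.append(np.column_stack([a * np.cos(theta), b * np.sin(theta)]))
        epi.append(np.column_stack([(a + wall_thickness_mm) * np.cos(theta),
                                    (b + wall_thickness_mm) * np.sin(theta)]))
        laxis.append(2.0 * a)
    return LVTrace(time=times, endo=endo, epi=epi,
                   long_axis_mm=np.asarray(laxis), view="PLAX")
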