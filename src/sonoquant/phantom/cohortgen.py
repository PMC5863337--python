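"""Generate a full synthetic two-group cohort on disk.

Produces per-animal vessel cines, coupled Doppler spectrograms, renal and
mitral Doppler spectrograms, LV border tracings and liver/kidney images,
plus the pipeline config that points at them.  Group-level biomarker
targets are drawn per animal from seeded normal distributions, so effect
directions (or planted nulls) are controlled exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from sonoquant import io
from sonoquant.phantom.cardiacphantom import make_lv_contour_trace
from sonoquant.phantom.doppler import make_doppler_trace
from sonoquant.phantom.tissue import make_liver_kidney_image
from sonoquant.phantom.truth import (
    DiameterWaveform,
    MitralWaveform,
    NoiseSpec,
    PhantomTruth,
    PulsatileWaveform,
)
from sonoquant.phantom.vessel import DEFAULT_VESSEL_NOISE, make_coupled_vessel

__all__ = ["GroupTargets", "WT_LIKE", "DBDB_LIKE", "generate_cohort"]


@dataclass(frozen=True)
class GroupTargets:
    """Mean biomarker targets for one group (per-animal jitter is relative)."""

    dd_mm: float = 1.00
    reld_pct: float = 21.0
    pwv_m_s: float = 2.0
    hr_bpm: float = 380.0
    renal_psv_mm_s: float = 120.0
    ri: float = 0.64
    pi: float = 1.02
    mitral_e_mm_s: float = 700.0
    ea: float = 1.37
    sv_ul: float = 39.0
    ef_pct: float = 53.5
    liver_gray: float = 95.0
    kidney_gray: float = 100.0
    jitter: float = 0.04  # relative sd applied to each target
    noise: NoiseSpec = field(default_factory=lambda: DEFAULT_VESSEL_NOISE)


# Effect directions for a leptin-receptor-deficient-like group: lower
# EF/FS/SV/CO/relD/WSR, higher E/A, RI, PI; equal steatosis targets keep
# the gray-level ratio as a planted null.
WT_LIKE = GroupTargets()
DBDB_LIKE = GroupTargets(dd_mm=0.92, reld_pct=17.0, hr_bpm=300.0,
                         ri=0.73, pi=1.23, ea=2.00, sv_ul=23.0, ef_pct=44.0)


def _jittered(rng: np.random.Generator, targets: GroupTargets) -> dict:
    def j(x, lo=None, hi=None):
        v = x * (1.0 + targets.jitter * rng.standard_normal())
        if lo is not None:
            v = max(v, lo)
        if hi is not None:
            v = min(v, hi)
        return float(v)

    return {
        "dd_mm": j(targets.dd_mm, lo=0.5),
        "reld_pct": j(targets.reld_pct, lo=5.0),
        "pwv_m_s": j(targets.pwv_m_s, lo=0.8),
        "hr_bpm": j(targets.hr_bpm, lo=150.0),
        "renal_psv": j(targets.renal_psv_mm_s, lo=50.0),
        "ri": j(targets.ri, lo=0.3, hi=0.9),
        "pi": j(targets.pi, lo=0.5),
        "mitral_e": j(targets.mitral_e_mm_s, lo=300.0),
        "ea": j(targets.ea, lo=0.8),
        "sv_ul": j(targets.sv_ul, lo=10.0),
        "ef_pct": j(targets.ef_pct, lo=25.0, hi=75.0),
        "liver_gray": j(targets.liver_gray, lo=30.0, hi=220.0),
        "kidney_gray": j(targets.kidney_gray, lo=30.0, hi=220.0),
    }


def _write_animal(out: Path, animal_id: str, params: dict, noise: NoiseSpec,
                  seed: int) -> dict:
    period = 60.0 / params["hr_bpm"]
    spec: dict = {"hr_bpm": params["hr_bpm"]}

    # vessel: coupled B-mode + Doppler so relD, PWV and WSR are consistent
    wave = DiameterWaveform(dd_mm=params["dd_mm"],
                            ds_mm=params["dd_mm"] * (1 + params["reld_pct"] / 100.0),
                            period_s=period)
    truth = PhantomTruth(seed=seed, diameter=wave, true_pwv_m_s=params["pwv_m_s"],
                         noise=noise)
    loop, sp, _, _ = make_coupled_vessel(truth, n_beats=3, image_shape=(120, 48),
                                         frame_rate=400.0)
    spec["vessel_cine"] = str(io.write_cine(loop, out / f"{animal_id}_vessel.tif"))
    spec["vessel_doppler"] = str(io.write_spectrogram(sp, out / f"{animal_id}_vdop.tif"))

    psv = params["renal_psv"]
    renal = PulsatileWaveform(psv_mm_s=psv, edv_mm_s=psv * (1 - params["ri"]),
                              mv_mm_s=psv * params["ri"] / params["pi"],
                              period_s=period)
    sp_r, _ = make_doppler_trace(renal, seed=seed + 1, noise=noise, n_cycles=3)
    spec["renal_doppler"] = str(io.write_spectrogram(sp_r, out / f"{animal_id}_renal.tif"))

    mitral = MitralWaveform(e_mm_s=params["mitral_e"],
                            a_mm_s=params["mitral_e"] / params["ea"],
                            period_s=period)
    sp_m, _ = make_doppler_trace(mitral, seed=seed + 2, noise=noise, n_cycles=3)
    spec["mitral_doppler"] = str(io.write_spectrogram(sp_m, out / f"{animal_id}_mitral.tif"))

    edv_ul = params["sv_ul"] / (params["ef_pct"] / 100.0)
    trace = make_lv_contour_trace(edv_ul=edv_ul, esv_ul=edv_ul - params["sv_ul"],
                                  period_s=period)
    spec["lv_contours"] = str(io.write_contours_csv(trace, out / f"{animal_id}_lv.csv"))

    img, liver_roi, kidney_roi = make_liver_kidney_image(
        (params["liver_gray"], params["kidney_gray"]), seed=seed + 3,
        noise=NoiseSpec(speckle=0.3, correlation_px=1.5))
    p_img = out / f"{animal_id}_liver.tif"
    tifffile.imwrite(p_img, img.astype(np.float32))
    spec["liver_image"] = str(p_img)
    spec["liver_roi"] = list(liver_roi)
    spec["kidney_roi"] = list(kidney_roi)
    return spec


def generate_cohort(
    out_dir: str | Path,
    n_per_group: int = 8,
    seed: int = 0,
    group_targets: dict[str, GroupTargets] | None = None,
) -> Path:
    """Write a two-group synthetic cohort; returns the config JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if group_targets is None:
        group_targets = {"wt": WT_LIKE, "dbdb": DBDB_LIKE}
    if len(group_targets) != 2:
        raise ValueError("exactly two groups required")

    rng = np.random.default_rng(seed)
    animals: dict[str, dict] = {}
    groups: dict[str, list[str]] = {}
    i = 0
    for gname in sorted(group_targets):
        targets = group_targets[gname]
        groups[gname] = []
        for k in range(n_per_group):
            animal_id = f"{gname}{k:02d}"
            params = _jittered(rng, targets)
            spec = _write_animal(out_dir, animal_id, params, targets.noise,
                                 seed=seed * 1000 + i)
            spec["group"] = gname
            animals[animal_id] = spec
            groups[gname].append(animal_id)
            i += 1

    config = {"groups": groups, "animals": animals, "pp_convention": "literal",
              "seed": seed}
    path = out_dir / "cohort_config.json"
    path.write_text(json.dumps(config, indent=1, sort_keys=True))
    return path
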