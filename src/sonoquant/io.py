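"""File round-tripping: multi-frame TIFF + JSON sidecars and CSV traces.

Cine loops and spectrograms travel as TIFF stacks with a JSON sidecar
holding calibration metadata; traces, contours and ECG go as plain CSV.
Every writer has a matching reader and the pair round-trips exactly
(within float32 storage precision for image data).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from sonoquant.datatypes import CineLoop, DiameterTrace, Ecg, LVTrace, Spectrogram, VelocityTrace

__all__ = [
    "write_cine", "read_cine",
    "write_spectrogram", "read_spectrogram",
    "write_ecg_csv", "read_ecg_csv",
    "write_diameter_csv", "read_diameter_csv",
    "write_velocity_csv", "read_velocity_csv",
    "write_contours_csv", "read_contours_csv",
]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_cine(loop: CineLoop, tiff_path: str | Path, extra_meta: Optional[dict] = None) -> Path:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, loop.frames.astype(np.float32))
    meta = {
        "kind": "cine",
        "pixel_spacing_mm": list(loop.pixel_spacing),
        "frame_rate_hz": loop.frame_rate,
        "view": loop.view,
    }
    if loop.ecg is not None:
        meta["ecg"] = {"sample_rate_hz": loop.ecg.sample_rate,
                       "samples": loop.ecg.samples.tolist()}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(tiff_path).write_text(json.dumps(meta, indent=1))
    return tiff_path


def read_cine(tiff_path: str | Path) -> CineLoop:
    tiff_path = Path(tiff_path)
    frames = np.asarray(tifffile.imread(tiff_path), dtype=float)
    meta = json.loads(_sidecar_path(tiff_path).read_text())
    ecg = None
    if "ecg" in meta:
        ecg = Ecg(samples=np.asarray(meta["ecg"]["samples"], dtype=float),
                  sample_rate=meta["ecg"]["sample_rate_hz"])
    return CineLoop(frames=frames, pixel_spacing=tuple(meta["pixel_spacing_mm"]),
                    frame_rate=meta["frame_rate_hz"], ecg=ecg, view=meta["view"])


def write_spectrogram(spec: Spectrogram, tiff_path: str | Path,
                      extra_meta: Optional[dict] = None) -> Path:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, spec.power.astype(np.float32))
    meta = {
        "kind": "spectrogram",
        "time_axis_s": spec.time_axis.tolist(),
        "velocity_axis_mm_s": spec.velocity_axis.tolist(),
        "prf_hz": spec.prf,
        "angle_correction_deg": spec.angle_correction,
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(tiff_path).write_text(json.dumps(meta, indent=1))
    return tiff_path


def read_spectrogram(tiff_path: str | Path) -> Spectrogram:
    tiff_path = Path(tiff_path)
    power = np.asarray(tifffile.imread(tiff_path), dtype=float)
    meta = json.loads(_sidecar_path(tiff_path).read_text())
    return Spectrogram(power=power,
                       time_axis=np.asarray(meta["time_axis_s"], dtype=float),
                       velocity_axis=np.asarray(meta["velocity_axis_mm_s"], dtype=float),
                       prf=meta["prf_hz"], angle_correction=meta["angle_correction_deg"])


def write_ecg_csv(ecg: Ecg, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": ecg.time, "value": ecg.samples}).to_csv(path, index=False)
    return path


def read_ecg_csv(path: str | Path) -> Ecg:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t)))
    return Ecg(samples=df["value"].to_numpy(), sample_rate=rate)


def write_diameter_csv(trace: DiameterTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "diameter_mm": trace.diameter}).to_csv(path, index=False)
    return path


def read_diameter_csv(path: str | Path) -> DiameterTrace:
    df = pd.read_csv(path)
    return DiameterTrace(time=df["time_s"].to_numpy(), diameter=df["diameter_mm"].to_numpy())


def write_velocity_csv(trace: VelocityTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "velocity_mm_s": trace.velocity}).to_csv(path, index=False)
    return path


def read_velocity_csv(path: str | Path) -> VelocityTrace:
    df = pd.read_csv(path)
    return VelocityTrace(time=df["time_s"].to_numpy(), velocity=df["velocity_mm_s"].to_numpy())


def write_contours_csv(trace: LVTrace, path: str | Path) -> Path:
    """Long-format contour table: frame, time, contour, point, x_mm, y_mm."""
    path = Path(path)
    rows = []
    for i, t in enumerate(trace.time):
        for name, contours in (("endo", trace.endo), ("epi", trace.epi)):
            if contours is None:
                continue
            for j, (x, y) in enumerate(contours[i]):
                rows.append((i, t, name, j, x, y))
    df = pd.DataFrame(rows, columns=["frame", "time_s", "contour", "point", "x_mm", "y_mm"])
    if trace.long_axis_mm is not None:
        la = pd.DataFrame({"frame": np.arange(trace.time.size),
                           "long_axis_mm": trace.long_axis_mm})
        df = df.merge(la, on="frame", how="left")
    df.to_csv(path, index=False)
    return path


def read_contours_csv(path: str | Path, view: str = "PLAX") -> LVTrace:
    df = pd.read_csv(path)
    frames = np.sort(df["frame"].unique())
    time = np.array([df.loc[df.frame == f, "time_s"].iloc[0] for f in frames])
    endo, epi = [], []
    has_epi = (df["contour"] == "epi").any()
    for f in frames:
        sub = df[df.frame == f]
        e = sub[sub.contour == "endo"].sort_values("point")
        endo.append(e[["x_mm", "y_mm"]].to_numpy())
        if has_epi:
            p = sub[sub.contour == "epi"].sort_values("point")
            epi.append(p[["x_mm", "y_mm"]].to_numpy())
    long_axis = None
    if "long_axis_mm" in df.columns:
        long_axis = np.array([df.loc[df.frame == f, "long_axis_mm"].iloc[0] for f in frames])
    return LVTrace(time=time, endo=endo, epi=epi if has_epi else None,
                   long_axis_mm=long_axis, view=view)
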