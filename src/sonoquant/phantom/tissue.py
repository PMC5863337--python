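"""Liver/kidney parenchyma phantom for gray-level ratio analysis."""

from __future__ import annotations

import numpy as np

from sonoquant.phantom.truth import NoiseSpec, speckle_field

__all__ = ["make_liver_kidney_image"]


def make_liver_kidney_image(
    gray_means: tuple[float, float],
    seed: int = 0,
    image_shape: tuple[int, int] = (200, 260),
    noise: NoiseSpec | None = None,
) -> tuple[np.ndarray, tuple[int, int, int, int], tuple[int, int, int, int]]:
    """One B-mode-like image holding liver (left) and kidney (right) textures.

    Returns ``(image, liver_roi, kidney_roi)`` with rectangular ROIs as
    ``(row0, row1, col0, col1)``, 0-based half-open, placed well inside each
    region.  Texture is unit-mean multiplicative speckle, so the expected
    ROI mean equals the prescribed mean.
    """
    liver_mean, kidney_mean = gray_means
    if not (0 <= liver_mean <= 255 and 0 <= kidney_mean <= 255):
        raise ValueError("gray means must lie in [0, 255]")
    noise = noise or NoiseSpec()
    H, W = image_shape
    rng = np.random.default_rng(seed)
    split = W // 2
    base = np.empty((H, W))
    base[:, :split] = liver_mean
    base[:, split:] = kidney_mean
    img = base
    if noise.speckle > 0:
        s = speckle_field((H, W), rng, noise.correlation_px)
        img = base * (1.0 + noise.speckle * (s - 1.0))
    if noise.additive > 0:
        img = img + rng.normal(0.0, noise.additive, size=(H, W))
    img = np.clip(img, 0.0, 255.0)

    m = 20  # ROI margin away from the region boundary
    liver_roi = (m, H - m, m, split - m)
    kidney_roi = (m, H - m, split + m, W - m)
    return img, liver_roi, kidney_roi
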