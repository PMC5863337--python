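"""Liver-to-kidney gray-level ratio on a single B-mode image.

The ratio of the mean gray level in a liver ROI to that in a
kidney-parenchyma ROI is a surrogate index of hepatic steatosis; the
brighter the liver relative to the kidney, the higher the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from skimage.draw import polygon as draw_polygon

from sonoquant.errors import RoiError

__all__ = ["SteatosisResult", "roi_mean", "steatoscore", "score_image"]

MIN_ROI_AREA_PX = 100
Rect = tuple[int, int, int, int]  # (row0, row1, col0, col1), 0-based half-open
Roi = Union[Rect, Sequence[tuple[float, float]]]


@dataclass(frozen=True)
class SteatosisResult:
    liver_mean: float
    kidney_mean: float
    steatoscore: float


def _roi_mask(image: np.ndarray, roi: Roi) -> np.ndarray:
    h, w = image.shape
    mask = np.zeros((h, w), dtype=bool)
    roi_arr = np.asarray(roi, dtype=float)
    if roi_arr.ndim == 1 and roi_arr.size == 4:
        r0, r1, c0, c1 = (int(v) for v in roi_arr)
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise RoiError(f"rectangle {roi} out of bounds for image {h}x{w}")
        mask[r0:r1, c0:c1] = True
    elif roi_arr.ndim == 2 and roi_arr.shape[1] == 2 and roi_arr.shape[0] >= 3:
        rows, cols = roi_arr[:, 0], roi_arr[:, 1]
        if rows.min() < 0 or cols.min() < 0 or rows.max() > h or cols.max() > w:
            raise RoiError("polygon vertex out of bounds")
        rr, cc = draw_polygon(rows, cols, shape=(h, w))
        mask[rr, cc] = True
    else:
        raise RoiError("ROI must be a (r0,r1,c0,c1) rectangle or >=3 (row,col) vertices")
    if mask.sum() < MIN_ROI_AREA_PX:
        raise RoiError(f"ROI area {int(mask.sum())} px below minimum {MIN_ROI_AREA_PX}")
    return mask


def roi_mean(image: np.ndarray, roi: Roi) -> float:
    """Arithmetic mean gray level strictly inside the ROI."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise RoiError("image must be 2-D grayscale")
    return float(image[_roi_mask(image, roi)].mean())


def steatoscore(liver_mean: float, kidney_mean: float, eps: float = 1e-6) -> float:
    """Liver/kidney mean gray-level ratio."""
    if kidney_mean <= eps:
        raise RoiError("kidney ROI mean is ~0: uninformative reference region")
    return liver_mean / kidney_mean


def score_image(image: np.ndarray, liver_roi: Roi, kidney_roi: Roi) -> SteatosisResult:
    """Compute the full result (means plus ratio) from one image.

    The two ROIs must not overlap.
    """
    image = np.asarray(image, dtype=float)
    m_l = _roi_mask(image, liver_roi)
    m_k = _roi_mask(image, kidney_roi)
    if np.any(m_l & m_k):
        raise RoiError("liver and kidney ROIs overlap")
    liver = float(image[m_l].mean())
    kidney = float(image[m_k].mean())
    return SteatosisResult(liver_mean=liver, kidney_mean=kidney,
                           steatoscore=steatoscore(liver, kidney))
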