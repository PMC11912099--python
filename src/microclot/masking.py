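"""Segmentation of the fibrin micro-clot from the first time-lapse frame.

The clot appears as a roughly circular region darker than the surrounding
well in the first brightfield frame.  The mask is produced by five steps:

1. binarize and invert (dark pixels become foreground),
2. morphological closing (suppress salt noise inside the clot),
3. hole filling,
4. morphological opening (remove small bright-field debris),
5. keep the largest connected component.

The resulting frame-1 mask is applied unchanged to every later frame; the
assay never re-segments, so everything downstream measures the *initial*
fibrin footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import (
    DegenerateThresholdError,
    InvalidInputError,
    NoObjectError,
    UndersizedMaskError,
)

__all__ = [
    "MaskParams",
    "FibrinMask",
    "binarize_invert",
    "close_fill_open",
    "largest_component",
    "generate_mask",
]


@dataclass(frozen=True)
class MaskParams:
    """Tunables of the five-step mask pipeline.

    connectivity: 1 = 4-connected, 2 = 8-connected (component labelling);
    hole filling always treats the background as 4-connected.
    min_mask_fraction rejects segmentations smaller than this fraction of
    the image area, so a failed segmentation errors out instead of silently
    tracking noise; max_mask_fraction rejects masks that swallow most of the
    image (thresholding pure noise merges into one giant blob after closing,
    which is not a clot and leaves no background for the intensity ratio).
    """

    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    closing_radius: int = 3
    opening_radius: int = 5
    connectivity: int = 2
    min_mask_fraction: float = 0.005
    max_mask_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise InvalidInputError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise InvalidInputError("fixed threshold method requires fixed_threshold")
        if self.closing_radius < 1 or self.opening_radius < 1:
            raise InvalidInputError("structuring-element radii must be >= 1")
        if self.connectivity not in (1, 2):
            raise InvalidInputError("connectivity must be 1 (4-conn) or 2 (8-conn)")
        if not 0 < self.min_mask_fraction < 1:
            raise InvalidInputError("min_mask_fraction must lie in (0, 1)")
        if not self.min_mask_fraction < self.max_mask_fraction <= 1:
            raise InvalidInputError("max_mask_fraction must lie in (min_mask_fraction, 1]")


@dataclass
class FibrinMask:
    """Boolean clot region with segmentation provenance."""

    mask: np.ndarray
    area_px: int
    threshold_used: float
    params: MaskParams

    @property
    def shape(self):
        return self.mask.shape


def _select_threshold(frame: np.ndarray, params: MaskParams) -> float:
    if params.threshold_method == "fixed":
        return float(params.fixed_threshold)
    if float(np.ptp(frame)) == 0.0:
        raise DegenerateThresholdError("frame has constant intensity; Otsu threshold undefined")
    return float(threshold_otsu(frame))


def binarize_invert(frame: np.ndarray, params: MaskParams = MaskParams()) -> np.ndarray:
    """Threshold the frame and invert so that dark (clot) pixels are foreground."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise InvalidInputError("frame is empty")
    if not np.all(np.isfinite(frame)):
        raise InvalidInputError("frame contains non-finite intensities")
    return frame < _select_threshold(frame, params)


def close_fill_open(binary: np.ndarray, params: MaskParams = MaskParams()) -> np.ndarray:
    """Closing, hole filling, then opening, with disc structuring elements."""
    binary = np.asarray(binary, dtype=bool)
    out = morphology.closing(binary, morphology.disk(params.closing_radius))
    # 4-connected background: holes are regions not reachable from the border
    out = ndimage.binary_fill_holes(out)
    out = morphology.opening(out, morphology.disk(params.opening_radius))
    return out.astype(bool)


def largest_component(binary: np.ndarray, params: MaskParams = MaskParams(),
                      threshold_used: float = float("nan")) -> FibrinMask:
    """Keep only the largest connected foreground component.

    Ties in area are broken deterministically by the component whose first
    pixel appears earliest in row-major scan order.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise NoObjectError("foreground is empty; no object to isolate")
    labels = label(binary, connectivity=params.connectivity)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    max_area = counts.max()
    candidates = np.nonzero(counts == max_area)[0]
    if candidates.size == 1:
        keep = candidates[0]
    else:
        flat = labels.ravel()
        keep = min(candidates, key=lambda lab: int(np.argmax(flat == lab)))
    mask = labels == keep
    area = int(max_area)
    if area < params.min_mask_fraction * binary.size:
        raise UndersizedMaskError(
            f"largest component has {area} px, below "
            f"{params.min_mask_fraction:.3%} of the image area"
        )
    if area > params.max_mask_fraction * binary.size:
        raise DegenerateThresholdError(
            f"largest component covers {area / binary.size:.1%} of the image; "
            "thresholding did not isolate a dark minority object"
        )
    return FibrinMask(mask=mask, area_px=area, threshold_used=threshold_used, params=params)


def generate_mask(first_frame: np.ndarray, params: MaskParams = MaskParams()) -> FibrinMask:
    """Full five-step mask pipeline on the first frame of a well."""
    frame = np.asarray(first_frame, dtype=float)
    if frame.size == 0:
        raise InvalidInputError("frame is empty")
    if not np.all(np.isfinite(frame)):
        raise InvalidInputError("frame contains non-finite intensities")
    threshold = _select_threshold(frame, params)
    binary = frame < threshold
    cleaned = close_fill_open(binary, params)
    return largest_component(cleaned, params, threshold_used=threshold)
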