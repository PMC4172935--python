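"""Hippocampus extraction and area measurement on normalized coronal slices.

The hippocampus shrinks early in Alzheimer's disease, so its cross-sectional
area on a coronal slice is a compact atrophy biomarker.  In Talairach-
normalized 498x498 coronal slices the left and right hippocampi fall inside
fixed rectangular regions of interest; the extraction chain per side is:

    ROI mask mapping -> ROI extraction -> noise removal -> region trimming
    -> hippocampus extraction -> area calculation

Noise removal binarizes the ROI at the lower GM threshold (tissue vs
CSF/background), applies morphological opening and keeps the largest
8-connected object.  Region trimming crops to that object's bounding box
(plus a small margin) and suppresses everything outside the object.  The
hippocampus estimate is then the GM-intensity-range pixels of the retained
object, and its area is the pixel count.

Coordinate convention: ROI corners are (column, row), 0-based, half-open
``[x1, x2) x [y1, y2)``.  The default rectangles for a 498x498 slice are
left (130, 300)-(225, 360) and right (280, 300)-(375, 360); other image
sizes scale these proportionally (round half up).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_opening
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk

from .errors import ValidationError
from .preprocess import SliceImage, ThreshRange

__all__ = [
    "ROIRect",
    "HippocampusConfig",
    "HippocampusResult",
    "default_masks",
    "extract_roi",
    "remove_noise",
    "trim_region",
    "extract_hippocampus",
    "hippocampus_area",
    "hippocampus_pipeline",
]

logger = logging.getLogger(__name__)

REFERENCE_SIZE = 498
LEFT_ROI_REF = (130, 300, 225, 360)
RIGHT_ROI_REF = (280, 300, 375, 360)


@dataclass(frozen=True)
class ROIRect:
    """Half-open rectangle ``[x1, x2) x [y1, y2)`` in (column, row) pixels."""

    x1: int
    y1: int
    x2: int
    y2: int

    def __post_init__(self) -> None:
        if not (0 <= self.x1 < self.x2 and 0 <= self.y1 < self.y2):
            raise ValidationError(
                f"invalid ROI rectangle ({self.x1},{self.y1})-({self.x2},{self.y2})"
            )

    @property
    def width(self) -> int:
        return self.x2 - self.x1

    @property
    def height(self) -> int:
        return self.y2 - self.y1

    def contains_point(self, x: float, y: float) -> bool:
        return self.x1 <= x < self.x2 and self.y1 <= y < self.y2


@dataclass(frozen=True)
class HippocampusConfig:
    """Tunable parameters of the extraction chain.

    opening_radius: disk radius (px) of the morphological opening used for
    noise removal.  margin: bounding-box expansion (px) applied during
    region trimming.  left_roi / right_roi override the default rectangles.
    """

    opening_radius: int = 1
    margin: int = 2
    left_roi: ROIRect | None = None
    right_roi: ROIRect | None = None

    def __post_init__(self) -> None:
        if self.opening_radius < 0:
            raise ValidationError("opening_radius must be >= 0")
        if self.margin < 0:
            raise ValidationError("margin must be >= 0")


@dataclass
class HippocampusResult:
    """Per-side outcome plus the intermediate images kept for audit."""

    side: str
    area: int
    roi_used: ROIRect
    roi_image: SliceImage
    cleaned_mask: np.ndarray
    trimmed: SliceImage
    final_mask: np.ndarray


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def default_masks(image_width: int, image_height: int) -> tuple[ROIRect, ROIRect]:
    """The left and right hippocampal ROI rectangles for a given slice size.

    For a 498x498 slice these are the reference rectangles; other sizes
    scale the corners proportionally (round half up).
    """
    if image_width < 2 or image_height < 2:
        raise ValidationError("image must be at least 2x2 to carry ROI masks")
    sx = image_width / REFERENCE_SIZE
    sy = image_height / REFERENCE_SIZE
    rects = []
    for x1, y1, x2, y2 in (LEFT_ROI_REF, RIGHT_ROI_REF):
        rects.append(
            ROIRect(
                _round_half_up(x1 * sx),
                _round_half_up(y1 * sy),
                _round_half_up(x2 * sx),
                _round_half_up(y2 * sy),
            )
        )
    return rects[0], rects[1]


def extract_roi(image: SliceImage, rect: ROIRect) -> SliceImage:
    """Copy the rectangular sub-image (and sub-mask) out of a slice."""
    if rect.x2 > image.width or rect.y2 > image.height:
        raise ValidationError(
            f"ROI ({rect.x1},{rect.y1})-({rect.x2},{rect.y2}) exceeds "
            f"{image.width}x{image.height} image bounds"
        )
    sub = image.pixels[rect.y1 : rect.y2, rect.x1 : rect.x2].copy()
    mask = None
    if image.brain_mask is not None:
        mask = image.brain_mask[rect.y1 : rect.y2, rect.x1 : rect.x2].copy()
    return SliceImage(sub, brain_mask=mask)


def _largest_component(labels: np.ndarray) -> np.ndarray:
    """Boolean mask of the largest labelled component.

    Ties on pixel count are broken by the smallest (row, col) bounding-box
    top-left corner, which makes the choice deterministic.
    """
    props = regionprops(labels)
    best = max(props, key=lambda p: (p.num_pixels, (-p.bbox[0], -p.bbox[1])))
    return labels == best.label


def remove_noise(
    roi: SliceImage, thresh: ThreshRange, opening_radius: int = 1
) -> np.ndarray:
    """Binarize the ROI at the lower GM threshold and keep the largest object.

    Pixels with intensity >= ``thresh.lo`` count as tissue; smaller objects
    are removed by morphological opening with a disk of ``opening_radius``,
    then only the largest 8-connected component is retained.  An empty
    result is returned as an all-False mask with a logged warning (the
    downstream area will be 0).
    """
    binary = roi.pixels >= thresh.lo
    if opening_radius > 0:
        binary = binary_opening(binary, structure=disk(opening_radius))
    labels = cc_label(binary, connectivity=2)
    if labels.max() == 0:
        logger.warning("ROI empty after binarization/opening; area will be 0")
        return np.zeros(roi.pixels.shape, dtype=bool)
    return _largest_component(labels)


def trim_region(
    roi: SliceImage, cleaned: np.ndarray, margin: int = 2
) -> SliceImage:
    """Crop the ROI to the retained object's bounding box plus a margin.

    Pixels outside the retained object are set to the background sentinel 0
    and the cropped object mask is carried along as the output's
    ``brain_mask``.  An empty ``cleaned`` mask yields a 1x1 background
    image (downstream area 0).
    """
    cleaned = np.asarray(cleaned, dtype=bool)
    if cleaned.shape != roi.pixels.shape:
        raise ValidationError("cleaned mask shape must match ROI shape")
    if not cleaned.any():
        return SliceImage(np.zeros((1, 1)), brain_mask=np.zeros((1, 1), dtype=bool))
    rows, cols = np.nonzero(cleaned)
    r0 = max(rows.min() - margin, 0)
    r1 = min(rows.max() + margin + 1, roi.height)
    c0 = max(cols.min() - margin, 0)
    c1 = min(cols.max() + margin + 1, roi.width)
    sub_mask = cleaned[r0:r1, c0:c1]
    sub = np.where(sub_mask, roi.pixels[r0:r1, c0:c1], 0.0)
    return SliceImage(sub, brain_mask=sub_mask.copy())


def extract_hippocampus(trimmed: SliceImage, thresh: ThreshRange) -> np.ndarray:
    """GM-range pixels of the retained object: the hippocampus estimate."""
    component = (
        trimmed.brain_mask
        if trimmed.brain_mask is not None
        else trimmed.pixels > 0
    )
    px = trimmed.pixels
    return component & (px >= thresh.lo) & (px <= thresh.hi)


def hippocampus_area(mask: np.ndarray) -> int:
    """Area of a hippocampus mask in pixels."""
    return int(np.count_nonzero(mask))


def _run_side(
    image: SliceImage, rect: ROIRect, thresh: ThreshRange, side: str,
    config: HippocampusConfig,
) -> HippocampusResult:
    roi = extract_roi(image, rect)
    cleaned = remove_noise(roi, thresh, opening_radius=config.opening_radius)
    trimmed = trim_region(roi, cleaned, margin=config.margin)
    final = extract_hippocampus(trimmed, thresh)
    return HippocampusResult(
        side=side,
        area=hippocampus_area(final),
        roi_used=rect,
        roi_image=roi,
        cleaned_mask=cleaned,
        trimmed=trimmed,
        final_mask=final,
    )


def hippocampus_pipeline(
    image: SliceImage,
    thresh: ThreshRange,
    config: HippocampusConfig | None = None,
) -> tuple[HippocampusResult, HippocampusResult]:
    """Run the full extraction chain for both sides; left reported first.

    An empty mask at any stage yields an area of 0 with a warning rather
    than a failure.
    """
    config = config or HippocampusConfig()
    left_rect, right_rect = default_masks(image.width, image.height)
    if config.left_roi is not None:
        left_rect = config.left_roi
    if config.right_roi is not None:
        right_rect = config.right_roi
    left = _run_side(image, left_rect, thresh, "left", config)
    right = _run_side(image, right_rect, thresh, "right", config)
    return left, right
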