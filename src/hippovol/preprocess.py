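"""Motion-correction-by-averaging and intensity-threshold tissue segmentation.

A T1-weighted coronal brain slice separates into three tissue classes by
intensity (CSF darkest, then grey matter, white matter brightest).  Grey
matter is described by an intensity threshold *range* ``[lo, hi]``: pixels
strictly below ``lo`` are CSF, pixels in the closed interval are GM, pixels
strictly above ``hi`` are WM.  The range can be supplied manually or
estimated per slice by a three-class between-class-variance (multi-Otsu)
partition of the in-brain intensity histogram.

Motion correction is the simple repeat-scan strategy: average k scans of the
same (pre-aligned) anatomy, reducing noise sd by a factor of sqrt(k).  No
registration is performed; inputs are assumed spatially normalized and
skull-stripped by upstream tools.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_multiotsu

from .errors import ThresholdEstimationError, ValidationError

__all__ = [
    "Tissue",
    "SliceImage",
    "ThreshRange",
    "TissueLabelMap",
    "average_scans",
    "estimate_thresh",
    "segment_tissues",
]


class Tissue(enum.IntEnum):
    """Per-pixel tissue class."""

    BACKGROUND = 0
    CSF = 1
    GM = 2
    WM = 3


@dataclass
class SliceImage:
    """A 2D grayscale slice with an optional brain mask.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities (arbitrary gray-level
        units).
    brain_mask
        Optional boolean array of the same shape; True marks brain tissue.
        When absent, pixels of intensity exactly 0 are treated as non-brain
        (the convention of skull-stripped images and of the phantom).
    """

    pixels: np.ndarray
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"slice must be 2D, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError("slice must be at least 1x1")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("slice intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValidationError("slice intensities must be non-negative")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.pixels.shape:
                raise ValidationError(
                    "brain_mask shape "
                    f"{self.brain_mask.shape} != pixels shape {self.pixels.shape}"
                )

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def effective_mask(self) -> np.ndarray:
        """The brain mask, or the nonzero-intensity mask when none is set."""
        if self.brain_mask is not None:
            return self.brain_mask
        return self.pixels > 0


@dataclass(frozen=True)
class ThreshRange:
    """Closed intensity interval ``[lo, hi]`` describing grey matter."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lo) and np.isfinite(self.hi)):
            raise ValidationError("threshold bounds must be finite")
        if self.lo > self.hi:
            raise ValidationError(f"thresh lo={self.lo} > hi={self.hi}")


@dataclass
class TissueLabelMap:
    """Per-pixel tissue labels plus the threshold range that produced them."""

    labels: np.ndarray
    thresh: ThreshRange

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValidationError("label map must be 2D")
        if self.labels.max(initial=0) > int(Tissue.WM):
            raise ValidationError("label map contains values outside Tissue")

    def count(self, tissue: Tissue) -> int:
        return int(np.count_nonzero(self.labels == int(tissue)))


def average_scans(stack: list[SliceImage]) -> SliceImage:
    """Average repeated scans of the same (pre-aligned) anatomy.

    Per-pixel arithmetic mean.  If any member carries a brain mask, the
    output mask is the intersection of all masks (members without a mask
    count as all-brain).  Raises :class:`ValidationError` on an empty stack
    or mismatched dimensions.
    """
    if not stack:
        raise ValidationError("cannot average an empty scan stack")
    shape = stack[0].pixels.shape
    for i, s in enumerate(stack):
        if s.pixels.shape != shape:
            raise ValidationError(
                f"scan {i} has shape {s.pixels.shape}, expected {shape}"
            )
    mean = np.mean([s.pixels for s in stack], axis=0)
    mask = None
    if any(s.brain_mask is not None for s in stack):
        mask = np.ones(shape, dtype=bool)
        for s in stack:
            if s.brain_mask is not None:
                mask &= s.brain_mask
    return SliceImage(mean, brain_mask=mask)


def estimate_thresh(image: SliceImage, nbins: int = 256) -> ThreshRange:
    """Estimate the GM threshold range by a three-class Otsu partition.

    The two cut points maximizing between-class variance over the in-mask
    intensity histogram are taken as ``lo`` and ``hi``.  With the closed-GM
    convention this reproduces the three-way CSF/GM/WM split on well
    separated histograms.

    Raises
    ------
    ThresholdEstimationError
        If the in-mask histogram has fewer than 3 distinct values, in which
        case a manual threshold range should be supplied instead.
    """
    vals = image.pixels[image.effective_mask()]
    if vals.size == 0 or np.unique(vals).size < 3:
        raise ThresholdEstimationError(
            "intensity histogram has fewer than 3 distinct in-mask values; "
            "supply a manual threshold range"
        )
    lo, hi = threshold_multiotsu(vals, classes=3, nbins=nbins)
    return ThreshRange(float(lo), float(hi))


def segment_tissues(image: SliceImage, thresh: ThreshRange) -> TissueLabelMap:
    """Partition a slice into CSF / GM / WM by the threshold range.

    Within the brain mask: intensity < lo -> CSF; lo <= intensity <= hi ->
    GM; intensity > hi -> WM.  Outside the mask -> BACKGROUND.  Without a
    mask, zero-intensity pixels are BACKGROUND and all others are
    classified.
    """
    mask = image.effective_mask()
    labels = np.full(image.pixels.shape, int(Tissue.BACKGROUND), dtype=np.uint8)
    px = image.pixels
    labels[mask & (px < thresh.lo)] = int(Tissue.CSF)
    labels[mask & (px >= thresh.lo) & (px <= thresh.hi)] = int(Tissue.GM)
    labels[mask & (px > thresh.hi)] = int(Tissue.WM)
    return TissueLabelMap(labels, thresh)
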