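"""Synthetic coronal brain-slice phantoms with known ground truth.

The phantom emulates a spatially normalized, skull-stripped 498x498 coronal
T1 slice with three tissue intensity classes (CSF < GM < WM): a circular
brain with a CSF rim, a cortical GM band and a WM interior, plus one
elliptical GM-intensity hippocampal body per hemisphere sitting in a
CSF-intensity "moat" inside the standard hippocampal ROI rectangle.  The
moat covers the ROI rectangle (expanded by a small margin) so that, as in
real coronal slices at hippocampal level, the ROI interior is CSF-dominated
and the hippocampus is the dominant above-threshold object.

Atrophy is a single factor in [0, 1) that shrinks the hippocampal
semi-axes and the cortical GM band thickness — smaller hippocampi and less
grey matter, the structural signature of Alzheimer's disease.  Gaussian
noise is added inside the brain and an optional smooth multiplicative
cosine field emulates MRI intensity inhomogeneity (bias field).

Every generator is a pure function of (spec, seed): identical inputs give
bit-identical outputs.  Ground truth records the noiseless label map and
exact painted hippocampal pixel counts, which downstream tests use as the
recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ValidationError
from .hippocampus import ROIRect, default_masks
from .preprocess import SliceImage, ThreshRange, Tissue, TissueLabelMap

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "generate_slice",
    "generate_repeat_stack",
    "generate_cohort",
    "generate_feature_table",
]

AD = 1
CONTROL = -1


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of a phantom slice.

    Intensities are mean gray levels on an arbitrary 0-255-like scale and
    must be strictly increasing CSF < GM < WM.  ``atrophy`` shrinks the
    hippocampal semi-axes and the GM band thickness by ``(1 - atrophy)``.
    Both hippocampal ellipses must lie strictly inside their standard ROI
    rectangles.
    """

    width: int = 498
    height: int = 498
    intensity_csf: float = 60.0
    intensity_gm: float = 110.0
    intensity_wm: float = 170.0
    noise_sd: float = 8.0
    bias_amplitude: float = 0.0
    hippo_left_center: tuple[float, float] = (177.0, 330.0)  # (col, row)
    hippo_right_center: tuple[float, float] = (327.0, 330.0)
    hippo_semi_axes: tuple[float, float] = (20.0, 12.0)  # (a along x, b along y)
    atrophy: float = 0.0
    brain_radius: float = 230.0
    csf_rim: float = 12.0
    gm_band: float = 30.0
    moat_margin: int = 6

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValidationError("phantom must be at least 2x2 pixels")
        if not (self.intensity_csf < self.intensity_gm < self.intensity_wm):
            raise ValidationError(
                "tissue intensities must satisfy CSF < GM < WM, got "
                f"{self.intensity_csf}, {self.intensity_gm}, {self.intensity_wm}"
            )
        if self.intensity_csf <= 0:
            raise ValidationError("intensity_csf must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0 <= self.bias_amplitude < 1):
            raise ValidationError("bias_amplitude must be in [0, 1)")
        if not (0 <= self.atrophy < 1):
            raise ValidationError("atrophy must be in [0, 1)")
        a, b = self.hippo_semi_axes
        if a <= 0 or b <= 0:
            raise ValidationError("hippo semi-axes must be positive")
        if self.brain_radius <= 0 or self.csf_rim < 0 or self.gm_band < 0:
            raise ValidationError("brain geometry parameters must be positive")
        left_roi, right_roi = default_masks(self.width, self.height)
        for name, (cx, cy), roi in (
            ("left", self.hippo_left_center, left_roi),
            ("right", self.hippo_right_center, right_roi),
        ):
            inside = (
                roi.x1 < cx - a and cx + a < roi.x2 - 1
                and roi.y1 < cy - b and cy + b < roi.y2 - 1
            )
            if not inside:
                raise ValidationError(
                    f"{name} hippocampal ellipse (center ({cx},{cy}), "
                    f"semi-axes ({a},{b})) must lie strictly inside ROI "
                    f"({roi.x1},{roi.y1})-({roi.x2},{roi.y2})"
                )

    def ideal_thresh(self) -> ThreshRange:
        """Midpoint threshold range separating the three tissue means."""
        return ThreshRange(
            (self.intensity_csf + self.intensity_gm) / 2.0,
            (self.intensity_gm + self.intensity_wm) / 2.0,
        )


@dataclass
class GroundTruth:
    """Noiseless labels, exact painted hippocampal areas and class label."""

    label_map: TissueLabelMap
    hippo_left_area: int
    hippo_right_area: int
    class_label: int = CONTROL
    atrophy: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in (AD, CONTROL):
            raise ValidationError("class_label must be +1 (AD) or -1 (control)")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with truncated-normal atrophy distributions.

    Defaults mirror a mild-AD study cohort: 37 patients vs 48 controls,
    with a clearly atrophic patient group.
    """

    n_ad: int = 37
    n_control: int = 48
    atrophy_ad_mean: float = 0.35
    atrophy_control_mean: float = 0.05
    atrophy_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ad < 0 or self.n_control < 0:
            raise ValidationError("subject counts must be >= 0")
        if self.atrophy_sd < 0:
            raise ValidationError("atrophy_sd must be >= 0")
        for m in (self.atrophy_ad_mean, self.atrophy_control_mean):
            if not (0 <= m < 1):
                raise ValidationError("atrophy means must be in [0, 1)")


def _ellipse_mask(
    xx: np.ndarray, yy: np.ndarray, center: tuple[float, float], a: float, b: float
) -> np.ndarray:
    cx, cy = center
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _expand_rect(roi: ROIRect, margin: int, width: int, height: int) -> ROIRect:
    return ROIRect(
        max(roi.x1 - margin, 0),
        max(roi.y1 - margin, 0),
        min(roi.x2 + margin, width),
        min(roi.y2 + margin, height),
    )


def _paint(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Noiseless label map, brain mask and exact hippocampal pixel counts."""
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    cx = (spec.width - 1) / 2.0
    cy = (spec.height - 1) / 2.0
    r = np.hypot(xx - cx, yy - cy)

    labels = np.full((spec.height, spec.width), int(Tissue.BACKGROUND), np.uint8)
    brain = r <= spec.brain_radius
    labels[brain] = int(Tissue.WM)
    gm_band = spec.gm_band * (1.0 - spec.atrophy)
    gm_outer = spec.brain_radius - spec.csf_rim
    labels[brain & (r > gm_outer - gm_band)] = int(Tissue.GM)
    labels[brain & (r > gm_outer)] = int(Tissue.CSF)

    left_roi, right_roi = default_masks(spec.width, spec.height)
    a = spec.hippo_semi_axes[0] * (1.0 - spec.atrophy)
    b = spec.hippo_semi_axes[1] * (1.0 - spec.atrophy)
    areas = []
    for center, roi in (
        (spec.hippo_left_center, left_roi),
        (spec.hippo_right_center, right_roi),
    ):
        moat = _expand_rect(roi, spec.moat_margin, spec.width, spec.height)
        labels[moat.y1 : moat.y2, moat.x1 : moat.x2] = int(Tissue.CSF)
        ell = _ellipse_mask(xx, yy, center, a, b)
        labels[ell] = int(Tissue.GM)
        areas.append(int(ell.sum()))

    return labels, brain, areas[0], areas[1]


_INTENSITY_LUT_FIELDS = ("intensity_csf", "intensity_gm", "intensity_wm")


def _render(
    spec: PhantomSpec, labels: np.ndarray, brain: np.ndarray,
    rng: np.random.Generator,
) -> SliceImage:
    lut = np.array(
        [0.0, spec.intensity_csf, spec.intensity_gm, spec.intensity_wm]
    )
    img = lut[labels]
    if spec.bias_amplitude > 0:
        yy, xx = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
        field_ = 1.0 + spec.bias_amplitude * np.cos(
            np.pi * xx / spec.width
        ) * np.cos(np.pi * yy / spec.height)
        img = img * field_
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.where(brain, img + noise, img)
    img = np.clip(img, 0.0, None)
    return SliceImage(img, brain_mask=brain.copy())


def generate_slice(
    spec: PhantomSpec, seed: int, class_label: int = CONTROL
) -> tuple[SliceImage, GroundTruth]:
    """Generate one phantom slice and its ground truth.

    Deterministic in (spec, seed).  With ``noise_sd=0`` and
    ``bias_amplitude=0`` every brain pixel is exactly one of the three
    tissue means.
    """
    labels, brain, left_area, right_area = _paint(spec)
    rng = np.random.default_rng(seed)
    image = _render(spec, labels, brain, rng)
    truth = GroundTruth(
        label_map=TissueLabelMap(labels, spec.ideal_thresh()),
        hippo_left_area=left_area,
        hippo_right_area=right_area,
        class_label=class_label,
        atrophy=spec.atrophy,
    )
    return image, truth


def generate_repeat_stack(
    spec: PhantomSpec, n_repeats: int, seed: int
) -> list[SliceImage]:
    """n_repeats scans of identical anatomy with independent noise.

    The first stack member is bit-identical to ``generate_slice(spec, seed)``.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    labels, brain, _, _ = _paint(spec)
    rng = np.random.default_rng(seed)
    return [_render(spec, labels, brain, rng) for _ in range(n_repeats)]


def generate_cohort(
    cspec: CohortSpec, base: PhantomSpec | None = None
) -> list[tuple[SliceImage, GroundTruth]]:
    """A labelled cohort of phantom subjects.

    AD subjects (label +1) draw atrophy from a truncated normal with mean
    ``atrophy_ad_mean``; controls (label -1) from ``atrophy_control_mean``;
    both truncated to [0, 1).  Per-subject image seeds are derived
    deterministically from ``cspec.seed``.
    """
    base = base or PhantomSpec()
    master = np.random.SeedSequence(cspec.seed)
    atr_rng = np.random.default_rng(master.spawn(1)[0])
    n_total = cspec.n_ad + cspec.n_control
    subject_seeds = master.generate_state(max(n_total, 1))

    def draw_atrophy(mean: float, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        if cspec.atrophy_sd == 0:
            return np.full(n, mean)
        a = (0.0 - mean) / cspec.atrophy_sd
        b = (1.0 - mean) / cspec.atrophy_sd
        vals = truncnorm.rvs(
            a, b, loc=mean, scale=cspec.atrophy_sd, size=n, random_state=atr_rng
        )
        return np.minimum(vals, np.nextafter(1.0, 0.0))

    atrophies = np.concatenate(
        [
            draw_atrophy(cspec.atrophy_ad_mean, cspec.n_ad),
            draw_atrophy(cspec.atrophy_control_mean, cspec.n_control),
        ]
    )
    labels = [AD] * cspec.n_ad + [CONTROL] * cspec.n_control
    cohort = []
    for i, (atr, lab) in enumerate(zip(atrophies, labels)):
        spec_i = replace(base, atrophy=float(atr))
        cohort.append(generate_slice(spec_i, int(subject_seeds[i]), class_label=lab))
    return cohort


FEATURE_COLUMNS = ["vol_gm", "vol_wm", "vol_csf", "left_area", "right_area"]


def generate_feature_table(
    n_per_class: int,
    class_means: tuple[np.ndarray, np.ndarray],
    class_sds: np.ndarray,
    seed: int,
) -> pd.DataFrame:
    """Bare Gaussian feature table for isolated classifier tests.

    ``class_means`` is (AD means, control means), each a 5-vector over
    (vol_gm, vol_wm, vol_csf, left_area, right_area); ``class_sds`` is a
    shared 5-vector of positive standard deviations.  Features are clipped
    at 0 (they are pixel counts).  Returns a DataFrame with the five
    feature columns plus ``label`` (+1 AD, -1 control).
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    mean_ad = np.asarray(class_means[0], dtype=float)
    mean_ctl = np.asarray(class_means[1], dtype=float)
    sds = np.asarray(class_sds, dtype=float)
    if mean_ad.shape != (5,) or mean_ctl.shape != (5,) or sds.shape != (5,):
        raise ValidationError("class means and sds must be 5-vectors")
    if np.any(sds <= 0):
        raise ValidationError("class_sds must be strictly positive")
    rng = np.random.default_rng(seed)
    ad = rng.normal(mean_ad, sds, size=(n_per_class, 5))
    ctl = rng.normal(mean_ctl, sds, size=(n_per_class, 5))
    data = np.clip(np.vstack([ad, ctl]), 0.0, None)
    frame = pd.DataFrame(data, columns=FEATURE_COLUMNS)
    frame["label"] = [AD] * n_per_class + [CONTROL] * n_per_class
    frame.insert(0, "subject_id", [f"sub-{i:04d}" for i in range(2 * n_per_class)])
    return frame
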