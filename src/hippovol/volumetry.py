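"""Tissue volumes as pixel counts summed over slices.

Volume_X = sum over slices of the number of pixels labelled X.  Counts are
raw pixels; multiply by a voxel size for physical units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .preprocess import Tissue, TissueLabelMap

__all__ = ["TissueVolumes", "tissue_volumes"]


@dataclass(frozen=True)
class TissueVolumes:
    """GM/WM/CSF pixel counts aggregated over ``n_slices`` slices."""

    vol_gm: int
    vol_wm: int
    vol_csf: int
    n_slices: int

    def __post_init__(self) -> None:
        for name in ("vol_gm", "vol_wm", "vol_csf", "n_slices"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer")

    def scaled(self, voxel_volume: float) -> tuple[float, float, float]:
        """(GM, WM, CSF) in physical units given the per-voxel volume."""
        return (
            self.vol_gm * voxel_volume,
            self.vol_wm * voxel_volume,
            self.vol_csf * voxel_volume,
        )


def tissue_volumes(label_maps: list[TissueLabelMap]) -> TissueVolumes:
    """Sum per-class pixel counts over a list of label maps.

    Additive over slices and invariant to slice order.  A single slice is a
    valid input (per-slice analysis).
    """
    if not label_maps:
        raise ValidationError("tissue_volumes requires at least one label map")
    gm = wm = csf = 0
    for lm in label_maps:
        gm += lm.count(Tissue.GM)
        wm += lm.count(Tissue.WM)
        csf += lm.count(Tissue.CSF)
    return TissueVolumes(vol_gm=gm, vol_wm=wm, vol_csf=csf, n_slices=len(label_maps))
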