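"""Readers and writers for the slice, label-map and table formats.

Slices travel as 16-bit grayscale PNG (lossless for 0-65535 integer gray
levels) or as single-slice NIfTI-1 / Analyze volumes; label maps as 8-bit
indexed PNG; tables as headered CSV; configs and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import SliceImage, TissueLabelMap, ThreshRange

__all__ = [
    "read_slice_png",
    "write_slice_png",
    "read_nifti_slice",
    "write_nifti_slice",
    "write_label_png",
    "read_label_png",
    "write_ground_truth_csv",
    "write_features_csv",
    "read_features_csv",
    "write_json",
]


def write_slice_png(image: SliceImage, path: str | Path) -> None:
    """Write a slice as 16-bit grayscale PNG (intensities rounded)."""
    px = np.round(image.pixels)
    if px.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValidationError("intensities exceed the 16-bit PNG range")
    iio.imwrite(Path(path), px.astype(np.uint16))


def read_slice_png(path: str | Path) -> SliceImage:
    """Read a grayscale PNG as a SliceImage (no brain mask attached)."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # collapse an RGB(A) read of a gray image
        arr = arr[..., 0]
    return SliceImage(arr.astype(np.float64))


def read_nifti_slice(
    path: str | Path, slice_axis: int = 1, slice_index: int | None = None
) -> SliceImage:
    """Take one coronal slice out of a NIfTI/Analyze volume.

    ``slice_axis`` selects the voxel axis to slice along (1, the second
    axis, is coronal under the usual RAS convention); ``slice_index``
    defaults to the middle slice.  2D images are returned as-is.
    """
    data = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if data.ndim == 2:
        return SliceImage(np.abs(data))
    if data.ndim != 3:
        raise ValidationError(f"expected a 2D or 3D volume, got shape {data.shape}")
    if not 0 <= slice_axis <= 2:
        raise ValidationError("slice_axis must be 0, 1 or 2")
    if slice_index is None:
        slice_index = data.shape[slice_axis] // 2
    if not 0 <= slice_index < data.shape[slice_axis]:
        raise ValidationError(
            f"slice_index {slice_index} out of range for axis of length "
            f"{data.shape[slice_axis]}"
        )
    sl = np.take(data, slice_index, axis=slice_axis)
    return SliceImage(np.clip(sl, 0.0, None))


def write_nifti_slice(image: SliceImage, path: str | Path) -> None:
    """Write a slice as a single-slice NIfTI-1 volume (identity affine)."""
    vol = image.pixels[:, :, np.newaxis].astype(np.float32)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def write_label_png(label_map: TissueLabelMap, path: str | Path) -> None:
    """Write a tissue label map as an 8-bit indexed PNG (labels 0-3)."""
    iio.imwrite(Path(path), label_map.labels.astype(np.uint8))


def read_label_png(path: str | Path, thresh: ThreshRange) -> TissueLabelMap:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return TissueLabelMap(arr.astype(np.uint8), thresh)


def write_ground_truth_csv(records: list[dict], path: str | Path) -> None:
    """Ground-truth table: subject_id, class_label, hippo areas, atrophy."""
    pd.DataFrame.from_records(records).to_csv(Path(path), index=False)


def write_features_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(Path(path), index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
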