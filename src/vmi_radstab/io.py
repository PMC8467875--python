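"""File I/O: NRRD/NIfTI volumes and masks, CSV feature tables, JSON sidecars.

Arrays are stored internally in (x, y, z) index order; SimpleITK works in
(z, y, x), so volumes are transposed on the way in and out. NRRD is the
default on-disk format; NIfTI-1 is selected by file extension.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .grid import SegmentationMask, VolumeGrid
from .synthetic import AcquisitionCondition

__all__ = [
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "write_condition_sidecar",
    "read_condition_sidecar",
    "write_feature_table",
    "read_feature_table",
]

_NIFTI_EXT = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_EXT)


def _write_array(arr: np.ndarray, spacing, origin, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        affine = np.diag(list(spacing) + [1.0])
        affine[:3, 3] = origin
        nib.save(nib.Nifti1Image(arr, affine), str(path))
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in spacing))
        img.SetOrigin(tuple(float(o) for o in origin))
        sitk.WriteImage(img, str(path))


def _read_array(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    if _is_nifti(path):
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
        affine = img.affine
        spacing = tuple(float(affine[i, i]) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        return arr, spacing, origin
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def write_volume(volume: VolumeGrid, path: str | Path) -> None:
    _write_array(volume.values, volume.spacing_mm, volume.origin_mm, Path(path))


def read_volume(path: str | Path) -> VolumeGrid:
    arr, spacing, origin = _read_array(Path(path))
    return VolumeGrid(arr.astype(float), spacing_mm=spacing, origin_mm=origin)


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    _write_array(
        mask.values.astype(np.uint8), mask.spacing_mm, mask.origin_mm, Path(path)
    )


def read_mask(path: str | Path) -> SegmentationMask:
    arr, spacing, origin = _read_array(Path(path))
    return SegmentationMask(arr > 0, spacing_mm=spacing, origin_mm=origin)


def write_condition_sidecar(
    condition: AcquisitionCondition, path: str | Path, **extra
) -> None:
    """JSON sidecar recording the acquisition condition and seeds."""
    payload = {**asdict(condition), **extra}
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_condition_sidecar(path: str | Path) -> tuple[AcquisitionCondition, dict]:
    data = json.loads(Path(path).read_text())
    cond = AcquisitionCondition(
        energy_kev=data.pop("energy_kev"),
        dose_mgy=data.pop("dose_mgy"),
        scanner=data.pop("scanner"),
        repeat_id=data.pop("repeat_id", 0),
    )
    return cond, data


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Tidy CSV: one row per object, one column per feature.

    Floats are written with 17 significant digits so the file round-trips
    through :func:`read_feature_table` without loss.
    """
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(p, index_label="object_id", float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    # round_trip parser: exact inverse of the %.17g writer
    return pd.read_csv(path, index_col="object_id", float_precision="round_trip")
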