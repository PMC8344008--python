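"""NIfTI and table I/O.

Volumes are stored as NIfTI with a diagonal affine built from the voxel
spacing (the package works in axis-aligned spacing-only world coordinates).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InputError
from .segmentation import LesionSegment, OrganMaskSet, PetVolume, ReviewAdjustments


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_pet(volume: PetVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_pet(path: str | Path, scan_id: str | None = None, timepoint: str = "baseline") -> PetVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise InputError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PetVolume(data, spacing, scan_id=scan_id or Path(path).stem, timepoint=timepoint)


def save_labels(labels: np.ndarray, spacing, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _affine(spacing))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def load_organ_masks(path: str | Path, label_map: dict[str, int]) -> OrganMaskSet:
    img = nib.load(str(path))
    return OrganMaskSet(np.asarray(img.dataobj, dtype=np.int32), label_map)


def lesion_label_volume(lesions: list[LesionSegment], shape) -> np.ndarray:
    """Label volume with lesion_id + 1 at each lesion's voxels."""
    out = np.zeros(shape, dtype=np.int16)
    for les in lesions:
        out[les.voxels[:, 0], les.voxels[:, 1], les.voxels[:, 2]] = les.lesion_id + 1
    return out


def load_adjustments(path: str | Path) -> ReviewAdjustments:
    """JSON review file: {"exclude_foci": [[i,j,k], ...], "include_regions": [...]}"""
    with open(path) as fh:
        raw = json.load(fh)
    return ReviewAdjustments(
        exclude_foci=tuple(tuple(p) for p in raw.get("exclude_foci", [])),
        include_regions=tuple(tuple(p) for p in raw.get("include_regions", [])),
    )
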