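"""Semi-automatic whole-body lesion segmentation for SUV-calibrated PET.

The segmentation chain mirrors the clinical workflow for quantifying total
tumor burden on PSMA PET:

1. A liver-referenced adaptive threshold is computed from the liver SUV
   statistics:  ``threshold = (4.3 / liver_mean) * (liver_mean + liver_sd)``.
   When the liver is perfectly homogeneous the threshold collapses to the
   fixed reference constant 4.3; liver noise raises it.
2. Every connected supra-threshold focus (26-connectivity) is detected.
3. Foci dominated by physiological uptake (kidney, spleen, liver) are
   removed; a reviewer may force-exclude foci or force-include regions
   (e.g. liver metastases) via :class:`ReviewAdjustments`.
4. Each retained focus is refined to the connected 50%-of-local-SUVmax
   isocontour around its hottest voxel, from which per-lesion volume (ml),
   SUVmean, SUVmax and TLQ (volume / SUVmean) are derived.

Boundary conventions are fixed and deliberate: detection is *strict*
(``SUV > threshold``), refinement is *inclusive* (``SUV >= 0.5 * SUVmax``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import InputError

#: Fixed reference constant of the liver-specific threshold formula (SUV).
REFERENCE_CONSTANT = 4.3

#: 3-D structuring element for 26-connectivity.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PetVolume:
    """A 3-D SUV grid with voxel spacing in mm.

    SUV values are assumed decay- and body-weight-corrected upstream; the
    grid is axis-aligned with world coordinates ``index * spacing`` (mm),
    no oblique affine.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    scan_id: str = "scan"
    timepoint: str = "baseline"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise InputError(f"PET volume must be 3-D, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise InputError("SUV values must be finite and >= 0")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise InputError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0


@dataclass(frozen=True)
class ReferenceStats:
    """Liver SUV statistics and the derived segmentation threshold."""

    liver_suv_mean: float
    liver_suv_sd: float
    threshold: float
    reference_constant: float = REFERENCE_CONSTANT


@dataclass(frozen=True)
class OrganMaskSet:
    """Integer label volume congruent with the PET grid.

    ``label_map`` maps organ names (``liver``, ``spleen``, ``kidney_left``,
    ``kidney_right`` ...) to positive integer labels; 0 is background.
    """

    labels: np.ndarray
    label_map: Mapping[str, int]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise InputError("organ label volume must be 3-D")
        if labels.min() < 0:
            raise InputError("organ labels must be nonnegative")
        object.__setattr__(self, "labels", labels.astype(np.int32))
        object.__setattr__(self, "label_map", dict(self.label_map))

    def mask(self, organ: str) -> np.ndarray:
        if organ not in self.label_map:
            raise InputError(f"organ {organ!r} not in label map {sorted(self.label_map)}")
        return self.labels == self.label_map[organ]

    def liver_mask(self) -> np.ndarray:
        return self.mask("liver")


@dataclass(frozen=True)
class ReviewAdjustments:
    """Physician review step, replaced by explicit include/exclude lists.

    ``exclude_foci``: voxel coordinates; any focus whose voxel set contains
    one of them is dropped (e.g. gastrointestinal uptake).
    ``include_regions``: seed coordinates forced back in as foci even inside
    organ masks (the liver-metastasis re-segmentation path).
    """

    exclude_foci: tuple[tuple[int, int, int], ...] = ()
    include_regions: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "exclude_foci", tuple(tuple(int(c) for c in p) for p in self.exclude_foci)
        )
        object.__setattr__(
            self,
            "include_regions",
            tuple(tuple(int(c) for c in p) for p in self.include_regions),
        )


@dataclass(frozen=True)
class Focus:
    """A candidate connected supra-threshold component."""

    voxels: np.ndarray  # (n, 3) int indices
    suv_max: float
    seed: tuple[int, int, int]  # argmax voxel
    forced: bool = False  # inserted via include_regions

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


@dataclass(frozen=True)
class LesionSegment:
    """One segmented metastasis with its quantitative metrics.

    ``tlq_lesion`` is the total lesion quotient: metabolic volume (ml)
    divided by the lesion SUVmean. Low-uptake bulky lesions score high.
    """

    lesion_id: int
    voxels: np.ndarray  # (n, 3) int indices
    suv_max: float
    suv_mean: float
    volume_ml: float
    tlq_lesion: float
    seed: tuple[int, int, int] = (0, 0, 0)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_threshold(liver_suv_mean: float, liver_suv_sd: float) -> float:
    """Liver-referenced adaptive segmentation threshold.

    ``(4.3 / mean) * (mean + sd)``; equals 4.3 exactly for a noiseless
    liver and grows linearly in the liver coefficient of variation.
    """
    if not liver_suv_mean > 0:
        raise InputError(f"liver SUVmean must be > 0, got {liver_suv_mean}")
    if liver_suv_sd < 0:
        raise InputError(f"liver SUVsd must be >= 0, got {liver_suv_sd}")
    return (REFERENCE_CONSTANT / liver_suv_mean) * (liver_suv_mean + liver_suv_sd)


def sphere_roi(
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    center_mm: Sequence[float],
    radius_mm: float,
) -> np.ndarray:
    """Boolean mask of voxel centers within ``radius_mm`` of ``center_mm``.

    Utility for placing a standard spherical liver reference VOI when no
    whole-organ mask is available.
    """
    if radius_mm <= 0:
        raise InputError("ROI radius must be positive")
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    return d2 <= radius_mm**2


def liver_reference_stats(
    volume: PetVolume,
    masks: OrganMaskSet | np.ndarray,
    ddof: int = 0,
) -> ReferenceStats:
    """Liver SUVmean/SUVsd over the liver mask and the derived threshold.

    ``ddof=0`` (population sd) is the default convention; pass ``ddof=1``
    for the sample convention.
    """
    liver = masks.liver_mask() if isinstance(masks, OrganMaskSet) else np.asarray(masks, bool)
    if liver.shape != volume.values.shape:
        raise InputError("liver mask shape does not match PET volume")
    vals = volume.values[liver]
    if vals.size == 0:
        raise InputError("liver mask is empty")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0
    return ReferenceStats(mean, sd, compute_threshold(mean, sd))


def detect_foci(
    volume: PetVolume, threshold: float, min_voxels: int = 1
) -> list[Focus]:
    """Connected components (26-connectivity) of ``{SUV > threshold}``.

    Components smaller than ``min_voxels`` are dropped. Each focus carries
    its SUVmax and the argmax voxel as seed (first in C order on ties).
    """
    if threshold <= 0:
        raise InputError("threshold must be positive")
    supra = volume.values > threshold
    labels, n = ndimage.label(supra, structure=STRUCT_26)
    foci: list[Focus] = []
    if n == 0:
        return foci
    objects = ndimage.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        sub = labels[slc] == lab
        if int(sub.sum()) < min_voxels:
            continue
        vals = np.where(sub, volume.values[slc], -np.inf)
        local_arg = np.unravel_index(int(np.argmax(vals)), vals.shape)
        offset = tuple(s.start for s in slc)
        seed = tuple(int(a + o) for a, o in zip(local_arg, offset))
        idx = np.argwhere(sub) + np.array(offset)
        foci.append(Focus(voxels=idx, suv_max=float(vals[local_arg]), seed=seed))
    return foci


def _focus_from_seed(volume: PetVolume, seed: tuple[int, int, int], threshold: float) -> Focus:
    """Build a forced focus around a reviewer seed.

    If the seed voxel is supra-threshold, its full connected supra-threshold
    component is the focus; otherwise the singleton seed is used and the 50%
    refinement grows it.
    """
    shape = volume.values.shape
    if any(not (0 <= c < n) for c, n in zip(seed, shape)):
        raise InputError(f"seed {seed} outside grid of shape {shape}")
    if volume.values[seed] > threshold:
        supra = volume.values > threshold
        labels, _ = ndimage.label(supra, structure=STRUCT_26)
        comp = labels == labels[seed]
        idx = np.argwhere(comp)
        vals = volume.values[comp]
        arg = idx[int(np.argmax(vals))]
        return Focus(voxels=idx, suv_max=float(vals.max()), seed=tuple(int(c) for c in arg), forced=True)
    return Focus(
        voxels=np.array([seed], dtype=int),
        suv_max=float(volume.values[seed]),
        seed=tuple(int(c) for c in seed),
        forced=True,
    )


def exclude_physiological(
    foci: Iterable[Focus],
    masks: OrganMaskSet,
    adjustments: ReviewAdjustments | None = None,
    volume: PetVolume | None = None,
    threshold: float | None = None,
    overlap_frac: float = 0.5,
) -> list[Focus]:
    """Remove foci dominated by physiological organ uptake.

    A focus is removed when the fraction of its voxels inside any single
    masked organ exceeds ``overlap_frac`` (default 0.5 — metastases merely
    abutting an organ survive). Reviewer ``exclude_foci`` coordinates remove
    the containing focus unconditionally; ``include_regions`` seeds are
    re-inserted as forced foci even inside organ masks (requires ``volume``
    and ``threshold``).
    """
    adjustments = adjustments or ReviewAdjustments()
    organ_labels = masks.labels
    retained: list[Focus] = []
    exclude_set = set(adjustments.exclude_foci)
    for focus in foci:
        vox = focus.voxels
        if exclude_set and any(tuple(v) in exclude_set for v in vox):
            continue
        labs = organ_labels[vox[:, 0], vox[:, 1], vox[:, 2]]
        drop = False
        for lab in np.unique(labs):
            if lab == 0:
                continue
            if (labs == lab).mean() > overlap_frac:
                drop = True
                break
        if not drop:
            retained.append(focus)
    if adjustments.include_regions:
        if volume is None or threshold is None:
            raise InputError("include_regions requires the PET volume and threshold")
        existing = {tuple(map(tuple, np.sort(f.voxels, axis=0))) for f in retained}
        for seed in adjustments.include_regions:
            focus = _focus_from_seed(volume, seed, threshold)
            key = tuple(map(tuple, np.sort(focus.voxels, axis=0)))
            if key not in existing:
                retained.append(focus)
                existing.add(key)
    return retained


def refine_lesion(volume: PetVolume, focus: Focus, next_lesion_id: int = 0) -> LesionSegment:
    """50%-of-local-SUVmax isocontour refinement of one focus.

    The final voxel set is the 26-connected component of
    ``{SUV >= 0.5 * local_SUVmax}`` containing the focus' hottest voxel; it
    may legitimately extend beyond the initial supra-threshold focus.
    """
    if focus.n_voxels == 0:
        raise InputError("cannot refine an empty focus")
    half = 0.5 * focus.suv_max
    iso = volume.values >= half
    labels, _ = ndimage.label(iso, structure=STRUCT_26)
    comp = labels == labels[focus.seed]
    idx = np.argwhere(comp)
    vals = volume.values[comp]
    suv_max = float(vals.max())
    suv_mean = float(vals.mean())
    volume_ml = idx.shape[0] * volume.voxel_volume_ml
    return LesionSegment(
        lesion_id=next_lesion_id,
        voxels=idx,
        suv_max=suv_max,
        suv_mean=suv_mean,
        volume_ml=volume_ml,
        tlq_lesion=volume_ml / suv_mean if suv_mean > 0 else float("nan"),
        seed=focus.seed,
    )


def _deduplicate(lesions: list[LesionSegment], volume: PetVolume) -> list[LesionSegment]:
    """Collapse identical voxel sets; merge overlapping sets by union.

    Merged 50% isocontours from nearby foci would otherwise double-count
    volume in the scan total.
    """
    merged: list[dict] = []  # each: {"set": set of voxel tuples, "seed": seed}
    for les in lesions:
        vox = {tuple(v) for v in les.voxels}
        hit = None
        for entry in merged:
            if entry["set"] & vox:
                hit = entry
                break
        if hit is None:
            merged.append({"set": vox, "seed": les.seed})
        else:
            hit["set"] |= vox
            # keep the hotter seed
            if volume.values[les.seed] > volume.values[hit["seed"]]:
                hit["seed"] = les.seed
    # transitive merges: repeat until stable
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                if merged[i]["set"] & merged[j]["set"]:
                    merged[i]["set"] |= merged[j]["set"]
                    if volume.values[merged[j]["seed"]] > volume.values[merged[i]["seed"]]:
                        merged[i]["seed"] = merged[j]["seed"]
                    del merged[j]
                    changed = True
                    break
            if changed:
                break
    out: list[LesionSegment] = []
    for entry in merged:
        idx = np.array(sorted(entry["set"]))
        vals = volume.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        suv_mean = float(vals.mean())
        vol_ml = idx.shape[0] * volume.voxel_volume_ml
        out.append(
            LesionSegment(
                lesion_id=0,
                voxels=idx,
                suv_max=float(vals.max()),
                suv_mean=suv_mean,
                volume_ml=vol_ml,
                tlq_lesion=vol_ml / suv_mean if suv_mean > 0 else float("nan"),
                seed=entry["seed"],
            )
        )
    return out


def segment_scan(
    volume: PetVolume,
    masks: OrganMaskSet,
    adjustments: ReviewAdjustments | None = None,
    min_voxels: int = 1,
    overlap_frac: float = 0.5,
    sd_ddof: int = 0,
) -> list[LesionSegment]:
    """Full segmentation chain for one scan.

    liver stats -> threshold -> focus detection -> organ exclusion ->
    50% refinement -> deduplication. Deterministic; lesions sorted by
    descending volume with a stable tie-break on seed index.
    """
    stats = liver_reference_stats(volume, masks, ddof=sd_ddof)
    foci = detect_foci(volume, stats.threshold, min_voxels=min_voxels)
    foci = exclude_physiological(
        foci, masks, adjustments, volume=volume, threshold=stats.threshold,
        overlap_frac=overlap_frac,
    )
    lesions = [refine_lesion(volume, f) for f in foci]
    lesions = _deduplicate(lesions, volume)
    shape = volume.values.shape
    lesions.sort(
        key=lambda l: (-l.volume_ml, np.ravel_multi_index(l.seed, shape))
    )
    return [
        LesionSegment(
            lesion_id=i,
            voxels=l.voxels,
            suv_max=l.suv_max,
            suv_mean=l.suv_mean,
            volume_ml=l.volume_ml,
            tlq_lesion=l.tlq_lesion,
            seed=l.seed,
        )
        for i, l in enumerate(lesions)
    ]
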