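"""Threshold-based lung segmentation.

The lung parenchyma is isolated by selecting all voxels in the closed HU
interval [-1024, -200] and then cleaning the candidate mask with a fixed,
deterministic rule set: exterior air (candidate components touching the grid
boundary) is deleted, the mask is opened with a small anisotropy-aware
structuring element, components below a minimum size are dropped, and an
optional airway rule removes air-density components entering through the top
slice.  This replaces the interactive vessel/bronchus editing of clinical
workstation workflows with a reproducible procedure.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume, VoxelMask, _require_aligned

#: 26-neighbour connectivity for 3-D component labelling.
_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


class NoLungFoundError(RuntimeError):
    """Raised when no interior lung component survives refinement."""


@dataclasses.dataclass
class SegmentationParams:
    """Parameters of the threshold segmentation.

    ``min_component_voxels=None`` means "1 cm^3 at the volume's spacing",
    resolved when the volume is known.
    """

    lung_hu_low: float = -1024.0
    lung_hu_high: float = -200.0
    min_component_voxels: int | None = None
    opening_radius_mm: float = 1.0
    exclude_airways: bool = True

    def __post_init__(self) -> None:
        if not self.lung_hu_low < self.lung_hu_high:
            raise ValueError("lung_hu_low must be < lung_hu_high")
        if self.opening_radius_mm < 0:
            raise ValueError("opening_radius_mm must be >= 0")

    def resolved_min_component_voxels(self, volume: CTVolume) -> int:
        if self.min_component_voxels is not None:
            return int(self.min_component_voxels)
        return max(1, int(round(1000.0 / volume.voxel_volume_mm3)))


def threshold_lung_candidates(
    volume: CTVolume, params: SegmentationParams | None = None
) -> VoxelMask:
    """Flag exactly the voxels with HU in the closed lung interval."""
    params = params or SegmentationParams()
    flags = (volume.voxels >= params.lung_hu_low) & (
        volume.voxels <= params.lung_hu_high
    )
    return VoxelMask(flags=flags, label="lung_candidates")


def _ellipsoid_structure(radius_mm: float, spacing_mm: tuple[float, float, float]) -> np.ndarray:
    """Anisotropy-aware ball: offsets within radius_mm in physical space."""
    half = [int(np.floor(radius_mm / s)) for s in spacing_mm]
    if all(h == 0 for h in half):
        return np.ones((1, 1, 1), dtype=bool)
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing_mm)], indexing="ij"
    )
    dist2 = sum(g**2 for g in grids)
    return dist2 <= radius_mm**2 + 1e-9


def _border_labels(labels: np.ndarray) -> set[int]:
    faces = [
        labels[0], labels[-1],
        labels[:, 0], labels[:, -1],
        labels[:, :, 0], labels[:, :, -1],
    ]
    out: set[int] = set()
    for face in faces:
        out.update(np.unique(face).tolist())
    out.discard(0)
    return out


def refine_lung_mask(
    candidates: VoxelMask,
    volume: CTVolume,
    params: SegmentationParams | None = None,
) -> VoxelMask:
    """Clean the thresholded candidates into a lung mask.

    Steps, in order: delete candidate components touching the grid boundary
    (exterior air), morphological opening of ``opening_radius_mm``, delete
    components smaller than the minimum size, and optionally delete
    air-density components that enter through the top slice (trachea-like).
    The result is always a subset of the candidates.

    Raises
    ------
    NoLungFoundError
        If nothing survives.
    """
    params = params or SegmentationParams()
    _require_aligned(candidates, volume)
    flags = candidates.flags.copy()

    labels, _ = ndimage.label(flags, structure=_STRUCTURE_26)
    exterior = _border_labels(labels)
    if exterior:
        flags &= ~np.isin(labels, sorted(exterior))

    if params.opening_radius_mm > 0:
        structure = _ellipsoid_structure(params.opening_radius_mm, volume.spacing_mm)
        if structure.sum() > 1:
            flags = ndimage.binary_opening(flags, structure=structure)

    labels, n = ndimage.label(flags, structure=_STRUCTURE_26)
    if n:
        min_vox = params.resolved_min_component_voxels(volume)
        sizes = ndimage.sum_labels(flags, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_vox) + 1
        flags = np.isin(labels, keep)
        if params.exclude_airways and keep.size:
            # Air-density (< -950 HU mean) components reaching the top slice
            # are treated as the trachea/main bronchi and removed.
            top = labels[0]
            airway_labels = []
            for lab in keep:
                if (top == lab).any():
                    mean_hu = float(volume.voxels[labels == lab].mean())
                    if mean_hu < -950.0:
                        airway_labels.append(lab)
            if airway_labels:
                flags &= ~np.isin(labels, airway_labels)

    if not flags.any():
        raise NoLungFoundError("no lung found")
    return VoxelMask(flags=flags, label="lung")


def segment_lungs(
    volume: CTVolume, params: SegmentationParams | None = None
) -> VoxelMask:
    """Threshold + refine in one call."""
    params = params or SegmentationParams()
    return refine_lung_mask(threshold_lung_candidates(volume, params), volume, params)


def dice(a: VoxelMask, b: VoxelMask) -> float:
    """Dice overlap between two aligned masks."""
    if a.shape != b.shape:
        raise ValueError("masks must have identical shape")
    inter = int((a.flags & b.flags).sum())
    denom = a.count() + b.count()
    if denom == 0:
        return 1.0
    return 2.0 * inter / denom
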