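"""Computer-aided (CaM) densitometric quantification of pulmonary fibrosis.

Within the segmented lung (HU in [-1024, -200]) voxels are partitioned by
attenuation into normal parenchyma [-1024, -700], interstitial lung disease
(-700, -500] and consolidation (-500, -200].  The percent pulmonary fibrosis
is

    100 * (n_total_lung - n_nonfibrotic) / n_total_lung

i.e. the non-normal share of the lung volume.  The half-open partition makes
the three class counts sum exactly to the lung total, so this equals
100 * (n_ild + n_consolidation) / n_total_lung.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .ct_io import CTVolume, VoxelMask, _require_aligned


@dataclasses.dataclass(frozen=True)
class HuThresholds:
    """HU cut points of the tissue-class partition.

    Membership convention is fixed: normal is the closed interval
    [lung_low, normal_cut]; ild is (normal_cut, ild_cut]; consolidation is
    (ild_cut, lung_high].
    """

    lung_low: float = -1024.0
    normal_cut: float = -700.0
    ild_cut: float = -500.0
    lung_high: float = -200.0

    def __post_init__(self) -> None:
        if not (self.lung_low < self.normal_cut < self.ild_cut < self.lung_high):
            raise ValueError("thresholds must satisfy lung_low < normal_cut < ild_cut < lung_high")


DEFAULT_THRESHOLDS = HuThresholds()

NON_LUNG = "non-lung"
NORMAL = "normal"
ILD = "ild"
CONSOLIDATION = "consolidation"


class EmptyLungMaskError(ValueError):
    """Raised when the lung mask flags no voxels."""


@dataclasses.dataclass
class TissueHistogram:
    """Voxel counts per HU tissue class inside the lung mask."""

    n_total_lung: int
    n_nonfibrotic: int
    n_ild: int
    n_consolidation: int
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        counts = (self.n_total_lung, self.n_nonfibrotic, self.n_ild, self.n_consolidation)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.n_total_lung != self.n_nonfibrotic + self.n_ild + self.n_consolidation:
            raise ValueError("class counts must partition the lung total")
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel volume must be positive")


@dataclasses.dataclass
class CaMResult:
    """Percent pulmonary fibrosis with its supporting histogram."""

    fibrosis_pct: float
    histogram: TissueHistogram
    total_lung_volume_ml: float


def classify_voxel(hu: float, thresholds: HuThresholds = DEFAULT_THRESHOLDS) -> str:
    """Classify a single calibrated HU value into a tissue class."""
    if hu < thresholds.lung_low or hu > thresholds.lung_high:
        return NON_LUNG
    if hu <= thresholds.normal_cut:
        return NORMAL
    if hu <= thresholds.ild_cut:
        return ILD
    return CONSOLIDATION


def build_histogram(
    volume: CTVolume,
    lung_mask: VoxelMask,
    thresholds: HuThresholds = DEFAULT_THRESHOLDS,
) -> TissueHistogram:
    """Count tissue-class voxels over the flagged voxels only."""
    _require_aligned(lung_mask, volume)
    if not lung_mask.flags.any():
        raise EmptyLungMaskError("empty lung mask")
    hu = volume.voxels[lung_mask.flags]
    in_lung = (hu >= thresholds.lung_low) & (hu <= thresholds.lung_high)
    hu = hu[in_lung]
    n_normal = int((hu <= thresholds.normal_cut).sum())
    n_ild = int(((hu > thresholds.normal_cut) & (hu <= thresholds.ild_cut)).sum())
    n_cons = int((hu > thresholds.ild_cut).sum())
    return TissueHistogram(
        n_total_lung=n_normal + n_ild + n_cons,
        n_nonfibrotic=n_normal,
        n_ild=n_ild,
        n_consolidation=n_cons,
        voxel_volume_mm3=volume.voxel_volume_mm3,
    )


def fibrosis_fraction(hist: TissueHistogram) -> CaMResult:
    """Percent fibrosis: non-normal lung volume over total lung volume."""
    if hist.n_total_lung == 0:
        raise ValueError("no lung voxels in histogram")
    pct = 100.0 * (hist.n_total_lung - hist.n_nonfibrotic) / hist.n_total_lung
    return CaMResult(
        fibrosis_pct=pct,
        histogram=hist,
        total_lung_volume_ml=hist.n_total_lung * hist.voxel_volume_mm3 / 1000.0,
    )


def cam_score(
    volume: CTVolume,
    lung_mask: VoxelMask,
    thresholds: HuThresholds = DEFAULT_THRESHOLDS,
) -> CaMResult:
    """Histogram + fibrosis fraction in one call."""
    return fibrosis_fraction(build_histogram(volume, lung_mask, thresholds))


def per_slice_fractions(
    volume: CTVolume,
    lung_mask: VoxelMask,
    thresholds: HuThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Diagnostic per-slice fibrosis profile (slices with lung voxels only)."""
    _require_aligned(lung_mask, volume)
    rows = []
    for i in range(volume.shape[0]):
        flags = lung_mask.flags[i]
        if not flags.any():
            continue
        hu = volume.voxels[i][flags]
        hu = hu[(hu >= thresholds.lung_low) & (hu <= thresholds.lung_high)]
        if hu.size == 0:
            continue
        n_normal = int((hu <= thresholds.normal_cut).sum())
        rows.append(
            {
                "slice": i,
                "n_lung": int(hu.size),
                "fibrosis_pct": 100.0 * (hu.size - n_normal) / hu.size,
            }
        )
    return pd.DataFrame(rows, columns=["slice", "n_lung", "fibrosis_pct"])


def result_to_dict(result: CaMResult) -> dict:
    """JSON-ready report of a CaM result (fractions at full precision)."""
    h = result.histogram
    return {
        "fibrosis_pct": result.fibrosis_pct,
        "total_lung_volume_ml": result.total_lung_volume_ml,
        "counts": {
            "total_lung": h.n_total_lung,
            "normal": h.n_nonfibrotic,
            "ild": h.n_ild,
            "consolidation": h.n_consolidation,
        },
        "voxel_volume_mm3": h.voxel_volume_mm3,
    }
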