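"""Tumor-bearing cohort quantification.

Tumor volumes come from enhancing-region ROIs (voxel count x voxel volume);
per-animal growth rate is the dimensionless fold change of tumor volume
between the treatment-day scan and the day-8 follow-up.  Treatment-induced
barrier opening outside the tumor is quantified by re-running the BBBo
classification on brain-minus-tumor voxels, with the minimum-cluster filter
re-applied after the subtraction.  Group comparisons use the two-sided
pooled-variance (Student's) two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bbbo import BBBoResult, ParamMaps, VoxelDims, classify_bbbo

__all__ = [
    "TumorROI",
    "GrowthRecord",
    "tumor_volume",
    "growth_rate",
    "bbbo_outside_tumor",
    "compare_groups",
]


@dataclass(frozen=True)
class TumorROI:
    """Union of enhancing-region ROIs over slices, as a 3D mask."""

    mask: np.ndarray
    voxel_dims: VoxelDims = VoxelDims()

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise ValueError("tumor ROI mask must be 3D")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class GrowthRecord:
    v_baseline: float  # mm^3, treatment day
    v_followup: float  # mm^3, day 8

    def __post_init__(self) -> None:
        if self.v_baseline < 0 or self.v_followup < 0:
            raise ValueError("volumes must be >= 0")

    @property
    def rate(self) -> float:
        return growth_rate(self.v_baseline, self.v_followup)


def tumor_volume(roi: TumorROI) -> float:
    """Tumor volume in mm^3: enhancing voxel count x voxel volume."""
    return int(roi.mask.sum()) * roi.voxel_dims.volume_mm3


def growth_rate(v_baseline: float, v_followup: float) -> float:
    """Dimensionless fold change of tumor volume (follow-up / baseline)."""
    if v_baseline <= 0:
        raise ValueError("baseline volume must be > 0 for a growth rate")
    return v_followup / v_baseline


def bbbo_outside_tumor(
    brain_mask: np.ndarray,
    tumor: TumorROI,
    maps: ParamMaps,
    r2_min: float = 0.6,
    dyn_min: float = 5.0,
    min_cluster: int = 30,
    voxel_dims: VoxelDims = VoxelDims(),
    connectivity: int = 6,
) -> BBBoResult:
    """BBBo classification restricted to brain AND NOT tumor voxels.

    The minimum-cluster filter is re-applied after the subtraction, so a
    cluster straddling the tumor boundary only counts if its extratumoral
    remainder still reaches ``min_cluster`` voxels.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != tumor.mask.shape or brain_mask.shape != maps.fitted_mask.shape:
        raise ValueError("brain, tumor and map shapes must match")
    if np.any(tumor.mask & ~brain_mask):
        warnings.warn("tumor ROI extends outside the brain mask; using intersection")
    keep = brain_mask & ~tumor.mask
    restricted = ParamMaps(
        dyn_map=np.where(keep, maps.dyn_map, np.nan),
        tt_map=np.where(keep, maps.tt_map, np.nan),
        aot_map=np.where(keep, maps.aot_map, np.nan),
        r2_map=np.where(keep, maps.r2_map, np.nan),
        fitted_mask=maps.fitted_mask & keep,
    )
    return classify_bbbo(restricted, r2_min=r2_min, dyn_min=dyn_min,
                         min_cluster=min_cluster, voxel_dims=voxel_dims,
                         connectivity=connectivity)


def compare_groups(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance (Student's) t-test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
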