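"""Cross-variant comparison of effect-size maps.

Given two thickness-difference maps (e.g. Down-syndrome AD vs
autosomal-dominant AD, where only the published effect maps — not subject
data — are available for the second variant), this module thresholds each
map at >= 0.2 mm thinning, quantifies mask overlap with the Dice
coefficient, builds a categorical overlap map, reports areas/ratios, and
correlates the raw maps across vertices (Spearman rho by default).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .surface import SurfaceMesh, VertexMap, downsample_map, vertex_areas

__all__ = [
    "OverlapSummary",
    "thinning_mask",
    "dice",
    "overlap_map",
    "spatial_correlation",
    "area_statistics",
    "summarize_overlap",
    "OVERLAP_CATEGORIES",
]

DEFAULT_THINNING_THRESHOLD_MM = 0.2
OVERLAP_CATEGORIES = {"neither": 0, "a_only": 1, "b_only": 2, "both": 3}


@dataclass
class OverlapSummary:
    hemisphere: str
    dice: float
    area_a_only_mm2: float
    area_b_only_mm2: float
    area_both_mm2: float
    containment_b_in_a: Optional[float]
    area_ratio_a_to_b: Optional[float]
    correlation: Optional[float]
    correlation_method: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def thinning_mask(
    effect_map: VertexMap, threshold_mm: float = DEFAULT_THINNING_THRESHOLD_MM
) -> np.ndarray:
    """Vertices with thinning of at least ``threshold_mm`` (inclusive).

    Expects a millimetre-difference map in the exported convention, thinning
    negative; the mask is ``delta <= -threshold``.  Maps whose magnitudes are
    implausible for mm thickness differences are rejected as a unit check.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    v = effect_map.values
    if np.abs(v).max() > 10.0:
        raise ValueError(
            "effect map magnitudes exceed 10; expected a thickness difference in mm"
        )
    return v <= -threshold_mm


def _check_same_length(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError("masks/maps are on different meshes (length mismatch)")


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Set Dice coefficient 2|A∩B| / (|A|+|B|) on vertex counts.

    1 means complete overlap, 0 complete separation.  Two empty masks return
    1.0 by convention, with a warning.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    _check_same_length(mask_a, mask_b)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na + nb == 0:
        warnings.warn("both masks empty; Dice = 1 by convention", RuntimeWarning, stacklevel=2)
        return 1.0
    return 2.0 * int((mask_a & mask_b).sum()) / (na + nb)


def area_weighted_dice(mask_a: np.ndarray, mask_b: np.ndarray, mesh: SurfaceMesh) -> float:
    """Dice on summed vertex areas instead of counts (reported alongside)."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    _check_same_length(mask_a, mask_b)
    a = vertex_areas(mesh).values
    s = a[mask_a].sum() + a[mask_b].sum()
    if s == 0:
        warnings.warn("both masks empty; Dice = 1 by convention", RuntimeWarning, stacklevel=2)
        return 1.0
    return float(2.0 * a[mask_a & mask_b].sum() / s)


def overlap_map(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Categorical vertex map: 0 neither, 1 A only, 2 B only, 3 both."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    _check_same_length(mask_a, mask_b)
    out = np.zeros(mask_a.shape[0], dtype=np.int8)
    out[mask_a & ~mask_b] = OVERLAP_CATEGORIES["a_only"]
    out[~mask_a & mask_b] = OVERLAP_CATEGORIES["b_only"]
    out[mask_a & mask_b] = OVERLAP_CATEGORIES["both"]
    return out


def spatial_correlation(
    map_a: VertexMap,
    map_b: VertexMap,
    method: str = "spearman",
    mesh: Optional[SurfaceMesh] = None,
    downsample_order: Optional[int] = None,
) -> float:
    """Across-vertex correlation of two maps (Spearman rho by default).

    ``downsample_order`` restricts both maps to the nested icosphere subset
    first (requires ``mesh``).  Constant maps have no defined correlation and
    return NaN with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    a, b = map_a.values, map_b.values
    _check_same_length(a, b)
    if downsample_order is not None:
        if mesh is None:
            raise ValueError("downsampling requires the source mesh")
        a = downsample_map(map_a, mesh, downsample_order).values
        b = downsample_map(map_b, mesh, downsample_order).values
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant map: correlation undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    return float(stats.pearsonr(a, b).statistic)


def area_statistics(mask_a: np.ndarray, mask_b: np.ndarray, mesh: SurfaceMesh) -> dict:
    """Surface areas of the two masks, their ratio, and mutual containment.

    containment_b_in_a = area(A∩B) / area(B): the fraction of B's affected
    area also implicated in A.  Ratios against an empty mask are undefined
    (None) and flagged with a warning.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    _check_same_length(mask_a, mask_b)
    if mask_a.shape[0] != mesh.n_vertices:
        raise ValueError("masks do not match mesh")
    a = vertex_areas(mesh).values
    area_a = float(a[mask_a].sum())
    area_b = float(a[mask_b].sum())
    area_both = float(a[mask_a & mask_b].sum())
    out = {"area_a_mm2": area_a, "area_b_mm2": area_b, "area_both_mm2": area_both}
    if area_b == 0:
        warnings.warn("mask B empty: ratio/containment undefined", RuntimeWarning, stacklevel=2)
        out["area_ratio_a_to_b"] = None
        out["containment_b_in_a"] = None
    else:
        out["area_ratio_a_to_b"] = area_a / area_b
        out["containment_b_in_a"] = area_both / area_b
    if area_a == 0:
        out["containment_a_in_b"] = None
    else:
        out["containment_a_in_b"] = area_both / area_a
    return out


def summarize_overlap(
    effect_a: VertexMap,
    effect_b: VertexMap,
    mesh: SurfaceMesh,
    threshold_mm: float = DEFAULT_THINNING_THRESHOLD_MM,
    method: str = "spearman",
    downsample_order: Optional[int] = None,
) -> OverlapSummary:
    """One-hemisphere overlap summary of two effect maps."""
    mask_a = thinning_mask(effect_a, threshold_mm)
    mask_b = thinning_mask(effect_b, threshold_mm)
    stats_ab = area_statistics(mask_a, mask_b, mesh)
    rho = spatial_correlation(
        effect_a, effect_b, method=method, mesh=mesh, downsample_order=downsample_order
    )
    return OverlapSummary(
        hemisphere=mesh.hemisphere,
        dice=dice(mask_a, mask_b),
        area_a_only_mm2=stats_ab["area_a_mm2"] - stats_ab["area_both_mm2"],
        area_b_only_mm2=stats_ab["area_b_mm2"] - stats_ab["area_both_mm2"],
        area_both_mm2=stats_ab["area_both_mm2"],
        containment_b_in_a=stats_ab["containment_b_in_a"],
        area_ratio_a_to_b=stats_ab["area_ratio_a_to_b"],
        correlation=rho,
        correlation_method=method,
    )
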