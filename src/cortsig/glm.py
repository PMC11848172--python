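"""Vertex-wise two-group comparison with nuisance covariates.

At every vertex, thickness is regressed on an intercept, a group indicator
and the covariates (age and sex by default) by ordinary least squares; the
group coefficient yields the t statistic, two-sided p, adjusted mean
difference in mm, and Cohen's d.  The internal sign convention is
reference-minus-advanced, so cortical *thinning* with advancing disease
stage is positive; exported effect-size maps flip the sign so thinning is
negative (blue in conventional surface renderings).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .surface import SurfaceMesh, VertexMap

__all__ = ["GroupComparisonResult", "vertex_glm", "fit_vertex_glm", "effect_size_map"]

DEFAULT_COVARIATES = ("age", "sex")


@dataclass
class GroupComparisonResult:
    """Per-vertex statistics for one ordered (reference, advanced) comparison.

    ``maps[hemisphere][kind]`` holds arrays for kinds ``t``, ``p``,
    ``delta_mm`` (reference minus advanced: thinning positive) and
    ``cohens_d`` (same sign convention).
    """

    comparison: tuple
    maps: dict
    n_reference: int
    n_advanced: int
    covariates: tuple
    dof: int
    meshes: dict = field(default_factory=dict, repr=False)

    @property
    def hemispheres(self) -> tuple:
        return tuple(self.maps.keys())


def _design_matrix(group: np.ndarray, covariates: Optional[np.ndarray], names: Sequence[str]):
    n = group.shape[0]
    cols = [np.ones(n), group.astype(np.float64)]
    kept = []
    if covariates is not None:
        for j, name in enumerate(names):
            col = covariates[:, j].astype(np.float64)
            if np.ptp(col) == 0.0:
                warnings.warn(
                    f"covariate {name!r} is constant in this comparison; dropped",
                    RuntimeWarning,
                    stacklevel=3,
                )
                continue
            cols.append(col)
            kept.append(name)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient after dropping constant covariates")
    return x, tuple(kept)


def vertex_glm(
    thickness: np.ndarray,
    group: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    covariate_names: Sequence[str] = (),
    adjusted_d: bool = True,
) -> dict:
    """OLS group comparison at every column of ``thickness``.

    Parameters
    ----------
    thickness
        ``(n_subjects, n_vertices)`` array.
    group
        Binary indicator, 1 for the more-advanced group.
    covariates
        Optional ``(n_subjects, n_covariates)`` nuisance matrix.
    adjusted_d
        Cohen's d from the covariate-adjusted difference over the pooled
        residual SD (default); if False, raw group means over pooled raw SDs.

    Returns
    -------
    dict with arrays ``t``, ``p``, ``delta_mm``, ``cohens_d`` plus scalars
    ``dof`` and ``covariates`` (names actually used).
    """
    y = np.asarray(thickness, dtype=np.float64)
    group = np.asarray(group)
    if y.ndim != 2 or y.shape[0] != group.shape[0]:
        raise ValueError("thickness must be (n_subjects, n_vertices) matching group")
    n1 = int((group == 0).sum())
    n2 = int((group == 1).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    x, kept = _design_matrix(group, covariates, covariate_names)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"too few subjects (n={n}) for {p}-column design")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    dof = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[1, 1])
    # beta[1] is advanced-minus-reference; flip to thinning-positive
    delta = -beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    if adjusted_d:
        sd = np.sqrt(np.maximum(sigma2, 0.0))
    else:
        y1, y2 = y[group == 0], y[group == 1]
        sd = np.sqrt(
            ((n1 - 1) * y1.var(axis=0, ddof=1) + (n2 - 1) * y2.var(axis=0, ddof=1)) / (n1 + n2 - 2)
        )
        delta = y1.mean(axis=0) - y2.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sd > 0, delta / sd, 0.0)
    return {
        "t": t,
        "p": pvals,
        "delta_mm": -beta[1],
        "cohens_d": d,
        "dof": dof,
        "covariates": kept,
    }


def _comparison_subjects(cohort, comparison, use_derivation_split):
    """Subjects for an ordered (reference, advanced) stage comparison.

    When the reference is CS- and an 80/20 split has been made, only the
    derivation portion enters model fitting (the withheld portion is reserved
    for unbiased ROC evaluation)."""
    ref, adv = comparison
    subjects = []
    for s in cohort.subjects:
        if s.stage == ref:
            if (
                use_derivation_split
                and ref == "CS-"
                and getattr(s, "split", None) == "withheld"
            ):
                continue
            subjects.append((s, 0))
        elif s.stage == adv:
            subjects.append((s, 1))
    return subjects


def build_covariate_matrix(subjects: Sequence, names: Sequence[str]) -> np.ndarray:
    cols = []
    for name in names:
        if name == "age":
            cols.append([s.age for s in subjects])
        elif name == "sex":
            cols.append([1.0 if s.sex == "M" else 0.0 for s in subjects])
        elif name == "centiloid":
            cols.append([s.centiloid for s in subjects])
        else:
            raise ValueError(f"unknown covariate {name!r}")
    return np.column_stack(cols) if cols else np.empty((len(subjects), 0))


def fit_vertex_glm(
    cohort,
    comparison: tuple,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    use_derivation_split: bool = True,
    adjusted_d: bool = True,
) -> GroupComparisonResult:
    """Fit the per-vertex GLM for one stage comparison on each hemisphere."""
    pairs = _comparison_subjects(cohort, comparison, use_derivation_split)
    subjects = [s for s, _ in pairs]
    group = np.array([g for _, g in pairs])
    if not subjects:
        raise ValueError(f"no subjects for comparison {comparison}")
    cov = build_covariate_matrix(subjects, covariates) if covariates else None
    maps = {}
    dof = None
    used_cov: tuple = ()
    for hemi, mesh in cohort.meshes.items():
        y = np.stack([s.thickness[hemi] for s in subjects])
        res = vertex_glm(y, group, cov, covariates, adjusted_d=adjusted_d)
        maps[hemi] = {k: res[k] for k in ("t", "p", "delta_mm", "cohens_d")}
        dof = res["dof"]
        used_cov = res["covariates"]
    return GroupComparisonResult(
        comparison=tuple(comparison),
        maps=maps,
        n_reference=int((group == 0).sum()),
        n_advanced=int((group == 1).sum()),
        covariates=used_cov,
        dof=dof,
        meshes=dict(cohort.meshes),
    )


def effect_size_map(
    result: GroupComparisonResult, kind: str, hemisphere: str = "left"
) -> VertexMap:
    """Extract an exported effect-size map (thinning negative).

    ``delta_mm`` gives the adjusted difference in mm; ``cohens_d`` the
    standardized difference.  Both are negated relative to the internal
    thinning-positive convention so that thinning plots negative/blue.
    """
    if kind not in ("delta_mm", "cohens_d"):
        raise ValueError(f"unknown effect-size kind {kind!r}")
    if hemisphere not in result.maps:
        raise ValueError(f"no {hemisphere} hemisphere in result")
    mesh = result.meshes.get(hemisphere)
    values = -result.maps[hemisphere][kind]
    if mesh is not None:
        return VertexMap.for_mesh(mesh, values)
    return VertexMap(values=values, mesh_id=f"unknown-{hemisphere}")
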