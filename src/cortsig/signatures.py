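"""Cortical-signature derivation, scoring, ROC evaluation and selection.

The procedure: threshold the vertex-wise |t| map at several vertex p-values,
form connected clusters, and keep clusters whose surface area beats a
permutation null of the maximal cluster area (Freedman-Lane residual
permutation, so age/sex covariates are respected) at the cluster-wise p
threshold.  Each surviving cluster map is a candidate cortical signature;
every candidate is scored per subject as the area-weighted mean thickness
over its vertices, evaluated by ROC against every stage comparison, and the
best-AUC candidate per comparison is the ideal signature.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from .glm import _comparison_subjects, build_covariate_matrix, _design_matrix
from .surface import (
    adjacency_matrix,
    connected_components,
    max_cluster_area,
    vertex_areas,
)

__all__ = [
    "SignatureMask",
    "RocResult",
    "DEFAULT_VERTEX_P_GRID",
    "derive_candidates",
    "signature_score",
    "roc_auc",
    "select_ideal_signature",
    "evaluate_signatures",
    "compare_effect_domains",
    "compare_aucs",
    "benjamini_hochberg",
]

DEFAULT_VERTEX_P_GRID = (0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001)
DEFAULT_COMPARISONS = (("CS-", "CS+"), ("CS+", "IMP+"), ("CS-", "IMP+"))


@dataclass
class SignatureMask:
    """Binary vertex sets (one per hemisphere) surviving cluster correction."""

    masks: dict  # hemisphere -> bool array
    comparison: tuple
    vertex_p_threshold: float
    cluster_p_threshold: float
    area_mm2: float
    cluster_tables: dict = field(default_factory=dict, repr=False)

    @property
    def is_empty(self) -> bool:
        return all(not m.any() for m in self.masks.values())

    @property
    def n_vertices(self) -> int:
        return int(sum(int(m.sum()) for m in self.masks.values()))

    @property
    def label(self) -> str:
        ref, adv = self.comparison
        return f"{ref}_vs_{adv}@p{self.vertex_p_threshold:g}"


@dataclass
class RocResult:
    """ROC curve and rank-based AUC for one score/label set.

    Orientation: the more-advanced stage is the positive class, and for
    thickness-like scores a *lower* value counts as more advanced
    (``positive_is_lower``), so an effect in the expected direction yields
    AUC >= 0.5.
    """

    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    scores: np.ndarray  # oriented: higher = more positive
    labels: np.ndarray
    positive_is_lower: bool
    comparison: Optional[tuple] = None

    def curve_area(self) -> float:
        fpr = 1.0 - self.specificity
        return float(np.trapezoid(self.sensitivity, fpr))


def _rank_auc(oriented_scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    r = stats.rankdata(oriented_scores)
    n_pos = int(labels.sum())
    n_neg = labels.shape[0] - n_pos
    return float((r[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    positive_is_lower: bool = True,
    comparison: Optional[tuple] = None,
) -> RocResult:
    """Rank-based AUC plus the full (threshold, sensitivity, specificity) curve."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    oriented = -scores if positive_is_lower else scores
    fpr, tpr, thr = _sk_roc_curve(labels, oriented)
    return RocResult(
        auc=_rank_auc(oriented, labels),
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        scores=oriented,
        labels=labels,
        positive_is_lower=positive_is_lower,
        comparison=comparison,
    )


# ---------------------------------------------------------------------------
# Candidate derivation


def _freedman_lane_tmaps(y, x, z, perms):
    """Permutation t statistics for the group column of ``x`` under the
    Freedman-Lane scheme: residuals from the reduced (covariate-only) model
    ``z`` are permuted, re-attached to the reduced fit, and the full model is
    refit.  Returns (n_perm, n_vertices)."""
    n, p = x.shape
    dof = n - p
    xtx_inv = np.linalg.inv(x.T @ x)
    h = xtx_inv @ x.T  # (p, n)
    z_pinv = np.linalg.pinv(z)
    fitted_red = z @ (z_pinv @ y)
    resid_red = y - fitted_red
    t_perm = np.empty((perms.shape[0], y.shape[1]))
    for k, perm in enumerate(perms):
        yp = fitted_red + resid_red[perm]
        beta = h @ yp
        resid = yp - x @ beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
        se = np.sqrt(np.maximum(sigma2, 1e-300) * xtx_inv[1, 1])
        t_perm[k] = beta[1] / se
    return t_perm


def derive_candidates(
    cohort,
    comparison: tuple,
    vertex_p_grid: Sequence[float] = DEFAULT_VERTEX_P_GRID,
    cluster_p: float = 0.001,
    n_perm: int = 1000,
    covariates: Sequence[str] = ("age", "sex"),
    seed: int = 0,
) -> list:
    """Candidate signatures: one per vertex-p grid point (both hemispheres).

    Model fitting uses the derivation subset only (withheld CS- members are
    skipped).  The permutation null pools the maximal suprathreshold cluster
    area over both hemispheres, giving family-wise control across the whole
    surface.  A grid point with no surviving cluster still yields an (empty)
    candidate: small effects may be detectable by signature means even when
    no vertex-wise difference survives correction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm + 1 < 1.0 / cluster_p:
        warnings.warn(
            f"n_perm={n_perm} cannot resolve cluster_p={cluster_p} "
            f"(needs >= {int(np.ceil(1.0 / cluster_p)) - 1}); no cluster can survive",
            RuntimeWarning,
            stacklevel=2,
        )
    pairs = _comparison_subjects(cohort, comparison, use_derivation_split=True)
    subjects = [s for s, _ in pairs]
    group = np.array([g for _, g in pairs], dtype=float)
    cov = build_covariate_matrix(subjects, covariates) if covariates else None
    x, _ = _design_matrix(group, cov, covariates)
    z = np.delete(x, 1, axis=1)  # reduced model: intercept + covariates
    n, p = x.shape
    dof = n - p

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])

    hemis = list(cohort.meshes.keys())
    observed_t = {}
    perm_t = {}
    areas = {}
    adj = {}
    for hemi in hemis:
        mesh = cohort.meshes[hemi]
        y = cohort.thickness_matrix(hemi, subjects)
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ (x.T @ y)
        resid = y - x @ beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
        se = np.sqrt(np.maximum(sigma2, 1e-300) * xtx_inv[1, 1])
        observed_t[hemi] = beta[1] / se
        perm_t[hemi] = _freedman_lane_tmaps(y, x, z, perms)
        areas[hemi] = vertex_areas(mesh).values
        adj[hemi] = adjacency_matrix(mesh)

    candidates = []
    for p_thr in vertex_p_grid:
        t_crit = stats.t.isf(p_thr / 2.0, dof)
        # permutation null of the max cluster area pooled over hemispheres
        null_max = np.zeros(n_perm)
        for hemi in hemis:
            abs_t = np.abs(perm_t[hemi])
            for k in range(n_perm):
                mask = abs_t[k] >= t_crit
                if mask.any():
                    a = max_cluster_area(adj[hemi], areas[hemi], mask)
                    if a > null_max[k]:
                        null_max[k] = a
        masks = {}
        tables = {}
        total_area = 0.0
        for hemi in hemis:
            mesh = cohort.meshes[hemi]
            supra = np.abs(observed_t[hemi]) >= t_crit
            table = connected_components(mesh, supra, stat_map=observed_t[hemi])
            keep = []
            for cl in table.clusters:
                cl.p_value = float(
                    (1 + np.count_nonzero(null_max >= cl.area_mm2)) / (n_perm + 1)
                )
                if cl.p_value <= cluster_p:
                    keep.append(cl)
            mask = np.zeros(mesh.n_vertices, dtype=bool)
            for cl in keep:
                mask[cl.vertices] = True
                total_area += cl.area_mm2
            masks[hemi] = mask
            table.clusters = keep
            tables[hemi] = table
        candidates.append(
            SignatureMask(
                masks=masks,
                comparison=tuple(comparison),
                vertex_p_threshold=float(p_thr),
                cluster_p_threshold=float(cluster_p),
                area_mm2=total_area,
                cluster_tables=tables,
            )
        )
    return candidates


# ---------------------------------------------------------------------------
# Scoring and selection


def area_weighted_mean(values: np.ndarray, areas: np.ndarray, mask: np.ndarray) -> float:
    w = areas[mask]
    return float(np.sum(w * values[mask]) / np.sum(w))


def signature_score(subject, mask: SignatureMask, meshes: dict) -> float:
    """Area-weighted mean thickness (mm) over the signature, hemispheres
    pooled by vertex area."""
    if mask.is_empty:
        raise ValueError("signature mask is empty; candidate unusable for scoring")
    num = 0.0
    den = 0.0
    for hemi, m in mask.masks.items():
        if not m.any():
            continue
        a = vertex_areas(meshes[hemi]).values
        num += float(np.sum(a[m] * subject.thickness[hemi][m]))
        den += float(np.sum(a[m]))
    return num / den


def score_subjects(subjects: Sequence, mask: SignatureMask, meshes: dict) -> np.ndarray:
    return np.array([signature_score(s, mask, meshes) for s in subjects])


def _evaluation_subjects(cohort, comparison):
    """Evaluation roster for a comparison: withheld CS- members when a split
    exists (unbiased ROC), all members of other stages."""
    ref, adv = comparison
    out = []
    for s in cohort.subjects:
        if s.stage == ref:
            if ref == "CS-" and getattr(s, "split", None) == "derivation":
                continue
            out.append((s, 0))
        elif s.stage == adv:
            out.append((s, 1))
    return out


def candidate_roc(cohort, mask: SignatureMask, comparison: tuple) -> RocResult:
    pairs = _evaluation_subjects(cohort, comparison)
    scores = score_subjects([s for s, _ in pairs], mask, cohort.meshes)
    labels = np.array([g for _, g in pairs])
    return roc_auc(scores, labels, positive_is_lower=True, comparison=tuple(comparison))


def select_ideal_signature(candidates: Sequence[SignatureMask], comparison: tuple, cohort):
    """Best-AUC candidate for the comparison; ties broken by smaller mask
    area.  Returns ``(mask, roc)`` or ``(None, None)`` when every candidate
    is empty (no-signature result)."""
    usable = [c for c in candidates if not c.is_empty]
    if not usable:
        return None, None
    best = None
    best_roc = None
    for cand in usable:
        roc = candidate_roc(cohort, cand, comparison)
        if (
            best is None
            or roc.auc > best_roc.auc + 1e-12
            or (abs(roc.auc - best_roc.auc) <= 1e-12 and cand.area_mm2 < best.area_mm2)
        ):
            best, best_roc = cand, roc
    return best, best_roc


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (delegates to statsmodels)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def evaluate_signatures(
    candidates: Sequence[SignatureMask],
    cohort,
    comparisons: Sequence[tuple] = DEFAULT_COMPARISONS,
) -> pd.DataFrame:
    """Full cross of candidates x comparisons: AUC, group means/SDs, Cohen's
    d, Welch t, raw p, and BH-adjusted p across the whole table.

    Signatures derived from one comparison are applied to every comparison;
    even an all-null-derived signature's mean thickness may separate stages.
    """
    rows = []
    for cand in candidates:
        for comp in comparisons:
            if cand.is_empty:
                continue
            pairs = _evaluation_subjects(cohort, comp)
            scores = score_subjects([s for s, _ in pairs], cand, cohort.meshes)
            labels = np.array([g for _, g in pairs])
            roc = roc_auc(scores, labels, positive_is_lower=True, comparison=tuple(comp))
            s_ref, s_adv = scores[labels == 0], scores[labels == 1]
            t_res = stats.ttest_ind(s_ref, s_adv, equal_var=False)
            pooled_sd = np.sqrt(
                (
                    (len(s_ref) - 1) * s_ref.var(ddof=1)
                    + (len(s_adv) - 1) * s_adv.var(ddof=1)
                )
                / (len(s_ref) + len(s_adv) - 2)
            )
            d = (s_ref.mean() - s_adv.mean()) / pooled_sd if pooled_sd > 0 else 0.0
            rows.append(
                {
                    "signature": cand.label,
                    "derived_from": f"{cand.comparison[0]}_vs_{cand.comparison[1]}",
                    "vertex_p": cand.vertex_p_threshold,
                    "comparison": f"{comp[0]}_vs_{comp[1]}",
                    "auc": roc.auc,
                    "mean_reference": s_ref.mean(),
                    "sd_reference": s_ref.std(ddof=1),
                    "mean_advanced": s_adv.mean(),
                    "sd_advanced": s_adv.std(ddof=1),
                    "cohens_d": d,
                    "t": float(t_res.statistic),
                    "p_raw": float(t_res.pvalue),
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_fdr"] = benjamini_hochberg(table["p_raw"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# Cross-domain comparisons


def compare_effect_domains(cortical_ds: Sequence[float], subcortical_ds: Sequence[float]) -> dict:
    """Welch comparison of two collections of effect sizes (e.g. cortical
    signature d's vs subcortical region d's)."""
    a = np.asarray(cortical_ds, dtype=float)
    b = np.asarray(subcortical_ds, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both effect-size lists must be nonempty")
    out = {"mean_cortical": float(a.mean()), "mean_subcortical": float(b.mean())}
    if a.size < 2 or b.size < 2:
        out.update(t=None, p=None, degenerate="singleton list")
        return out
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            out.update(t=0.0, p=1.0, degenerate=None)
        else:
            out.update(t=float("inf"), p=0.0, degenerate="zero variance")
        return out
    res = stats.ttest_ind(a, b, equal_var=False)
    out.update(t=float(res.statistic), p=float(res.pvalue), degenerate=None)
    return out


def _delong_variance(oriented: np.ndarray, labels: np.ndarray):
    """Placement values for DeLong covariance estimation."""
    pos = oriented[labels == 1]
    neg = oriented[labels == 0]
    m, n = len(pos), len(neg)

    def midrank(x):
        return stats.rankdata(x)

    all_ranks = midrank(np.concatenate([pos, neg]))
    pos_ranks = midrank(pos)
    neg_ranks = midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # per-positive placements
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per-negative placements
    auc = v10.mean()
    return auc, v10, v01


def compare_aucs(
    roc_a: RocResult,
    roc_b: RocResult,
    paired: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Two-sided test of AUC(a) = AUC(b).

    Paired (same subjects): DeLong's covariance-corrected z test.  Unpaired:
    bootstrap of the AUC difference.  The method used is recorded in the
    returned dict.
    """
    if roc_a.comparison != roc_b.comparison:
        raise ValueError("ROC results compare different stage pairs")
    if paired:
        if roc_a.labels.shape != roc_b.labels.shape or not np.array_equal(
            roc_a.labels, roc_b.labels
        ):
            raise ValueError("paired DeLong test requires identical subjects/labels")
        auc_a, v10_a, v01_a = _delong_variance(roc_a.scores, roc_a.labels)
        auc_b, v10_b, v01_b = _delong_variance(roc_b.scores, roc_b.labels)
        m, n = len(v10_a), len(v01_a)
        s10 = np.cov(np.stack([v10_a, v10_b])) if m > 1 else np.zeros((2, 2))
        s01 = np.cov(np.stack([v01_a, v01_b])) if n > 1 else np.zeros((2, 2))
        cov = s10 / m + s01 / n
        var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
        diff = auc_a - auc_b
        if var_diff <= 0:
            p = 1.0 if diff == 0 else 0.0
            z = 0.0 if diff == 0 else np.sign(diff) * np.inf
        else:
            z = diff / np.sqrt(var_diff)
            p = float(2.0 * stats.norm.sf(abs(z)))
        return {"method": "delong", "auc_a": float(auc_a), "auc_b": float(auc_b),
                "z": float(z), "p": p}
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for k in range(n_boot):
        sa = _boot_auc(roc_a, rng)
        sb = _boot_auc(roc_b, rng)
        diffs[k] = sa - sb
    observed = roc_a.auc - roc_b.auc
    # percentile-bootstrap two-sided p for H0: difference = 0
    p = 2.0 * min(np.mean(diffs <= 0.0), np.mean(diffs >= 0.0))
    p = float(min(max(p, 1.0 / n_boot), 1.0))
    return {"method": "bootstrap", "auc_a": roc_a.auc, "auc_b": roc_b.auc,
            "observed_diff": float(observed), "p": p, "n_boot": n_boot}


def _boot_auc(roc: RocResult, rng: np.random.Generator) -> float:
    """Stratified bootstrap AUC resample."""
    pos = roc.scores[roc.labels == 1]
    neg = roc.scores[roc.labels == 0]
    pos_s = rng.choice(pos, size=len(pos), replace=True)
    neg_s = rng.choice(neg, size=len(neg), replace=True)
    scores = np.concatenate([neg_s, pos_s])
    labels = np.concatenate([np.zeros(len(neg_s), dtype=int), np.ones(len(pos_s), dtype=int)])
    return _rank_auc(scores, labels)
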