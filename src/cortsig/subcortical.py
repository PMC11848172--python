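"""Intracranial-volume correction and staging evaluation of subcortical volumes.

ICV correction uses the residual (regression) method: the volume-on-ICV
slope is estimated per region and side within a reference group (CS- by
default, so disease effects cannot bias the slope) and every subject's
volume is adjusted to the reference mean ICV.  Each adjusted region is then
evaluated as a stage classifier with the same ROC / Welch-t / FDR machinery
used for cortical signatures, with smaller volume counting as more advanced.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import DEFAULT_COMPARISONS, benjamini_hochberg, roc_auc

__all__ = ["IcvModel", "icv_correct", "region_staging_table", "volume_scores"]

REQUIRED_COLUMNS = ("subject_id", "region", "side", "volume_mm3", "icv_mm3", "stage")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"volume table missing columns {missing}")
    dup = table.duplicated(subset=["subject_id", "region", "side"])
    if dup.any():
        raise ValueError("volume table has duplicate (subject, region, side) rows")
    if (table["volume_mm3"] <= 0).any():
        raise ValueError("volumes must be positive")


@dataclass
class IcvModel:
    """Per (region, side) regression parameters used for the adjustment."""

    slopes: pd.DataFrame  # region, side, slope, reference_mean_icv
    reference_group: str


def icv_correct(
    table: pd.DataFrame, reference_group: str = "CS-", min_reference: int = 10
) -> tuple:
    """Residual-method ICV adjustment.

    adjusted = raw - slope * (ICV - mean ICV of the reference group), with
    the slope fit by least squares per region and side within the reference
    group only.  Returns ``(adjusted_table, IcvModel)``.  Idempotent: the
    adjusted volumes are uncorrelated with ICV in the reference group, so a
    second pass refits a ~zero slope.
    """
    _check_table(table)
    ref = table[table["stage"] == reference_group]
    n_ref = ref["subject_id"].nunique()
    if n_ref < min_reference:
        raise ValueError(
            f"reference group {reference_group!r} has {n_ref} subjects (< {min_reference})"
        )
    icv_by_subject = ref.drop_duplicates("subject_id")["icv_mm3"]
    if icv_by_subject.std(ddof=1) == 0:
        raise ValueError("degenerate ICV variance in reference group")
    ref_icv_mean = float(icv_by_subject.mean())

    out = table.copy()
    rows = []
    for (region, side), grp in ref.groupby(["region", "side"], sort=True):
        slope = float(np.polyfit(grp["icv_mm3"], grp["volume_mm3"], 1)[0])
        rows.append((region, side, slope, ref_icv_mean))
        sel = (out["region"] == region) & (out["side"] == side)
        out.loc[sel, "volume_mm3"] = out.loc[sel, "volume_mm3"] - slope * (
            out.loc[sel, "icv_mm3"] - ref_icv_mean
        )
    model = IcvModel(
        slopes=pd.DataFrame(rows, columns=["region", "side", "slope", "reference_mean_icv"]),
        reference_group=reference_group,
    )
    return out, model


def volume_scores(table: pd.DataFrame, region: str, side: str) -> pd.DataFrame:
    sel = table[(table["region"] == region) & (table["side"] == side)]
    return sel[["subject_id", "volume_mm3", "stage"]]


def region_staging_table(
    table: pd.DataFrame,
    comparisons=DEFAULT_COMPARISONS,
    withheld_reference: bool = False,
    split_by_subject: dict | None = None,
) -> pd.DataFrame:
    """Per (region, side, comparison) AUC, Cohen's d, Welch t and FDR p.

    Orientation: smaller (adjusted) volume = more advanced stage.  When
    ``withheld_reference`` is set and ``split_by_subject`` maps subject id to
    a split label, CS- rows restrict to the withheld subset for ROC parity
    with the cortical evaluation.
    """
    _check_table(table)
    rows = []
    for (region, side), grp in table.groupby(["region", "side"], sort=True):
        for ref, adv in comparisons:
            g_ref = grp[grp["stage"] == ref]
            if withheld_reference and ref == "CS-" and split_by_subject:
                keep = g_ref["subject_id"].map(lambda i: split_by_subject.get(i) != "derivation")
                g_ref = g_ref[keep]
            g_adv = grp[grp["stage"] == adv]
            if len(g_ref) < 2 or len(g_adv) < 2:
                continue
            v_ref = g_ref["volume_mm3"].to_numpy()
            v_adv = g_adv["volume_mm3"].to_numpy()
            scores = np.concatenate([v_ref, v_adv])
            labels = np.concatenate([np.zeros(len(v_ref), int), np.ones(len(v_adv), int)])
            roc = roc_auc(scores, labels, positive_is_lower=True, comparison=(ref, adv))
            t_res = stats.ttest_ind(v_ref, v_adv, equal_var=False)
            pooled_sd = np.sqrt(
                ((len(v_ref) - 1) * v_ref.var(ddof=1) + (len(v_adv) - 1) * v_adv.var(ddof=1))
                / (len(v_ref) + len(v_adv) - 2)
            )
            d = (v_ref.mean() - v_adv.mean()) / pooled_sd if pooled_sd > 0 else 0.0
            rows.append(
                {
                    "region": region,
                    "side": side,
                    "comparison": f"{ref}_vs_{adv}",
                    "n_reference": len(v_ref),
                    "n_advanced": len(v_adv),
                    "auc": roc.auc,
                    "cohens_d": d,
                    "t": float(t_res.statistic),
                    "p_raw": float(t_res.pvalue),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = benjamini_hochberg(out["p_raw"].to_numpy())
    return out
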