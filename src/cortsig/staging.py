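"""Amyloid positivity, disease-stage assignment, and the 80/20 reference split.

Stages follow the preclinical-AD convention for adults with Down syndrome:
``CS-`` cognitively stable and amyloid-PET negative, ``CS+`` cognitively
stable and amyloid positive (preclinical), ``IMP+`` impaired (MCI-DS or
dementia) and amyloid positive.  Impaired amyloid-negative subjects, those
with undetermined cognition and those without amyloid PET are excluded.
Amyloid positivity uses tracer-specific centiloid cut-offs: >= 16.4 for
Pittsburgh compound B, >= 20.6 for florbetapir (both inclusive).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "PIB_CENTILOID_THRESHOLD",
    "FLORBETAPIR_CENTILOID_THRESHOLD",
    "StageLabel",
    "classify_amyloid",
    "assign_stage",
    "split_reference",
]

PIB_CENTILOID_THRESHOLD = 16.4
FLORBETAPIR_CENTILOID_THRESHOLD = 20.6

STAGES = ("CS-", "CS+", "IMP+")
CLINICAL_STATUSES = ("CS", "MCI-DS", "DEM", "undetermined")
EXCLUSION_REASONS = (
    "uncertain cognition",
    "missing amyloid",
    "impaired amyloid-negative",
    "none",
)


@dataclass(frozen=True)
class StageLabel:
    value: str  # CS-, CS+, IMP+, excluded
    exclusion_reason: str = "none"

    def __post_init__(self):
        if self.value not in STAGES + ("excluded",):
            raise ValueError(f"invalid stage {self.value!r}")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"invalid exclusion reason {self.exclusion_reason!r}")
        if (self.value == "excluded") == (self.exclusion_reason == "none"):
            raise ValueError("exclusion_reason must be set exactly when value is 'excluded'")

    @property
    def excluded(self) -> bool:
        return self.value == "excluded"


def classify_amyloid(tracer: str, centiloid: float) -> str:
    """'positive' or 'negative' by tracer-specific inclusive centiloid cut-off."""
    if not math.isfinite(centiloid):
        raise ValueError("centiloid must be finite")
    thresholds = {
        "PiB": PIB_CENTILOID_THRESHOLD,
        "florbetapir": FLORBETAPIR_CENTILOID_THRESHOLD,
    }
    if tracer not in thresholds:
        raise ValueError(f"unknown tracer {tracer!r}; expected PiB or florbetapir")
    return "positive" if centiloid >= thresholds[tracer] else "negative"


def assign_stage(amyloid: str, clinical: str) -> StageLabel:
    """Total map from (amyloid status, clinical status) to a stage label."""
    if amyloid not in ("positive", "negative", "missing"):
        raise ValueError(f"invalid amyloid status {amyloid!r}")
    if clinical not in CLINICAL_STATUSES:
        raise ValueError(f"invalid clinical status {clinical!r}")
    if clinical == "undetermined":
        return StageLabel("excluded", "uncertain cognition")
    if amyloid == "missing":
        return StageLabel("excluded", "missing amyloid")
    impaired = clinical in ("MCI-DS", "DEM")
    if amyloid == "negative":
        if impaired:
            return StageLabel("excluded", "impaired amyloid-negative")
        return StageLabel("CS-")
    return StageLabel("IMP+") if impaired else StageLabel("CS+")


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or len(b) < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _proportion_p(k1: int, n1: int, k2: int, n2: int) -> float:
    if n1 == 0 or n2 == 0:
        return 1.0
    k_tot = k1 + k2
    if k_tot == 0 or k_tot == n1 + n2:
        return 1.0
    _, p = proportions_ztest([k1, k2], [n1, n2])
    return float(p)


def balance_report(derivation, withheld) -> pd.DataFrame:
    """Two-sided balance checks between split halves: Welch t on age and
    centiloid, two-proportion z on sex and APOE e4 carriage."""
    rows = []
    age_d = np.array([s.age for s in derivation])
    age_w = np.array([s.age for s in withheld])
    cl_d = np.array([s.centiloid for s in derivation])
    cl_w = np.array([s.centiloid for s in withheld])
    rows.append(("age", "welch_t", _welch_p(age_d, age_w)))
    rows.append(("centiloid", "welch_t", _welch_p(cl_d, cl_w)))
    male_d = sum(s.sex == "M" for s in derivation)
    male_w = sum(s.sex == "M" for s in withheld)
    rows.append(
        ("sex", "two_proportion_z", _proportion_p(male_d, len(derivation), male_w, len(withheld)))
    )
    apoe_d = sum(bool(s.apoe_e4) for s in derivation)
    apoe_w = sum(bool(s.apoe_e4) for s in withheld)
    rows.append(
        ("apoe_e4", "two_proportion_z", _proportion_p(apoe_d, len(derivation), apoe_w, len(withheld)))
    )
    return pd.DataFrame(rows, columns=["variable", "test", "p_value"])


def split_reference(cohort, group: str = "CS-", fraction: float = 0.8, seed: int = 0):
    """Randomly split one stage group into derivation and withheld subsets.

    The derivation side gets ``ceil(fraction * n)`` members.  Subjects of the
    named group get their ``split`` attribute set ('derivation'/'withheld');
    all other groups are untouched.  Returns
    ``(derivation_subjects, withheld_subjects, balance_report)``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in the open interval (0, 1)")
    members = [s for s in cohort.subjects if s.stage == group]
    n = len(members)
    if n == 0:
        raise ValueError(f"group {group!r} not present in cohort")
    if fraction * n < 2:
        raise ValueError(f"fraction*n = {fraction * n:.2f} < 2; split too small")
    n_deriv = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    deriv_idx = set(order[:n_deriv].tolist())
    derivation, withheld = [], []
    for i, s in enumerate(members):
        if i in deriv_idx:
            s.split = "derivation"
            derivation.append(s)
        else:
            s.split = "withheld"
            withheld.append(s)
    return derivation, withheld, balance_report(derivation, withheld)
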