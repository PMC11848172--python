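# cortsig

Surface-based staging of Alzheimer's disease in Down syndrome (DSAD) from
cortical thickness. Adults with Down syndrome develop amyloid pathology and
dementia at high rates, and trials need imaging markers that track disease
*stage*. `cortsig` implements the full analysis as a tested, reusable
pipeline:

- **staging** — cross amyloid-PET status (centiloid ≥ 16.4 for PiB,
  ≥ 20.6 for florbetapir) with clinical status into CS− / CS+ / IMP+
  groups, with explicit exclusion rules and an 80/20 CS− reference split;
- **vertex-wise GLM** — per-vertex OLS of thickness on group, age and sex,
  yielding t, p, Δmm and Cohen's *d* maps per hemisphere;
- **cortical signatures** — threshold |t| at multiple vertex-wise p values,
  keep clusters that survive a Freedman–Lane permutation null of maximal
  cluster area (cluster-wise p ≤ 0.001), score each candidate as the
  area-weighted mean thickness per subject, and select the best-AUC
  candidate per group comparison as the *ideal* signature;
- **subcortical volumes** — residual-method ICV correction (slope fit in
  CS− only) and the same ROC / Welch-t / Benjamini–Hochberg evaluation per
  region and side;
- **map comparison** — ≥ 0.2 mm thinning masks, Dice overlap, overlap
  category maps, area ratios, and across-vertex Spearman correlation
  between effect-size maps of different disease variants (e.g. DSAD vs
  autosomal-dominant AD, where only maps are shareable);
- **synthetic cohorts** — generated populations with the target study's
  demographic structure and configurable focal-thinning patches on
  icosphere meshes, with ground truth retained, so everything above is
  testable without restricted clinical data.

The statistic at the core: for a signature *S* with vertex areas
*a<sub>v</sub>*, a subject's score is
x̄ = Σ<sub>v∈S</sub> a<sub>v</sub> x<sub>v</sub> / Σ<sub>v∈S</sub> a<sub>v</sub>,
and the staging performance of *S* is the Mann–Whitney AUC
P(x̄<sub>advanced</sub> < x̄<sub>earlier</sub>) (+½ for ties) on subjects not
used in derivation.

## Worked example

```python
import numpy as np
from cortsig import generate_cohort, split_reference
from cortsig.signatures import derive_candidates, select_ideal_signature
from cortsig.subcortical import icv_correct, region_staging_table
from cortsig.overlap import dice

cohort = generate_cohort(seed=1)                      # 106 CS-, 45 CS+, 27 IMP+
split_reference(cohort, seed=2)                       # 85/21 CS- split
candidates = derive_candidates(cohort, ("CS-", "IMP+"), n_perm=999, seed=3)
mask, roc = select_ideal_signature(candidates, ("CS-", "IMP+"), cohort)
truth = np.concatenate([cohort.truth_masks[h] for h in ("left", "right")])
found = np.concatenate([mask.masks[h] for h in ("left", "right")])
print(f"ideal signature: {mask.label}, {mask.n_vertices} vertices, "
      f"{mask.area_mm2:.0f} mm^2")
print(f"AUC (withheld CS- vs IMP+): {roc.auc:.3f}")
print(f"Dice vs ground-truth patches: {dice(truth, found):.3f}")

adjusted, _ = icv_correct(cohort.volume_table())
table = region_staging_table(adjusted, comparisons=(("CS-", "IMP+"),))
best = table.loc[table["auc"].idxmax()]
print(f"best subcortical region: {best.side} {best.region}, AUC {best.auc:.3f}")
```

prints

```
ideal signature: CS-_vs_IMP+@p0.001, 47 vertices, 2172 mm^2
AUC (withheld CS- vs IMP+): 1.000
Dice vs ground-truth patches: 0.591
best subcortical region: left hippocampus, AUC 0.983
```

Reading this: from a synthetic cohort with the default study demographics,
the derivation subset (85 CS− plus all 27 IMP+) yields a surviving cluster
map at vertex p = 0.001 covering 2,172 mm²; its mean thickness separates the
*withheld* 21 CS− from IMP+ perfectly (the configured 0.30–0.375 mm patch
thinning is a strong effect at this noise level), and the recovered
signature overlaps the true seeded patches with Dice 0.59. Among
ICV-corrected subcortical volumes, the hippocampus — configured to decline
monotonically across stages — classifies best, mirroring the cortical
result.

A command-line interface wraps the same functions
(`cortsig simulate | stage | glm | derive | evaluate | subcortical |
compare-maps | run-all`); `cortsig run-all` executes every stage and writes
a report bundle (JSON report, evaluation CSVs, signature label files, ROC
plots).

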