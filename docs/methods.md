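# Methods

`cortsig` implements a surface-based staging analysis for Alzheimer's disease
in adults with Down syndrome (DSAD): data-driven *cortical signatures* are
derived from vertex-wise thickness comparisons between disease-stage groups,
evaluated as stage classifiers by ROC analysis alongside ICV-corrected
subcortical volumes, and effect-size maps are compared across disease
variants by Dice overlap and spatial correlation. This note documents the
models, the synthetic cohorts the package is validated on, and the numerical
choices a user should know about.

## Disease staging

Participants are staged by crossing amyloid-PET status with clinical status:

- **CS−** — cognitively stable, amyloid negative;
- **CS+** — cognitively stable, amyloid positive (preclinical);
- **IMP+** — impaired (MCI-DS or dementia) and amyloid positive.

Amyloid positivity uses tracer-specific centiloid cut-offs, both inclusive:
≥ 16.4 for Pittsburgh compound B, ≥ 20.6 for florbetapir. Subjects with
undetermined cognition, missing amyloid PET, or impairment despite a negative
scan are excluded (each with a recorded reason). To keep ROC evaluation of
CS−-based comparisons unbiased, the CS− group is split 80/20: the derivation
side (⌈0.8·n⌉ subjects) enters all model fitting, the withheld side is used
only for ROC scoring. The split is simple random (not stratified); a balance
report (Welch t on age and centiloid, two-proportion z on sex and APOE ε4) is
emitted so a user can check any given split.

## Vertex-wise model

At every mesh vertex, thickness is regressed by OLS on an intercept, a group
indicator, and covariates (age and sex by default; a constant covariate is
dropped with a warning). The group coefficient provides the t statistic
(df = n − p), two-sided p, the adjusted mean difference in mm, and Cohen's d.
One shared covariate slope is fit for both groups (no group × covariate
interaction). Cohen's d defaults to the covariate-adjusted difference over
the pooled residual SD; a raw-SD variant is available
(`vertex_glm(..., adjusted_d=False)`) since either convention appears in the
literature. Sign conventions: internally the difference is
reference − advanced, so thinning with advancing stage is positive; exported
effect maps are negated so thinning plots negative (blue), and the ≥ 0.2 mm
thinning threshold is applied as Δ ≤ −0.2 on exported maps.

## Signature derivation and selection

For each vertex-p threshold in a grid (default 0.05, 0.01, 0.005, 0.001,
0.0005, 0.0001) the |t| map is thresholded and connected clusters are formed
under mesh adjacency. Cluster-wise inference uses a Freedman–Lane
permutation null: residuals from the covariate-only model are permuted,
re-attached to the reduced fit, the full model refit, and the maximal
suprathreshold cluster area (pooled over both hemispheres) recorded per
permutation. A cluster survives when its permutation p,
(1 + #{null ≥ area}) / (n_perm + 1), is ≤ the cluster-wise threshold
(default 0.001; n_perm must be ≥ 1/cluster_p − 1 for any cluster to survive,
and the code warns otherwise). Surviving clusters at one grid point form one
candidate signature; a grid point with no survivors still yields an (empty)
candidate, because signature means can separate stages even when no single
vertex effect survives correction.

A subject's signature score is the area-weighted mean thickness over the
signature's vertices, hemispheres pooled by vertex area (one third of
incident triangle areas, so areas sum exactly to the mesh surface area).
AUC is the Mann–Whitney rank statistic with midrank ties, oriented so that
lower thickness counts as more advanced; the full
(threshold, sensitivity, specificity) curve is kept. Every candidate is
scored on every comparison (signatures transfer across comparisons), tested
with Welch t, and Benjamini–Hochberg-adjusted across the whole evaluation
table. The best-AUC candidate per comparison is the ideal signature; exact
AUC ties go to the smaller-area mask. AUC differences are tested with
DeLong's paired test (same subjects) or a stratified bootstrap (otherwise).

## Subcortical volumes

Regional volumes (hippocampus, amygdala, accumbens, caudate, putamen,
pallidum, thalamus; per side) are ICV-corrected by the residual method: the
volume-on-ICV slope is fit per region and side within CS− only — so disease
effects cannot bias the slope — and volumes are adjusted to the reference
mean ICV. Correction is idempotent and decorrelates volume from ICV in the
reference group. Per-side correction (rather than pooled hemispheres) was
chosen and is noted as a convention, not a finding. Each adjusted region is
then evaluated with the same ROC/Welch/FDR machinery, smaller volume =
more advanced.

## Cross-variant map comparison

Only effect-size maps (not subject data) are assumed available for the
second variant (the autosomal-dominant AD situation), so the interface takes
bare vertex maps. Thinning masks are thresholded at ≥ 0.2 mm; overlap is
quantified by the Dice coefficient on vertex counts (the cited set-based
definition; an area-weighted variant is reported alongside), a four-category
overlap map (neither / A only / B only / both), area ratios and containment
fractions from vertex areas, and across-vertex correlation — Spearman rho by
default (the conventional reading of "Rho"), Pearson switchable, with
optional nested-icosphere downsampling first. Two empty masks give Dice 1 by
convention, flagged with a warning.

## Surface geometry

Meshes are triangulated spheres: generated icospheres (order k has
10·4^k + 2 vertices; order 7 matches fsaverage's 163,842 per hemisphere,
order 4 the 2,562-vertex downsampling used for scatter comparisons) with
nested vertex ordering, so downsampling a map is a prefix slice. Real
FreeSurfer/GIFTI surfaces load through `cortsig.io`. Smoothing is iterated
self-inclusive neighbor averaging (the FreeSurfer-style approach) with the
iteration count — plus a relaxation factor for sub-iteration granularity —
calibrated at run time so a unit spike spreads to the requested FWHM,
measured against graph-geodesic distance; the calibration contract is ±20%.
A requested FWHM below the mean edge length cannot be realized and returns
the map unsmoothed with a warning. Each iteration is a convex combination,
so constant maps are exact fixed points and extrema never widen.

## Synthetic cohorts

The generator emulates the target study population so every stage is
testable without restricted data:

- **Demographics** (defaults): group sizes 106/45/27; ages Gaussian with
  means (SD) 36.20 (6.20), 48.91 (6.18), 51.93 (4.33) years; centiloids
  Gaussian 1.05 (7.42), 51.96 (23.82), 76.37 (35.32), truncated at the
  tracer-specific positivity bound so CS− subjects are all negative and
  CS+/IMP+ all positive; sex (54/106, 28/45, 19/27 male), APOE ε4 (22/106,
  6/45, 8/27), tracer mix (115 PiB : 63 florbetapir) and the 15/12
  MCI-DS/DEM split drawn as exact rounded counts, randomly placed.
- **Thickness**: baseline 2.5 mm plus a smooth Gaussian field (white noise
  surface-smoothed to 20 mm FWHM, rescaled to 0.25 mm pointwise SD), an age
  slope of −0.005 mm/year about the cohort mean age, and group-dependent
  focal thinning in geodesic-disc patches at parietal-like and temporal-like
  locations (radii 25 and 18 mm; CS+ 0.10 mm, IMP+ 0.30 mm on the left,
  ×1.25 on the right to mimic rightward asymmetry). Draws below 0.5 mm are
  truncated with a warning. The within-group spatial SD of 0.25 mm and the
  patch magnitudes are stated assumptions — the study reports no thickness
  variance — chosen so per-vertex effects are in the d ≈ 1 regime typical of
  symptomatic-stage atrophy.
- **Subcortical volumes**: region means/SDs at adult norms, stagewise shifts
  with hippocampus declining monotonically, accumbens shifting mostly
  CS−→CS+, putamen mostly CS+→IMP+ (the qualitative early/late pattern);
  volumes scale with ICV (mean 1.2×10⁶ mm³, SD 1.1×10⁵) through an
  elasticity of 0.8.
- **Variant pairs**: a second cohort with the same patch centers, 1/6 of the
  patch area and no asymmetry stands in for the autosomal-dominant variant;
  ground-truth masks are retained so derived-map overlap can be scored.

What the generator does *not* emulate: real cortical folding and curvature
(spheres only), anatomically realistic thickness topography, site/scanner
effects, spatially varying noise, longitudinal change, or correlation
between thickness and subcortical atrophy. Passing recovery tests therefore
demonstrates the statistical machinery is correct and well-calibrated under
a known truth — not that effect sizes on real data will match.

## Validation suites and problem sizes

- Oracle equivalence: AUC vs brute-force concordant-pair counting (n ≤ 20);
  GLM t vs an explicit normal-equations solve (50 subjects × 100 vertices,
  1e-10); connected components vs BFS flood fill (order-4, 2,562 vertices);
  BH vs the step-up definition.
- Error control: 200 no-effect cohorts on order-3 meshes; the family-wise
  rate of any surviving cluster at nominal 0.05 must stay ≤ 0.08 (binomial
  band); signature evaluation of arbitrary masks on a null cohort must show
  (essentially) no FDR-significant rows.
- Parameter recovery: 25 default cohorts (order-4, full group sizes,
  n_perm = 999); median Dice between the selected CS− vs IMP+ signature and
  the true patch mask ≥ 0.5, and mean in-patch adjusted deltas within 2 SE
  of the configured 0.30/0.375 mm.
- Closed form: empirical AUC of two unit-variance Gaussians at d = 1.2 and
  1.0 within 3 SE of Φ(d/√2) ≈ 0.802 and 0.760.
- Geometry and formats: exact icosphere counts for k = 0..7, exact
  163,842 → 2,562 downsampling, 1e-9 area conservation, bit-exact
  curv/label/GIFTI round trips (including cross-reads with nibabel).

These sizes keep the full suite at roughly two to three minutes on one CPU.

## Known limitations

- Smoothing FWHM granularity is limited on coarse meshes; order-3 meshes
  (mean edge ≈ 15 mm) cannot realize a 10 mm kernel at all.
- Graph-geodesic (Dijkstra) distances overestimate true geodesics by up to
  ~15% anisotropically, which inflates small geodesic discs relative to
  large ones; patch-area ratios converge to their configured values only as
  the mesh refines.
- The permutation null resolution bounds attainable cluster p-values at
  1/(n_perm + 1).
- DSAD-vs-ADAD comparisons here are synthetic scenarios with configured
  geometry; printed overlap statistics characterize the scenario, not the
  restricted clinical datasets.
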