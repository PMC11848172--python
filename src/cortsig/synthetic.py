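"""Synthetic cohorts with the demographic and spatial-effect structure of a
Down-syndrome AD staging study.

The generator emulates three disease-stage groups — cognitively stable
amyloid-negative (CS-), preclinical (CS+), and impaired amyloid-positive
(IMP+) — with group sizes 106/45/27 and group-wise age, centiloid, sex and
APOE e4 distributions matching the study population the pipeline targets.
Thickness maps are smooth spatially correlated fields on shared left/right
icosphere meshes, with focal effect patches (parietal/temporal-like
locations, a 1.25x rightward asymmetry) thinned per group, and an age slope.
Subcortical volumes follow region-specific stagewise trajectories
(hippocampus declining monotonically, accumbens shifting early, putamen
late) and scale with intracranial volume.  Ground-truth patch masks are
retained on the cohort so downstream recovery can be scored.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import staging
from .surface import SurfaceMesh, build_icosphere, geodesic_disc, smooth_values

__all__ = [
    "EffectPatch",
    "RegionParams",
    "CohortConfig",
    "Subject",
    "Cohort",
    "generate_cohort",
    "generate_variant_pair",
    "adad_like_config",
    "true_thinning_mask",
]

GROUPS = ("CS-", "CS+", "IMP+")
REGIONS = ("hippocampus", "amygdala", "accumbens", "caudate", "putamen", "pallidum", "thalamus")
SIDES = ("left", "right")


@dataclass(frozen=True)
class EffectPatch:
    """A geodesic disc of group-dependent cortical thinning.

    ``center_direction`` locates the patch as the vertex maximizing the dot
    product with the given 3-vector (stable across mesh orders); an explicit
    ``center_vertex`` overrides it.  ``thinning`` maps group -> mean thinning
    in mm applied inside the disc.
    """

    hemisphere: str
    radius_mm: float
    thinning: dict
    center_direction: Optional[tuple] = None
    center_vertex: Optional[int] = None

    def resolve_center(self, mesh: SurfaceMesh) -> int:
        if self.center_vertex is not None:
            return int(self.center_vertex)
        if self.center_direction is None:
            raise ValueError("patch needs center_direction or center_vertex")
        d = np.asarray(self.center_direction, dtype=float)
        return int(np.argmax(mesh.vertex_coords @ d))


@dataclass(frozen=True)
class RegionParams:
    """Subcortical region volume model: mean/SD in mm^3 and per-group shifts."""

    mean_mm3: float
    sd_mm3: float
    shifts: dict  # group -> additive mean shift (mm^3); CS- implicitly 0


def _default_patches() -> tuple:
    # Parietal-like (superior-posterior) and temporal-like (lateral-inferior)
    # discs; right-hemisphere thinning is 1.25x the left (rightward asymmetry).
    parietal = (-0.2, -0.6, 0.75)
    temporal = (0.7, -0.1, -0.45)
    left = {"CS+": 0.10, "IMP+": 0.30}
    right = {g: 1.25 * v for g, v in left.items()}
    return (
        EffectPatch("left", 25.0, dict(left), center_direction=parietal),
        EffectPatch("left", 18.0, dict(left), center_direction=temporal),
        EffectPatch("right", 25.0, dict(right), center_direction=parietal),
        EffectPatch("right", 18.0, dict(right), center_direction=temporal),
    )


def _default_regions() -> dict:
    return {
        "hippocampus": RegionParams(3500.0, 280.0, {"CS+": -250.0, "IMP+": -700.0}),
        "amygdala": RegionParams(1500.0, 130.0, {"CS+": -100.0, "IMP+": -220.0}),
        "accumbens": RegionParams(520.0, 60.0, {"CS+": -70.0, "IMP+": -80.0}),
        "caudate": RegionParams(3400.0, 300.0, {"CS+": 0.0, "IMP+": -120.0}),
        "putamen": RegionParams(4500.0, 380.0, {"CS+": -60.0, "IMP+": -560.0}),
        "pallidum": RegionParams(1550.0, 140.0, {"CS+": 0.0, "IMP+": -80.0}),
        "thalamus": RegionParams(7000.0, 550.0, {"CS+": -80.0, "IMP+": -300.0}),
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; defaults reproduce the target
    study's demographics table."""

    group_sizes: dict = field(default_factory=lambda: {"CS-": 106, "CS+": 45, "IMP+": 27})
    age_mean: dict = field(default_factory=lambda: {"CS-": 36.20, "CS+": 48.91, "IMP+": 51.93})
    age_sd: dict = field(default_factory=lambda: {"CS-": 6.20, "CS+": 6.18, "IMP+": 4.33})
    male_fraction: dict = field(
        default_factory=lambda: {"CS-": 54 / 106, "CS+": 28 / 45, "IMP+": 19 / 27}
    )
    apoe_fraction: dict = field(
        default_factory=lambda: {"CS-": 22 / 106, "CS+": 6 / 45, "IMP+": 8 / 27}
    )
    centiloid_mean: dict = field(
        default_factory=lambda: {"CS-": 1.05, "CS+": 51.96, "IMP+": 76.37}
    )
    centiloid_sd: dict = field(
        default_factory=lambda: {"CS-": 7.42, "CS+": 23.82, "IMP+": 35.32}
    )
    pib_fraction: float = 115 / 178  # PiB vs florbetapir tracer mix
    mci_fraction_impaired: float = 15 / 27  # MCI-DS vs DEM split inside IMP+

    mesh_order: int = 4
    baseline_thickness_mm: float = 2.5
    noise_sd_mm: float = 0.25
    noise_fwhm_mm: float = 20.0
    age_slope_mm_per_year: float = -0.005
    patches: tuple = field(default_factory=_default_patches)
    min_thickness_mm: float = 0.5

    regions: dict = field(default_factory=_default_regions)
    icv_mean_mm3: float = 1.2e6
    icv_sd_mm3: float = 1.1e5
    icv_elasticity: float = 0.8  # relative volume change per relative ICV change

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"negative group size for {g}")
        for d in (self.age_sd, self.centiloid_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("SDs must be >= 0")
        for d in (self.male_fraction, self.apoe_fraction):
            if any(not 0 <= v <= 1 for v in d.values()):
                raise ValueError("fractions must lie in [0, 1]")
        for p in self.patches:
            if p.radius_mm <= 0:
                raise ValueError("patch radii must be positive")


@dataclass
class Subject:
    id: str
    group: str
    clinical_status: str
    age: float
    sex: str  # 'M'/'F'
    apoe_e4: bool
    tracer: str
    centiloid: float
    thickness: dict = field(default_factory=dict)  # hemisphere -> (V,) array
    volumes: dict = field(default_factory=dict)  # (region, side) -> mm^3
    icv: float = float("nan")
    stage: str = ""
    split: Optional[str] = None


@dataclass
class Cohort:
    subjects: list
    meshes: dict  # hemisphere -> SurfaceMesh
    truth_masks: dict  # hemisphere -> bool array (true thinning >= 0.2 mm at IMP+)
    config: CohortConfig

    def select(self, stage: Optional[str] = None, split: Optional[str] = None) -> list:
        out = []
        for s in self.subjects:
            if stage is not None and s.stage != stage:
                continue
            if split is not None and s.split != split:
                continue
            out.append(s)
        return out

    def thickness_matrix(self, hemisphere: str, subjects: Optional[Sequence] = None) -> np.ndarray:
        subjects = self.subjects if subjects is None else subjects
        return np.stack([s.thickness[hemisphere] for s in subjects])

    def subject_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "apoe_e4": [int(s.apoe_e4) for s in self.subjects],
                "clinical_status": [s.clinical_status for s in self.subjects],
                "tracer": [s.tracer for s in self.subjects],
                "centiloid": [s.centiloid for s in self.subjects],
                "stage": [s.stage for s in self.subjects],
                "split": [s.split if s.split else "" for s in self.subjects],
            }
        )

    def volume_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for (region, side), vol in s.volumes.items():
                rows.append((s.id, region, side, vol, s.icv, s.stage))
        return pd.DataFrame(
            rows, columns=["subject_id", "region", "side", "volume_mm3", "icv_mm3", "stage"]
        )

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for s in self.subjects:
            h.update(s.id.encode())
            h.update(np.float64([s.age, s.centiloid, s.icv]).tobytes())
            h.update(s.sex.encode() + s.tracer.encode() + s.stage.encode())
            for hemi in sorted(s.thickness):
                h.update(np.asarray(s.thickness[hemi]).tobytes())
            for key in sorted(s.volumes):
                h.update(np.float64(s.volumes[key]).tobytes())
        return h.hexdigest()


def _exact_count_flags(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean vector with round(n*fraction) True entries, randomly placed."""
    k = int(round(n * fraction))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def _truncated_centiloids(
    n: int, mean: float, sd: float, bound: np.ndarray, below: bool, rng: np.random.Generator
) -> np.ndarray:
    """Per-subject truncated normals: below the (tracer-specific) positivity
    bound for amyloid-negative groups, at/above it otherwise."""
    out = np.empty(n)
    for i in range(n):
        if sd == 0:
            out[i] = mean
            continue
        if below:
            a, b = -np.inf, (bound[i] - mean) / sd
        else:
            a, b = (bound[i] - mean) / sd, np.inf
        out[i] = truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    return out


def sample_demographics(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the demographic table only (no imaging), group by group.

    Sex, APOE and tracer use exact rounded counts per group (shuffled), so a
    default cohort reproduces the target composition; age is Gaussian and
    centiloid a tracer-threshold-truncated Gaussian consistent with each
    group's amyloid status.
    """
    frames = []
    offset = 0
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        if n == 0:
            continue
        ages = rng.normal(config.age_mean[group], config.age_sd[group], size=n)
        male = _exact_count_flags(n, config.male_fraction[group], rng)
        apoe = _exact_count_flags(n, config.apoe_fraction[group], rng)
        pib = _exact_count_flags(n, config.pib_fraction, rng)
        tracer = np.where(pib, "PiB", "florbetapir")
        bounds = np.where(
            pib, staging.PIB_CENTILOID_THRESHOLD, staging.FLORBETAPIR_CENTILOID_THRESHOLD
        ).astype(float)
        centiloid = _truncated_centiloids(
            n,
            config.centiloid_mean[group],
            config.centiloid_sd[group],
            bounds,
            below=(group == "CS-"),
            rng=rng,
        )
        if group == "IMP+":
            mci = _exact_count_flags(n, config.mci_fraction_impaired, rng)
            clinical = np.where(mci, "MCI-DS", "DEM")
        else:
            clinical = np.full(n, "CS")
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"sub-{offset + i + 1:04d}" for i in range(n)],
                    "group": group,
                    "clinical_status": clinical,
                    "age": ages,
                    "sex": np.where(male, "M", "F"),
                    "apoe_e4": apoe,
                    "tracer": tracer,
                    "centiloid": centiloid,
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)


def patch_masks(config: CohortConfig, meshes: dict) -> list:
    """Resolved (patch, hemisphere, bool mask) triples on the given meshes."""
    resolved = []
    for patch in config.patches:
        mesh = meshes[patch.hemisphere]
        center = patch.resolve_center(mesh)
        resolved.append((patch, patch.hemisphere, geodesic_disc(mesh, center, patch.radius_mm)))
    return resolved


def true_thinning_mask(
    config: CohortConfig, meshes: dict, group: str = "IMP+", threshold_mm: float = 0.2
) -> dict:
    """Ground-truth mask of vertices whose configured thinning for ``group``
    (relative to CS-) meets the threshold; the reference for recovery tests."""
    masks = {h: np.zeros(m.n_vertices, dtype=bool) for h, m in meshes.items()}
    for patch, hemi, mask in patch_masks(config, meshes):
        if patch.thinning.get(group, 0.0) >= threshold_mm:
            masks[hemi] |= mask
    return masks


def _smooth_noise(
    mesh: SurfaceMesh, n: int, sd: float, fwhm: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, V) spatially correlated Gaussian fields with pointwise SD ~ sd."""
    white = rng.standard_normal((n, mesh.n_vertices))
    if sd == 0:
        return np.zeros_like(white)
    smoothed = smooth_values(mesh, white, fwhm)
    scale = sd / smoothed.std()
    return smoothed * scale


def generate_cohort(config: Optional[CohortConfig] = None, seed: int = 0) -> Cohort:
    """Generate a full synthetic cohort; deterministic given (config, seed)."""
    config = config if config is not None else CohortConfig()
    rng = np.random.default_rng(seed)
    demo = sample_demographics(config, rng)
    n_total = len(demo)
    meshes = {h: build_icosphere(config.mesh_order, hemisphere=h) for h in SIDES}
    resolved_patches = patch_masks(config, meshes)

    subjects = []
    for row in demo.itertuples(index=False):
        amyloid = staging.classify_amyloid(row.tracer, row.centiloid)
        label = staging.assign_stage(amyloid, row.clinical_status)
        subjects.append(
            Subject(
                id=row.id,
                group=row.group,
                clinical_status=row.clinical_status,
                age=float(row.age),
                sex=row.sex,
                apoe_e4=bool(row.apoe_e4),
                tracer=row.tracer,
                centiloid=float(row.centiloid),
                stage=label.value,
            )
        )

    ages = demo["age"].to_numpy()
    mean_age = float(ages.mean())
    age_term = config.age_slope_mm_per_year * (ages - mean_age)

    n_clipped = 0
    for hemi in SIDES:
        mesh = meshes[hemi]
        thick = config.baseline_thickness_mm + _smooth_noise(
            mesh, n_total, config.noise_sd_mm, config.noise_fwhm_mm, rng
        )
        thick += age_term[:, None]
        for patch, p_hemi, mask in resolved_patches:
            if p_hemi != hemi:
                continue
            for i, s in enumerate(subjects):
                depth = patch.thinning.get(s.group, 0.0)
                if depth:
                    thick[i, mask] -= depth
        clipped = thick < config.min_thickness_mm
        n_clipped += int(clipped.sum())
        np.clip(thick, config.min_thickness_mm, None, out=thick)
        for i, s in enumerate(subjects):
            s.thickness[hemi] = thick[i]
    if n_clipped:
        warnings.warn(
            f"{n_clipped} thickness draws truncated at {config.min_thickness_mm} mm",
            RuntimeWarning,
            stacklevel=2,
        )

    icvs = rng.normal(config.icv_mean_mm3, config.icv_sd_mm3, size=n_total)
    icvs = np.clip(icvs, 0.5 * config.icv_mean_mm3, None)
    for i, s in enumerate(subjects):
        s.icv = float(icvs[i])
        rel_icv = (s.icv - config.icv_mean_mm3) / config.icv_mean_mm3
        for region, params in config.regions.items():
            for side in SIDES:
                vol = (
                    params.mean_mm3
                    + params.shifts.get(s.group, 0.0)
                    + config.icv_elasticity * params.mean_mm3 * rel_icv
                    + rng.normal(0.0, params.sd_mm3)
                )
                s.volumes[(region, side)] = float(max(vol, 1.0))

    return Cohort(
        subjects=subjects,
        meshes=meshes,
        truth_masks=true_thinning_mask(config, meshes),
        config=config,
    )


def adad_like_config(base: Optional[CohortConfig] = None, area_ratio: float = 6.0) -> CohortConfig:
    """Variant configuration standing in for autosomal-dominant AD maps:
    same patch centers but ``1/area_ratio`` of the patch area and no
    hemispheric asymmetry (left-level thinning bilaterally)."""
    base = base if base is not None else CohortConfig()
    radius_scale = 1.0 / np.sqrt(area_ratio)
    left_thinning = {}
    for p in base.patches:
        if p.hemisphere == "left":
            left_thinning[p.radius_mm] = dict(p.thinning)
    new_patches = tuple(
        EffectPatch(
            hemisphere=p.hemisphere,
            radius_mm=p.radius_mm * radius_scale,
            thinning=dict(left_thinning.get(p.radius_mm, p.thinning)),
            center_direction=p.center_direction,
            center_vertex=p.center_vertex,
        )
        for p in base.patches
    )
    cfg_dict = asdict(base)
    cfg_dict["patches"] = new_patches
    cfg_dict["regions"] = dict(base.regions)
    return CohortConfig(**cfg_dict)


def generate_variant_pair(
    config_a: Optional[CohortConfig] = None,
    config_b: Optional[CohortConfig] = None,
    seed: int = 0,
):
    """Two cohorts whose true effect patches differ in extent and symmetry,
    standing in for a DSAD-vs-ADAD cross-variant comparison.  Ground-truth
    masks stay attached so derived-map overlap can be scored against the
    analytic overlap of the configured patches."""
    config_a = config_a if config_a is not None else CohortConfig()
    config_b = config_b if config_b is not None else adad_like_config(config_a)
    if config_a.mesh_order != config_b.mesh_order:
        raise ValueError("variant configs must share the same mesh order")
    cohort_a = generate_cohort(config_a, seed=seed)
    cohort_b = generate_cohort(config_b, seed=seed + 1)
    return cohort_a, cohort_b
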