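"""End-to-end orchestration: cohort -> staging/split -> smoothing -> GLMs ->
candidate derivation -> signature evaluation/selection -> subcortical
staging -> optional cross-variant map comparison -> report bundle.

Every stage logs its seed and parameters; the report JSON is deterministic
for a fixed configuration and seed.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import cohort_io, io as fio
from .glm import effect_size_map, fit_vertex_glm
from .overlap import summarize_overlap
from .signatures import (
    DEFAULT_COMPARISONS,
    DEFAULT_VERTEX_P_GRID,
    candidate_roc,
    compare_effect_domains,
    derive_candidates,
    evaluate_signatures,
    select_ideal_signature,
)
from .staging import split_reference
from .subcortical import icv_correct, region_staging_table
from .surface import smooth_values, mean_edge_length
from .synthetic import CohortConfig, generate_cohort, generate_variant_pair
from .overlap import dice as dice_coefficient, thinning_mask

logger = logging.getLogger("cortsig.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; round-trips losslessly through YAML."""

    cohort_dir: Optional[str] = None  # load a cohort instead of simulating
    cohort: CohortConfig = field(default_factory=CohortConfig)
    smoothing_fwhm_mm: float = 10.0
    vertex_p_grid: tuple = DEFAULT_VERTEX_P_GRID
    cluster_p: float = 0.001
    n_perm: int = 1000
    withheld_fraction: float = 0.2
    thinning_threshold_mm: float = 0.2
    compare_variants: bool = False
    seed: int = 0
    output_dir: str = "cortsig_output"

    def __post_init__(self):
        if self.smoothing_fwhm_mm <= 0 or self.cluster_p <= 0 or self.thinning_threshold_mm <= 0:
            raise ValueError("thresholds must be positive")
        if not self.vertex_p_grid:
            raise ValueError("vertex p grid must be nonempty")
        self.vertex_p_grid = tuple(float(p) for p in self.vertex_p_grid)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["vertex_p_grid"] = list(self.vertex_p_grid)
        coh = d["cohort"]
        coh["patches"] = [
            {
                "hemisphere": p.hemisphere,
                "radius_mm": p.radius_mm,
                "thinning": dict(p.thinning),
                "center_direction": list(p.center_direction) if p.center_direction else None,
                "center_vertex": p.center_vertex,
            }
            for p in self.cohort.patches
        ]
        coh["regions"] = {
            name: {"mean_mm3": r.mean_mm3, "sd_mm3": r.sd_mm3, "shifts": dict(r.shifts)}
            for name, r in self.cohort.regions.items()
        }
        fio.save_yaml(d, path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        from .synthetic import EffectPatch, RegionParams

        d = fio.load_yaml(path)
        coh = d.pop("cohort", {})
        patches = tuple(
            EffectPatch(
                hemisphere=p["hemisphere"],
                radius_mm=p["radius_mm"],
                thinning=dict(p["thinning"]),
                center_direction=tuple(p["center_direction"]) if p.get("center_direction") else None,
                center_vertex=p.get("center_vertex"),
            )
            for p in coh.pop("patches", [])
        ) or None
        regions = {
            name: RegionParams(r["mean_mm3"], r["sd_mm3"], dict(r["shifts"]))
            for name, r in coh.pop("regions", {}).items()
        } or None
        kwargs = dict(coh)
        if patches is not None:
            kwargs["patches"] = patches
        if regions is not None:
            kwargs["regions"] = regions
        d["cohort"] = CohortConfig(**kwargs)
        d["vertex_p_grid"] = tuple(d.get("vertex_p_grid", DEFAULT_VERTEX_P_GRID))
        return cls(**d)


def _stage(name):
    logger.info("stage: %s", name)
    return name


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> dict:
    """Execute all stages; returns the machine-readable report dict.

    Stage failures propagate as exceptions whose message names the stage.
    """
    report = {"seed": config.seed, "stages": []}
    out_dir = Path(config.output_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)

    stage = "cohort"
    try:
        report["stages"].append(_stage(stage))
        if config.cohort_dir:
            cohort = cohort_io.read_cohort(config.cohort_dir)
        else:
            cohort = generate_cohort(config.cohort, seed=config.seed)
        report["cohort"] = {
            "n_subjects": len(cohort.subjects),
            "stage_counts": {
                st: len(cohort.select(stage=st)) for st in ("CS-", "CS+", "IMP+")
            },
        }

        stage = "staging_split"
        report["stages"].append(_stage(stage))
        derivation, withheld, balance = split_reference(
            cohort, group="CS-", fraction=1.0 - config.withheld_fraction, seed=config.seed + 1
        )
        report["split"] = {
            "n_derivation": len(derivation),
            "n_withheld": len(withheld),
            "balance": {
                row.variable: round(float(row.p_value), 6) for row in balance.itertuples()
            },
        }

        stage = "smoothing"
        report["stages"].append(_stage(stage))
        for hemi, mesh in cohort.meshes.items():
            if config.smoothing_fwhm_mm < mean_edge_length(mesh):
                warnings.warn(
                    f"smoothing FWHM {config.smoothing_fwhm_mm} mm below mean edge "
                    f"length of {hemi} mesh; maps left unsmoothed",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            y = cohort.thickness_matrix(hemi)
            y = smooth_values(mesh, y, config.smoothing_fwhm_mm)
            for i, s in enumerate(cohort.subjects):
                s.thickness[hemi] = y[i]
        report["smoothing_fwhm_mm"] = config.smoothing_fwhm_mm

        stage = "glm"
        report["stages"].append(_stage(stage))
        glm_results = {}
        report["glm"] = {}
        for comp in DEFAULT_COMPARISONS:
            res = fit_vertex_glm(cohort, comp)
            glm_results[comp] = res
            key = f"{comp[0]}_vs_{comp[1]}"
            report["glm"][key] = {
                "n_reference": res.n_reference,
                "n_advanced": res.n_advanced,
                "covariates": list(res.covariates),
                "max_abs_t": {
                    h: round(float(np.abs(m["t"]).max()), 4) for h, m in res.maps.items()
                },
            }

        stage = "derive_candidates"
        report["stages"].append(_stage(stage))
        all_candidates = []
        report["candidates"] = []
        for j, comp in enumerate(DEFAULT_COMPARISONS):
            cands = derive_candidates(
                cohort,
                comp,
                vertex_p_grid=config.vertex_p_grid,
                cluster_p=config.cluster_p,
                n_perm=config.n_perm,
                seed=config.seed + 100 + j,
            )
            all_candidates.extend(cands)
            for c in cands:
                report["candidates"].append(
                    {
                        "signature": c.label,
                        "n_vertices": c.n_vertices,
                        "area_mm2": round(c.area_mm2, 3),
                    }
                )

        stage = "evaluate_select"
        report["stages"].append(_stage(stage))
        evaluation = evaluate_signatures(all_candidates, cohort)
        report["evaluation"] = (
            evaluation.round(6).to_dict(orient="records") if len(evaluation) else []
        )
        report["selection"] = {}
        selected = {}
        for comp in DEFAULT_COMPARISONS:
            # candidates transfer across comparisons: a signature derived from
            # one contrast may classify another best
            mask, roc = select_ideal_signature(all_candidates, comp, cohort)
            key = f"{comp[0]}_vs_{comp[1]}"
            if mask is None:
                report["selection"][key] = None
            else:
                selected[comp] = (mask, roc)
                report["selection"][key] = {
                    "signature": mask.label,
                    "auc": round(roc.auc, 6),
                    "area_mm2": round(mask.area_mm2, 3),
                }

        stage = "subcortical"
        report["stages"].append(_stage(stage))
        vol_table = cohort.volume_table()
        adjusted, icv_model = icv_correct(vol_table)
        split_map = {s.id: s.split for s in cohort.subjects}
        staging_table = region_staging_table(
            adjusted, withheld_reference=True, split_by_subject=split_map
        )
        report["subcortical"] = staging_table.round(6).to_dict(orient="records")

        stage = "domain_comparison"
        report["stages"].append(_stage(stage))
        report["domain_comparison"] = {}
        if len(evaluation):
            for comp in DEFAULT_COMPARISONS:
                key = f"{comp[0]}_vs_{comp[1]}"
                cort = evaluation[evaluation["comparison"] == key]["cohens_d"].tolist()
                sub = staging_table[staging_table["comparison"] == key]["cohens_d"].tolist()
                if cort and len(sub) >= 2 and len(cort) >= 2:
                    report["domain_comparison"][key] = {
                        k: (round(v, 6) if isinstance(v, float) else v)
                        for k, v in compare_effect_domains(cort, sub).items()
                    }

        if config.compare_variants:
            stage = "map_comparison"
            report["stages"].append(_stage(stage))
            cohort_a, cohort_b = generate_variant_pair(
                config_a=config.cohort, seed=config.seed + 500
            )
            report["map_comparison"] = {}
            res_a = fit_vertex_glm(cohort_a, ("CS-", "IMP+"), use_derivation_split=False)
            res_b = fit_vertex_glm(cohort_b, ("CS-", "IMP+"), use_derivation_split=False)
            for hemi in cohort_a.meshes:
                summary = summarize_overlap(
                    effect_size_map(res_a, "delta_mm", hemi),
                    effect_size_map(res_b, "delta_mm", hemi),
                    cohort_a.meshes[hemi],
                    threshold_mm=config.thinning_threshold_mm,
                )
                report["map_comparison"][hemi] = {
                    k: (round(v, 6) if isinstance(v, float) else v)
                    for k, v in summary.to_dict().items()
                }

        stage = "report"
        report["stages"].append(_stage(stage))
        if write_outputs:
            evaluation.to_csv(out_dir / "signature_evaluation.csv", index=False)
            staging_table.to_csv(out_dir / "subcortical_staging.csv", index=False)
            icv_model.slopes.to_csv(out_dir / "icv_model.csv", index=False)
            for comp, (mask, roc) in selected.items():
                tag = f"{comp[0]}_vs_{comp[1]}".replace("-", "n").replace("+", "p")
                for hemi, m in mask.masks.items():
                    fio.mask_to_label(
                        out_dir / f"signature_{tag}.{hemi}.label", m, cohort.meshes[hemi]
                    )
                _write_roc_plot(out_dir / f"roc_{tag}.png", roc)
            with open(out_dir / "report.json", "w") as f:
                json.dump(report, f, indent=2, sort_keys=True)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    return report


def _write_roc_plot(path, roc) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(1.0 - roc.specificity, roc.sensitivity, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
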