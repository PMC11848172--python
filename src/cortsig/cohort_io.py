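"""Cohort round-trip to a directory of plain files.

Layout written by :func:`write_cohort`::

    <dir>/subjects.csv            id, demographics, stage, split
    <dir>/volumes.csv             subject_id, region, side, volume_mm3, icv_mm3, stage
    <dir>/surf/lh.sphere / rh.sphere        FreeSurfer binary geometry
    <dir>/thickness/<id>.<lh|rh>.curv       per-subject thickness maps
    <dir>/truth/<lh|rh>.truth.label         ground-truth patch masks (if any)
    <dir>/meta.yaml               mesh order and format metadata
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .surface import SurfaceMesh
from .synthetic import Cohort, CohortConfig, Subject

__all__ = ["write_cohort", "read_cohort"]

_HEMI_CODE = {"left": "lh", "right": "rh"}
_CODE_HEMI = {v: k for k, v in _HEMI_CODE.items()}


def write_cohort(cohort: Cohort, directory) -> Path:
    d = Path(directory)
    (d / "surf").mkdir(parents=True, exist_ok=True)
    (d / "thickness").mkdir(exist_ok=True)
    cohort.subject_table().to_csv(d / "subjects.csv", index=False)
    cohort.volume_table().to_csv(d / "volumes.csv", index=False)
    for hemi, mesh in cohort.meshes.items():
        fio.write_surface(d / "surf" / f"{_HEMI_CODE[hemi]}.sphere", mesh)
    for s in cohort.subjects:
        for hemi, values in s.thickness.items():
            fio.write_curv(d / "thickness" / f"{s.id}.{_HEMI_CODE[hemi]}.curv", values)
    if cohort.truth_masks:
        (d / "truth").mkdir(exist_ok=True)
        for hemi, mask in cohort.truth_masks.items():
            fio.mask_to_label(
                d / "truth" / f"{_HEMI_CODE[hemi]}.truth.label", mask, cohort.meshes[hemi]
            )
    orders = {h: m.subdivision_order for h, m in cohort.meshes.items()}
    fio.save_yaml({"mesh_order": orders, "format": "cortsig-cohort-v1"}, d / "meta.yaml")
    return d


def read_cohort(directory) -> Cohort:
    d = Path(directory)
    meta = fio.load_yaml(d / "meta.yaml")
    subjects_df = pd.read_csv(d / "subjects.csv", keep_default_na=False)
    volumes_df = pd.read_csv(d / "volumes.csv")
    meshes = {}
    for code, hemi in _CODE_HEMI.items():
        p = d / "surf" / f"{code}.sphere"
        if p.exists():
            mesh = fio.read_surface(p, hemisphere=hemi)
            mesh.subdivision_order = (meta.get("mesh_order") or {}).get(hemi)
            meshes[hemi] = mesh
    subjects = []
    for row in subjects_df.itertuples(index=False):
        s = Subject(
            id=row.id,
            group=row.stage,
            clinical_status=row.clinical_status,
            age=float(row.age),
            sex=row.sex,
            apoe_e4=bool(int(row.apoe_e4)),
            tracer=row.tracer,
            centiloid=float(row.centiloid),
            stage=row.stage,
            split=row.split if row.split else None,
        )
        for hemi in meshes:
            p = d / "thickness" / f"{s.id}.{_HEMI_CODE[hemi]}.curv"
            if p.exists():
                s.thickness[hemi] = fio.read_curv(p, expected_n=meshes[hemi].n_vertices)
        subjects.append(s)
    icv_by_subject = volumes_df.drop_duplicates("subject_id").set_index("subject_id")["icv_mm3"]
    for s in subjects:
        if s.id in icv_by_subject.index:
            s.icv = float(icv_by_subject[s.id])
    by_id = {s.id: s for s in subjects}
    for row in volumes_df.itertuples(index=False):
        if row.subject_id in by_id:
            by_id[row.subject_id].volumes[(row.region, row.side)] = float(row.volume_mm3)
    truth = {}
    for code, hemi in _CODE_HEMI.items():
        p = d / "truth" / f"{code}.truth.label"
        if p.exists() and hemi in meshes:
            truth[hemi] = fio.label_to_mask(p, meshes[hemi].n_vertices)
    return Cohort(subjects=subjects, meshes=meshes, truth_masks=truth, config=CohortConfig())
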