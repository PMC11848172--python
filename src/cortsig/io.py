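"""Surface-file adapters: FreeSurfer curv/label/binary surface and GIFTI.

The curv ("morph data") reader and writer handle the new-format dialect
only: 3-byte magic ``0xFFFFFF``, big-endian int32 triple header
(vertex count, face count, values per vertex) and big-endian float32 data.
Old-format two-byte-header files are rejected explicitly rather than
guessed at.  Truncated files raise instead of being zero-padded.
"""
from __future__ import annotations

import struct
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import yaml

from .surface import SurfaceMesh, VertexMap

__all__ = [
    "FormatError",
    "read_curv",
    "write_curv",
    "read_label",
    "write_label",
    "read_gifti_map",
    "write_gifti_map",
    "read_surface",
    "write_surface",
    "read_vertex_map",
    "write_vertex_map",
]

_CURV_MAGIC = b"\xff\xff\xff"


class FormatError(ValueError):
    """Raised for malformed, truncated or unsupported surface files."""


# ---------------------------------------------------------------------------
# FreeSurfer curv (morph data)


def write_curv(path, values: np.ndarray, n_faces: int = 0) -> None:
    values = np.asarray(values, dtype=">f4")
    if values.ndim != 1:
        raise ValueError("curv data must be 1-D")
    with open(path, "wb") as f:
        f.write(_CURV_MAGIC)
        f.write(struct.pack(">iii", values.shape[0], n_faces, 1))
        f.write(values.tobytes())


def read_curv(path, expected_n: Optional[int] = None) -> np.ndarray:
    with open(path, "rb") as f:
        magic = f.read(3)
        if magic != _CURV_MAGIC:
            raise FormatError(
                f"{path}: not a new-format curv file (magic {magic!r}); "
                "old-format curv files are not supported"
            )
        header = f.read(12)
        if len(header) < 12:
            raise FormatError(f"{path}: truncated curv header")
        vnum, _fnum, vals_per_vertex = struct.unpack(">iii", header)
        if vals_per_vertex != 1:
            raise FormatError(f"{path}: vals_per_vertex={vals_per_vertex} unsupported")
        data = np.frombuffer(f.read(), dtype=">f4")
    if data.shape[0] != vnum:
        raise FormatError(f"{path}: header promises {vnum} values, file holds {data.shape[0]}")
    if expected_n is not None and vnum != expected_n:
        raise FormatError(f"{path}: {vnum} values do not match mesh with {expected_n} vertices")
    return data.astype(np.float64)


# ---------------------------------------------------------------------------
# FreeSurfer label (ASCII vertex list)


def write_label(path, vertex_indices: np.ndarray, mesh: Optional[SurfaceMesh] = None) -> None:
    idx = np.asarray(vertex_indices, dtype=np.int64)
    coords = (
        mesh.vertex_coords[idx] if mesh is not None else np.zeros((idx.shape[0], 3))
    )
    with open(path, "w") as f:
        f.write("#!ascii label, written by cortsig\n")
        f.write(f"{idx.shape[0]}\n")
        for i, (x, y, z) in zip(idx, coords):
            f.write(f"{i} {x:.6f} {y:.6f} {z:.6f} 0.000000\n")


def read_label(path, expected_n: Optional[int] = None) -> np.ndarray:
    with open(path) as f:
        header = f.readline()
        if not header.startswith("#!ascii"):
            raise FormatError(f"{path}: missing label header")
        try:
            n = int(f.readline().strip())
        except ValueError as e:
            raise FormatError(f"{path}: bad vertex count line") from e
        idx = []
        for line in f:
            if line.strip():
                idx.append(int(line.split()[0]))
    if len(idx) != n:
        raise FormatError(f"{path}: label promises {n} vertices, file holds {len(idx)}")
    idx = np.array(sorted(idx), dtype=np.int64)
    if expected_n is not None and idx.size and idx.max() >= expected_n:
        raise FormatError(f"{path}: label vertex {idx.max()} outside mesh of {expected_n}")
    return idx


def mask_to_label(path, mask: np.ndarray, mesh: Optional[SurfaceMesh] = None) -> None:
    write_label(path, np.nonzero(np.asarray(mask, dtype=bool))[0], mesh)


def label_to_mask(path, n_vertices: int) -> np.ndarray:
    idx = read_label(path, expected_n=n_vertices)
    mask = np.zeros(n_vertices, dtype=bool)
    mask[idx] = True
    return mask


# ---------------------------------------------------------------------------
# GIFTI functional maps and surfaces (via nibabel)


def write_gifti_map(path, values: np.ndarray) -> None:
    darray = nib.gifti.GiftiDataArray(
        np.asarray(values, dtype=np.float32), intent="NIFTI_INTENT_SHAPE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[darray]), str(path))


def read_gifti_map(path, expected_n: Optional[int] = None) -> np.ndarray:
    img = nib.load(str(path))
    if not img.darrays:
        raise FormatError(f"{path}: GIFTI file holds no data arrays")
    data = img.darrays[0].data.astype(np.float64)
    if expected_n is not None and data.shape[0] != expected_n:
        raise FormatError(f"{path}: {data.shape[0]} values do not match {expected_n} vertices")
    return data


def write_surface(path, mesh: SurfaceMesh) -> None:
    """GIFTI (.gii) or FreeSurfer binary geometry, by extension."""
    path = str(path)
    if path.endswith(".gii"):
        pts = nib.gifti.GiftiDataArray(
            mesh.vertex_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
        )
        tri = nib.gifti.GiftiDataArray(
            mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
        )
        nib.save(nib.gifti.GiftiImage(darrays=[pts, tri]), path)
    else:
        nib.freesurfer.write_geometry(path, mesh.vertex_coords, mesh.faces)


def read_surface(path, hemisphere: str = "left") -> SurfaceMesh:
    path = str(path)
    if path.endswith(".gii"):
        img = nib.load(path)
        pts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")
        tri = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")
        if not pts or not tri:
            raise FormatError(f"{path}: GIFTI surface missing pointset/triangle arrays")
        return SurfaceMesh(pts[0].data, tri[0].data, hemisphere=hemisphere)
    coords, faces = nib.freesurfer.read_geometry(path)
    return SurfaceMesh(coords, faces, hemisphere=hemisphere)


# ---------------------------------------------------------------------------
# Unified vertex-map entry points


def write_vertex_map(vmap: VertexMap, path, fmt: Optional[str] = None) -> None:
    fmt = fmt or ("gifti" if str(path).endswith(".gii") else "curv")
    if fmt == "curv":
        write_curv(path, vmap.values)
    elif fmt == "gifti":
        write_gifti_map(path, vmap.values)
    else:
        raise ValueError(f"unknown vertex-map format {fmt!r}")


def read_vertex_map(path, expected_mesh: SurfaceMesh) -> VertexMap:
    if str(path).endswith(".gii"):
        values = read_gifti_map(path, expected_n=expected_mesh.n_vertices)
    else:
        values = read_curv(path, expected_n=expected_mesh.n_vertices)
    return VertexMap.for_mesh(expected_mesh, values)


# ---------------------------------------------------------------------------
# YAML helpers


def save_yaml(obj: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=True)


def load_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
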