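"""Triangulated-surface primitives for vertex-wise cortical analysis.

Everything downstream — smoothing, per-vertex statistics, cluster-level
correction, signature masks — operates on a :class:`SurfaceMesh` and scalar
:class:`VertexMap` objects bound to it.  Real FreeSurfer surfaces can be
loaded through :mod:`cortsig.io`; generated icospheres with nested vertex
ordering serve as a desk-scale stand-in for the fsaverage template (order 7
reproduces fsaverage's 163,842 vertices per hemisphere, order 4 the 2,562
vertices used for downsampled scatter comparisons).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _sp_connected_components
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "SurfaceMesh",
    "VertexMap",
    "Cluster",
    "ClusterTable",
    "build_icosphere",
    "vertex_adjacency",
    "adjacency_matrix",
    "vertex_areas",
    "smooth_map",
    "smooth_values",
    "connected_components",
    "downsample_map",
    "icosphere_order_from_count",
    "icosphere_vertex_count",
    "geodesic_disc",
]

MAX_ICOSPHERE_ORDER = 7
DEFAULT_RADIUS_MM = 100.0


def icosphere_vertex_count(order: int) -> int:
    """Closed icosphere of subdivision order k has 10*4**k + 2 vertices."""
    return 10 * 4**order + 2


def icosphere_order_from_count(n_vertices: int) -> int:
    """Inverse of :func:`icosphere_vertex_count`; raises for non-icosphere counts."""
    for k in range(MAX_ICOSPHERE_ORDER + 1):
        if icosphere_vertex_count(k) == n_vertices:
            return k
    raise ValueError(f"{n_vertices} vertices does not match any icosphere order 0..7")


@dataclass
class SurfaceMesh:
    """A triangulated hemisphere surface.

    Parameters
    ----------
    vertex_coords
        ``(V, 3)`` float array of positions in mm.
    faces
        ``(F, 3)`` integer array of counter-clockwise vertex triples.
    hemisphere
        ``"left"`` or ``"right"``.
    subdivision_order
        Set when the mesh is a generated icosphere with nested vertex
        ordering; ``None`` for imported surfaces.
    """

    vertex_coords: np.ndarray
    faces: np.ndarray
    hemisphere: str = "left"
    subdivision_order: Optional[int] = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if self.vertex_coords.ndim != 2 or self.vertex_coords.shape[1] != 3:
            raise ValueError("vertex_coords must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def mesh_id(self) -> str:
        order = f"ico{self.subdivision_order}" if self.subdivision_order is not None else "mesh"
        return f"{order}-{self.hemisphere}-{self.n_vertices}"

    def euler_characteristic(self) -> int:
        edges = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        return self.n_vertices - edges.shape[0] + self.n_faces

    def is_connected(self) -> bool:
        n_comp, _ = _sp_connected_components(adjacency_matrix(self), directed=False)
        return n_comp == 1


@dataclass
class VertexMap:
    """One scalar per mesh vertex (thickness mm, t statistic, p, Δmm, Cohen's d)."""

    values: np.ndarray
    mesh_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("VertexMap values must be 1-D")

    def __len__(self) -> int:
        return self.values.shape[0]

    def check_bound(self, mesh: SurfaceMesh) -> None:
        if len(self) != mesh.n_vertices:
            raise ValueError(
                f"map length {len(self)} does not match mesh with {mesh.n_vertices} vertices"
            )

    @classmethod
    def for_mesh(cls, mesh: SurfaceMesh, values: np.ndarray) -> "VertexMap":
        vm = cls(values=np.asarray(values, dtype=np.float64), mesh_id=mesh.mesh_id)
        vm.check_bound(mesh)
        return vm


@dataclass
class Cluster:
    """A connected suprathreshold vertex set with its surface area."""

    vertices: np.ndarray
    area_mm2: float
    peak_stat: Optional[float] = None
    p_value: Optional[float] = None


@dataclass
class ClusterTable:
    clusters: list

    def __len__(self) -> int:
        return len(self.clusters)

    def to_mask(self, n_vertices: int) -> np.ndarray:
        mask = np.zeros(n_vertices, dtype=bool)
        for c in self.clusters:
            mask[c.vertices] = True
        return mask


# ---------------------------------------------------------------------------
# Icosphere construction

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=np.float64,
)

_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def _subdivide(vertices: np.ndarray, faces: np.ndarray, radius: float):
    """One 1-to-4 subdivision; new midpoint vertices are appended after the
    parents, which keeps the vertex ordering nested across orders."""
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    unique_edges, inverse = np.unique(edges, axis=0, return_inverse=True)
    midpoints = vertices[unique_edges[:, 0]] + vertices[unique_edges[:, 1]]
    midpoints *= radius / np.linalg.norm(midpoints, axis=1, keepdims=True)
    mid_index = vertices.shape[0] + np.arange(unique_edges.shape[0])

    n_faces = faces.shape[0]
    m01 = mid_index[inverse[:n_faces]]
    m12 = mid_index[inverse[n_faces : 2 * n_faces]]
    m20 = mid_index[inverse[2 * n_faces :]]
    v0, v1, v2 = faces[:, 0], faces[:, 1], faces[:, 2]
    new_faces = np.vstack(
        [
            np.column_stack([v0, m01, m20]),
            np.column_stack([v1, m12, m01]),
            np.column_stack([v2, m20, m12]),
            np.column_stack([m01, m12, m20]),
        ]
    )
    return np.vstack([vertices, midpoints]), new_faces


def build_icosphere(
    order: int, hemisphere: str = "left", radius: float = DEFAULT_RADIUS_MM
) -> SurfaceMesh:
    """Icosahedron subdivided ``order`` times and projected to a sphere.

    Vertex ordering is nested: the vertices of order ``k`` are exactly the
    first ``10*4**k + 2`` vertices of order ``k+1``, so downsampling a vertex
    map is a prefix slice (:func:`downsample_map`).
    """
    if not isinstance(order, (int, np.integer)) or order < 0:
        raise ValueError("order must be a non-negative integer")
    if order > MAX_ICOSPHERE_ORDER:
        raise ValueError(
            f"order {order} exceeds the supported maximum {MAX_ICOSPHERE_ORDER} (memory guard)"
        )
    vertices = _ICO_VERTS * (radius / np.linalg.norm(_ICO_VERTS[0]))
    faces = _ICO_FACES.copy()
    for _ in range(order):
        vertices, faces = _subdivide(vertices, faces, radius)
    return SurfaceMesh(vertices, faces, hemisphere=hemisphere, subdivision_order=order)


# ---------------------------------------------------------------------------
# Adjacency and areas


def adjacency_matrix(mesh: SurfaceMesh) -> sparse.csr_matrix:
    """Symmetric sparse vertex-adjacency (1 where vertices share a face edge)."""
    if "adjacency" in mesh._cache:
        return mesh._cache["adjacency"]
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
    data = np.ones(rows.shape[0], dtype=np.float64)
    a = sparse.csr_matrix((data, (rows, cols)), shape=(mesh.n_vertices, mesh.n_vertices))
    a.data[:] = 1.0  # collapse duplicate edge entries
    mesh._cache["adjacency"] = a
    return a


def vertex_adjacency(mesh: SurfaceMesh) -> list:
    """Per-vertex sorted neighbor index arrays."""
    a = adjacency_matrix(mesh)
    return [a.indices[a.indptr[i] : a.indptr[i + 1]].copy() for i in range(mesh.n_vertices)]


def _face_areas(mesh: SurfaceMesh) -> np.ndarray:
    v = mesh.vertex_coords
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def vertex_areas(mesh: SurfaceMesh) -> VertexMap:
    """Per-vertex surface area: one third of each incident triangle's area.

    The vertex areas therefore sum exactly to the total mesh surface area,
    which is what cluster areas and area-weighted signature means rely on.
    """
    if "vertex_areas" in mesh._cache:
        return mesh._cache["vertex_areas"]
    fa = _face_areas(mesh)
    if np.any(fa == 0.0):
        warnings.warn(
            f"{int((fa == 0).sum())} degenerate zero-area faces", RuntimeWarning, stacklevel=2
        )
    areas = np.zeros(mesh.n_vertices)
    third = fa / 3.0
    for k in range(3):
        np.add.at(areas, mesh.faces[:, k], third)
    vm = VertexMap.for_mesh(mesh, areas)
    mesh._cache["vertex_areas"] = vm
    return vm


def total_area(mesh: SurfaceMesh) -> float:
    return float(_face_areas(mesh).sum())


def _edge_lengths(mesh: SurfaceMesh) -> np.ndarray:
    f = mesh.faces
    edges = np.unique(
        np.sort(np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1), axis=0
    )
    d = mesh.vertex_coords[edges[:, 0]] - mesh.vertex_coords[edges[:, 1]]
    return np.linalg.norm(d, axis=1)


def mean_edge_length(mesh: SurfaceMesh) -> float:
    if "mean_edge" not in mesh._cache:
        mesh._cache["mean_edge"] = float(_edge_lengths(mesh).mean())
    return mesh._cache["mean_edge"]


def _distance_graph(mesh: SurfaceMesh) -> sparse.csr_matrix:
    """Edge graph weighted by Euclidean edge length (geodesic approximation)."""
    if "distance_graph" in mesh._cache:
        return mesh._cache["distance_graph"]
    a = adjacency_matrix(mesh).tocoo()
    d = np.linalg.norm(mesh.vertex_coords[a.row] - mesh.vertex_coords[a.col], axis=1)
    g = sparse.csr_matrix((d, (a.row, a.col)), shape=a.shape)
    mesh._cache["distance_graph"] = g
    return g


def geodesic_distances(mesh: SurfaceMesh, source: int) -> np.ndarray:
    """Graph-geodesic distance (mm) from ``source`` to every vertex."""
    return dijkstra(_distance_graph(mesh), directed=False, indices=source)


def geodesic_disc(mesh: SurfaceMesh, center: int, radius_mm: float) -> np.ndarray:
    """Boolean mask of vertices within graph-geodesic ``radius_mm`` of ``center``."""
    return geodesic_distances(mesh, center) <= radius_mm


# ---------------------------------------------------------------------------
# Smoothing

_MAX_SMOOTH_ITER = 400


def _averaging_operator(mesh: SurfaceMesh) -> sparse.csr_matrix:
    """Row-stochastic self-inclusive neighbor averaging with unit (symmetric)
    edge weights: x_i <- (x_i + sum_{j~i} x_j) / (1 + deg_i)."""
    if "averaging_operator" in mesh._cache:
        return mesh._cache["averaging_operator"]
    a = adjacency_matrix(mesh) + sparse.identity(mesh.n_vertices, format="csr")
    inv_deg = 1.0 / np.asarray(a.sum(axis=1)).ravel()
    w = sparse.diags(inv_deg) @ a
    w = w.tocsr()
    mesh._cache["averaging_operator"] = w
    return w


def _profile_fwhm(distances: np.ndarray, values: np.ndarray) -> float:
    """Empirical FWHM of a radially decaying kernel profile around its peak."""
    order = np.argsort(distances)
    d = distances[order]
    v = values[order]
    peak = v[0]
    if peak <= 0:
        return 0.0
    half = peak / 2.0
    below = np.nonzero(v < half)[0]
    if below.size == 0:
        return float(2.0 * d[-1])  # kernel wider than the mesh
    i = below[0]
    if i == 0:
        return 0.0
    j = i - 1
    denom = v[j] - v[i]
    frac = 0.5 if denom <= 0 else (v[j] - half) / denom
    r_half = d[j] + frac * (d[i] - d[j])
    return float(2.0 * r_half)


def _calibrate_smoother(mesh: SurfaceMesh, fwhm_mm: float):
    """Choose (iterations, relaxation) so a unit spike spreads to the requested
    FWHM, measured against graph-geodesic distance.  Cached per mesh."""
    key = ("smoother", round(float(fwhm_mm), 6))
    if key in mesh._cache:
        return mesh._cache[key]
    w = _averaging_operator(mesh)
    degrees = np.diff(adjacency_matrix(mesh).indptr)
    hexa = np.nonzero(degrees == 6)[0]
    center = int(hexa[0]) if hexa.size else 0
    dist = geodesic_distances(mesh, center)

    best = (1, 1.0, np.inf)  # (n_iter, lam, measured)
    for lam in (1.0, 0.5, 0.25, 0.125):
        x = np.zeros(mesh.n_vertices)
        x[center] = 1.0
        prev_f = 0.0
        for n in range(1, _MAX_SMOOTH_ITER + 1):
            x = lam * (w @ x) + (1.0 - lam) * x
            f = _profile_fwhm(dist, x)
            if f >= fwhm_mm:
                if n > 1 and abs(prev_f - fwhm_mm) < abs(f - fwhm_mm):
                    cand = (n - 1, lam, prev_f)
                else:
                    cand = (n, lam, f)
                if abs(cand[2] - fwhm_mm) < abs(best[2] - fwhm_mm):
                    best = cand
                break
            prev_f = f
        if np.isfinite(best[2]) and abs(best[2] - fwhm_mm) / fwhm_mm <= 0.2:
            break
    if not np.isfinite(best[2]):
        best = (_MAX_SMOOTH_ITER, 1.0, prev_f)
    if abs(best[2] - fwhm_mm) / fwhm_mm > 0.2:
        warnings.warn(
            f"smoothing calibration reached FWHM {best[2]:.1f} mm for requested "
            f"{fwhm_mm:.1f} mm (outside 20%)",
            RuntimeWarning,
            stacklevel=2,
        )
    mesh._cache[key] = best
    return best


def smooth_values(mesh: SurfaceMesh, values: np.ndarray, fwhm_mm: float) -> np.ndarray:
    """Surface-smooth raw arrays; rows of a 2-D array are smoothed independently.

    Iterated self-inclusive neighbor averaging with the iteration count (and a
    relaxation factor for sub-iteration granularity) calibrated so a spike
    spreads to ``fwhm_mm``.  Constant maps are exact fixed points and each
    iteration is a convex combination, so extrema never widen.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    arr = np.asarray(values, dtype=np.float64)
    flat = arr.ndim == 1
    if flat:
        arr = arr[None, :]
    if arr.shape[1] != mesh.n_vertices:
        raise ValueError("values length does not match mesh")
    if fwhm_mm < mean_edge_length(mesh):
        warnings.warn(
            f"requested FWHM {fwhm_mm:.2f} mm is below the mean edge length "
            f"{mean_edge_length(mesh):.2f} mm; returning the map unsmoothed",
            RuntimeWarning,
            stacklevel=2,
        )
        out = arr.copy()
        return out[0] if flat else out
    n_iter, lam, _ = _calibrate_smoother(mesh, fwhm_mm)
    w = _averaging_operator(mesh)
    x = arr.T.copy()  # (V, n) for CSR matmul
    for _ in range(n_iter):
        x = lam * (w @ x) + (1.0 - lam) * x
    out = x.T
    return out[0] if flat else out


def smooth_map(mesh: SurfaceMesh, vmap: VertexMap, fwhm_mm: float) -> VertexMap:
    """Smooth a bound :class:`VertexMap` (see :func:`smooth_values`)."""
    vmap.check_bound(mesh)
    return VertexMap.for_mesh(mesh, smooth_values(mesh, vmap.values, fwhm_mm))


# ---------------------------------------------------------------------------
# Clusters and downsampling


def _cluster_labels(adj: sparse.csr_matrix, mask: np.ndarray):
    """Connected-component labels of the subgraph induced by ``mask``.

    Returns (member vertex indices, component label per member)."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return idx, np.empty(0, dtype=np.int32)
    sub = adj[idx][:, idx]
    _, labels = _sp_connected_components(sub, directed=False)
    return idx, labels


def connected_components(
    mesh: SurfaceMesh, mask: np.ndarray, stat_map: Optional[np.ndarray] = None
) -> ClusterTable:
    """Maximal connected vertex sets of a binary mask under mesh adjacency.

    Cluster areas are sums of member vertex areas; ``peak_stat`` is the
    maximum ``|stat_map|`` inside each cluster when a statistic map is given.
    Cluster-wise p-values are left unset (filled by permutation correction).
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    if mask.shape[0] != mesh.n_vertices:
        raise ValueError("mask length does not match mesh")
    areas = vertex_areas(mesh).values
    idx, labels = _cluster_labels(adjacency_matrix(mesh), mask)
    clusters = []
    for lab in range(labels.max() + 1 if labels.size else 0):
        members = idx[labels == lab]
        peak = float(np.abs(stat_map[members]).max()) if stat_map is not None else None
        clusters.append(Cluster(members, float(areas[members].sum()), peak))
    clusters.sort(key=lambda c: -c.area_mm2)
    return ClusterTable(clusters)


def max_cluster_area(adj: sparse.csr_matrix, areas: np.ndarray, mask: np.ndarray) -> float:
    """Largest connected-cluster area of ``mask``; 0.0 for an empty mask.

    Low-level fast path used inside the permutation null loop."""
    idx, labels = _cluster_labels(adj, mask)
    if idx.size == 0:
        return 0.0
    return float(np.bincount(labels, weights=areas[idx]).max())


def downsample_map(vmap: VertexMap, source_mesh: SurfaceMesh, target_order: int) -> VertexMap:
    """Restrict a map on an order-k icosphere to the nested order-``target`` subset."""
    if source_mesh.subdivision_order is None:
        raise ValueError("downsample_map requires a nested-ordering icosphere mesh")
    vmap.check_bound(source_mesh)
    k = source_mesh.subdivision_order
    if not 0 <= target_order < k:
        raise ValueError(f"target_order must be in [0, {k})")
    n = icosphere_vertex_count(target_order)
    target_mesh = build_icosphere(target_order, hemisphere=source_mesh.hemisphere)
    return VertexMap.for_mesh(target_mesh, vmap.values[:n].copy())
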