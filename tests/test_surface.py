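"""Mesh geometry, adjacency, smoothing, clustering and downsampling."""
import numpy as np
import pytest

from cortsig import surface as S
from cortsig.surface import (
    SurfaceMesh,
    VertexMap,
    build_icosphere,
    connected_components,
    downsample_map,
    geodesic_disc,
    smooth_values,
    vertex_adjacency,
    vertex_areas,
)


def single_triangle(coords=None):
    coords = coords if coords is not None else np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, np.sqrt(3) / 2, 0.0]]
    )
    return SurfaceMesh(coords, np.array([[0, 1, 2]]))


class TestIcosphere:
    @pytest.mark.parametrize("order", range(6))
    def test_counts_and_topology(self, order):
        mesh = build_icosphere(order)
        assert mesh.n_vertices == 10 * 4**order + 2
        assert mesh.n_faces == 20 * 4**order
        assert mesh.euler_characteristic() == 2
        assert mesh.is_connected()

    def test_vertices_on_sphere(self, ico3):
        radii = np.linalg.norm(ico3.vertex_coords, axis=1)
        assert np.allclose(radii, 100.0, atol=1e-9)

    def test_nested_ordering(self):
        m2 = build_icosphere(2)
        m3 = build_icosphere(3)
        assert np.allclose(m3.vertex_coords[: m2.n_vertices], m2.vertex_coords)

    def test_order_guard(self):
        with pytest.raises(ValueError):
            build_icosphere(8)
        with pytest.raises(ValueError):
            build_icosphere(-1)

    def test_face_index_bounds_checked(self):
        with pytest.raises(ValueError):
            SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 3]]))


class TestAdjacency:
    def test_icosahedron_is_degree_five(self):
        nbrs = vertex_adjacency(build_icosphere(0))
        assert all(len(n) == 5 for n in nbrs)

    def test_order2_degree_census(self, ico2):
        degrees = np.array([len(n) for n in vertex_adjacency(ico2)])
        assert (degrees == 5).sum() == 12
        assert (degrees == 6).sum() == ico2.n_vertices - 12

    def test_matches_brute_force_edge_enumeration(self, ico2):
        expected = {i: set() for i in range(ico2.n_vertices)}
        for a, b, c in ico2.faces:
            for u, v in ((a, b), (b, c), (c, a)):
                expected[u].add(v)
                expected[v].add(u)
        nbrs = vertex_adjacency(ico2)
        for i in range(ico2.n_vertices):
            assert set(nbrs[i].tolist()) == expected[i]

    def test_symmetry(self, ico3):
        a = S.adjacency_matrix(ico3)
        assert (a != a.T).nnz == 0

    def test_single_triangle(self):
        nbrs = vertex_adjacency(single_triangle())
        assert [len(n) for n in nbrs] == [2, 2, 2]


class TestVertexAreas:
    def test_equilateral_triangle_analytic(self):
        areas = vertex_areas(single_triangle()).values
        assert np.allclose(areas, (np.sqrt(3) / 4) / 3)

    def test_conservation(self, ico3):
        va = vertex_areas(ico3).values
        assert abs(va.sum() - S.total_area(ico3)) <= 1e-9 * S.total_area(ico3)

    def test_sphere_area_within_three_percent(self, ico3):
        analytic = 4 * np.pi * 100.0**2
        assert abs(S.total_area(ico3) - analytic) / analytic < 0.03

    def test_degenerate_face_flagged(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [0.5, 1, 0]], dtype=float)
        mesh = SurfaceMesh(coords, np.array([[0, 1, 3], [1, 2, 3]]))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            vertex_areas(mesh)


class TestSmoothing:
    def test_constant_map_is_fixed_point(self, ico3):
        x = np.full(ico3.n_vertices, 2.5)
        assert np.array_equal(smooth_values(ico3, x, 25.0), x)

    def test_extrema_contract(self, ico3):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(ico3.n_vertices)
        sm = smooth_values(ico3, x, 25.0)
        assert sm.max() <= x.max() + 1e-12
        assert sm.min() >= x.min() - 1e-12

    def test_commutes_with_scaling(self, ico3):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(ico3.n_vertices)
        a = smooth_values(ico3, 7.5 * x, 25.0)
        b = 7.5 * smooth_values(ico3, x, 25.0)
        assert np.max(np.abs(a - b)) <= 1e-12 * np.max(np.abs(b))

    @pytest.mark.parametrize("order,fwhm", [(3, 25.0), (3, 35.0), (4, 10.0), (4, 20.0)])
    def test_spike_fwhm_within_twenty_percent(self, order, fwhm):
        mesh = build_icosphere(order)
        spike = np.zeros(mesh.n_vertices)
        center = 40  # a degree-6 vertex on any order >= 2 icosphere
        spike[center] = 1.0
        sm = smooth_values(mesh, spike, fwhm)
        dist = S.geodesic_distances(mesh, center)
        measured = S._profile_fwhm(dist, sm)
        assert abs(measured - fwhm) / fwhm <= 0.2

    @pytest.mark.parametrize("order,fwhm", [(3, 25.0), (4, 15.0)])
    def test_spike_profile_close_to_geodesic_gaussian(self, order, fwhm):
        """The empirical kernel should track an explicit geodesic Gaussian of
        the same bandwidth (the independent oracle)."""
        mesh = build_icosphere(order)
        center = 40
        spike = np.zeros(mesh.n_vertices)
        spike[center] = 1.0
        sm = smooth_values(mesh, spike, fwhm)
        dist = S.geodesic_distances(mesh, center)
        measured = S._profile_fwhm(dist, sm)
        sigma = measured / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        oracle = np.exp(-0.5 * (dist / sigma) ** 2)
        a = sm / np.linalg.norm(sm)
        b = oracle / np.linalg.norm(oracle)
        assert float(a @ b) > 0.95

    def test_subresolution_fwhm_warns_and_passes_through(self, ico2):
        x = np.random.default_rng(2).standard_normal(ico2.n_vertices)
        with pytest.warns(RuntimeWarning, match="mean edge length"):
            out = smooth_values(ico2, x, 1.0)
        assert np.array_equal(out, x)

    def test_rejects_nonpositive_fwhm(self, ico2):
        with pytest.raises(ValueError):
            smooth_values(ico2, np.zeros(ico2.n_vertices), 0.0)


def flood_fill_oracle(mesh, mask):
    """Brute-force BFS connected components of a masked vertex set."""
    nbrs = vertex_adjacency(mesh)
    unvisited = set(np.nonzero(mask)[0].tolist())
    comps = []
    while unvisited:
        seed = unvisited.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for u in nbrs[v]:
                u = int(u)
                if u in unvisited:
                    unvisited.remove(u)
                    comp.add(u)
                    frontier.append(u)
        comps.append(frozenset(comp))
    return set(comps)


class TestConnectedComponents:
    def test_empty_mask(self, ico3):
        assert len(connected_components(ico3, np.zeros(ico3.n_vertices, dtype=bool))) == 0

    def test_full_mask_single_cluster(self, ico3):
        table = connected_components(ico3, np.ones(ico3.n_vertices, dtype=bool))
        assert len(table) == 1
        assert table.clusters[0].area_mm2 == pytest.approx(S.total_area(ico3), rel=1e-9)

    def test_two_disjoint_discs(self, ico4):
        disc_a = geodesic_disc(ico4, 0, 20.0)
        far = int(np.argmax(S.geodesic_distances(ico4, 0)))
        disc_b = geodesic_disc(ico4, far, 15.0)
        assert not (disc_a & disc_b).any()
        table = connected_components(ico4, disc_a | disc_b)
        assert len(table) == 2
        found = {frozenset(c.vertices.tolist()) for c in table.clusters}
        assert found == {
            frozenset(np.nonzero(disc_a)[0].tolist()),
            frozenset(np.nonzero(disc_b)[0].tolist()),
        }

    @pytest.mark.parametrize("density", [0.05, 0.2, 0.5, 0.8])
    def test_matches_flood_fill_oracle(self, ico3, density):
        rng = np.random.default_rng(int(density * 100))
        mask = rng.random(ico3.n_vertices) < density
        table = connected_components(ico3, mask)
        got = {frozenset(c.vertices.tolist()) for c in table.clusters}
        assert got == flood_fill_oracle(ico3, mask)

    def test_rejects_non_binary_mask(self, ico2):
        with pytest.raises(ValueError):
            connected_components(ico2, np.full(ico2.n_vertices, 0.5))

    def test_peak_stat_recorded(self, ico3):
        mask = geodesic_disc(ico3, 0, 30.0)
        stat = np.zeros(ico3.n_vertices)
        stat[0] = -4.2
        table = connected_components(ico3, mask, stat_map=stat)
        assert table.clusters[0].peak_stat == pytest.approx(4.2)


class TestDownsample:
    def test_nested_prefix(self):
        m5 = build_icosphere(5)
        vm = VertexMap.for_mesh(m5, np.arange(m5.n_vertices, dtype=float))
        down = downsample_map(vm, m5, 3)
        assert len(down) == 642
        assert np.array_equal(down.values, np.arange(642.0))

    def test_constant_preserved(self, ico4):
        vm = VertexMap.for_mesh(ico4, np.full(ico4.n_vertices, 3.3))
        assert np.all(downsample_map(vm, ico4, 2).values == 3.3)

    def test_rejects_non_icosphere(self):
        tri = single_triangle()
        vm = VertexMap.for_mesh(tri, np.zeros(3))
        with pytest.raises(ValueError):
            downsample_map(vm, tri, 0)

    def test_rejects_bad_order(self, ico3):
        vm = VertexMap.for_mesh(ico3, np.zeros(ico3.n_vertices))
        with pytest.raises(ValueError):
            downsample_map(vm, ico3, 3)
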