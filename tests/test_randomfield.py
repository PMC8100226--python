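"""Smoothness estimation, mesh smoothing, clustering and the simulated null."""

import math

import numpy as np
import pytest

from surfglm.fsio import SurfaceMesh
from surfglm.randomfield import (
    clusterwise_correct,
    estimate_fwhm,
    find_clusters,
    fwhm_from_rho,
    simulate_null_max_areas,
    smooth_on_mesh,
)
from surfglm.synthetic import make_icosphere, patch_profile


class TestFwhmEstimator:
    def test_closed_form_rho_half(self):
        assert fwhm_from_rho(0.5, 1.0) == pytest.approx(2.0, abs=1e-12)

    def test_nonpositive_rho_maps_to_zero(self):
        assert fwhm_from_rho(0.0, 1.0) == 0.0
        assert fwhm_from_rho(-0.3, 1.0) == 0.0

    def test_white_noise_fwhm_near_zero(self, ico2):
        rng = np.random.default_rng(0)
        res = rng.standard_normal((200, ico2.n_vertices))
        est = estimate_fwhm(res, ico2, np.ones(ico2.n_vertices, dtype=bool))
        assert abs(est.rho_edge) < 0.05
        assert est.fwhm_mm < 0.35 * ico2.edge_mean

    def test_monotone_in_smoothing_iterations(self, ico2):
        rng = np.random.default_rng(1)
        noise = rng.standard_normal((60, ico2.n_vertices))
        mask = np.ones(ico2.n_vertices, dtype=bool)
        fwhms = []
        for iters in (0, 1, 2, 4, 8):
            sm = smooth_on_mesh(noise, ico2, iters)
            fwhms.append(estimate_fwhm(sm, ico2, mask).fwhm_mm)
        assert all(b >= a for a, b in zip(fwhms, fwhms[1:]))

    def test_constant_field_rejected(self, ico2):
        with pytest.raises(ValueError, match="constant"):
            estimate_fwhm(np.ones((5, ico2.n_vertices)), ico2, np.ones(ico2.n_vertices, bool))


class TestSmoothing:
    def test_constant_map_is_fixed_point(self, ico2):
        x = np.full(ico2.n_vertices, 3.7)
        np.testing.assert_allclose(smooth_on_mesh(x, ico2, 5), x, rtol=1e-12)

    def test_zero_iterations_is_identity(self, ico2):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(ico2.n_vertices)
        np.testing.assert_array_equal(smooth_on_mesh(x, ico2, 0), x)

    def test_mean_preserved_on_regular_mesh(self, ico0):
        # the icosahedron is degree-regular, so averaging is doubly stochastic
        rng = np.random.default_rng(3)
        x = rng.standard_normal(12)
        sm = smooth_on_mesh(x, ico0, 3)
        assert sm.mean() == pytest.approx(x.mean(), rel=1e-12)

    def test_variance_strictly_decreases(self, ico2):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(ico2.n_vertices)
        prev = x.var()
        for _ in range(5):
            x = smooth_on_mesh(x, ico2, 1)
            assert x.var() < prev
            prev = x.var()


def _flood_fill_oracle(supra, sign, mesh):
    """Brute-force BFS connected components over same-sign supra vertices."""
    seen = set()
    comps = []
    for start in np.flatnonzero(supra):
        if start in seen:
            continue
        comp, queue = [], [start]
        seen.add(start)
        while queue:
            u = queue.pop()
            comp.append(u)
            for v in mesh.adjacency[u]:
                if v not in seen and supra[v] and sign[v] == sign[u]:
                    seen.add(v)
                    queue.append(v)
        comps.append(sorted(comp))
    return sorted(comps)


class TestFindClusters:
    def test_no_supra_threshold_gives_empty_table(self, ico2):
        v = ico2.n_vertices
        table = find_clusters(np.ones(v), np.ones(v), ico2, np.ones(v, bool), 0.001)
        assert len(table) == 0

    def test_full_mesh_single_cluster(self, ico2):
        v = ico2.n_vertices
        table = find_clusters(np.zeros(v), np.ones(v), ico2, np.ones(v, bool), 0.5)
        assert len(table) == 1
        assert table.clusters[0].n_vertices == v
        assert table.clusters[0].area_mm2 == pytest.approx(ico2.total_area, rel=1e-9)

    def test_two_planted_patches_match_flood_fill(self, ico2):
        v = ico2.n_vertices
        rng = np.random.default_rng(5)
        p1 = patch_profile(ico2, 0, 40.0) >= 1
        p2 = patch_profile(ico2, 80, 40.0) >= 1
        assert not np.any(p1 & p2)
        pmap = np.ones(v)
        tmap = rng.standard_normal(v) * 0.1
        pmap[p1 | p2] = 1e-6
        tmap[p1] = 5.0
        tmap[p2] = -4.0
        mask = np.ones(v, bool)
        table = find_clusters(pmap, tmap, ico2, mask, 0.001)
        assert len(table) == 2
        supra = pmap < 0.001
        oracle = _flood_fill_oracle(supra, np.sign(tmap), ico2)
        got = sorted(sorted(c.vertices.tolist()) for c in table)
        assert got == oracle
        for c in table:
            assert c.area_mm2 == pytest.approx(ico2.vertex_area[c.vertices].sum(), rel=1e-12)
        signs = {c.sign for c in table}
        assert signs == {"+", "-"}

    def test_opposite_signs_split_adjacent_components(self, ico2):
        v = ico2.n_vertices
        tmap = np.where(ico2.coords[:, 2] >= 0, 3.0, -3.0)
        pmap = np.full(v, 1e-5)
        table = find_clusters(pmap, tmap, ico2, np.ones(v, bool), 0.001)
        assert len(table) == 2
        assert {c.sign for c in table} == {"+", "-"}

    def test_relabeling_invariance(self, ico2):
        v = ico2.n_vertices
        rng = np.random.default_rng(6)
        pmap = rng.uniform(0, 1, v) ** 4
        tmap = rng.standard_normal(v)
        mask = np.ones(v, bool)
        perm = rng.permutation(v)
        inv = np.empty(v, dtype=int)
        inv[perm] = np.arange(v)
        mesh2 = SurfaceMesh(coords=ico2.coords[perm], faces=inv[ico2.faces])
        t1 = find_clusters(pmap, tmap, ico2, mask, 0.05)
        t2 = find_clusters(pmap[perm], tmap[perm], mesh2, mask, 0.05)
        a1 = sorted(round(c.area_mm2, 9) for c in t1)
        a2 = sorted(round(c.area_mm2, 9) for c in t2)
        assert a1 == a2


class TestNullSimulation:
    def test_same_seed_identical(self, ico2):
        mask = np.ones(ico2.n_vertices, bool)
        a = simulate_null_max_areas(ico2, mask, 40.0, 0.001, n_sim=50, seed=9)
        b = simulate_null_max_areas(ico2, mask, 40.0, 0.001, n_sim=50, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_threshold_near_one_covers_mesh(self, ico2):
        # with the threshold near 1 every vertex is supra-threshold; clusters
        # are still split by t sign, so they partition the whole mesh and the
        # recorded maximum is the largest sign-coherent component
        v = ico2.n_vertices
        mask = np.ones(v, bool)
        rng = np.random.default_rng(0)
        field = rng.standard_normal(v)
        from scipy import stats

        pmap = 2 * stats.norm.sf(np.abs(field))
        table = find_clusters(pmap, field, ico2, mask, 0.999999)
        assert sum(c.n_vertices for c in table) == v
        assert sum(c.area_mm2 for c in table) == pytest.approx(ico2.total_area, rel=1e-9)
        areas = simulate_null_max_areas(ico2, mask, 0.0, mcz_thr=0.999999, n_sim=5, seed=1)
        assert np.all(areas > 0) and np.all(areas <= ico2.total_area + 1e-9)
        # a sign-constant field is one single whole-mesh cluster
        table1 = find_clusters(pmap, np.ones(v), ico2, mask, 0.999999)
        assert len(table1) == 1 and table1.clusters[0].area_mm2 == pytest.approx(ico2.total_area, rel=1e-9)

    def test_mean_max_area_monotone_in_fwhm(self, ico2):
        mask = np.ones(ico2.n_vertices, bool)
        means = []
        for fwhm in (0.0, 60.0, 120.0):
            areas = simulate_null_max_areas(ico2, mask, fwhm, 0.01, n_sim=150, seed=3)
            means.append(areas.mean())
        assert means[0] < means[1] < means[2]


class TestClusterwiseCorrect:
    def test_counting_arithmetic(self, ico2):
        table = find_clusters(
            np.where(np.arange(ico2.n_vertices) < 3, 1e-9, 1.0),
            np.ones(ico2.n_vertices),
            ico2,
            np.ones(ico2.n_vertices, bool),
            0.001,
        )
        area = table.clusters[0].area_mm2
        null = np.array([area - 1.5, area - 0.5, area + 0.5, area + 1.5])
        clusterwise_correct(table, null)
        assert table.clusters[0].cwp == pytest.approx((1 + 2) / 5)

    def test_extreme_observed_area(self, ico2):
        table = find_clusters(
            np.where(np.arange(ico2.n_vertices) < 3, 1e-9, 1.0),
            np.ones(ico2.n_vertices),
            ico2,
            np.ones(ico2.n_vertices, bool),
            0.001,
        )
        clusterwise_correct(table, np.zeros(100))
        assert table.clusters[0].cwp == pytest.approx(1 / 101)
        assert table.clusters[0].cwp > 0

    def test_monotone_nonincreasing_in_area(self):
        null = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        n_sim = len(null)
        cwps = [(1 + (null >= a).sum()) / (1 + n_sim) for a in np.linspace(0, 6, 30)]
        assert all(b <= a for a, b in zip(cwps, cwps[1:]))
        assert min(cwps) > 0

    def test_maps_emitted(self, ico2):
        v = ico2.n_vertices
        pmap = np.ones(v)
        pmap[:4] = 1e-9
        table = find_clusters(pmap, np.ones(v), ico2, np.ones(v, bool), 0.001)
        _, logp, sig = clusterwise_correct(table, np.zeros(50), cwp_thr=0.025, n_vertices=v)
        verts = np.concatenate([c.vertices for c in table])
        assert np.all(logp[verts] == pytest.approx(-math.log10(1 / 51)))
        assert np.all(sig[verts] == 1.0)
        off = np.setdiff1d(np.arange(v), verts)
        assert np.all(logp[off] == 0) and np.all(sig[off] == 0)
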