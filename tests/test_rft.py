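"""Smoothness estimation, cluster detection and RFT-corrected p-values."""

import numpy as np
import pytest
from scipy.stats import t as t_dist

from deviate.errors import DataError
from deviate.glm import DeviationMap, build_design, fit_normative
from deviate.mesh import TriangleMesh
from deviate.rft import (
    SmoothnessEstimate,
    Cluster,
    ClusterTable,
    cluster_corrected_p,
    cluster_forming_threshold,
    ec_density,
    estimate_fwhm,
    expected_ec,
    find_clusters,
    peak_corrected_p,
)
from deviate.synthetic import (
    default_truth,
    generate_cohort,
    generate_thickness,
    grow_patch,
)


def _dev(values, excluded=None):
    values = np.asarray(values, dtype=float)
    if excluded is None:
        excluded = np.zeros(len(values), dtype=bool)
    return DeviationMap(values=values, excluded=excluded)


def _fit(mesh, seed=0, n=50, fwhm_factor=3.0):
    truth = default_truth(mesh, seed=seed, fwhm_factor=fwhm_factor)
    cohort = generate_cohort(n=n, seed=seed)
    stack = generate_thickness(mesh, cohort, truth)
    design = build_design(cohort, 43.0)
    model, resid = fit_normative(stack, design, return_residuals=True)
    return truth, model, resid


class TestEcDensities:
    def test_gaussian_limit(self):
        # at huge df the t densities converge to the Gaussian ones
        z = np.array([2.0, 3.0, 4.0])
        big = ec_density(2, z, 1e7)
        gauss = 4 * np.log(2) / (2 * np.pi) ** 1.5 * z * np.exp(-z * z / 2)
        assert np.allclose(big, gauss, rtol=1e-4)

    def test_zero_resel_degeneracy_reduces_to_t_tail(self):
        nu = 30.0
        t = np.linspace(0.5, 5, 20)
        assert np.allclose(expected_ec(t, (1.0, 0.0, 0.0), nu), t_dist.sf(t, nu))

    def test_densities_vanish_at_infinity(self):
        for d in (0, 1, 2):
            assert ec_density(d, np.inf, 20.0) == 0.0


class TestSmoothness:
    def test_recovers_generator_fwhm(self, ico4):
        truth, model, resid = _fit(ico4, seed=1, fwhm_factor=3.0)
        est = estimate_fwhm(resid, model, ico4)
        assert abs(est.fwhm - truth.noise_fwhm) / truth.noise_fwhm < 0.2
        assert est.resels[0] == 2  # closed sphere
        assert np.isclose(est.resels[2], est.area / est.fwhm**2)

    def test_scale_equivariance(self, ico3):
        truth, model, resid = _fit(ico3, seed=2)
        est = estimate_fwhm(resid, model, ico3)
        doubled = TriangleMesh(2.0 * ico3.vertices, ico3.faces)
        est2 = estimate_fwhm(resid, model, doubled)
        assert np.isclose(est2.fwhm, 2 * est.fwhm, rtol=1e-12)
        assert np.isclose(est2.resels[2], est.resels[2], rtol=1e-12)

    def test_white_noise_fwhm_below_lattice_scale(self, ico3):
        # sub-edge noise FWHM makes the generator fall back to white noise
        truth, model, resid = _fit(ico3, seed=3, fwhm_factor=0.01)
        est = estimate_fwhm(resid, model, ico3)
        assert est.fwhm < 1.5 * ico3.mean_edge_length()

    def test_all_zero_variance_is_data_error(self, ico2):
        _, model, resid = _fit(ico2, seed=4)
        with pytest.raises(DataError, match="zero variance"):
            estimate_fwhm(np.zeros_like(resid), model, ico2)


class TestFindClusters:
    def test_null_map_empty_table(self, ico3):
        table = find_clusters(_dev(np.zeros(ico3.n_vertices)), 3.0, ico3)
        assert len(table) == 0

    def test_hand_built_patches_recovered(self, ico3):
        values = np.zeros(ico3.n_vertices)
        patch_a = grow_patch(ico3, 0, 3)
        patch_b = grow_patch(ico3, 300, 3)
        values[patch_a] = 5.0
        values[patch_b] = -4.0
        table = find_clusters(_dev(values), 3.0, ico3, sign="two_sided")
        assert len(table) == 2
        by_sign = {c.sign: c for c in table}
        assert np.array_equal(by_sign[+1].vertices, np.sort(patch_a))
        assert np.array_equal(by_sign[-1].vertices, np.sort(patch_b))
        assert by_sign[+1].peak_stat == 5.0 and by_sign[-1].peak_stat == -4.0

    def test_one_sided_modes_filter_by_sign(self, ico3):
        values = np.zeros(ico3.n_vertices)
        values[grow_patch(ico3, 0, 4)] = 5.0
        values[grow_patch(ico3, 300, 4)] = -5.0
        assert len(find_clusters(_dev(values), 3.0, ico3, sign="positive")) == 1
        assert len(find_clusters(_dev(values), 3.0, ico3, sign="negative")) == 1

    def test_sign_flip_maps_modes_onto_each_other(self, ico3, rng):
        values = rng.standard_normal(ico3.n_vertices) * 2.0
        pos = find_clusters(_dev(values), 2.5, ico3, sign="positive")
        neg = find_clusters(_dev(-values), 2.5, ico3, sign="negative")
        assert len(pos) == len(neg)
        for a, b in zip(pos, neg):
            assert np.array_equal(a.vertices, b.vertices)
            assert a.peak_stat == -b.peak_stat

    def test_membership_invariant_under_reindexing(self, ico2, rng):
        values = rng.standard_normal(ico2.n_vertices) * 2.0
        perm = rng.permutation(ico2.n_vertices)
        inv = np.argsort(perm)
        shuffled = TriangleMesh(ico2.vertices[perm], inv[ico2.faces])
        orig = find_clusters(_dev(values), 2.0, ico2)
        moved = find_clusters(_dev(values[perm]), 2.0, shuffled)
        orig_sets = {frozenset(c.vertices.tolist()) for c in orig}
        moved_sets = {frozenset(perm[c.vertices].tolist()) for c in moved}
        assert orig_sets == moved_sets

    def test_injected_patch_dice(self, ico4, rng):
        # a +5 SD, 150-vertex patch must be recovered with Dice >= 0.7
        from deviate.synthetic import SmoothFieldSampler

        patch = grow_patch(ico4, 0, 150)
        in_patch = np.zeros(ico4.n_vertices, bool)
        in_patch[patch] = True
        sampler = SmoothFieldSampler(ico4, 3 * ico4.mean_edge_length())
        z = cluster_forming_threshold(0.001, 183)
        dices = []
        for _ in range(50):
            field = sampler.sample(1, rng)[0]
            field[patch] += 5.0
            table = find_clusters(_dev(field), z, ico4, sign="positive")
            best = max(table, key=lambda c: in_patch[c.vertices].sum())
            inter = in_patch[best.vertices].sum()
            dices.append(2 * inter / (len(best.vertices) + len(patch)))
        assert np.median(dices) >= 0.7

    def test_invalid_threshold(self, ico2):
        with pytest.raises(DataError):
            find_clusters(_dev(np.zeros(ico2.n_vertices)), -1.0, ico2)


class TestCorrectedP:
    SMOOTH = SmoothnessEstimate(fwhm=1.0, resels=(2.0, 0.0, 100.0), area=100.0)

    def test_peak_limits(self):
        dev = _dev([np.inf, -np.inf, 0.0])
        p = peak_corrected_p(dev, self.SMOOTH, nu=50, sign="positive")
        assert p.values[0] == 0.0
        assert p.values[1] == 1.0  # capped
        assert 0 < p.values[2] <= 1.0

    def test_peak_monotone_decreasing_in_statistic(self):
        s = np.linspace(0.5, 8, 30)
        p = peak_corrected_p(_dev(s), self.SMOOTH, nu=50, sign="positive")
        assert (np.diff(p.values[p.values < 1.0]) < 0).all()

    def test_excluded_vertices_get_p_one(self):
        dev = _dev([5.0, 5.0], excluded=np.array([False, True]))
        p = peak_corrected_p(dev, self.SMOOTH, nu=50)
        assert p.values[1] == 1.0 and p.values[0] < 0.05

    def test_empty_cluster_table_unchanged(self):
        table = ClusterTable(clusters=[], threshold=3.0, sign="positive")
        out = cluster_corrected_p(table, 3.0, self.SMOOTH, nu=50)
        assert len(out) == 0

    def test_larger_extent_smaller_p(self):
        mk = lambda i, area: Cluster(id=i, sign=1, vertices=np.arange(3), area_mm2=area,
                                     peak_stat=4.0, peak_vertex=0)
        table = ClusterTable(clusters=[mk(1, 10.0), mk(2, 100.0)], threshold=3.2,
                             sign="positive")
        out = cluster_corrected_p(table, 3.2, self.SMOOTH, nu=50)
        ps = {c.id: c.p for c in out}
        assert ps[2] < ps[1]
        assert all(0 <= c.p <= 1 for c in out)
        assert np.isclose(out.clusters[0].resels, 10.0)  # fwhm = 1

    def test_threshold_mismatch_rejected(self):
        table = ClusterTable(clusters=[], threshold=3.0, sign="positive")
        with pytest.raises(DataError, match="threshold"):
            cluster_corrected_p(table, 2.5, self.SMOOTH, nu=50)

    def test_cluster_forming_threshold_is_t_quantile(self):
        assert np.isclose(cluster_forming_threshold(0.001, 183), t_dist.isf(0.001, 183))
        with pytest.raises(DataError):
            cluster_forming_threshold(1.5, 183)
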