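"""Tests of CBC5 subtype clustering: SAC surfaces, depth correction,
profiles, PCA+GMM and the shift/swap refinement."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import oplconn as oc
from oplconn.cbc5 import (
    DepthProfile,
    cluster_cost,
    flatten_depth,
    pca_gmm_init,
    pca_scores,
    refine_assignments,
    sac_band_surface,
    subtype_labels,
)
from oplconn.synthetic import generate_sac_bands_and_cbc5_axons


def flat_cloud(z, n=3000, seed=0, w=100.0, h=80.0):
    rng = np.random.default_rng(seed)
    xy = rng.uniform([0, 0], [w, h], (n, 2))
    return np.column_stack([xy, np.full(n, z)])


class TestSacSurface:
    def test_plane_recovered_exactly(self):
        surf = sac_band_surface(flat_cloud(-45.0))
        x = np.linspace(5, 95, 15)
        y = np.linspace(5, 75, 15)
        assert np.allclose(surf(x, y), -45.0, atol=1e-6)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            sac_band_surface(np.empty((0, 3)))

    def test_warped_band_recovered_within_bin_height(self):
        """Fit error against the generating surface stays below the
        depth-bin height over the interpolation-supported interior
        (between the outermost grid-cell centres)."""
        cfg = oc.OplSimConfig(seed=3)
        sac = generate_sac_bands_and_cbc5_axons(cfg)
        depth_bin = 0.5
        for pts, true in [(sac.on_points, sac.true_on), (sac.off_points, sac.true_off)]:
            surf = sac_band_surface(pts, grid=(10, 8), depth_bin=depth_bin)
            xmin, xmax, ymin, ymax = surf.bounds
            mx, my = (xmax - xmin) / 10 / 2, (ymax - ymin) / 8 / 2
            gx = np.linspace(xmin + mx, xmax - mx, 25)
            gy = np.linspace(ymin + my, ymax - my, 25)
            xx, yy = np.meshgrid(gx, gy)
            err = np.abs(surf(xx.ravel(), yy.ravel()) - true(xx.ravel(), yy.ravel()))
            assert err.max() < depth_bin

    def test_bimodal_bin_takes_higher_density_mode(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform([0, 0], [50, 50], (4000, 2))
        z = np.where(rng.random(4000) < 0.7, -40.0, -30.0)
        surf = sac_band_surface(np.column_stack([xy, z]), grid=(4, 4), depth_bin=1.0)
        assert np.allclose(surf(25.0, 25.0), -40.0, atol=1.0)


class TestFlattenDepth:
    def _surfaces(self):
        on = sac_band_surface(flat_cloud(-52.0))
        off = sac_band_surface(flat_cloud(-42.0))
        return on, off

    def test_band_endpoints_map_to_0_and_1(self):
        on, off = self._surfaces()
        assert flatten_depth(np.array([[50, 40, -52.0]]), on, off)[0] == pytest.approx(0.0, abs=1e-6)
        assert flatten_depth(np.array([[50, 40, -42.0]]), on, off)[0] == pytest.approx(1.0, abs=1e-6)
        assert flatten_depth(np.array([[50, 40, -47.0]]), on, off)[0] == pytest.approx(0.5, abs=1e-6)

    def test_mapping_is_affine_per_column(self, rng):
        on, off = self._surfaces()
        for _ in range(20):
            x, y = rng.uniform(10, 90), rng.uniform(10, 70)
            z1, z2 = rng.uniform(-60, -35, 2)
            a = rng.uniform()
            lhs = flatten_depth(np.array([[x, y, a * z1 + (1 - a) * z2]]), on, off)[0]
            f1 = flatten_depth(np.array([[x, y, z1]]), on, off)[0]
            f2 = flatten_depth(np.array([[x, y, z2]]), on, off)[0]
            assert lhs == pytest.approx(a * f1 + (1 - a) * f2, abs=1e-9)

    def test_coincident_surfaces_rejected(self):
        on = sac_band_surface(flat_cloud(-45.0))
        with pytest.raises(ValueError, match="coincide"):
            flatten_depth(np.array([[50, 40, -45.0]]), on, on)


class TestProfiles:
    def test_single_point_gives_indicator_bin(self):
        on = sac_band_surface(flat_cloud(-52.0))
        off = sac_band_surface(flat_cloud(-42.0))
        profiles = oc.axon_profiles({"cell": np.array([[50, 40, -47.0]])}, on, off)
        p = profiles[0]
        assert p.density.sum() == pytest.approx(1.0)
        assert np.count_nonzero(p.density) == 1
        assert p.peak_depth == pytest.approx(0.5, abs=0.03)

    def test_profiles_are_unit_normalised(self):
        cfg = oc.OplSimConfig(seed=4)
        sac = generate_sac_bands_and_cbc5_axons(cfg)
        on = sac_band_surface(sac.on_points)
        off = sac_band_surface(sac.off_points)
        profiles = oc.axon_profiles(sac.axon_clouds, on, off)
        for p in profiles:
            assert p.density.sum() == pytest.approx(1.0)
            assert np.all(p.density >= 0)

    def test_planted_peak_recovered_within_one_bin(self):
        cfg = oc.OplSimConfig(seed=4)
        sac = generate_sac_bands_and_cbc5_axons(cfg)
        on = sac_band_surface(sac.on_points)
        off = sac_band_surface(sac.off_points)
        profiles = oc.axon_profiles(sac.axon_clouds, on, off)
        bin_w = profiles[0].bin_centers[1] - profiles[0].bin_centers[0]
        by_type = {}
        for p in profiles:
            by_type.setdefault(sac.subtype_truth[p.cell_id], []).append(p.peak_depth)
        for st, peaks in by_type.items():
            planted = sac.planted_depths[st]
            assert abs(np.mean(peaks) - planted) <= 1.5 * bin_w

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            DepthProfile("c", np.array([0.0, 1.0]), np.array([0.5, -0.5]))


class TestPcaGmm:
    def _profiles(self, seed=0):
        cfg = oc.OplSimConfig(seed=seed)
        sac = generate_sac_bands_and_cbc5_axons(cfg)
        on = sac_band_surface(sac.on_points)
        off = sac_band_surface(sac.off_points)
        return oc.axon_profiles(sac.axon_clouds, on, off), sac

    def test_scores_match_eigendecomposition_oracle(self):
        profiles, _ = self._profiles()
        M = np.array([p.density for p in profiles])
        Mc = M - M.mean(axis=0)
        # independent oracle: eigendecomposition of the covariance
        C = Mc.T @ Mc
        w, V = np.linalg.eigh(C)
        V = V[:, np.argsort(w)[::-1][:3]]
        oracle = Mc @ V
        scores = pca_scores(profiles, 3)
        for k in range(3):
            col = scores[:, k]
            assert min(
                np.max(np.abs(col - oracle[:, k])),
                np.max(np.abs(col + oracle[:, k])),
            ) < 1e-8

    def test_well_separated_subtypes_recovered(self):
        profiles, sac = self._profiles(seed=2)
        state = pca_gmm_init(profiles, seed=2)
        truth = [sac.subtype_truth[p.cell_id] for p in profiles]
        assert adjusted_rand_score(truth, state.assignments) >= 0.9

    def test_same_seed_reproduces_assignments(self):
        profiles, _ = self._profiles(seed=5)
        s1 = pca_gmm_init(profiles, seed=9)
        s2 = pca_gmm_init(profiles, seed=9)
        assert np.array_equal(s1.assignments, s2.assignments)

    def test_too_few_cells_rejected(self):
        profiles, _ = self._profiles()
        with pytest.raises(ValueError):
            pca_gmm_init(profiles[:2], seed=0)


def hand_state(x, assignments, means, covs, O_opl, O_ipl, lam1=1.0, lam2=1.0,
               use_inverse=True):
    from oplconn.cbc5 import ClusterState

    n = len(x)
    return ClusterState(
        cell_ids=[f"c{i}" for i in range(n)],
        x=np.asarray(x, float),
        assignments=np.asarray(assignments),
        means=np.asarray(means, float),
        covariances=np.asarray(covs, float),
        lambda1=lam1,
        lambda2=lam2,
        area_opl=np.diag(O_opl).astype(float),
        area_ipl=np.diag(O_ipl).astype(float),
        overlap_opl=np.asarray(O_opl, float),
        overlap_ipl=np.asarray(O_ipl, float),
        use_inverse_covariance=use_inverse,
    )


class TestClusterCost:
    def test_zero_when_cells_sit_on_their_means_and_lambda2_zero(self):
        x = [[0, 0, 0], [1, 1, 1], [2, 2, 2]]
        means = [[0, 0, 0], [1, 1, 1], [2, 2, 2]]
        covs = [np.eye(3)] * 3
        O = np.zeros((3, 3))
        st = hand_state(x, [0, 1, 2], means, covs, O, O, lam2=0.0)
        assert cluster_cost(st) == pytest.approx(0.0, abs=1e-9)

    def test_two_cell_overlap_hand_computation(self):
        # two cells, same cluster, lambda1 = 0: symmetric-sum convention
        # gives 2*O12/(A1+A2) per compartment
        O_opl = np.array([[10.0, 4.0], [4.0, 6.0]])
        O_ipl = np.array([[8.0, 2.0], [2.0, 8.0]])
        st = hand_state(
            [[0, 0, 0], [0, 0, 0]], [1, 1],
            [np.zeros(3)] * 3, [np.eye(3)] * 3,
            O_opl, O_ipl, lam1=0.0, lam2=3.0,
        )
        expected = 3.0 * (2 * 4.0 / 16.0 + 2 * 2.0 / 16.0)
        assert cluster_cost(st) == pytest.approx(expected)

    def test_distinct_clusters_have_no_overlap_penalty(self):
        O = np.array([[10.0, 9.0], [9.0, 6.0]])
        st = hand_state(
            [[0, 0, 0], [0, 0, 0]], [0, 1],
            [np.zeros(3)] * 3, [np.eye(3)] * 3, O, O, lam1=0.0, lam2=5.0,
        )
        assert cluster_cost(st) == pytest.approx(0.0)

    def test_cost_invariant_under_cluster_relabeling(self, rng):
        n = 12
        x = rng.normal(size=(n, 3))
        means = rng.normal(size=(3, 3))
        covs = np.array([np.eye(3)] * 3)
        O = rng.uniform(0, 2, (n, n))
        O = (O + O.T) / 2
        np.fill_diagonal(O, 5.0)
        assign = rng.integers(0, 3, n)
        st = hand_state(x, assign, means, covs, O, O)
        base = cluster_cost(st)
        perm = np.array([2, 0, 1])
        st2 = hand_state(x, perm[assign], means[np.argsort(perm)], covs, O, O)
        assert cluster_cost(st2) == pytest.approx(base)

    def test_literal_form_available(self):
        x = [[1, 0, 0], [0, 1, 0], [0, 0, 1]]
        covs = [2.0 * np.eye(3)] * 3
        O = np.zeros((3, 3))
        st_inv = hand_state(x, [0, 0, 0], [np.zeros(3)] * 3, covs, O, O)
        st_lit = hand_state(x, [0, 0, 0], [np.zeros(3)] * 3, covs, O, O,
                            use_inverse=False)
        assert cluster_cost(st_inv) == pytest.approx(3 / (2 + 1e-6), rel=1e-4)
        assert cluster_cost(st_lit) == pytest.approx(6.0)


class TestRefinement:
    def _planted_state(self, seed=6):
        cfg = oc.OplSimConfig(seed=seed)
        ds = oc.generate_dataset(cfg, bc_types=["CBC5T", "CBC5O", "CBC5I"])
        res = oc.run_cbc5_typing(ds, seed=seed, refine=False)
        return ds, res["state"]

    def test_local_minimum_left_unchanged(self):
        _, state = self._planted_state()
        refined = refine_assignments(state)
        twice = refine_assignments(refined)
        assert np.array_equal(refined.assignments, twice.assignments)
        assert cluster_cost(refined) <= cluster_cost(state) + 1e-12

    def test_deliberate_swap_is_repaired(self):
        ds, state = self._planted_state()
        base = refine_assignments(state)
        corrupted = base.copy()
        # swap two cells between different clusters
        i = 0
        j = next(
            k for k in range(len(base.cell_ids))
            if base.assignments[k] != base.assignments[i]
        )
        corrupted.assignments[i], corrupted.assignments[j] = (
            base.assignments[j],
            base.assignments[i],
        )
        repaired = refine_assignments(corrupted)
        assert np.array_equal(repaired.assignments, base.assignments)

    def test_cost_never_increases(self):
        _, state = self._planted_state(seed=8)
        refined = refine_assignments(state)
        assert cluster_cost(refined) <= cluster_cost(state) + 1e-12


def test_end_to_end_subtype_labels_follow_depth_order():
    cfg = oc.OplSimConfig(seed=9)
    ds = oc.generate_dataset(cfg, bc_types=["CBC5T", "CBC5O", "CBC5I"])
    res = oc.run_cbc5_typing(ds, seed=9)
    labels = res["labels"]
    truth = ds.truth.cbc5_subtype
    acc = np.mean([labels[c] == truth[c] for c in labels])
    assert acc >= 0.9
    # cluster naming follows ascending corrected-depth order
    peaks = {p.cell_id: p.peak_depth for p in res["profiles"]}
    mean_peak = {
        st: np.mean([peaks[c] for c, s in labels.items() if s == st])
        for st in ("5T", "5O", "5I")
    }
    assert mean_peak["5T"] < mean_peak["5O"] < mean_peak["5I"]
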