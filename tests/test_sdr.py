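"""SDR detection: masks, contrasts, smoothness, cluster null, overlap rules."""

import numpy as np
import pytest
from scipy import stats

from restica.sdr import (
    Cluster,
    build_network_mask,
    estimate_smoothness,
    extract_clusters,
    monte_carlo_cluster_threshold,
    pairwise_contrast,
    resolve_sdr_patterns,
)
from restica.synthetic import gaussian_smooth

# Student-t upper-tail quantile isf(1e-6, df=102) computed independently by
# high-precision inversion of the regularized incomplete beta function
T_CRIT_103_50K = 5.042738958511783


class TestNetworkMask:
    def test_consistent_positive_voxel_included(self, rng):
        mask = np.ones((5, 5, 5), dtype=bool)
        maps = np.zeros((20, 5, 5, 5))
        maps[:, 2, 2, 2] = 1.0 + 0.01 * rng.standard_normal(20)
        nm = build_network_mask(maps, mask)
        assert nm.mask[2, 2, 2]
        assert nm.n_voxels == 1

    def test_null_false_inclusion_rate_calibrated(self, rng):
        """Pure-noise maps: expected false inclusions per simulation <= alpha."""
        n_sim, n_sub, n_vox = 200, 20, 1000
        mask = np.ones((10, 10, 10), dtype=bool)
        counts = []
        for _ in range(n_sim):
            maps = rng.standard_normal((n_sub, n_vox))
            nm = build_network_mask(maps.reshape(n_sub, 10, 10, 10), mask)
            counts.append(nm.n_voxels)
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(n_sim)
        assert mean <= 0.05 + 3 * se + 1e-9

    def test_critical_t_matches_high_precision_quantile(self):
        maps = np.random.default_rng(0).standard_normal((103, 4, 4, 4))
        # scale the Bonferroni denominator to mimic a 50,000-voxel brain mask
        mask = np.ones((4, 4, 4), dtype=bool)
        nm = build_network_mask(maps, mask, alpha=0.05 * 64 / 50_000)
        assert nm.t_threshold == pytest.approx(T_CRIT_103_50K, abs=1e-9)


class TestPairwiseContrast:
    def test_identical_groups_zero_t(self, rng):
        mask = np.ones((4, 4, 4), dtype=bool)
        maps = rng.standard_normal((6, 4, 4, 4))
        cm = pairwise_contrast(maps, maps.copy(), mask)
        assert np.abs(cm.t_map[mask]).max() < 1e-10

    def test_orthogonal_covariate_changes_only_df(self, rng):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = True
        n = 16
        y = rng.standard_normal((n, 3, 3, 3))
        group = np.array([1.0] * 8 + [0.0] * 8)
        # covariate orthogonal to intercept, group and response at the voxel
        resp = y[:, 0, 0, 0]
        basis = np.column_stack([np.ones(n), group, resp])
        q, _ = np.linalg.qr(np.column_stack([basis, rng.standard_normal(n)]))
        cov = q[:, 3]
        plain = pairwise_contrast(y[:8], y[8:], mask)
        adj = pairwise_contrast(y[:8], y[8:], mask,
                                covariates_a=cov[:8], covariates_b=cov[8:])
        assert adj.df == plain.df - 1
        # beta and RSS are unchanged, only the df scaling of sigma-hat moves
        scale = np.sqrt(adj.df / plain.df)
        assert adj.t_map[0, 0, 0] == pytest.approx(plain.t_map[0, 0, 0] * scale, rel=1e-9)

    def test_reproduces_printed_combat_exposure_t(self, rng):
        """Groups matching the printed summary (53.4+-16.2, n=50 vs
        42.6+-14.5, n=28) give the pooled t of ~2.92 with df 76."""
        def sample(mean, sd, n, seed):
            x = np.random.default_rng(seed).standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1)
            return (mean + sd * x).reshape(n, 1, 1, 1)

        mask = np.ones((1, 1, 1), dtype=bool)
        cm = pairwise_contrast(sample(53.4, 16.2, 50, 1), sample(42.6, 14.5, 28, 2), mask)
        assert cm.df == 76
        assert cm.t_map[0, 0, 0] == pytest.approx(2.92, abs=0.02)

    def test_collinear_covariate_rejected(self, rng):
        mask = np.ones((2, 2, 2), dtype=bool)
        y = rng.standard_normal((8, 2, 2, 2))
        group = np.array([1.0] * 4 + [0.0] * 4)
        with pytest.raises(ValueError, match="rank"):
            pairwise_contrast(y[:4], y[4:], mask,
                              covariates_a=group[:4], covariates_b=group[4:])


class TestSmoothness:
    def test_white_noise_fwhm_near_voxel(self, rng):
        mask = np.ones((24, 24, 24), dtype=bool)
        maps = [rng.standard_normal((24, 24, 24)) for _ in range(20)]
        fwhm = estimate_smoothness(maps, mask, 3.0)
        assert 3.0 * 0.85 <= fwhm <= 3.0 * 1.15

    def test_smoothed_noise_recovers_kernel(self, rng):
        mask = np.ones((24, 24, 24), dtype=bool)
        maps = [gaussian_smooth(rng.standard_normal((24, 24, 24)), 6.0, 3.0)
                for _ in range(20)]
        fwhm = estimate_smoothness(maps, mask, 3.0)
        assert 5.0 <= fwhm <= 7.0

    def test_constant_maps_degenerate(self):
        mask = np.ones((8, 8, 8), dtype=bool)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                estimate_smoothness([np.ones((8, 8, 8))] * 3, mask, 3.0)

    def test_needs_two_maps(self, rng):
        with pytest.raises(ValueError):
            estimate_smoothness([rng.standard_normal((8, 8, 8))], np.ones((8, 8, 8), bool), 3.0)


class TestClusterNull:
    def test_unsmoothed_null_small_kmin(self):
        """With no smoothing, suprathreshold voxels are nearly independent
        and the expected count on 1000 voxels at p=0.001 is 1; max cluster
        sizes are tiny."""
        mask = np.ones((10, 10, 10), dtype=bool)
        null = monte_carlo_cluster_threshold(mask, 0.0, 3.0, n_iter=500, seed=1)
        assert null.k_min[0.05] <= 3

    def test_kmin_monotone_and_deterministic(self):
        mask = np.ones((12, 12, 12), dtype=bool)
        a = monte_carlo_cluster_threshold(mask, 6.0, 3.0, n_iter=300, seed=4)
        b = monte_carlo_cluster_threshold(mask, 6.0, 3.0, n_iter=300, seed=4)
        assert a.k_min[0.05 / 13] >= a.k_min[0.05]
        assert np.array_equal(a.max_extents, b.max_extents)

    def test_t_null_matches_low_df_statistic(self):
        """At matched marginal level a low-df t-field crosses its (higher)
        threshold in smaller patches than a Gaussian field, so the df-matched
        null yields extents and k_min no larger than the z-field null."""
        mask = np.ones((12, 12, 12), dtype=bool)
        z = monte_carlo_cluster_threshold(mask, 6.0, 3.0, n_iter=400, seed=2)
        t = monte_carlo_cluster_threshold(mask, 6.0, 3.0, n_iter=400, seed=2,
                                          null_type="t", group_sizes=(6, 5))
        assert t.max_extents.mean() <= z.max_extents.mean()
        assert t.k_min[0.05] <= z.k_min[0.05]

    def test_small_mask_rejected(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[0, 0, :5] = True
        with pytest.raises(ValueError):
            monte_carlo_cluster_threshold(mask, 6.0, 3.0, n_iter=300)


class TestExtractClusters:
    def test_face_adjacent_pair_single_cluster(self):
        b = np.zeros((5, 5, 5), dtype=bool)
        b[1, 1, 1] = b[1, 1, 2] = True
        cl = extract_clusters(b, 3.0)
        assert len(cl) == 1
        assert cl[0].size_mm3 == 54.0

    def test_corner_touch_depends_on_connectivity(self):
        b = np.zeros((5, 5, 5), dtype=bool)
        b[1, 1, 1] = b[2, 2, 2] = True
        assert len(extract_clusters(b, 3.0, connectivity=26)) == 1
        assert len(extract_clusters(b, 3.0, connectivity=6)) == 2

    def test_empty_map(self):
        assert extract_clusters(np.zeros((4, 4, 4), dtype=bool), 3.0) == []

    def test_peak_from_t_map_with_tie_break(self):
        b = np.zeros((4, 4, 4), dtype=bool)
        b[0, 0, 0] = b[0, 0, 1] = True
        t = np.zeros((4, 4, 4))
        t[0, 0, 0] = -5.0
        t[0, 0, 1] = 5.0  # tie on |t|; smaller linear index wins
        cl = extract_clusters(b, 3.0, t_map=t)
        assert cl[0].peak_index == (0, 0, 0)
        assert cl[0].peak_t == -5.0


def _clus(voxels, pair, positive):
    vox = np.asarray(voxels)
    return Cluster(voxels=vox, n_voxels=len(vox), size_mm3=27.0 * len(vox),
                   peak_t=4.0 if positive else -4.0,
                   peak_index=tuple(vox[0]), peak_mm=tuple(3.0 * v for v in vox[0]),
                   pair=pair, positive=positive)


class TestResolvePatterns:
    def test_same_direction_overlap_merges_to_combat(self):
        ptsd = _clus([(i, 0, 0) for i in range(40)], "PTSD_vs_CC", True)
        cec = _clus([(i, 0, 0) for i in range(30, 55)], "CEC_vs_CC", True)
        recs = resolve_sdr_patterns([(ptsd, True), (cec, False)], component=2)
        assert len(recs) == 1
        assert recs[0].pattern == "Combat Increasing"
        assert recs[0].size_mm3 == 27.0 * 40  # extent of the larger cluster

    def test_opposite_directions_yield_two_sdrs(self):
        up = _clus([(i, 0, 0) for i in range(10)], "PTSD_vs_CC", True)
        down = _clus([(i, 1, 0) for i in range(5, 15)], "PTSD_vs_CC", False)
        cec = _clus([(i, 0, 0) for i in range(5, 12)] + [(i, 1, 0) for i in range(5, 12)],
                    "CEC_vs_CC", True)
        recs = resolve_sdr_patterns([(up, False), (down, False), (cec, False)], 1)
        assert len(recs) == 2
        patterns = {r.pattern for r in recs}
        assert "Combat Increasing" in patterns
        assert "PTSD<CC" in patterns

    def test_disjoint_cluster_single_pattern(self):
        c = _clus([(0, 0, 0), (0, 0, 1)], "PTSD_vs_CC", False)
        recs = resolve_sdr_patterns([(c, True)], 4)
        assert len(recs) == 1
        assert recs[0].pattern == "PTSD<CC"
        assert recs[0].survives_bonferroni
        assert recs[0].sdr_id == "4-1"
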