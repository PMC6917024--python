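"""Group decomposition: PCA stages, Infomax, ICASSO, flags, matching."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from restica.decomposition import (
    _abs_corr,
    edge_shell,
    flag_artifacts,
    group_pca_concat,
    highfreq_power_fraction,
    icasso_select,
    infomax_ica,
    match_components,
    subject_pca,
    zscore_map,
)


class TestSubjectPCA:
    def test_exact_rank_fully_retained(self, rng):
        x = rng.standard_normal((50, 5)) @ rng.standard_normal((5, 400))
        res = subject_pca(x, 5)
        assert res.retained_variance == pytest.approx(1.0, abs=1e-9)

    def test_full_dimension_retains_everything(self, rng):
        x = rng.standard_normal((20, 300))
        assert subject_pca(x, 20).retained_variance == pytest.approx(1.0, abs=1e-9)

    def test_retained_matches_svd_oracle(self, rng):
        x = rng.standard_normal((50, 1000))
        res = subject_pca(x, 10)
        xc = x - x.mean(axis=0, keepdims=True)
        sv = np.linalg.svd(xc, compute_uv=False) ** 2
        assert res.retained_variance == pytest.approx(sv[:10].sum() / sv.sum(), abs=1e-9)

    def test_rows_orthogonal(self, rng):
        red = subject_pca(rng.standard_normal((30, 500)), 8).reduced
        gram = red @ red.T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_d1_exceeding_t_rejected(self, rng):
        with pytest.raises(ValueError):
            subject_pca(rng.standard_normal((10, 50)), 11)


def _principal_angles(a, b):
    qa, _ = np.linalg.qr(a.T)
    qb, _ = np.linalg.qr(b.T)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.degrees(np.arccos(np.clip(s, -1, 1)))


class TestGroupPCA:
    def test_whitened_identity_covariance(self, rng):
        reds = [subject_pca(rng.standard_normal((30, 800)), 10).reduced for _ in range(3)]
        y = group_pca_concat(reds, 6)
        cov = y @ y.T / y.shape[1]
        assert np.abs(cov - np.eye(6)).max() < 1e-8

    def test_single_subject_spans_pca_subspace(self, rng):
        x = rng.standard_normal((30, 500))
        red = subject_pca(x, 8).reduced
        y = group_pca_concat([red], 8)
        assert _principal_angles(red - red.mean(1, keepdims=True), y).max() < 1e-5

    def test_duplicated_subject_adds_nothing(self, rng):
        x = rng.standard_normal((30, 500))
        red = subject_pca(x, 8).reduced
        y1 = group_pca_concat([red], 8)
        y2 = group_pca_concat([red, red], 8)
        assert _principal_angles(y1, y2).max() < 1e-5

    def test_inconsistent_voxel_counts_rejected(self, rng):
        a = rng.standard_normal((5, 100))
        b = rng.standard_normal((5, 101))
        with pytest.raises(ValueError):
            group_pca_concat([a, b], 4)

    def test_signal_subspace_captured(self):
        """With d equal to the number of planted networks, the group-reduced
        subspace contains nearly all of the noiseless map energy (planted
        group effects add directions of their own, so they are off here)."""
        from restica import make_ground_truth, simulate_cohort

        gt = make_ground_truth(
            grid_shape=(16, 16, 16), n_timepoints=100, effect_delta=0.0,
            fnc_pair=None, symptom_beta=0.0, seed=2,
        )
        cohort = simulate_cohort(gt, (4, 3, 3), seed=2)
        mask = cohort.brain_mask
        reds = [subject_pca(s, 30).reduced for s in cohort.subjects]
        y = group_pca_concat(reds, gt.n_networks)
        q, _ = np.linalg.qr(y.T)  # orthonormal basis of the subspace
        truth = gt.network_maps[:, mask].copy()
        truth = truth - truth.mean(axis=1, keepdims=True)
        proj = (truth @ q) @ q.T
        captured = (proj**2).sum() / (truth**2).sum()
        assert captured >= 0.99


class TestInfomax:
    def test_recovers_independent_uniform_sources(self, rng):
        s = rng.uniform(-np.sqrt(3), np.sqrt(3), size=(2, 20000))
        a = rng.standard_normal((2, 2))
        x = a @ s
        x = x - x.mean(axis=1, keepdims=True)
        cov = x @ x.T / x.shape[1]
        evals, evecs = np.linalg.eigh(cov)
        white = (evecs / np.sqrt(evals)).T @ x
        res = infomax_ica(white, seed=0)
        corr = _abs_corr(res.sources, s)
        assert sorted(corr.max(axis=1))[0] > 0.99

    def test_deterministic_given_seed(self, rng):
        s = rng.uniform(-1, 1, size=(3, 5000))
        a = infomax_ica(s, seed=42)
        b = infomax_ica(s, seed=42)
        assert np.array_equal(a.sources, b.sources)

    def test_sources_decorrelated(self, small_decomp):
        k = small_decomp.model_order
        flat = small_decomp.group_maps.reshape(k, -1)
        r = np.corrcoef(flat)
        assert np.abs(r[~np.eye(k, dtype=bool)]).max() < 0.05

    def test_gaussian_input_warns_but_returns(self, rng):
        x = rng.standard_normal((2, 20000))
        x = x - x.mean(axis=1, keepdims=True)
        cov = x @ x.T / x.shape[1]
        evals, evecs = np.linalg.eigh(cov)
        white = (evecs / np.sqrt(evals)).T @ x
        with pytest.warns(UserWarning, match="Gaussian"):
            res = infomax_ica(white, seed=1)
        assert res.gaussian_warning


class TestIcasso:
    def test_stable_sources_high_iq_and_best_run(self, rng):
        s = rng.uniform(-1, 1, size=(3, 8000))
        res = icasso_select(s, n_runs=5, seed=0)
        assert res.stability_iq.shape == (3,)
        assert (res.stability_iq > 0.9).all()
        # exhaustive check: no other run beats the selected one on similarity
        # to its own components' best matches across runs
        cents = res.sources
        scores = [
            _abs_corr(run, cents).max(axis=1).sum() for run in res.run_sources
        ]
        assert scores[res.best_run] >= max(scores) - 1e-9

    def test_needs_two_runs(self, rng):
        with pytest.raises(ValueError):
            icasso_select(rng.standard_normal((2, 100)), n_runs=1)

    def test_iq_within_unit_interval(self, small_decomp):
        assert (small_decomp.stability_iq >= 0).all()
        assert (small_decomp.stability_iq <= 1).all()


class TestZscoreMap:
    def test_hand_case(self):
        m = np.array([[[1.0, 2.0, 3.0]]])
        mask = np.ones_like(m, dtype=bool)
        out = zscore_map(m, mask)
        assert np.allclose(out.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_idempotent_and_scale_invariant(self, rng):
        m = rng.standard_normal((6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.3
        z1 = zscore_map(m, mask)
        assert np.allclose(zscore_map(z1, mask), z1, atol=1e-9)
        assert np.allclose(zscore_map(10 * m, mask), z1, atol=1e-9)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zscore_map(np.ones((4, 4, 4)), np.ones((4, 4, 4), dtype=bool))


class TestArtifactFlags:
    def test_edge_component_flagged(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[2:10, 2:10, 2:10] = True
        shell = edge_shell(mask)
        comp = np.where(shell, 5.0, 0.0)
        flags = flag_artifacts(comp[None], mask)
        assert flags[0][0] and "edge_ring" in flags[0][1]

    def test_interior_slow_component_clean(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[2:10, 2:10, 2:10] = True
        comp = np.zeros((12, 12, 12))
        comp[5:7, 5:7, 5:7] = 5.0
        t = np.arange(100) * 3.0
        tc = np.cos(2 * np.pi * 0.02 * t)
        flags = flag_artifacts(comp[None], mask, timecourses=tc[None], tr_s=3.0)
        assert not flags[0][0]

    def test_white_noise_highfreq_fraction_near_expectation(self, rng):
        """At TR 3 s the band above 0.10 Hz carries ~40% of white-noise power
        in expectation, below the 0.5 flagging threshold."""
        fracs = [
            highfreq_power_fraction(rng.standard_normal(150), 3.0) for _ in range(200)
        ]
        assert np.mean(fracs) == pytest.approx(0.40, abs=0.05)

    def test_manual_override_wins(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[1:7, 1:7, 1:7] = True
        comp = np.zeros((8, 8, 8))
        comp[3:5, 3:5, 3:5] = 5.0
        flags = flag_artifacts(comp[None], mask, manual_override={0: True})
        assert flags[0] == (True, ["manual_override"])


class TestMatchComponents:
    def test_self_matching_perfect(self, rng):
        maps = rng.standard_normal((4, 6, 6, 6))
        labels = match_components(maps, maps)
        assert all(l.matched_reference == l.component for l in labels)
        assert all(abs(l.spatial_r - 1) < 1e-12 for l in labels)

    def test_uncorrelated_maps_unmatched(self, rng):
        maps = rng.standard_normal((2, 8, 8, 8))
        templates = rng.standard_normal((2, 8, 8, 8))
        labels = match_components(maps, templates)
        assert all(l.matched_reference is None for l in labels)
        assert all(abs(l.spatial_r) < 0.2 for l in labels)

    def test_greedy_equals_optimal_assignment(self, small_cohort, small_decomp):
        gt = small_cohort.ground_truth
        labels = match_components(
            small_decomp.group_maps, gt.network_maps, mask=gt.brain_mask
        )
        gm = small_decomp.group_maps[:, gt.brain_mask]
        tm = gt.network_maps[:, gt.brain_mask]
        corr = np.abs(np.corrcoef(gm, tm)[: len(gm), len(gm):])
        rows, cols = linear_sum_assignment(-corr)
        optimal = dict(zip(rows, cols))
        for l in labels:
            assert l.matched_reference == optimal[l.component]
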