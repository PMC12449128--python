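"""PLS decompositions, resampling inference and latent regressions."""

import numpy as np
import pandas as pd
import pytest

from beliefvar import pls


class TestTaskPLS:
    def test_rank_one_structure_recovered(self, rng):
        # two conditions differing by a fixed voxel pattern d
        d = rng.normal(0, 1, 50)
        brain = np.zeros((10, 2, 50))
        brain[:, 1, :] = d
        brain += rng.normal(0, 1e-6, brain.shape)
        res = pls.task_pls(brain)
        sal = res.saliences[:, 0]
        r = np.corrcoef(sal, d)[0, 1]
        assert abs(r) > 0.9999
        assert res.explained[0] > 0.999

    def test_brain_scores_are_projections(self, rng):
        brain = rng.normal(0, 1, (6, 3, 20))
        res = pls.task_pls(brain)
        manual = brain @ res.saliences[:, 0]
        assert np.allclose(res.brain_scores[:, :, 0], manual)

    def test_svd_reconstruction(self, rng):
        brain = rng.normal(0, 1, (8, 4, 30))
        model = pls.TaskPLS(brain)
        mat = model._crossblock(brain)
        res = model.fit()
        rebuilt = (res.weights * res.singular_values) @ res.saliences.T
        assert np.allclose(rebuilt, mat, atol=1e-8)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            pls.TaskPLS(rng.normal(0, 1, (5, 1, 10)))
        with pytest.raises(ValueError):
            pls.TaskPLS(rng.normal(0, 1, (2, 3, 10)))

    def test_planted_condition_effect_detected(self, rng):
        brain = rng.normal(0, 0.5, (12, 5, 40))
        brain += np.linspace(1, 0, 5)[None, :, None]
        res = pls.task_pls(brain, n_perm=200, seed=0)
        assert res.perm_p[0] <= 1 / 201 + 1e-12


class TestBehavioralPLS:
    def test_duplicate_behavior_columns_one_lv(self, rng):
        beh = rng.normal(0, 1, 20)
        brain = beh[:, None] * rng.normal(0, 1, 60)[None, :]
        res = pls.behavioral_pls(brain, np.column_stack([beh, beh]))
        assert res.explained[0] > 0.999

    def test_planted_pattern_recovered(self, rng):
        beh = rng.normal(0, 1, 40)
        pattern = rng.normal(0, 1, 200)
        signal = beh[:, None] * pattern[None, :]
        brain = signal + rng.normal(0, signal.std(), signal.shape)  # SNR 1
        res = pls.behavioral_pls(brain, beh, n_perm=200, seed=1)
        assert res.perm_p[0] < 0.05
        assert abs(np.corrcoef(res.saliences[:, 0], pattern)[0, 1]) > 0.9

    def test_rank_invariance_under_monotone_transform(self, rng):
        beh = rng.uniform(1, 2, 15)
        brain = rng.normal(0, 1, (15, 30))
        a = pls.behavioral_pls(brain, beh, rank=True)
        b = pls.behavioral_pls(brain, np.exp(3 * beh), rank=True)
        assert np.allclose(a.singular_values, b.singular_values)
        assert np.allclose(a.saliences, b.saliences)

    def test_constant_behavior_rejected(self, rng):
        with pytest.raises(ValueError):
            pls.behavioral_pls(rng.normal(0, 1, (10, 5)), np.ones(10))

    def test_permutation_p_lower_bound_on_planted_signal(self, rng):
        beh = rng.normal(0, 1, 30)
        brain = beh[:, None] * np.ones((1, 50)) + rng.normal(0, 0.1, (30, 50))
        res = pls.behavioral_pls(brain, beh, n_perm=500, seed=2)
        assert res.perm_p[0] == pytest.approx(1 / 501)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 120
        for _ in range(n_rep):
            brain = rng.normal(0, 1, (16, 40))
            beh = rng.normal(0, 1, 16)
            res = pls.behavioral_pls(
                brain, beh, n_perm=200, seed=int(rng.integers(2**31))
            )
            hits += res.perm_p[0] < 0.05
        assert 0.01 < hits / n_rep < 0.10


class TestBootstrap:
    def test_zero_noise_pattern_gives_huge_bsr(self, rng):
        beh = rng.normal(0, 1, 20)
        pattern = np.r_[np.ones(10), np.zeros(10)]
        brain = beh[:, None] * pattern[None, :] + rng.normal(0, 1e-4, (20, 20))
        res = pls.behavioral_pls(brain, beh, rank=False, n_boot=200, seed=3)
        assert np.all(np.abs(res.bsr[:10, 0]) > 3)

    def test_null_voxels_rarely_exceed_threshold(self, rng):
        beh = rng.normal(0, 1, 30)
        pattern = np.r_[np.ones(20), np.zeros(180)]
        brain = beh[:, None] * pattern[None, :] + rng.normal(0, 1.0, (30, 200))
        res = pls.behavioral_pls(brain, beh, n_boot=300, seed=4)
        null_rate = (np.abs(res.bsr[20:, 0]) > 3).mean()
        assert null_rate < 0.05


class TestClusterThreshold:
    @staticmethod
    def _volume_with_blob(size):
        vol = np.zeros((12, 12, 12), dtype=bool)
        n = 0
        for idx in np.ndindex(4, 4, 4):
            if n >= size:
                break
            vol[2 + idx[0], 2 + idx[1], 2 + idx[2]] = True
            n += 1
        return vol

    def test_subthreshold_blob_removed(self):
        pruned, table = pls.cluster_threshold(self._volume_with_blob(24))
        assert pruned.sum() == 0 and table.empty

    def test_threshold_blob_retained(self):
        pruned, table = pls.cluster_threshold(self._volume_with_blob(25))
        assert pruned.sum() == 25
        assert table.iloc[0]["size"] == 25

    def test_touching_blobs_merge_under_face_connectivity(self):
        vol = np.zeros((10, 10, 10), dtype=bool)
        vol[1:4, 1:4, 1:4] = True  # 27 voxels
        vol[4, 1:4, 1:4] = True  # face-adjacent slab, 9 voxels
        _, table = pls.cluster_threshold(vol)
        assert len(table) == 1 and table.iloc[0]["size"] == 36

    def test_diagonal_blobs_do_not_merge(self):
        vol = np.zeros((12, 12, 12), dtype=bool)
        vol[0:3, 0:3, 0:3] = True  # 27
        vol[3:6, 3:6, 3:6] = True  # corner-touching only
        _, table = pls.cluster_threshold(vol)
        assert len(table) == 2

    def test_peak_bsr_reported(self):
        vol = self._volume_with_blob(30)
        bsr = np.zeros(vol.shape)
        bsr[3, 3, 3] = -7.0
        bsr[vol & (bsr == 0)] = 3.5
        _, table = pls.cluster_threshold(vol, bsr_volume=bsr)
        assert table.iloc[0]["peak_bsr"] == -7.0


class TestCooksScreen:
    def test_gross_outlier_flagged(self, rng):
        x = np.linspace(0, 1, 25)
        y = 2 * x + rng.normal(0, 0.01, 25)
        x = np.r_[x, 3.0]
        y = np.r_[y, -5.0]
        flagged = pls.cooks_screen(x, y)
        assert 25 in flagged

    def test_exact_fit_no_flags(self):
        x = np.linspace(0, 1, 10)
        assert pls.cooks_screen(x, 3 * x + 1).size == 0

    def test_flag_set_monotone_in_threshold(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 0.5, 30)
        loose = set(pls.cooks_screen(x, y, threshold_factor=4.0))
        strict = set(pls.cooks_screen(x, y, threshold_factor=8.0))
        assert strict <= loose


class TestSpatiallyMatchedLatent:
    def test_self_consistency(self, rng):
        brain = rng.normal(0, 1, (10, 25))
        beh = rng.normal(0, 1, 10)
        res = pls.behavioral_pls(brain, beh, rank=False)
        scores = pls.spatially_matched_latent(res.saliences[:, 0], brain)
        # projecting the analysis' own (unranked) brain data reproduces scores
        assert np.allclose(scores, res.brain_scores[:, 0])

    def test_orthogonal_measure_scores_zero(self, rng):
        sal = np.zeros(10)
        sal[0] = 1.0
        measure = np.zeros((4, 10))
        measure[:, 1:] = rng.normal(0, 1, (4, 9))
        assert np.allclose(pls.spatially_matched_latent(sal, measure), 0.0)

    def test_linearity(self, rng):
        sal = rng.normal(0, 1, 15)
        a = rng.normal(0, 1, (6, 15))
        b = rng.normal(0, 1, (6, 15))
        assert np.allclose(
            pls.spatially_matched_latent(sal, a + b),
            pls.spatially_matched_latent(sal, a) + pls.spatially_matched_latent(sal, b),
        )

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            pls.spatially_matched_latent(np.ones(5), rng.normal(0, 1, (3, 4)))


class TestLatentRegression:
    def test_exact_linear_fit(self):
        x = np.arange(10.0)
        res = pls.latent_regression(2 * x + 1, pd.DataFrame({"x": x}), rank=False)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            y = rng.normal(0, 1, 25)
            X = pd.DataFrame({"a": rng.normal(0, 1, 25)})
            hits += pls.latent_regression(y, X)["predictors"]["p"].iloc[0] < 0.05
        assert 0.025 < hits / n_rep < 0.08

    def test_semi_partial_eta2_orthogonal_predictors(self, rng):
        n = 200
        a = rng.normal(0, 1, n)
        b = rng.normal(0, 1, n)
        y = 2 * a + 0.5 * b + rng.normal(0, 0.5, n)
        res = pls.latent_regression(y, pd.DataFrame({"a": a, "b": b}), rank=False)
        tab = res["predictors"].set_index("predictor")
        assert tab.loc["a", "semi_partial_eta2"] > tab.loc["b", "semi_partial_eta2"]
        # with near-orthogonal predictors the unique shares sum to ~R^2
        total = tab["semi_partial_eta2"].sum()
        assert total == pytest.approx(res["r_squared"], abs=0.05)


class TestPolynomialContrasts:
    def test_linear_decline_dominant(self, rng):
        scores = np.linspace(1, 0, 5)[None, :] + rng.normal(0, 0.01, (12, 5))
        tab = pls.polynomial_contrasts(scores).set_index("order")
        assert tab.loc["linear", "F"] > 50 * tab.loc["quadratic", "F"]
        assert tab.loc["linear", "F"] > 50 * tab.loc["cubic", "F"]

    def test_u_shape_quadratic_dominant(self, rng):
        shape = np.array([1.0, 0.2, 0.0, 0.2, 1.0])
        scores = shape[None, :] + rng.normal(0, 0.01, (12, 5))
        tab = pls.polynomial_contrasts(scores).set_index("order")
        assert tab.loc["quadratic", "F"] > tab.loc["linear", "F"]
        assert tab.loc["quadratic", "F"] > tab.loc["cubic", "F"]

    def test_contrast_weights_orthogonal_zero_sum(self):
        w = list(pls.POLY_WEIGHTS.values())
        for v in w:
            assert v.sum() == 0
        for i in range(3):
            for j in range(i + 1, 3):
                assert w[i] @ w[j] == 0
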