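"""HRF basis, design matrices, LS-S betas, SD_BOLD maps and GLMs."""

import numpy as np
import pandas as pd
import pytest

from beliefvar import glm
from beliefvar.bold_sim import BoldRun

TR = 0.645


def make_events(onsets, trial_types=None, durations=1.0, trial_ids=None):
    n = len(onsets)
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": np.broadcast_to(durations, n).astype(float),
            "trial_type": trial_types or ["sample_1"] * n,
            "trial_id": trial_ids if trial_ids is not None else np.arange(n),
        }
    )


def synth_run(events, amplitudes, n_scans, noise_sd=0.0, seed=0, tr=TR):
    """Noise-free (or white-noise) run whose signal uses the canonical HRF."""
    reg = glm._event_regressors(
        events["onset"], events["duration"], np.ones(len(events)), tr, n_scans
    )[:, :, 0]
    data = reg @ np.atleast_2d(amplitudes)
    if noise_sd:
        data = data + np.random.default_rng(seed).normal(0, noise_sd, data.shape)
    return BoldRun(data=data, tr=tr, events=events, run_id=0)


class TestHrfBasis:
    def test_canonical_peak_location(self):
        basis = glm.hrf_basis(0.05)
        peak_t = float(np.argmax(basis[0]) * 0.05)
        assert 4.0 < peak_t < 7.0
        assert basis[0].max() == pytest.approx(1.0)

    def test_temporal_derivative_integrates_to_zero(self):
        basis = glm.hrf_basis(0.05, length=40.0)
        assert abs(basis[1].sum() * 0.05) < 0.05 * np.abs(basis[1]).sum() * 0.05 + 1e-2

    def test_sampling_converges(self):
        fine = glm.hrf_basis(0.005)[0]
        t_fine = np.arange(fine.size) * 0.005

        def gap(tr):
            c = glm.hrf_basis(tr)[0]
            return np.max(np.abs(c - np.interp(np.arange(c.size) * tr, t_fine, fine)))

        gaps = [gap(tr) for tr in (0.1, 0.05, 0.02)]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.01

    def test_invalid_tr(self):
        with pytest.raises(ValueError):
            glm.hrf_basis(0.0)


class TestBuildDesign:
    def test_seven_conditions_give_21_plus_constant(self):
        onsets, types = [], []
        for k, cond in enumerate(
            [f"sample_{i}" for i in range(1, 6)] + ["estimation", "gamble"]
        ):
            onsets += [10.0 + 30 * k, 200.0 + 30 * k]
            types += [cond, cond]
        design = glm.build_design(make_events(onsets, types), TR, 700)
        assert design.values.shape[1] == 22
        assert design.names[-1] == "constant"
        tags = set(design.basis_tags.values())
        assert tags == {"canonical", "derivative", "dispersion", "constant"}

    def test_event_past_run_end_rejected(self):
        with pytest.raises(ValueError):
            glm.build_design(make_events([10.0, 900.0]), TR, 100)

    def test_convolution_linearity(self):
        # pooled regressor equals the sum of single-event regressors
        ev = make_events([10.0, 40.0, 90.0])
        pooled = glm.build_design(ev, TR, 300).frame["sample_1"].to_numpy()
        singles = glm._event_regressors(
            ev["onset"], ev["duration"], np.ones(3), TR, 300
        )[:, :, 0]
        assert np.allclose(pooled, singles.sum(axis=1), atol=1e-10)


class TestLssBetas:
    def test_isolated_events_recover_amplitudes(self):
        # amplitudes vary across voxels, constant across trials, so the
        # pooled-other regressor fits the remaining events exactly
        onsets = np.arange(6) * 40.0 + 5.0
        ev = make_events(onsets)
        amps = np.ones((6, 1)) * np.array([[1.0, 2.0, 0.5]])
        run = synth_run(ev, amps, n_scans=450)
        out = glm.lss_betas(run, "sample_1")
        assert out.betas.shape == (6, 3)
        assert np.allclose(out.betas, amps, atol=1e-6)

    def test_equals_per_trial_ols_when_isolated(self):
        onsets = np.arange(5) * 50.0 + 5.0
        ev = make_events(onsets)
        amps = np.ones((5, 1)) * np.array([[1.0, 0.7]])
        run = synth_run(ev, amps, n_scans=430)
        lss = glm.lss_betas(run, "sample_1")
        # standard per-trial OLS: all events as separate regressors
        reg = glm._event_regressors(
            ev["onset"], ev["duration"], np.ones(5), TR, 430
        )
        X = np.hstack([reg.reshape(430, -1), np.ones((430, 1))])
        ols = np.linalg.lstsq(X, run.data, rcond=None)[0]
        ols_canonical = ols[0 : 15 : 3]
        assert np.allclose(lss.betas, ols_canonical, atol=1e-8)

    def test_close_to_per_trial_ols_with_varying_amplitudes(self):
        # with heterogeneous amplitudes the two models differ only through
        # the shared baseline column; agreement is approximate
        onsets = np.arange(5) * 50.0 + 5.0
        ev = make_events(onsets)
        rng = np.random.default_rng(1)
        amps = rng.uniform(0.5, 2.0, (5, 2))
        run = synth_run(ev, amps, n_scans=430, noise_sd=0.3)
        lss = glm.lss_betas(run, "sample_1")
        reg = glm._event_regressors(
            ev["onset"], ev["duration"], np.ones(5), TR, 430
        )
        X = np.hstack([reg.reshape(430, -1), np.ones((430, 1))])
        ols = np.linalg.lstsq(X, run.data, rcond=None)[0][0:15:3]
        assert np.allclose(lss.betas, ols, atol=0.02)

    def test_final_window_events_discarded(self):
        n_scans = 400
        run_end = n_scans * TR
        onsets = [5.0, 60.0, 120.0, run_end - 10.0]
        run = synth_run(make_events(onsets), np.ones((4, 1)), n_scans)
        out = glm.lss_betas(run, "sample_1")
        assert out.trial_ids == [0, 1, 2]

    def test_constant_offset_absorbed(self):
        onsets = np.arange(4) * 45.0 + 5.0
        ev = make_events(onsets)
        run = synth_run(ev, np.ones((4, 1)) * 2.0, n_scans=330)
        shifted = BoldRun(data=run.data + 7.5, tr=TR, events=ev, run_id=0)
        a = glm.lss_betas(run, "sample_1").betas
        b = glm.lss_betas(shifted, "sample_1").betas
        assert np.allclose(a, b, atol=1e-8)

    def test_too_few_events_rejected(self):
        run = synth_run(make_events([5.0]), np.ones((1, 1)), 200)
        with pytest.raises(ValueError):
            glm.lss_betas(run, "sample_1")


class TestSdBold:
    def test_sample_sd_closed_form(self):
        bm = glm.TrialBetaMatrix("sample_1", np.array([[1.0], [2.0], [3.0]]), [0, 1, 2])
        out = glm.sd_bold([bm])
        assert out.sd[0, 0] == pytest.approx(1.0)

    def test_identical_betas_zero_sd(self):
        bm = glm.TrialBetaMatrix("sample_1", np.ones((5, 2)), list(range(5)))
        assert np.allclose(glm.sd_bold([bm]).sd, 0.0)

    def test_pooled_across_runs(self):
        a = glm.TrialBetaMatrix("sample_1", np.array([[1.0], [2.0]]), [0, 1])
        b = glm.TrialBetaMatrix("sample_1", np.array([[3.0]]), [2])
        out = glm.sd_bold([a, b])
        assert out.n_trials["sample_1"] == 3
        assert out.sd[0, 0] == pytest.approx(1.0)

    def test_single_trial_rejected(self):
        bm = glm.TrialBetaMatrix("sample_1", np.ones((1, 2)), [0])
        with pytest.raises(ValueError):
            glm.sd_bold([bm])

    def test_scale_and_shift_invariance(self, rng):
        betas = rng.normal(0, 1, (20, 4))
        base = glm.TrialBetaMatrix("sample_1", betas, list(range(20)))
        shifted = glm.TrialBetaMatrix("sample_1", betas + 5.0, list(range(20)))
        scaled = glm.TrialBetaMatrix("sample_1", betas * 3.0, list(range(20)))
        assert np.allclose(glm.sd_bold([shifted]).sd, glm.sd_bold([base]).sd)
        assert np.allclose(glm.sd_bold([scaled]).sd, 3 * glm.sd_bold([base]).sd)


class TestSdboldChange:
    def test_linear_decline_slope(self):
        sd = np.array([[5.0], [4.0], [3.0], [2.0], [1.0]])
        m = glm.SDBoldMap(list(glm.SAMPLE_CONDITIONS), sd, {})
        assert glm.sdbold_change(m)[0] == pytest.approx(-1.0)

    def test_constant_zero_slope(self):
        m = glm.SDBoldMap(list(glm.SAMPLE_CONDITIONS), np.ones((5, 3)), {})
        assert np.allclose(glm.sdbold_change(m), 0.0)


class TestConditionMeanGlm:
    @staticmethod
    def _multi_cond_run(amp_by_cond, noise_sd=0.0):
        onsets, types, ids = [], [], []
        rng = np.random.default_rng(0)
        t = 8.0
        tid = 0
        for rep in range(6):
            for cond in glm.SAMPLE_CONDITIONS:
                onsets.append(t)
                types.append(cond)
                ids.append(tid)
                t += 14.0 + rng.uniform(0, 4)
            tid += 1
        ev = make_events(onsets, types, trial_ids=ids)
        amps = np.array([[amp_by_cond[c]] for c in types])
        return synth_run(ev, amps, n_scans=int(t / TR) + 60, noise_sd=noise_sd)

    def test_constant_amplitudes_equal_betas_cubic_zero(self):
        run = self._multi_cond_run({c: 2.0 for c in glm.SAMPLE_CONDITIONS})
        betas = glm.condition_mean_glm([run])
        assert np.allclose(betas.to_numpy(), 2.0, atol=1e-6)
        assert np.allclose(glm.condition_change(betas, "cubic"), 0.0, atol=1e-6)

    def test_betas_linear_in_amplitude(self):
        amp = {c: 1.0 + i for i, c in enumerate(glm.SAMPLE_CONDITIONS)}
        run = self._multi_cond_run(amp)
        betas = glm.condition_mean_glm([run])
        assert np.allclose(
            betas.to_numpy().ravel(), np.arange(1.0, 6.0), atol=1e-5
        )

    def test_matches_lss_trial_means_on_sparse_design(self):
        amp = {c: 1.5 for c in glm.SAMPLE_CONDITIONS}
        run = self._multi_cond_run(amp, noise_sd=0.1)
        betas = glm.condition_mean_glm([run])
        lss_means = [
            glm.lss_betas(run, c).betas.mean(axis=0) for c in glm.SAMPLE_CONDITIONS
        ]
        assert np.allclose(
            betas.loc[list(glm.SAMPLE_CONDITIONS)].to_numpy(),
            np.vstack(lss_means),
            atol=0.05,
        )


class TestParametricGlm:
    @staticmethod
    def _run_with_modulated_amps(coef, n_events=30, seed=0):
        rng = np.random.default_rng(seed)
        onsets = np.cumsum(rng.uniform(10, 16, n_events)) + 5.0
        types = [glm.SAMPLE_CONDITIONS[i % 5] for i in range(n_events)]
        ev = make_events(onsets, types)
        mod = rng.uniform(0.2, 1.0, n_events)
        amps = (1.0 + coef * (mod - mod.mean()))[:, None]
        run = synth_run(ev, amps, n_scans=int(onsets[-1] / TR) + 60)
        return run, mod

    @pytest.mark.parametrize("coef", [2.0, -2.0])
    def test_sign_recovered(self, coef):
        run, mod = self._run_with_modulated_amps(coef)
        beta = glm.parametric_uncertainty_glm([run], [mod])
        assert np.sign(beta[0]) == np.sign(coef)
        assert beta[0] == pytest.approx(coef, rel=0.15)

    def test_modulator_shift_invariance(self):
        run, mod = self._run_with_modulated_amps(1.5)
        a = glm.parametric_uncertainty_glm([run], [mod])
        b = glm.parametric_uncertainty_glm([run], [mod + 10.0])
        assert np.allclose(a, b, atol=1e-8)

    def test_constant_modulator_rejected(self):
        run, mod = self._run_with_modulated_amps(1.0)
        with pytest.raises(ValueError):
            glm.parametric_uncertainty_glm([run], [np.full_like(mod, 0.3)])

    def test_count_mismatch_rejected(self):
        run, mod = self._run_with_modulated_amps(1.0)
        with pytest.raises(ValueError):
            glm.parametric_uncertainty_glm([run], [mod[:-1]])


class TestSplitHalf:
    def test_duplicated_halves_perfect(self, rng):
        half = rng.normal(0, 1, (10, 50))
        bm = glm.TrialBetaMatrix(
            "sample_1", np.vstack([half, half]), list(range(20))
        )
        out = glm.split_half_reliability([bm])
        assert out["sample_1"] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(40):
            bm = glm.TrialBetaMatrix(
                "sample_1", rng.normal(0, 1, (40, 200)), list(range(40))
            )
            rs.append(glm.split_half_reliability([bm])["sample_1"])
        assert abs(np.median(rs)) < 0.2
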