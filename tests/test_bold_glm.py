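"""AM-GLM pipeline: preprocessing, confound model, nuisance regression,
AM regressor construction, per-unit OLS, fixed effects, group level."""

import numpy as np
import pytest

from attn_states import (HRFSpec, build_am_regressor, build_confound_matrix,
                         combine_runs_fixed_effects, fit_am_glm,
                         group_level_glm, preprocess_bold, regress_nuisance)
from attn_states.bold_glm import GLMResult, sample_hrf, t_to_z
from attn_states.synthetic import BoldRun

from conftest import convolve_oracle


def toy_run(n_parcels=3, n_frames=50, tr=0.8, seed=0, const=None):
    rng = np.random.default_rng(seed)
    sig = (np.full((n_parcels, n_frames), const, dtype=float) if const is not None
           else rng.normal(100, 1, (n_parcels, n_frames)))
    return BoldRun(signal=sig, tr_s=tr,
                   motion=rng.normal(0, 0.1, (n_frames, 6)),
                   tissue=rng.normal(100, 1, (n_frames, 3)))


class TestPreprocess:
    def test_identity_mode(self):
        run = toy_run()
        out = preprocess_bold(run, n_drop_frames=0, normalize="none")
        np.testing.assert_array_equal(out.signal, run.signal)
        assert out.t0_s == 0.0

    def test_constant_series_scaled_to_100(self):
        out = preprocess_bold(toy_run(const=37.0), 0, "mean100")
        np.testing.assert_allclose(out.signal, 100.0)

    def test_frame_drop_shifts_time_origin(self):
        run = toy_run(n_frames=400)
        out = preprocess_bold(run, n_drop_frames=8, normalize="none")
        assert out.n_frames == 392
        assert out.t0_s == pytest.approx(8 * 0.8)
        assert out.motion.shape[0] == 392

    def test_dropping_all_frames_rejected(self):
        with pytest.raises(ValueError):
            preprocess_bold(toy_run(n_frames=5), n_drop_frames=5)


class TestConfoundMatrix:
    def test_has_21_columns(self):
        C = build_confound_matrix(np.random.default_rng(0).normal(size=(30, 6)),
                                  np.zeros((30, 3)))
        assert C.shape == (30, 21)

    def test_zero_motion_gives_zero_motion_columns(self):
        C = build_confound_matrix(np.zeros((30, 6)), np.ones((30, 3)))
        np.testing.assert_array_equal(C[:, :18], 0.0)
        np.testing.assert_array_equal(C[:, 18:], 1.0)

    def test_derivative_of_ramp_is_constant_after_padding(self):
        motion = np.outer(np.arange(20.0), np.ones(6))
        C = build_confound_matrix(motion, np.zeros((20, 3)))
        deriv = C[:, 6:12]
        np.testing.assert_array_equal(deriv[0], 0.0)
        np.testing.assert_allclose(deriv[1:], 1.0)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError):
            build_confound_matrix(np.zeros((10, 5)), np.zeros((10, 3)))


class TestNuisanceRegression:
    def test_residuals_orthogonal_to_every_column(self):
        rng = np.random.default_rng(1)
        C = build_confound_matrix(rng.normal(size=(200, 6)),
                                  rng.normal(size=(200, 3)))
        Y = rng.normal(size=(5, 200))
        R = regress_nuisance(Y, C)
        for j in range(C.shape[1]):
            dots = np.abs(R @ C[:, j])
            assert (dots < 1e-8 * np.linalg.norm(R, axis=1)
                    * np.linalg.norm(C[:, j])).all()

    def test_confound_equal_signal_removed_entirely(self):
        rng = np.random.default_rng(2)
        C = rng.normal(size=(100, 4))
        Y = C[:, 1][None, :].copy()
        R = regress_nuisance(Y, C)
        np.testing.assert_allclose(R, 0.0, atol=1e-10)

    def test_projection_contracts_variance(self):
        rng = np.random.default_rng(3)
        C = rng.normal(size=(150, 10))
        Y = rng.normal(size=(8, 150))
        R = regress_nuisance(Y, C)
        assert (R.var(axis=1) <= Y.var(axis=1) + 1e-12).all()

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        C = rng.normal(size=(100, 3))
        C = np.hstack([C, C[:, :1] * 2.0])  # duplicate direction
        Y = rng.normal(size=(2, 100))
        with pytest.warns(UserWarning):
            R = regress_nuisance(Y, C)
        assert np.isfinite(R).all()


class TestAMRegressor:
    def test_centered_zero_amplitudes_give_zero_regressor(self):
        reg = build_am_regressor(np.full(5, 3.3), np.arange(5) * 3.0, 0.8,
                                 HRFSpec(), 60)
        np.testing.assert_allclose(reg, 0.0, atol=1e-12)

    def test_single_impulse_is_scaled_kernel(self):
        hrf = HRFSpec()
        reg = build_am_regressor(np.array([2.0]), np.array([4.0]), 0.8, hrf,
                                 60, mean_center=False)
        kernel = sample_hrf(hrf, 0.8)
        expected = np.zeros(60)
        expected[5:5 + len(kernel)] = 2.0 * kernel
        np.testing.assert_allclose(reg, expected, atol=1e-12)

    def test_multi_trial_matches_convolution_oracle(self):
        rng = np.random.default_rng(5)
        onsets = np.cumsum(rng.uniform(2.0, 3.5, 20))
        amps = rng.normal(0, 1, 20)
        hrf = HRFSpec()
        n_frames = 120
        reg = build_am_regressor(amps, onsets, 0.8, hrf, n_frames)
        impulses = np.zeros(n_frames)
        centered = amps - amps.mean()
        for on, a in zip(onsets, centered):
            impulses[int(round(on / 0.8))] += a
        np.testing.assert_allclose(
            reg, convolve_oracle(impulses, sample_hrf(hrf, 0.8)), atol=1e-10)

    def test_onset_beyond_run_rejected(self):
        with pytest.raises(ValueError):
            build_am_regressor(np.array([1.0]), np.array([100.0]), 0.8,
                               HRFSpec(), 60)


class TestHRF:
    def test_gaussian_peaks_at_delay(self):
        k = sample_hrf(HRFSpec(kind="gaussian", peak_delay_s=5.0), 0.1)
        assert np.argmax(k) * 0.1 == pytest.approx(5.0, abs=0.1)
        assert k.max() == pytest.approx(1.0)

    def test_double_gamma_has_undershoot(self):
        k = sample_hrf(HRFSpec(kind="double_gamma", support_s=32.0), 0.1)
        assert k.max() == pytest.approx(1.0)
        assert k.min() < 0  # the post-peak undershoot

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HRFSpec(kind="boxcar")
        with pytest.raises(ValueError):
            HRFSpec(peak_delay_s=-1.0)


class TestAMGLMFit:
    def test_exact_linear_signal_recovers_slope(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 80)
        Y = 2.0 * x[None, :] + 5.0
        res = fit_am_glm(Y, x)
        assert res.beta[0] == pytest.approx(2.0, abs=1e-10)
        assert res.var[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_ols_on_toy(self):
        x = np.arange(10.0)
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0, 8.0, 7.0, 9.0, 11.0])
        # closed-form simple regression
        xc = x - x.mean()
        b = (xc @ y) / (xc @ xc)
        resid = y - y.mean() - b * xc
        s2 = (resid ** 2).sum() / 8
        var = s2 / (xc @ xc)
        res = fit_am_glm(y[None, :], x)
        assert res.beta[0] == pytest.approx(b)
        assert res.var[0] == pytest.approx(var)
        assert res.tstat[0] == pytest.approx(b / np.sqrt(var))
        assert res.dof == 8

    def test_zero_variance_regressor_rejected(self):
        with pytest.raises(ValueError):
            fit_am_glm(np.zeros((1, 10)), np.ones(10))


class TestFixedEffects:
    def test_equal_variances_give_simple_mean(self):
        r1 = GLMResult(np.array([1.0]), np.array([1.0]), np.array([1.0]), 10)
        r2 = GLMResult(np.array([3.0]), np.array([1.0]), np.array([3.0]), 10)
        out = combine_runs_fixed_effects([r1, r2])
        assert out.beta[0] == pytest.approx(2.0)
        assert out.var[0] == pytest.approx(0.5)

    def test_inverse_variance_weighting_closed_form(self):
        r1 = GLMResult(np.array([1.0]), np.array([0.5]), np.array([0.0]), 10)
        r2 = GLMResult(np.array([4.0]), np.array([2.0]), np.array([0.0]), 10)
        out = combine_runs_fixed_effects([r1, r2])
        w1, w2 = 2.0, 0.5
        assert out.beta[0] == pytest.approx((w1 * 1 + w2 * 4) / (w1 + w2))
        assert out.var[0] == pytest.approx(1 / (w1 + w2))

    def test_infinite_variance_run_gets_zero_weight(self):
        r1 = GLMResult(np.array([1.0]), np.array([np.inf]), np.array([0.0]), 10)
        r2 = GLMResult(np.array([3.0]), np.array([1.0]), np.array([3.0]), 10)
        out = combine_runs_fixed_effects([r1, r2])
        assert out.beta[0] == pytest.approx(3.0)
        assert out.var[0] == pytest.approx(1.0)


class TestGroupLevel:
    def test_matches_one_sample_t_oracle(self):
        B = np.array([[0.2], [0.5], [0.1], [0.4], [0.3]])
        gm = group_level_glm(B)
        m, s = B.mean(), B.std(ddof=1)
        t = m / (s / np.sqrt(5))
        z = t_to_z(np.array([t]), 4)[0]
        assert gm.beta[0] == pytest.approx(m)
        assert gm.z[0] == pytest.approx(z)

    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        B = rng.normal(0, 1, size=(100, 4000))
        gm = group_level_glm(B)
        fpr = np.mean(np.abs(gm.z) > 1.96)
        assert fpr == pytest.approx(0.05, abs=0.01)

    def test_degenerate_zero_residual_capped(self):
        B = np.full((5, 2), 1.3)
        with pytest.warns(UserWarning):
            gm = group_level_glm(B)
        assert np.isfinite(gm.z).all()
        assert (np.abs(gm.z) <= 40.0).all()

    def test_covariate_adjustment_changes_nothing_when_orthogonal(self):
        rng = np.random.default_rng(8)
        B = rng.normal(0.3, 1, size=(50, 20))
        cov = rng.normal(size=(50, 2))
        cov -= cov.mean(axis=0)
        gm0 = group_level_glm(B)
        gm1 = group_level_glm(B, covariates=cov)
        # intercept estimates agree closely; small dof difference in z
        np.testing.assert_allclose(gm0.beta, gm1.beta, atol=0.15)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            group_level_glm(np.zeros((2, 5)))


class TestTwoStepVersusJointFit:
    def test_two_step_equals_joint_only_after_orthogonalization(self):
        """Residualize-then-fit equals the joint model containing the
        confounds iff the AM regressor is first orthogonalized against
        them — the documented property of the two-step shortcut."""
        rng = np.random.default_rng(9)
        n = 120
        C = rng.normal(size=(n, 3))
        x = rng.normal(size=n) + 0.8 * C[:, 0]  # correlated with confound
        y = 1.5 * x + C @ [0.5, -0.3, 0.2] + rng.normal(0, 0.1, n)

        # joint OLS slope for x
        X = np.column_stack([np.ones(n), x, C])
        joint = np.linalg.lstsq(X, y, rcond=None)[0][1]

        resid_y = regress_nuisance(y[None, :], C)[0]
        two_step = fit_am_glm(resid_y[None, :], x).beta[0]
        assert two_step != pytest.approx(joint, abs=1e-6)

        x_orth = regress_nuisance(x[None, :], C)[0]
        two_step_orth = fit_am_glm(resid_y[None, :], x_orth).beta[0]
        assert two_step_orth == pytest.approx(joint, abs=1e-8)
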