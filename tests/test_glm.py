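"""GLM designs, OLS fitting, contrasts, FIR deconvolution, PSC scaling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stgboundary.glm import (
    block_hrf_kernel,
    build_block_design,
    build_tent_design,
    contrast_clear_vs_noisy,
    estimate_hrf_tent,
    fit_glm,
    localizer_response,
    scale_to_psc,
)
from stgboundary.synthetic import CONDITIONS, EventSchedule, make_event_schedule


def _motion(n, rng=None):
    if rng is None:
        rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.standard_normal((n, 6)) * 0.01, columns=[f"motion{i}" for i in range(6)]
    )


def _single_trial_schedule(onset_s=30.0):
    trials = pd.DataFrame(
        {
            "run": [0],
            "onset_s": [onset_s],
            "duration_s": [3.0],
            "condition": ["AclearVclear"],
        }
    )
    return EventSchedule(trials=trials, n_runs=1, tr_s=1.5, volumes_per_run=160)


class TestBlockDesign:
    def test_ten_regressors(self, schedule):
        dm = build_block_design(schedule, _motion(schedule.total_volumes))
        assert dm.n_columns == 10
        assert len(dm.columns_with_role("condition")) == 4
        assert len(dm.columns_with_role("motion")) == 6

    def test_no_events_motion_only(self):
        s = make_event_schedule(n_runs=1, trials_per_condition_per_run=0, seed=0)
        dm = build_block_design(s, _motion(160))
        assert dm.n_columns == 6
        assert dm.columns_with_role("condition") == []

    def test_single_trial_regressor_peaks_4p5_to_6s(self):
        """Convolution oracle: the isolated-trial response peaks 4.5-6 s
        after onset with the default kernel."""
        s = _single_trial_schedule(onset_s=30.0)
        dm = build_block_design(s, _motion(160))
        reg = dm.matrix["AclearVclear"].to_numpy()
        t_peak = np.argmax(reg) * 1.5 - 30.0
        assert 4.5 <= t_peak <= 6.0
        # unit continuous-time peak; TR sampling may land just off the crest
        assert 0.98 < reg.max() <= 1.0 + 1e-9

    def test_mismatched_motion_length_rejected(self, schedule):
        with pytest.raises(ValueError):
            build_block_design(schedule, _motion(10))


class TestTentDesign:
    def test_fifty_regressors_eleven_knots(self, schedule):
        dm = build_tent_design(schedule, _motion(schedule.total_volumes))
        assert dm.n_columns == 50  # 4 conditions x 11 knots + 6 motion
        assert dm.knot_times_s.size == 11
        assert np.allclose(np.diff(dm.knot_times_s), 1.5)

    def test_grid_aligned_trial_gives_unit_impulses(self):
        s = _single_trial_schedule(onset_s=30.0)  # on the TR lattice
        dm = build_tent_design(s, _motion(160) * 0.0)
        for ki, kt in enumerate(dm.knot_times_s):
            col = dm.matrix[f"AclearVclear@{kt:g}s"].to_numpy()
            expected = np.zeros(160)
            expected[int((30.0 + kt) / 1.5)] = 1.0
            assert np.allclose(col, expected)

    def test_window_tr_mismatch_rejected(self, schedule):
        with pytest.raises(ValueError, match="spacing"):
            build_tent_design(schedule, _motion(schedule.total_volumes), n_knots=7)


class TestScaleToPsc:
    def test_constant_series(self):
        out = scale_to_psc(np.full(50, 200.0))
        assert np.allclose(out, 100.0)

    def test_mean_exactly_100(self, rng):
        x = rng.uniform(800, 1200, (20, 300))
        out = scale_to_psc(x)
        assert np.allclose(out.mean(axis=1), 100.0, atol=1e-12)

    def test_idempotent(self, rng):
        x = rng.uniform(800, 1200, (5, 100))
        once = scale_to_psc(x)
        twice = scale_to_psc(once)
        assert np.allclose(once, twice)

    def test_beta_rescaling_algebra(self, rng):
        """beta in scaled units = raw beta x 100 / raw mean."""
        n = 160
        x = np.zeros(n)
        x[20:40] = 1.0
        raw = 900.0 + 5.0 * x + rng.standard_normal(n) * 0.5
        design = np.column_stack([x, np.ones(n)])
        b_raw = np.linalg.lstsq(design, raw, rcond=None)[0][0]
        b_scaled = np.linalg.lstsq(design, scale_to_psc(raw), rcond=None)[0][0]
        assert b_scaled == pytest.approx(b_raw * 100.0 / raw.mean(), rel=1e-10)

    def test_nonpositive_mean_masked(self):
        x = np.vstack([np.full(50, 100.0), np.full(50, -1.0)])
        out = scale_to_psc(x)
        assert np.isnan(out[1]).all() and not np.isnan(out[0]).any()


class TestFitGlm:
    @pytest.mark.parametrize("n,p", [(50, 4), (120, 12), (200, 54)])
    def test_betas_match_pseudoinverse_oracle(self, n, p, rng):
        """OLS equivalence with an explicit normal-equations solve."""
        x = rng.standard_normal((n, p))
        y = rng.standard_normal((7, n))
        trials = pd.DataFrame(
            {"run": [], "onset_s": [], "duration_s": [], "condition": []}
        )
        sched = EventSchedule(trials=trials, n_runs=1, tr_s=1.5, volumes_per_run=n)
        from stgboundary.glm import DesignMatrix

        dm = DesignMatrix(
            matrix=pd.DataFrame(x, columns=[f"c{i}" for i in range(p)]),
            roles={f"c{i}": "condition" for i in range(p)},
            basis="block",
            run_lengths=[n],
        )
        res = fit_glm(y, dm, add_baseline_per_run=False)
        expected = np.linalg.pinv(x) @ y.T
        assert np.allclose(res.betas, expected.T, rtol=1e-8, atol=1e-10)

    def test_rank_deficient_rejected(self, schedule):
        m = _motion(schedule.total_volumes)
        m["motion5"] = m["motion0"]
        dm = build_block_design(schedule, m)
        with pytest.raises(ValueError, match="rank"):
            fit_glm(np.random.default_rng(0).standard_normal(
                (2, schedule.total_volumes)), dm)

    def test_null_t_distribution_calibrated(self, schedule, rng):
        """On pure-noise voxels the contrast t follows Student's t."""
        dm = build_block_design(schedule, _motion(schedule.total_volumes, rng))
        y = rng.standard_normal((400, schedule.total_volumes))
        res = fit_glm(y, dm)
        _, t = contrast_clear_vs_noisy(res)
        ks = stats.kstest(t, stats.t(df=res.dof).cdf)
        assert ks.pvalue > 0.01

    def test_contrast_symmetry_on_equal_betas(self, one_run_schedule, rng):
        dm = build_block_design(one_run_schedule, _motion(160, rng))
        x = dm.matrix[list(CONDITIONS)].to_numpy()
        y = (x @ np.array([0.5, 0.5, 0.5, 0.5]))[None, :] + 100.0
        res = fit_glm(y, dm)
        est_sum, _ = res.contrast(np.array([1, 1, 1, 1]), list(CONDITIONS))
        est_diff, _ = contrast_clear_vs_noisy(res)
        assert est_sum[0] == pytest.approx(2.0, abs=1e-8)
        assert est_diff[0] == pytest.approx(0.0, abs=1e-10)

    def test_zero_residual_sentinel(self, one_run_schedule, rng):
        dm = build_block_design(one_run_schedule, _motion(160, rng))
        x = dm.matrix[list(CONDITIONS)].to_numpy()
        y = (x @ np.array([1.0, 1.0, 0.0, 0.0]))[None, :] + 100.0
        res = fit_glm(y, dm)
        assert res.zero_residual[0]
        _, t = contrast_clear_vs_noisy(res)
        assert np.isinf(t[0]) and t[0] > 0


class TestContrastClearVsNoisy:
    def test_printed_amplitude_arithmetic(self, one_run_schedule, rng):
        """Betas (0.37, 0.37, 0.24, 0.24) -> contrast estimate +0.26."""
        dm = build_block_design(one_run_schedule, _motion(160, rng))
        x = dm.matrix[list(CONDITIONS)].to_numpy()
        amps = np.array([0.37, 0.37, 0.24, 0.24])
        y = (x @ amps)[None, :] + 100.0 + rng.standard_normal(160) * 1e-9
        res = fit_glm(y, dm)
        est, _ = contrast_clear_vs_noisy(res)
        assert est[0] == pytest.approx(0.26, abs=1e-6)

    def test_wrong_column_order_rejected(self, one_run_schedule, rng):
        dm = build_block_design(one_run_schedule, _motion(160, rng))
        dm.matrix = dm.matrix[list(CONDITIONS[::-1]) + dm.columns_with_role("motion")]
        res = fit_glm(np.zeros((1, 160)) + 100.0, dm)
        res.column_names = list(dm.matrix.columns)
        with pytest.raises(ValueError, match="order"):
            contrast_clear_vs_noisy(res)


class TestTentEstimation:
    def test_tent_basis_data_recovered_exactly(self, one_run_schedule, rng):
        """Data generated from the tent basis itself is recovered exactly."""
        dm = build_tent_design(one_run_schedule, _motion(160, rng))
        x = dm.matrix.to_numpy()
        beta_true = rng.standard_normal(x.shape[1]) * 0.3
        y = (x @ beta_true)[None, :] + 100.0
        res = fit_glm(y, dm)
        assert np.allclose(res.betas[0], beta_true, atol=1e-10)

    def test_noiseless_fir_tracks_true_response(self, one_run_schedule,
                                                noiseless_bold):
        """Deconvolution of a noiseless session reproduces the ground-truth
        response shape at the knot times (convolution oracle), up to the
        truncation error of the 15 s estimation window (the true response
        tail extends beyond it)."""
        from stgboundary.synthetic import bold_response_kernel, ground_truth_hrf

        sess = noiseless_bold
        y = scale_to_psc(sess.data)
        dm = build_tent_design(one_run_schedule, sess.motion)
        res = fit_glm(y, dm)
        times, fir = estimate_hrf_tent(res, "AclearVclear")
        hrf = ground_truth_hrf(dt_s=0.001)
        kernel = bold_response_kernel(hrf.kernel, 0.001, block_s=0.6)
        truth = kernel[(times / 0.001).astype(int)]
        amps = sess.generating_amplitudes["AclearVclear"].to_numpy()
        assert np.allclose(fir[0], amps[0] * truth, atol=0.05)
        # peak knot and undershoot sign are faithful
        assert times[np.argmax(fir[0])] in (4.5, 6.0)
        assert fir[0][np.isclose(times, 10.5)][0] < 0

    def test_null_condition_fir_near_zero(self, one_run_schedule, rng):
        dm = build_tent_design(one_run_schedule, _motion(160, rng))
        y = np.full((1, 160), 100.0) + rng.standard_normal(160) * 0.01
        res = fit_glm(y, dm)
        _, fir = estimate_hrf_tent(res, "AnoisyVblur")
        assert np.abs(fir).max() < 0.05

    def test_unknown_condition_rejected(self, one_run_schedule, rng):
        dm = build_tent_design(one_run_schedule, _motion(160, rng))
        res = fit_glm(np.full((1, 160), 100.0) + rng.standard_normal(160), dm)
        with pytest.raises(ValueError):
            estimate_hrf_tent(res, "nosuch")


class TestLocalizerResponse:
    def test_constant_knots(self):
        times = np.linspace(0, 30, 21)
        assert localizer_response(times, np.ones(21)) == pytest.approx(1.0)

    def test_arithmetic_mean_of_named_knots(self):
        times = np.linspace(0, 30, 21)
        betas = np.zeros(21)
        betas[np.isclose(times, 4.5)] = 0.3
        betas[np.isclose(times, 6.0)] = 0.6
        betas[np.isclose(times, 7.5)] = 0.3
        assert localizer_response(times, betas) == pytest.approx(0.4)

    def test_21_knots_span_0_30_at_tr(self):
        times = np.linspace(0.0, 30.0, 21)
        assert times.size == 21
        assert np.allclose(np.diff(times), 1.5)

    def test_missing_knot_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            localizer_response(np.array([0.0, 1.5, 3.0]), np.ones(3))
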