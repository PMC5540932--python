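"""Unit and property tests for the LSSRM kinetic core."""

import numpy as np
import pytest
from scipy import integrate
from scipy.integrate import solve_ivp

from raclopy.kinetics import (
    ActivationProfile,
    FrameSchedule,
    KineticParams,
    TimeActivityCurve,
    bp_activation,
    bp_baseline,
    build_design_matrix,
    compute_bp,
    fit_lssrm,
    fit_srtm,
    gamma_variate,
    mean_activation,
    read_tac_csv,
    simulate_target_tac,
    write_tac_csv,
)
from raclopy.synth import reference_curve


def _draw_params(rng):
    r1 = rng.uniform(0.7, 1.3)
    k2 = rng.uniform(0.1, 0.5)
    bp0 = rng.uniform(0.5, 3.0)
    gamma = rng.uniform(0.0, 0.05)
    return KineticParams(r1=r1, k2=k2, k2a=k2 / (1 + bp0), gamma=gamma)


class TestFrameSchedule:
    def test_default_matches_acquisition_protocol(self, schedule):
        # 8x2 + 4x3 + 2x4 + 5 + 6 + 8 + 3x8.3 minutes = 79.9 min, 20 frames
        assert schedule.n_frames == 20
        assert schedule.total_duration == pytest.approx(79.9)
        assert np.all(np.diff(schedule.start) > 0)

    def test_rejects_gaps_overlaps_and_nonpositive_durations(self):
        with pytest.raises(ValueError, match="contiguous"):
            FrameSchedule(start=[0.0, 3.0], duration=[2.0, 2.0])
        with pytest.raises(ValueError, match="positive"):
            FrameSchedule(start=[0.0, 2.0], duration=[2.0, -1.0])
        with pytest.raises(ValueError, match="increasing"):
            FrameSchedule(start=[2.0, 0.0], duration=[2.0, 2.0])

    def test_tac_validation(self, schedule):
        with pytest.raises(ValueError, match="length"):
            TimeActivityCurve(schedule=schedule, values=np.ones(5))
        with pytest.raises(ValueError, match="finite"):
            TimeActivityCurve(schedule=schedule,
                              values=np.full(20, np.nan))


class TestGammaVariate:
    def test_zero_before_onset_unit_peak_and_decay(self, profile):
        assert gamma_variate(50.0, profile) == 0.0
        assert gamma_variate(profile.onset, profile) == 0.0
        peak_t = profile.onset + profile.time_to_peak
        assert gamma_variate(peak_t, profile) == pytest.approx(1.0)
        t = np.linspace(0, 500, 20000)
        h = gamma_variate(t, profile)
        assert h.max() == pytest.approx(1.0, abs=1e-6)
        assert np.argmax(h) == pytest.approx(
            np.searchsorted(t, peak_t), abs=2)
        assert h[-1] < 1e-10  # h -> 0 far beyond the peak

    def test_closed_form_value_at_twice_peak_time(self, profile):
        # tau/tp = 2, lambda = 3: h = 2^3 * exp(3*(1-2)) = 8 e^-3
        t = profile.onset + 2 * profile.time_to_peak
        assert gamma_variate(t, profile) == pytest.approx(
            8.0 * np.exp(-3.0), rel=1e-12)

    def test_continuity_at_onset(self, profile):
        eps = 1e-9
        assert gamma_variate(profile.onset + eps, profile) < 1e-6

    def test_rejects_nonfinite_time(self, profile):
        with pytest.raises(ValueError):
            gamma_variate(np.nan, profile)

    def test_mean_activation_matches_fine_quadrature(self, profile):
        t = np.linspace(55.0, 79.9, int((79.9 - 55.0) * 60) + 1)
        expected = np.trapezoid(gamma_variate(t, profile), t) / (79.9 - 55.0)
        assert mean_activation(profile) == pytest.approx(expected, abs=1e-4)


class TestForwardSimulation:
    def test_zero_reference_gives_zero_target(self, schedule, profile):
        ref = TimeActivityCurve(schedule=schedule, values=np.zeros(20),
                                role="reference")
        tac = simulate_target_tac(ref, KineticParams(1.0, 0.3, 0.1, 0.0),
                                  profile)
        assert np.allclose(tac.values, 0.0)

    def test_bp0_zero_target_tracks_reference_at_plateau(
            self, reference_tac, profile):
        # R1 = 1, k2 = k2a means BP0 = 0: at the late plateau the target
        # equals the reference
        tac = simulate_target_tac(reference_tac,
                                  KineticParams(1.0, 0.3, 0.3, 0.0), profile)
        assert tac.values[-1] == pytest.approx(reference_tac.values[-1],
                                               rel=0.01)

    def test_agrees_with_independent_stiff_ode_solver(self, schedule,
                                                      profile):
        params = KineticParams(1.0, 0.3, 0.1, 0.02)
        tac = simulate_target_tac(
            TimeActivityCurve(schedule, np.ones(20), role="reference"),
            params, profile, ref_fun=reference_curve)

        def rhs(t, y):
            eps = 1e-6
            dcr = (reference_curve(t + eps) - reference_curve(t - eps)) \
                / (2 * eps)
            k = params.k2a + params.gamma * gamma_variate(t, profile)
            return dcr * params.r1 + params.k2 * reference_curve(t) - k * y[0]

        grid = np.linspace(0, schedule.total_duration, 4795)
        sol = solve_ivp(rhs, (0, schedule.total_duration), [0.0],
                        t_eval=grid, method="LSODA", rtol=1e-10, atol=1e-12)
        frame_avg = np.array([
            np.trapezoid(sol.y[0][(grid >= a) & (grid <= b + 1e-9)],
                         grid[(grid >= a) & (grid <= b + 1e-9)]) / (b - a)
            for a, b in zip(schedule.start, schedule.end)])
        assert np.allclose(tac.values, frame_avg, rtol=1e-3)

    def test_activation_depresses_late_frames(self, reference_tac, profile):
        base = simulate_target_tac(reference_tac,
                                   KineticParams(1.0, 0.3, 0.1, 0.0), profile)
        act = simulate_target_tac(reference_tac,
                                  KineticParams(1.0, 0.3, 0.1, 0.02), profile)
        late = reference_tac.schedule.mid_time > 55.0
        assert np.all(act.values[late] < base.values[late])
        assert np.allclose(act.values[~late], base.values[~late], rtol=1e-6)

    def test_nonpositive_k2a_warns(self, reference_tac, profile):
        with pytest.warns(RuntimeWarning, match="k2a"):
            simulate_target_tac(reference_tac,
                                KineticParams(1.0, 0.3, -0.01, 0.0), profile)


class TestDesignMatrix:
    def test_activation_column_zero_when_h_is_zero(self, reference_tac):
        late_profile = ActivationProfile(onset=200.0, window_end=300.0)
        tac = simulate_target_tac(reference_tac,
                                  KineticParams(1.0, 0.3, 0.1, 0.0),
                                  late_profile)
        A = build_design_matrix(tac, reference_tac, late_profile)
        assert np.allclose(A[:, 3], 0.0)

    def test_constant_reference_integral_grows_linearly(self, profile):
        sched = FrameSchedule(start=np.arange(10.0) * 2,
                              duration=np.full(10, 2.0))
        c = 7.0
        ref = TimeActivityCurve(sched, np.full(10, c), role="reference")
        tac = TimeActivityCurve(sched, np.full(10, c))
        A = build_design_matrix(tac, ref, profile)
        # frame-averaged running integral of a constant c is c * mid_time
        assert np.allclose(A[1:, 1], c * sched.mid_time[1:], rtol=0.05)

    def test_columns_match_fine_grid_quadrature(self, reference_tac,
                                                profile):
        """Design columns agree with 1-s quadrature of the analytic
        continuous curves that generated the frame data to <0.5%."""
        params = KineticParams(1.0, 0.3, 0.1, 0.02)
        tac = simulate_target_tac(reference_tac, params, profile,
                                  ref_fun=reference_curve)
        A = build_design_matrix(tac, reference_tac, profile)
        sched = reference_tac.schedule
        t = np.linspace(0, sched.total_duration, 4795)
        crv = reference_curve(t)
        h = gamma_variate(t, profile)
        k = params.k2a + params.gamma * h
        kcum = integrate.cumulative_trapezoid(k, t, initial=0)
        src = (params.k2 - params.r1 * k) * crv
        ct = params.r1 * crv + np.exp(-kcum) * integrate.cumulative_trapezoid(
            src * np.exp(kcum), t, initial=0)

        def frame_avg(curve):
            cum = integrate.cumulative_trapezoid(curve, t, initial=0)
            idx = np.searchsorted(t, np.concatenate([[0.0], sched.end]))
            return np.diff(cum[np.clip(idx, 0, t.size - 1)]) / sched.duration

        oracle1 = frame_avg(integrate.cumulative_trapezoid(crv, t, initial=0))
        oracle2 = -frame_avg(integrate.cumulative_trapezoid(ct, t, initial=0))
        oracle3 = -frame_avg(
            integrate.cumulative_trapezoid(ct * h, t, initial=0))
        # the first two frames' within-frame shapes are not determined by
        # binned data alone, so their small cumulative values carry a
        # larger relative (but negligible absolute) error; later frames
        # agree to <0.5% and the early ones to <0.05% of column scale
        assert np.allclose(A[2:, 1], oracle1[2:], rtol=0.005)
        assert np.allclose(A[2:, 2], oracle2[2:], rtol=0.005)
        assert np.all(np.abs(A[:2, 1] - oracle1[:2])
                      < 5e-4 * np.abs(oracle1).max())
        assert np.all(np.abs(A[:2, 2] - oracle2[:2])
                      < 5e-4 * np.abs(oracle2).max())
        nz = np.abs(oracle3) > 1e-9
        assert np.allclose(A[nz, 3], oracle3[nz], rtol=0.005)

    def test_too_few_frames_rejected(self, profile):
        sched = FrameSchedule(start=[0, 2, 4, 6.0], duration=[2, 2, 2, 2.0])
        ref = TimeActivityCurve(sched, np.ones(4), role="reference")
        tac = TimeActivityCurve(sched, np.ones(4))
        with pytest.raises(ValueError, match="5 frames"):
            build_design_matrix(tac, ref, profile)

    def test_schedule_mismatch_rejected(self, reference_tac, profile):
        other = FrameSchedule(start=np.arange(10.0) * 2,
                              duration=np.full(10, 2.0))
        tac = TimeActivityCurve(other, np.ones(10))
        with pytest.raises(ValueError, match="schedules differ"):
            build_design_matrix(tac, reference_tac, profile)


class TestFit:
    def test_round_trip_recovers_parameters(self, reference_tac, profile,
                                            rng):
        """Noise-free simulate-then-fit recovers all four parameters to
        well under 1% relative error across the physiological range."""
        for _ in range(100):
            true = _draw_params(rng)
            tac = simulate_target_tac(reference_tac, true, profile)
            fit = fit_lssrm(tac, reference_tac, profile)
            est = fit.params.as_array()
            rel = np.abs(est - true.as_array()) / np.maximum(
                np.abs(true.as_array()), 0.01)
            assert rel.max() < 0.01, (true, est)

    def test_single_round_trip_tight(self, reference_tac, profile):
        true = KineticParams(1.0, 0.3, 0.1, 0.02)
        tac = simulate_target_tac(reference_tac, true, profile)
        est = fit_lssrm(tac, reference_tac, profile).params.as_array()
        assert np.allclose(est, true.as_array(), rtol=1e-6)

    def test_nesting_gamma_zero_equals_srtm(self, reference_tac, profile):
        true = KineticParams(1.0, 0.3, 0.1, 0.0)
        tac = simulate_target_tac(reference_tac, true, profile)
        f4 = fit_lssrm(tac, reference_tac, profile)
        f3 = fit_srtm(tac, reference_tac)
        assert abs(f4.params.gamma) < 1e-8
        assert np.max(np.abs(f4.params.as_array()[:3]
                             - f3.params.as_array()[:3])) < 1e-8

    def test_unit_delivery_equal_rates_gives_bp0_zero(self, reference_tac,
                                                      profile):
        # R1 = 1 with k2 = k2a (BP0 = 0) makes the target track the
        # reference.  The individual rates are then unidentifiable (any
        # common value fits), but the identifiable quantities must come
        # back: R1 = 1, k2 == k2a (i.e. BP0 = 0), gamma = 0.
        tac = simulate_target_tac(reference_tac,
                                  KineticParams(1.0, 0.3, 0.3, 0.0), profile)
        fit = fit_lssrm(tac, reference_tac, profile)
        assert fit.params.r1 == pytest.approx(1.0, abs=1e-8)
        assert fit.params.k2 == pytest.approx(fit.params.k2a, abs=1e-10)
        assert fit.params.gamma == pytest.approx(0.0, abs=1e-10)
        # BP0 = 0 at slightly off-unity BP0 where rates are identifiable
        tac2 = simulate_target_tac(reference_tac,
                                   KineticParams(1.0, 0.33, 0.3, 0.0),
                                   profile)
        fit2 = fit_lssrm(tac2, reference_tac, profile)
        assert bp_baseline(fit2.params) == pytest.approx(0.1, abs=1e-8)

    def test_nonfinite_values_rejected_at_construction(self, reference_tac):
        bad = reference_tac.values.copy()
        bad[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            TimeActivityCurve(reference_tac.schedule, bad)

    def test_rank_deficient_design_names_columns(self, profile):
        sched = FrameSchedule(start=np.arange(20.0) * 2,
                              duration=np.full(20, 2.0))
        # a constant reference makes C_R and (scaled) int C_R collinear
        # with the target columns when target == reference
        ref = TimeActivityCurve(sched, np.full(20, 5.0), role="reference")
        tac = TimeActivityCurve(sched, np.full(20, 5.0))
        with pytest.raises(np.linalg.LinAlgError, match="collinear|rank"):
            fit_lssrm(tac, ref, profile)

    def test_duration_weights_accepted(self, reference_tac, profile):
        true = KineticParams(1.0, 0.3, 0.1, 0.02)
        tac = simulate_target_tac(reference_tac, true, profile)
        fit = fit_lssrm(tac, reference_tac, profile,
                        weights=reference_tac.schedule.duration)
        assert np.allclose(fit.params.as_array(), true.as_array(), rtol=1e-4)


class TestBindingPotentials:
    def test_bp0_direct_ratio(self):
        assert bp_baseline(KineticParams(1.0, 0.36, 0.12)) \
            == pytest.approx(2.0)
        assert bp_baseline(KineticParams(1.0, 0.2, 0.2)) == pytest.approx(0.0)

    def test_bp0_randomized_equals_recomputation(self, rng):
        for _ in range(50):
            p = _draw_params(rng)
            assert bp_baseline(p) == pytest.approx(p.k2 / p.k2a - 1.0)

    def test_invalid_k2a_flags_not_raises(self):
        p = KineticParams(1.0, 0.3, -0.05, 0.0)
        assert np.isnan(bp_baseline(p))
        bp = compute_bp(p)
        assert not bp.valid

    def test_gamma_zero_bp1_equals_bp0(self, profile):
        p = KineticParams(1.0, 0.3, 0.1, 0.0)
        assert bp_activation(p, profile) == bp_baseline(p)
        assert bp_activation(p, profile, mode="bp_average") \
            == pytest.approx(bp_baseline(p))

    def test_displacement_direction(self, profile, rng):
        # gamma > 0 lowers binding: BP1 < BP0; gamma < 0 raises it
        for _ in range(25):
            p = _draw_params(rng)
            if p.gamma == 0:
                continue
            bp = compute_bp(p, profile)
            assert bp.delta < 0
            neg = KineticParams(p.r1, p.k2, p.k2a, -p.gamma)
            assert compute_bp(neg, profile).delta > 0

    def test_delta_is_exact_difference(self, profile, rng):
        p = _draw_params(rng)
        bp = compute_bp(p, profile)
        assert bp.delta == bp.bp1 - bp.bp0

    def test_bp_average_mode_close_to_rate_average(self, profile):
        p = KineticParams(1.0, 0.35, 0.1, 0.02)
        a = bp_activation(p, profile, mode="rate_average")
        b = bp_activation(p, profile, mode="bp_average")
        assert a == pytest.approx(b, rel=0.05)
        assert a != b


class TestTacIO:
    def test_csv_round_trip(self, reference_tac, tmp_path):
        path = tmp_path / "tac.csv"
        write_tac_csv(path, reference_tac)
        back = read_tac_csv(path, role="reference")
        assert back.schedule == reference_tac.schedule
        assert np.allclose(back.values, reference_tac.values)
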