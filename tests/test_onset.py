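import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tacdelay.onset import (
    OnsetConfig,
    OnsetFit,
    OnsetFitParams,
    aggregate_fits,
    apply_plateau_correction,
    detect_plateau,
    estimate_delay,
    estimate_onset,
    fit_summed_range,
    onset_time,
    select_fit_endpoints,
    sigmoid_model,
    summed_model,
)
from tacdelay.tac_core import CumulativeCurve, TimeActivityCurve, build_schedule, cumulative_sum


class TestModels:
    def test_sigmoid_values(self):
        p = OnsetFitParams(100.0, 1.0, 10.0)
        assert sigmoid_model(10.0, p) == pytest.approx(50.0)
        assert sigmoid_model(12.0, p) == pytest.approx(100 / (1 + math.exp(-2)), rel=1e-9)
        assert sigmoid_model(1e6, p) == pytest.approx(100.0)
        assert sigmoid_model(-1e6, p) == pytest.approx(0.0, abs=1e-12)

    def test_summed_closed_form(self):
        p = OnsetFitParams(100.0, 1.0, 10.0)
        assert summed_model(10.0, p) == pytest.approx(100 * math.log(2), rel=1e-12)

    def test_summed_is_antiderivative_of_sigmoid(self):
        # relative error < 1e-6 of the numerical derivative against the rise model
        p = OnsetFitParams(500.0, 1.7, 23.0)
        t = np.linspace(0, 60, 20001)
        h = t[1] - t[0]
        deriv = np.gradient(summed_model(t, p), h)
        expected = sigmoid_model(t, p)
        sel = expected > 1e-3 * p.a
        assert np.max(np.abs(deriv[sel] - expected[sel]) / expected[sel]) < 1e-6

    def test_summed_small_b_is_ramp(self):
        p = OnsetFitParams(7.0, 0.01, 10.0)
        t = np.array([0.0, 9.0, 10.0, 20.0, 50.0])
        np.testing.assert_allclose(
            summed_model(t, p), 7.0 * np.maximum(0.0, t - 10.0), atol=0.1
        )

    def test_overflow_safety(self):
        p = OnsetFitParams(1.0, 0.01, 60.0)
        assert np.isfinite(summed_model(np.array([0.0, 1e4]), p)).all()
        assert np.isfinite(sigmoid_model(np.array([0.0, 1e4]), p)).all()

    def test_b_must_be_positive(self):
        with pytest.raises(ValueError):
            sigmoid_model(0.0, OnsetFitParams(1.0, 0.0, 1.0))
        with pytest.raises(ValueError):
            summed_model(0.0, OnsetFitParams(1.0, -1.0, 1.0))

    @pytest.mark.parametrize(
        "b, c, expected", [(1.0, 10.0, 6.5), (0.01, 0.035, 0.0), (2.0, 5.0, -2.0)]
    )
    def test_onset_time_formula(self, b, c, expected):
        assert onset_time(OnsetFitParams(1.0, b, c)) == pytest.approx(expected)


class TestPlateau:
    def test_ramp_has_no_plateau(self):
        sched = build_schedule([(10, 1)])
        curve = cumulative_sum(TimeActivityCurve(sched, np.full(10, 100.0)))
        assert not detect_plateau(curve).detected

    def test_step_plateau_found(self):
        sched = build_schedule([(10, 1)])
        vals = np.array([0.0, 0.0, 5.0, 5.0, 5.0, 5.0, 20.0, 40.0, 60.0, 80.0])
        curve = CumulativeCurve(sched, vals)
        corr = detect_plateau(curve, band_fraction=0.01)  # band = 0.8 << 5
        assert corr.detected
        assert corr.plateau_end_index == 5
        assert corr.plateau_level == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exhaustive_scan_oracle(self, seed):
        """Detected run agrees with a brute-force scan over all windows."""
        rng = np.random.default_rng(seed)
        n = 30
        sched = build_schedule([(n, 1)])
        vals = np.cumsum(rng.integers(0, 2, n) * rng.uniform(0, 30, n))
        curve = CumulativeCurve(sched, vals)
        band = 0.02 * vals.max()
        corr = detect_plateau(curve, band_fraction=0.02)
        # oracle: for each end j, the widest window [i..j] with >=3 points and
        # spread <= band, kept only if the curve still rises above its level
        ends = []
        for j in range(2, n):
            widths = [i for i in range(j - 1) if np.ptp(vals[i : j + 1]) <= band]
            if not widths:
                continue
            level = vals[min(widths) : j + 1].mean()
            if j + 1 < n and vals[j + 1 :].max() > level + band:
                ends.append(j)
        assert corr.detected == bool(ends)
        if ends:
            assert corr.plateau_end_index == max(ends)

    def test_tail_outside_window_ignored(self):
        # flat only after 120 s: must not be treated as a pre-arrival plateau
        sched = build_schedule([(40, 1), (5, 4), (6, 10), (3, 20)])
        t = sched.mid_time
        vals = np.where(t < 120, t * 10.0, 1200.0)
        assert not detect_plateau(CumulativeCurve(sched, vals)).detected

    def test_correction_zeroes_prefix_and_shifts(self):
        sched = build_schedule([(10, 1)])
        vals = np.array([0.0, 0.0, 5.0, 5.0, 5.0, 5.0, 20.0, 40.0, 60.0, 80.0])
        curve = CumulativeCurve(sched, vals)
        corr = detect_plateau(curve, band_fraction=0.01)
        out = apply_plateau_correction(curve, corr)
        assert out.plateau_corrected
        np.testing.assert_allclose(out.values[:6], 0.0)
        np.testing.assert_allclose(out.values[6:], vals[6:] - 5.0)
        # re-detection on the corrected curve finds no plateau before the rise
        corr2 = detect_plateau(out, band_fraction=0.01)
        if corr2.detected:
            assert corr2.plateau_level == pytest.approx(0.0, abs=1e-9)

    def test_zero_level_plateau_only_zeroes_prefix(self):
        sched = build_schedule([(10, 1)])
        vals = np.array([0.0, 0.0, 0.0, 0.0, 10.0, 30.0, 60.0, 90.0, 120.0, 150.0])
        curve = CumulativeCurve(sched, vals)
        corr = detect_plateau(curve, band_fraction=0.001)
        assert corr.detected and corr.plateau_level == 0.0
        out = apply_plateau_correction(curve, corr)
        np.testing.assert_array_equal(out.values[corr.plateau_end_index + 1 :],
                                      vals[corr.plateau_end_index + 1 :])

    def test_undetected_correction_is_noop(self, caplog):
        sched = build_schedule([(5, 1)])
        curve = CumulativeCurve(sched, np.arange(5.0))
        from tacdelay.onset import PlateauCorrection

        out = apply_plateau_correction(curve, PlateauCorrection(False))
        np.testing.assert_array_equal(out.values, curve.values)


class TestEndpoints:
    def _break_curve(self, k, n=20):
        """Piecewise-linear summed curve with a slope break at index k."""
        sched = build_schedule([(n, 1)])
        t = sched.mid_time
        vals = np.where(np.arange(n) <= k, t, t[k] + 5 * (t - t[k]))
        return CumulativeCurve(sched, vals)

    def test_single_slope_break_found(self):
        for k in (5, 9, 13):
            assert select_fit_endpoints(self._break_curve(k))[0] in (k, k + 1)

    def test_straight_ramp_falls_back_to_last_frame(self):
        sched = build_schedule([(10, 1)])
        curve = CumulativeCurve(sched, sched.mid_time * 3.0)
        assert select_fit_endpoints(curve) == [9]

    def test_two_breaks_ordered_by_magnitude(self):
        sched = build_schedule([(30, 1)])
        t = sched.mid_time
        vals = np.piecewise(
            t, [t < 10, (t >= 10) & (t < 20), t >= 20],
            [lambda t: t, lambda t: 10 + 3 * (t - 10), lambda t: 40 + 13 * (t - 20)],
        )
        eps = select_fit_endpoints(CumulativeCurve(sched, vals))
        # larger break (slope jump 10 at t=20) ranked before smaller (jump 2 at t=10)
        assert abs(eps[0] - 20) <= 1 and abs(eps[1] - 10) <= 1

    def test_brute_force_second_difference_oracle(self, rng):
        sched = build_schedule([(25, 1), (5, 4)])
        vals = np.cumsum(rng.uniform(0, 10, 30))
        curve = CumulativeCurve(sched, vals)
        t = sched.mid_time
        d2 = np.abs(
            2 * (np.diff(vals[1:]) / np.diff(t[1:]) - np.diff(vals[:-1]) / np.diff(t[:-1]))
            / (t[2:] - t[:-2])
        )
        oracle = sorted(
            (i + 1 for i in range(1, len(d2) - 1)
             if d2[i] > d2[i - 1] and d2[i] >= d2[i + 1] and d2[i] > 0),
            key=lambda idx: (-d2[idx - 1], idx),
        )[:10]
        assert select_fit_endpoints(curve) == oracle

    def test_too_few_frames_raise(self):
        sched = build_schedule([(4, 1)])
        with pytest.raises(ValueError):
            select_fit_endpoints(CumulativeCurve(sched, np.arange(4.0)))


class TestFitting:
    def test_noise_free_round_trip(self, h2o_schedule):
        true = OnsetFitParams(1000.0, 2.0, 15.0)
        curve = CumulativeCurve(h2o_schedule, np.asarray(summed_model(h2o_schedule.mid_time, true)))
        end = int(np.searchsorted(h2o_schedule.mid_time, 60.0))
        fit = fit_summed_range(curve, end)
        assert fit.r_squared > 0.999
        assert fit.params.a == pytest.approx(true.a, rel=0.01)
        assert fit.params.b == pytest.approx(true.b, rel=0.01)
        assert fit.params.c == pytest.approx(true.c, rel=0.01)
        assert abs(fit.params.c - true.c) < 0.1
        assert abs(fit.params.b - true.b) / true.b < 0.05

    def test_all_zero_curve_rejected(self, h2o_schedule):
        curve = CumulativeCurve(h2o_schedule, np.zeros(h2o_schedule.n_frames))
        fit = fit_summed_range(curve, 20)
        assert fit.r_squared == -math.inf
        assert aggregate_fits([fit]).n_fits_accepted == 0

    def test_late_onset_near_bound_flagged(self, h2o_schedule):
        true = OnsetFitParams(1000.0, 1.0, 55.0)
        curve = CumulativeCurve(h2o_schedule, np.asarray(summed_model(h2o_schedule.mid_time, true)))
        fit = fit_summed_range(curve, h2o_schedule.n_frames - 1)
        assert fit.params.c == pytest.approx(55.0, abs=1.0)

    def test_aggregate_hand_computed_median(self):
        def mk(c, r2):
            p = OnsetFitParams(1.0, 1.0, c)
            return OnsetFit(p, r2, 50, 170.0, onset_time(p))

        fits = [mk(10, 0.99), mk(10, 0.98), mk(12, 0.97), mk(30, 0.96)]
        est = aggregate_fits(fits)
        assert est.n_fits_accepted == 4
        # top 2 by R^2 kept: c = [10, 10] -> median 10, onset = 10 - 3.5
        assert est.median_params.c == pytest.approx(10.0)
        assert est.onset_time == pytest.approx(6.5)

    def test_aggregate_single_fit(self):
        p = OnsetFitParams(5.0, 1.0, 20.0)
        est = aggregate_fits([OnsetFit(p, 0.95, 40, 100.0, onset_time(p))])
        assert est.onset_time == pytest.approx(16.5)

    def test_aggregate_rejects_low_r2_negative_or_late_onset(self):
        p_ok = OnsetFitParams(1.0, 1.0, 10.0)
        low_r2 = OnsetFit(p_ok, 0.5, 50, 170.0, onset_time(p_ok))
        p_neg = OnsetFitParams(1.0, 2.0, 5.0)  # onset -2
        negative = OnsetFit(p_neg, 0.99, 50, 170.0, onset_time(p_neg))
        p_late = OnsetFitParams(1.0, 1.0, 50.0)  # onset 46.5, range ends at 30
        late = OnsetFit(p_late, 0.99, 20, 30.0, onset_time(p_late))
        est = aggregate_fits([low_r2, negative, late])
        assert est.n_fits_accepted == 0
        assert math.isnan(est.onset_time)


class TestPipeline:
    def test_idif_onset_near_true_arrival(self, idif_tac, idif_model):
        est = estimate_onset(idif_tac)
        assert est.ok
        assert est.onset_time == pytest.approx(idif_model.arrival_time, abs=1.5)

    def test_determinism(self, make_tissue):
        tac = make_tissue(sigma=0.3, seed=4)
        a, b = estimate_onset(tac), estimate_onset(tac)
        assert a == b

    def test_pure_noise_yields_no_fits(self, h2o_schedule):
        rng = np.random.default_rng(12345)
        tac = TimeActivityCurve(h2o_schedule, rng.normal(0, 100, h2o_schedule.n_frames))
        est = estimate_onset(tac)
        assert est.n_fits_accepted == 0
        assert math.isnan(est.onset_time)

    def test_degenerate_inputs_fail_softly(self, h2o_schedule):
        zero = TimeActivityCurve(h2o_schedule, np.zeros(h2o_schedule.n_frames))
        assert not estimate_onset(zero).ok

    def test_self_delay_is_exactly_zero(self, make_tissue, idif_tac):
        assert estimate_delay(idif_tac, idif_tac) == 0.0
        tac = make_tissue(sigma=0.2, seed=7)
        assert estimate_delay(tac, tac) == 0.0

    @pytest.mark.parametrize("shift", [5.0, -3.0])
    def test_shift_equivariance(self, make_tissue, shift):
        base = estimate_onset(make_tissue(delay=0.0))
        moved = estimate_onset(make_tissue(delay=shift))
        assert moved.onset_time - base.onset_time == pytest.approx(shift, abs=0.5)

    def test_scale_invariance(self, make_tissue):
        tac = make_tissue(sigma=0.1, seed=3)
        a = estimate_onset(tac).onset_time
        b = estimate_onset(tac.scaled(37.5)).onset_time
        assert a == pytest.approx(b, abs=1e-3)

    def test_delay_from_simulated_shift(self, make_tissue, idif_tac):
        d = estimate_delay(make_tissue(delay=5.0), idif_tac) - estimate_delay(
            make_tissue(delay=0.0), idif_tac
        )
        assert d == pytest.approx(5.0, abs=0.5)

    @settings(deadline=None, max_examples=10)
    @given(st.integers(0, 10_000))
    def test_accepted_fit_contract_random_inputs(self, seed):
        """Every fit contributing to an estimate meets all three filter criteria."""
        rng = np.random.default_rng(seed)
        sched = build_schedule([(40, 1), (5, 4), (6, 10), (3, 20)])
        from tacdelay.synthetic import INPUT_PRESETS, SimulationSpec, simulate_tissue

        spec = SimulationSpec(
            K1=float(rng.uniform(1, 350)), k2=float(rng.uniform(0.05, 3)),
            delay=float(rng.uniform(-10, 10)), sigma=float(rng.uniform(0, 0.5)),
            seed=int(seed), schedule=sched, input_model=INPUT_PRESETS["h2o_idif"],
        )
        tac = simulate_tissue(spec)
        from tacdelay.onset import OnsetConfig
        from tacdelay.tac_core import cumulative_sum as csum
        from tacdelay.onset import (
            apply_plateau_correction as apc,
            detect_plateau as dp,
            select_fit_endpoints as sfe,
        )

        cfg = OnsetConfig()
        curve = csum(tac)
        corr = dp(curve)
        if corr.detected:
            curve = apc(curve, corr)
        fits = [fit_summed_range(curve, e, cfg) for e in sfe(curve) if e >= 4]
        est = aggregate_fits(fits, cfg)
        accepted = [
            f for f in fits
            if f.params is not None and f.r_squared >= cfg.r2_min
            and 0 < f.onset_time < f.range_end_time
        ]
        assert est.n_fits_accepted == len(accepted)
        if est.ok:
            assert est.n_fits_accepted >= 1


class TestConfig:
    def test_from_dotted_keys(self):
        cfg = OnsetConfig.from_dict(
            {"plateau.min_points": 5, "fit.r2_min": 0.9, "fit.bounds": {"b": [0.1, 5]},
             "onset.shape_factor": 3.0}
        )
        assert cfg.plateau_min_points == 5
        assert cfg.r2_min == 0.9
        assert cfg.b_bounds == (0.1, 5.0)
        assert cfg.shape_factor == 3.0

    def test_unknown_key_raises(self):
        with pytest.raises(KeyError):
            OnsetConfig.from_dict({"nope": 1})
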