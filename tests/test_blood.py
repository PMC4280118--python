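import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from petidif.blood import (BiExpParams, HillParams, apply_dispersion,
                           assemble_input_function, calibrate_idif,
                           correct_dispersion, correct_inversion,
                           estimate_delay, fit_blood_to_plasma,
                           fit_parent_fraction)
from petidif.curves import InsufficientDataError, TimeActivityCurve
from petidif.io import ManualSample
from tests.conftest import gamma_bolus

SAMPLE_TIMES = [1.5, 2.5, 7.0, 15.0, 30.0, 45.0, 60.0, 90.0]


def make_samples(ratio_fn, pf_fn, wb_fn=lambda t: 50.0 * np.exp(-0.05 * t) + 5):
    out = []
    for t in SAMPLE_TIMES:
        wb = wb_fn(t)
        out.append(ManualSample(t, wb, wb / ratio_fn(t), pf_fn(t)))
    return out


class TestBloodToPlasma:
    def test_constant_ratio_predicts_constant(self):
        samples = make_samples(lambda t: 1.2, lambda t: 1.0)
        fit = fit_blood_to_plasma(samples)
        t = np.linspace(0, 120, 50)
        np.testing.assert_allclose(fit.predict(t), 1.2, rtol=1e-3)

    def test_recovers_known_biexponential(self):
        truth = BiExpParams(a1=-0.25, a2=-0.15, b1=0.15, b2=0.02, offset=1.2)
        samples = make_samples(lambda t: float(truth.predict(t)), lambda t: 1.0)
        fit = fit_blood_to_plasma(samples)
        t = np.linspace(0.5, 100, 200)
        np.testing.assert_allclose(fit.predict(t), truth.predict(t), rtol=0.01)

    def test_too_few_samples(self):
        samples = make_samples(lambda t: 1.2, lambda t: 1.0)[:2]
        with pytest.raises(InsufficientDataError):
            fit_blood_to_plasma(samples)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            BiExpParams(1.0, 0.0, -0.1, 0.0, 1.0)


class TestParentFraction:
    def test_unmetabolized_tracer(self):
        samples = make_samples(lambda t: 1.2, lambda t: 1.0)
        fit = fit_parent_fraction(samples)
        np.testing.assert_allclose(fit.predict(np.linspace(0, 120, 40)), 1.0,
                                   atol=1e-3)

    def test_recovers_known_hill_curve(self):
        truth = HillParams(amplitude=0.9, half_time=20.0, slope=2.0)
        samples = make_samples(lambda t: 1.2, lambda t: float(truth.predict(t)))
        fit = fit_parent_fraction(samples)
        t = np.linspace(0.5, 100, 200)
        np.testing.assert_allclose(fit.predict(t), truth.predict(t), rtol=0.01)

    def test_half_time_definition(self):
        """With full metabolism (amplitude 1), pf(half_time) = 0.5."""
        p = HillParams(amplitude=1.0, half_time=20.0, slope=3.0)
        assert p.predict(20.0) == pytest.approx(0.5)
        assert p.predict(0.0) == 1.0
        t = np.linspace(0, 200, 500)
        assert np.all(np.diff(p.predict(t)) <= 1e-12)  # non-increasing


class TestDispersion:
    def test_tau_zero_identity(self, smooth_bolus_tac):
        out = apply_dispersion(smooth_bolus_tac, 0.0)
        np.testing.assert_array_equal(out.values, smooth_bolus_tac.values)
        out = correct_dispersion(smooth_bolus_tac, 0.0)
        np.testing.assert_array_equal(out.values, smooth_bolus_tac.values)

    def test_step_input_closed_form(self):
        t = np.arange(0.0, 200.0, 0.1)
        step = TimeActivityCurve(t, np.full(t.size, 10.0))
        out = apply_dispersion(step, 16.0)
        expected = 10.0 * (1.0 - np.exp(-(t + 0.05) / 16.0))
        np.testing.assert_allclose(out.values, expected, atol=0.05)

    def test_matches_fine_grid_numerical_convolution(self, smooth_bolus_tac):
        out = apply_dispersion(smooth_bolus_tac, 16.0)
        # independent oracle: exact ODE y' = (x - y)/tau at tight tolerance
        from scipy.integrate import solve_ivp
        tac = smooth_bolus_tac
        sol = solve_ivp(lambda tt, yy: (np.interp(tt, tac.times, tac.values)
                                        - yy) / 16.0,
                        (tac.times[0], tac.times[-1]), [0.0],
                        t_eval=tac.times, max_step=0.05, rtol=1e-8, atol=1e-10)
        err = np.max(np.abs(sol.y[0] - out.values)) / tac.values.max()
        assert err < 0.005

    def test_preserves_auc(self):
        # compact-support bolus on a horizon >= 20 tau
        tau = 16.0
        t = np.arange(0.0, 25 * tau, 0.25)
        x = np.where(t < 150, gamma_bolus(t, t_peak=20.0), 0.0)
        tac = TimeActivityCurve(t, np.maximum(x, 0.0))
        out = apply_dispersion(tac, tau)
        assert out.auc() == pytest.approx(tac.auc(), rel=0.005)

    def test_round_trip_recovers_smooth_bolus(self, smooth_bolus_tac):
        rec = correct_dispersion(apply_dispersion(smooth_bolus_tac, 16.0), 16.0)
        err = np.max(np.abs(rec.values - smooth_bolus_tac.values))
        assert err / smooth_bolus_tac.values.max() < 0.01

    def test_constant_curve_unchanged_by_correction(self):
        t = np.arange(0.0, 100.0, 1.0)
        const = TimeActivityCurve(t, np.full(t.size, 7.0))
        out = correct_dispersion(const, 16.0)
        np.testing.assert_allclose(out.values, 7.0, atol=1e-9)

    def test_coarse_grid_warns_and_resamples(self, smooth_bolus_tac):
        coarse = smooth_bolus_tac.resample(30.0)
        with pytest.warns(UserWarning):
            correct_dispersion(coarse, 16.0)

    def test_negative_tau_rejected(self, smooth_bolus_tac):
        with pytest.raises(ValueError):
            apply_dispersion(smooth_bolus_tac, -1.0)


class TestDelayEstimation:
    def _head_from_blood(self, blood, delta, k=0.1):
        t = blood.times
        shifted = np.interp(t - delta, t, blood.values, left=0.0)
        return TimeActivityCurve(t, k * cumulative_trapezoid(shifted, t,
                                                             initial=0.0))

    def test_recovers_known_delay(self, smooth_bolus_tac):
        blood = smooth_bolus_tac.resample(0.05, 0.0, 60.0)
        head = self._head_from_blood(blood, 6.0)
        assert estimate_delay(blood, head) == pytest.approx(6.0, abs=0.5)

    def test_zero_delay(self, smooth_bolus_tac):
        blood = smooth_bolus_tac.resample(0.05, 0.0, 60.0)
        head = self._head_from_blood(blood, 0.0)
        assert estimate_delay(blood, head) == pytest.approx(0.0, abs=0.5)

    def test_degenerate_inputs(self, smooth_bolus_tac):
        t = np.arange(0.0, 60.0, 0.5)
        zero = TimeActivityCurve(t, np.zeros(t.size))
        with pytest.raises(ValueError):
            estimate_delay(zero, smooth_bolus_tac)
        with pytest.raises(ValueError):
            estimate_delay(smooth_bolus_tac, zero)


class TestAssembleInputFunction:
    def test_arithmetic(self):
        t = np.array([0.0, 900.0])
        wb = TimeActivityCurve(t, np.array([100.0, 100.0]))
        b2p = BiExpParams(0.0, 0.0, 0.0, 0.0, 1.25)
        # amplitude 1, enormous half-time => pf ~ 0.5 via offset trick
        hill = HillParams(amplitude=0.5, half_time=1e-3, slope=2.0)
        out = assemble_input_function(wb, b2p, hill)
        np.testing.assert_allclose(out.values[1], 100.0 / 1.25 * 0.5, rtol=1e-6)

    def test_identity_when_ratio_and_pf_are_one(self, smooth_bolus_tac):
        b2p = BiExpParams(0.0, 0.0, 0.0, 0.0, 1.0)
        hill = HillParams(amplitude=0.0, half_time=10.0, slope=2.0)
        out = assemble_input_function(smooth_bolus_tac, b2p, hill)
        np.testing.assert_allclose(out.values, smooth_bolus_tac.values)

    def test_positive_homogeneity(self, smooth_bolus_tac):
        b2p = BiExpParams(-0.2, 0.0, 0.1, 0.0, 1.2)
        hill = HillParams(amplitude=0.8, half_time=20.0, slope=2.0)
        out1 = assemble_input_function(smooth_bolus_tac, b2p, hill)
        scaled = smooth_bolus_tac.with_values(3.0 * smooth_bolus_tac.values)
        out3 = assemble_input_function(scaled, b2p, hill)
        np.testing.assert_allclose(out3.values, 3.0 * out1.values, rtol=1e-12)

    def test_nonpositive_ratio_rejected(self, smooth_bolus_tac):
        b2p = BiExpParams(-2.0, 0.0, 0.0, 0.0, 1.0)  # ratio = -1 everywhere
        hill = HillParams(amplitude=0.0, half_time=10.0, slope=2.0)
        with pytest.raises(ValueError):
            assemble_input_function(smooth_bolus_tac, b2p, hill)

    def test_phantom_truth_round_trip(self, ideal_phantom):
        """Assembling from the true blood, ratio and parent fraction
        reproduces the true parent-plasma curve within 0.1%."""
        _, truth = ideal_phantom
        wb = TimeActivityCurve(truth.fine_times, truth.arterial_fine)
        out = assemble_input_function(wb, truth.b2p, truth.hill)
        np.testing.assert_allclose(out.values, truth.parent_plasma_fine,
                                   rtol=1e-3, atol=1e-9)


class TestCalibration:
    def _idif(self):
        t = np.arange(0.0, 1800.0, 30.0)
        return TimeActivityCurve(t, np.full(t.size, 5.0))

    def test_scales_curve(self):
        sample = ManualSample(15.0, 10.0, 8.0, 0.5)
        out = calibrate_idif(self._idif(), sample)
        np.testing.assert_allclose(out.values, 10.0)
        assert out.calibration["scale"] == pytest.approx(2.0)

    def test_identity_and_fixed_point(self):
        sample = ManualSample(15.0, 5.0, 4.0, 0.5)
        out = calibrate_idif(self._idif(), sample)
        np.testing.assert_allclose(out.values, self._idif().values)
        assert float(out(900.0)) == pytest.approx(5.0)

    def test_idempotent_after_first_application(self):
        sample = ManualSample(15.0, 10.0, 8.0, 0.5)
        once = calibrate_idif(self._idif(), sample)
        twice = calibrate_idif(once, sample)
        np.testing.assert_allclose(twice.values, once.values)

    def test_uncovered_time_rejected(self):
        t = np.arange(0.0, 300.0, 30.0)
        short = TimeActivityCurve(t, np.full(t.size, 5.0))
        with pytest.raises(ValueError):
            calibrate_idif(short, ManualSample(15.0, 10.0, 8.0, 0.5))


class TestInversionCorrection:
    def _decay_curve(self, dip_at=None, dip_frac=0.5):
        t = np.arange(0.0, 300.0, 10.0)
        v = 100.0 * np.exp(-t / 60.0) + 5.0
        v[:3] = [10.0, 60.0, 110.0]  # rise to a peak at 20 s
        if dip_at is not None:
            i = int(dip_at // 10)
            v[i] *= dip_frac
        return TimeActivityCurve(t, v)

    def test_monotone_curve_unchanged(self):
        tac = self._decay_curve()
        out = correct_inversion(tac)
        np.testing.assert_array_equal(out.values, tac.values)
        assert out.inversion_repaired is False

    def test_dip_repaired_to_local_monotonicity(self):
        tac = self._decay_curve(dip_at=90.0)
        out = correct_inversion(tac)
        assert out.inversion_repaired
        i = 9
        assert out.values[i - 1] >= out.values[i] >= out.values[i + 1]

    def test_sample_replaces_coincident_point(self):
        tac = self._decay_curve(dip_at=90.0)
        sample = ManualSample(1.5, 42.0, 30.0, 0.9)  # 1.5 min = 90 s
        out = correct_inversion(tac, sample)
        assert out.values[9] == pytest.approx(42.0)

    def test_sample_scale_applied(self):
        tac = self._decay_curve(dip_at=90.0)
        sample = ManualSample(1.5, 42.0, 30.0, 0.9)
        out = correct_inversion(tac, sample, scale=0.5)
        assert out.values[9] == pytest.approx(21.0)
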