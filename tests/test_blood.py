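"""Blood processing: plasma/whole-blood curve fits, parent-fraction model,
input-function assembly and SUV."""

import numpy as np
import pytest
from scipy.integrate import quad

from petkin import (
    BloodSampleTable, InputFunction, ParentFractionModel, PlasmaCurveModel,
    fit_parent_fraction, fit_plasma_curve, make_input_function, suv,
    suv_to_activity,
)


def _mono_exp_samples():
    t = np.concatenate([[0.5], np.linspace(1.0, 120.0, 20)])
    y = np.where(t < 1.0, 5.0 * t, 10.0 * np.exp(-0.01 * (t - 1.0)))
    return t, y


class TestPlasmaCurveFit:
    def test_noiseless_mono_exponential_recovery(self):
        t, y = _mono_exp_samples()
        model = fit_plasma_curve(t, y, n_exponentials=1)
        assert model.amplitudes[0] == pytest.approx(10.0, rel=1e-4)
        assert model.rates[0] == pytest.approx(0.01, rel=1e-4)

    def test_constant_tail_degenerates_to_zero_rate(self):
        t = np.array([0.5, 1.0, 5.0, 20.0, 60.0, 120.0, 180.0])
        y = np.array([2.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0])
        model = fit_plasma_curve(t, y, n_exponentials=1)
        assert model.rates[0] < 1e-6
        assert model(np.array([10.0, 90.0, 180.0])) == pytest.approx(
            [5.0, 5.0, 5.0], rel=1e-6)

    def test_triexponential_recovery_within_half_percent(self):
        A = np.array([5.0, 3.0, 1.0])
        lam = np.array([0.5, 0.05, 0.002])
        tau = np.linspace(0.0, 175.0, 30)
        t = 1.0 + tau
        y = (A * np.exp(-np.outer(tau, lam))).sum(axis=1)
        t_all = np.concatenate([[0.5], t])
        y_all = np.concatenate([[4.0], y])
        model = fit_plasma_curve(t_all, y_all, n_exponentials=3)
        assert np.allclose(model(t), y, rtol=5e-3)

    def test_too_few_post_peak_samples_is_explicit(self):
        t = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 9.0, 8.0, 7.0, 6.0])
        with pytest.raises(ValueError, match="at least 5"):
            fit_plasma_curve(t, y, n_exponentials=3)

    def test_all_zero_activities_fail(self):
        with pytest.raises(ValueError, match="zero"):
            fit_plasma_curve(np.arange(1.0, 9.0), np.zeros(8))

    def test_continuity_at_peak(self):
        t, y = _mono_exp_samples()
        model = fit_plasma_curve(t, y, n_exponentials=2)
        eps = 1e-9
        left = model(model.peak_time - eps)
        right = model(model.peak_time + eps)
        peak = model(model.peak_time)
        assert abs(left - right) < 1e-6 * peak

    def test_auto_selects_parsimonious_tail(self):
        t, y = _mono_exp_samples()
        model = fit_plasma_curve(t, y, n_exponentials="auto")
        assert len(model.rates) == 1


class TestParentFraction:
    def test_no_metabolism_gives_a_zero(self):
        t = np.array([5.0, 15.0, 30.0, 60.0, 90.0, 120.0, 180.0])
        model = fit_parent_fraction(t, np.ones(7))
        assert model.a == 0.0
        assert model(np.array([0.0, 90.0, 400.0])) == pytest.approx([1, 1, 1])

    def test_noiseless_parameter_recovery(self):
        truth = ParentFractionModel(a=0.3, alpha=2.0, beta=0.02)
        t = np.array([5.0, 15.0, 30.0, 60.0, 90.0, 120.0, 180.0])
        model = fit_parent_fraction(t, truth(t))
        assert model.a == pytest.approx(0.3, rel=1e-3)
        assert model.alpha == pytest.approx(2.0, rel=1e-3)
        assert model.beta == pytest.approx(0.02, rel=1e-3)

    def test_slow_metabolism_three_point_fit(self):
        # late parent fractions typical of the lead tracer
        model = fit_parent_fraction([30.0, 90.0, 180.0], [0.88, 0.83, 0.79])
        assert model(180.0) == pytest.approx(0.79, abs=0.02)

    def test_fitted_curve_monotone_even_with_noisy_samples(self):
        t = np.array([5.0, 15.0, 30.0, 60.0, 90.0, 120.0, 180.0])
        pf = np.array([0.97, 0.92, 0.94, 0.85, 0.87, 0.82, 0.80])
        model = fit_parent_fraction(t, pf)
        grid = model(np.linspace(0.0, 300.0, 2000))
        assert np.all(np.diff(grid) <= 1e-12)
        assert model(0.0) == pytest.approx(1.0)

    def test_out_of_range_fractions_fail(self):
        with pytest.raises(ValueError):
            fit_parent_fraction([5.0, 30.0, 90.0, 180.0], [1.2, 0.9, 0.8, 0.7])


class TestInputFunction:
    @pytest.fixture()
    def parts(self):
        t, y = _mono_exp_samples()
        plasma = fit_plasma_curve(t, y, n_exponentials=1)
        wb = fit_plasma_curve(t, 0.85 * y, n_exponentials=1)
        parent = ParentFractionModel(a=0.3, alpha=2.0, beta=0.02)
        return plasma, parent, wb

    def test_unit_parent_fraction_is_identity(self, parts):
        plasma, _, wb = parts
        inp = make_input_function(plasma, ParentFractionModel(0.0, 2.0, 0.02),
                                  wb, f_p=0.135)
        t = np.linspace(0.0, 180.0, 500)
        assert np.allclose(inp.corrected_plasma(t), plasma(t))

    def test_correction_is_pointwise_product(self, parts):
        plasma, parent, wb = parts
        inp = make_input_function(plasma, parent, wb, f_p=0.135)
        assert inp.corrected_plasma(180.0) == pytest.approx(
            plasma(180.0) * parent(180.0))

    def test_corrected_never_exceeds_total_plasma(self, parts):
        plasma, parent, wb = parts
        inp = make_input_function(plasma, parent, wb)
        t = np.linspace(0.0, 300.0, 1000)
        assert np.all(inp.corrected_plasma(t) <= plasma(t) + 1e-12)

    def test_integral_matches_quadrature(self, parts):
        plasma, parent, wb = parts
        inp = make_input_function(plasma, parent, wb)
        t = np.linspace(0.0, 180.0, 36001)
        trapz = np.trapezoid(inp.corrected_plasma(t), t)
        ref = sum(
            quad(lambda s: float(inp.corrected_plasma(s)), a, b, limit=400)[0]
            for a, b in [(0.0, 1.0), (1.0, 30.0), (30.0, 180.0)]
        )
        assert trapz == pytest.approx(ref, rel=1e-3)

    def test_roundtrip_through_json_dict(self, parts):
        plasma, parent, wb = parts
        inp = make_input_function(plasma, parent, wb, f_p=0.124)
        back = InputFunction.from_dict(inp.to_dict())
        t = np.linspace(0.0, 180.0, 100)
        assert np.allclose(back.corrected_plasma(t), inp.corrected_plasma(t))
        assert back.f_p == inp.f_p


class TestRecoveryProperty:
    def test_randomized_noiseless_recovery(self):
        """Plasma and parent-fraction fits recover randomized admissible
        generating parameters within 1% (seeded)."""
        rng = np.random.default_rng(123)
        t_pf = np.array([5.0, 15.0, 30.0, 60.0, 90.0, 120.0, 180.0])
        tau = np.concatenate([np.linspace(0, 10, 8), np.linspace(15, 179, 14)])
        for _ in range(100):
            # bi-exponential plasma tail with well-separated random rates
            A = rng.uniform(2.0, 20.0, size=2)
            lam = np.array([rng.uniform(0.2, 0.8), rng.uniform(0.002, 0.02)])
            y = (A * np.exp(-np.outer(tau, lam))).sum(axis=1)
            t = np.concatenate([[0.5], 1.0 + tau])
            model = fit_plasma_curve(t, np.concatenate([[1.0], y]),
                                     n_exponentials=2)
            assert np.allclose(model(1.0 + tau), y, rtol=0.01)

            truth = ParentFractionModel(
                a=rng.uniform(0.1, 0.9), alpha=rng.uniform(0.8, 4.0),
                beta=rng.uniform(0.005, 0.1))
            fit = fit_parent_fraction(t_pf, truth(t_pf))
            grid = np.linspace(1.0, 200.0, 50)
            assert np.allclose(fit(grid), truth(grid), rtol=0.01)


class TestSuv:
    def test_worked_example(self):
        assert suv(5.0, 180.0, 5.0) == pytest.approx(0.13889, abs=1e-4)

    def test_zero_activity(self):
        assert suv(0.0, 180.0, 5.0) == 0.0

    def test_roundtrip_identity(self):
        a = 7.31
        back = suv_to_activity(suv(a, 182.0, 5.5), 182.0, 5.5)
        assert back == pytest.approx(a, abs=1e-12)

    @pytest.mark.parametrize("dose,weight", [(0.0, 5.0), (-1.0, 5.0), (180.0, 0.0)])
    def test_nonpositive_dose_or_weight_fails(self, dose, weight):
        with pytest.raises(ValueError):
            suv(5.0, dose, weight)


def test_blood_table_invariants():
    with pytest.raises(ValueError, match="increasing"):
        BloodSampleTable([1.0, 1.0, 2.0, 3.0], [1, 1, 1, 1], [1, 1, 1, 1])
    with pytest.raises(ValueError, match="at least 4"):
        BloodSampleTable([1.0, 2.0, 3.0], [1, 1, 1], [1, 1, 1])
    with pytest.raises(ValueError, match="non-negative"):
        BloodSampleTable([1.0, 2.0, 3.0, 4.0], [1, 1, -1, 1], [1, 1, 1, 1])
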