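"""Compartment-model forward predictions, delay estimation, fitting and
macroparameters."""

import numpy as np
import pytest

from petkin import (
    FrameSchedule, KineticParameters, TimeActivityCurve,
    derive_macroparameters, estimate_delay, fit_tissue_model, predict_tac,
    predict_tissue_curve,
)
from petkin.kinetics import vt_or_raise
from petkin.simulate import SyntheticStudyConfig, generate_tacs

from conftest import rk4_ode_tac

K2_SLOW = np.log(2.0) / 175.0


class _ConstantPlasma:
    """Unit plasma input with no blood signal (closed-form oracle input)."""

    def corrected_plasma(self, t):
        t = np.asarray(t, float)
        return np.where(t > 0, 1.0, 0.0)

    def whole_blood(self, t):
        return np.zeros_like(np.asarray(t, float))


class TestPredict:
    def test_vascular_only_equals_scaled_whole_blood(self, truth_input, schedule):
        params = KineticParameters(K1=0.0, k2=0.01, vb=0.05, model_kind="1TCM")
        pred = predict_tac(params, truth_input, schedule)
        # frame-averaged whole blood via the same machinery (no tissue term)
        wb_params = KineticParameters(K1=0.0, k2=0.01, vb=0.2, model_kind="1TCM")
        full = predict_tac(wb_params, truth_input, schedule) / 0.2
        assert np.allclose(pred, 0.05 * full, rtol=1e-12)

    def test_constant_input_matches_closed_form(self):
        K1 = 0.0135
        params = KineticParameters(K1=K1, k2=K2_SLOW, model_kind="1TCM")
        t = np.linspace(0.0, 180.0, 3601)
        curve = predict_tissue_curve(params, _ConstantPlasma(), t)
        closed = (K1 / K2_SLOW) * (1.0 - np.exp(-K2_SLOW * 180.0))
        assert curve[-1] == pytest.approx(closed, rel=2e-4)

    def test_2tcm_with_zero_k3_collapses_to_1tcm(self, truth_input, schedule):
        one = KineticParameters(K1=0.0135, k2=0.01, vb=0.036, model_kind="1TCM")
        two = KineticParameters(K1=0.0135, k2=0.01, k3=0.0, k4=0.003,
                                vb=0.036, model_kind="2TCM")
        a = predict_tac(one, truth_input, schedule)
        b = predict_tac(two, truth_input, schedule)
        assert np.allclose(a, b, atol=1e-8 * a.max())

    def test_ode_oracle_agreement(self, truth_input, schedule):
        """Analytic convolution vs brute-force RK4 on a 0.01-min grid."""
        rng = np.random.default_rng(42)
        for i in range(6):
            kind = "2TCM" if i % 2 else "1TCM"
            params = KineticParameters(
                K1=rng.uniform(0.005, 0.05), k2=rng.uniform(0.003, 0.05),
                k3=rng.uniform(0.002, 0.03) if kind == "2TCM" else 0.0,
                k4=rng.uniform(0.002, 0.03) if kind == "2TCM" else 0.0,
                vb=0.036, model_kind=kind)
            a = predict_tac(params, truth_input, schedule)
            b = rk4_ode_tac(params, truth_input, schedule)
            assert np.max(np.abs(a - b)) < 1e-3 * np.max(a)

    def test_delay_shift_consistency(self, truth_input, schedule):
        """Shifting the input by +dt with delta_t = 0 matches delta_t = dt."""
        dt = 0.7

        class Shifted:
            def corrected_plasma(self, t):
                return truth_input.corrected_plasma(np.asarray(t, float) - dt)

            def whole_blood(self, t):
                return truth_input.whole_blood(np.asarray(t, float) - dt)

        p0 = KineticParameters(K1=0.0135, k2=K2_SLOW, vb=0.036,
                               delta_t=dt, model_kind="1TCM")
        p1 = KineticParameters(K1=0.0135, k2=K2_SLOW, vb=0.036,
                               delta_t=0.0, model_kind="1TCM")
        a = predict_tac(p0, truth_input, schedule)
        b = predict_tac(p1, Shifted(), schedule)
        assert np.allclose(a, b, atol=2e-3 * a.max())

    def test_patlak_limit_for_irreversible_model(self):
        """2TiCM with constant input: the late slope of C_T(t) equals K_i."""
        params = KineticParameters(K1=0.01, k2=0.01, k3=0.01, vb=0.0,
                                   model_kind="2TiCM")
        t = np.linspace(0.0, 2000.0, 40001)
        curve = predict_tissue_curve(params, _ConstantPlasma(), t,
                                     include_blood=False)
        slope = (curve[-1] - curve[-2001]) / (t[-1] - t[-2001])
        ki = derive_macroparameters(params)["K_i"]
        assert slope == pytest.approx(ki, rel=0.01)


class TestDelay:
    @pytest.mark.parametrize("dt_true,tol", [(0.5, 0.1), (0.0, 0.05)])
    def test_delay_recovery(self, noiseless_config, truth_input, dt_true, tol):
        cfg = SyntheticStudyConfig(tac_noise_cv=0, blood_noise_cv=0,
                                   pf_noise_sd=0, delta_t=dt_true)
        tacs, _ = generate_tacs(cfg)
        wb = TimeActivityCurve("wb", tacs[0].schedule,
                               np.mean([t.activity for t in tacs], axis=0))
        assert estimate_delay(wb, truth_input) == pytest.approx(dt_true, abs=tol)

    def test_delay_invariant_to_global_scaling(self, noiseless_config, truth_input):
        cfg = SyntheticStudyConfig(tac_noise_cv=0, blood_noise_cv=0,
                                   pf_noise_sd=0, delta_t=0.5)
        tacs, _ = generate_tacs(cfg)
        mean = np.mean([t.activity for t in tacs], axis=0)
        sched = tacs[0].schedule
        d1 = estimate_delay(TimeActivityCurve("wb", sched, mean), truth_input)
        d2 = estimate_delay(TimeActivityCurve("wb", sched, 2.0 * mean), truth_input)
        assert d1 == pytest.approx(d2, abs=0.05)

    def test_too_few_early_frames_fail(self, truth_input):
        sched = FrameSchedule(start=[0.0, 5.0, 10.0, 20.0, 40.0],
                              end=[5.0, 10.0, 20.0, 40.0, 60.0])
        tac = TimeActivityCurve("wb", sched, np.ones(5))
        with pytest.raises(ValueError, match="at least 5"):
            estimate_delay(tac, truth_input)


class TestFit:
    def test_noiseless_1tcm_recovery(self, truth_input, schedule):
        truth = KineticParameters(K1=0.0135, k2=0.004, vb=0.036,
                                  model_kind="1TCM")
        tac = TimeActivityCurve("roi", schedule,
                                predict_tac(truth, truth_input, schedule))
        fit = fit_tissue_model(tac, truth_input, "1TCM")
        assert fit.parameters.K1 == pytest.approx(0.0135, rel=1e-3)
        assert fit.parameters.k2 == pytest.approx(0.004, rel=1e-3)
        assert fit.parameters.vb == pytest.approx(0.036, rel=1e-3)
        assert fit.converged

    def test_k1_reporting_unit_conversion(self, truth_input, schedule):
        params = KineticParameters(K1=0.0135, k2=0.004, model_kind="1TCM")
        assert params.K1_uL == pytest.approx(13.5)

    def test_weights_scale_invariance(self, truth_input, schedule):
        truth = KineticParameters(K1=0.0135, k2=0.004, vb=0.036,
                                  model_kind="1TCM")
        y = predict_tac(truth, truth_input, schedule)
        w = schedule.duration
        f1 = fit_tissue_model(TimeActivityCurve("r", schedule, y, w),
                              truth_input, "1TCM")
        f2 = fit_tissue_model(TimeActivityCurve("r", schedule, y, 2.0 * w),
                              truth_input, "1TCM")
        assert np.allclose(f1.estimates, f2.estimates, rtol=1e-12)
        assert f1.rse == pytest.approx(f2.rse)

    def test_wrss_nesting_on_noisy_tacs(self, truth_input):
        """WRSS(2TCM) <= WRSS(1TCM) <= WRSS(2TiCM with k3 = 0 forced)."""
        cfg = SyntheticStudyConfig(tac_noise_cv=0.05, blood_noise_cv=0,
                                   pf_noise_sd=0)
        n_checked = 0
        for rep in range(2):
            tacs, _ = generate_tacs(cfg, seed=500 + rep)
            for tac in tacs[::2]:
                f1 = fit_tissue_model(tac, truth_input, "1TCM")
                f2 = fit_tissue_model(tac, truth_input, "2TCM")
                fi = fit_tissue_model(
                    tac, truth_input, "2TiCM",
                    bounds={"k3": (0.0, 1e-12)})
                assert f2.wrss <= f1.wrss * (1 + 1e-6)
                assert f1.wrss <= fi.wrss * (1 + 1e-6)
                n_checked += 1
        assert n_checked >= 10

    def test_too_few_frames_fail(self, truth_input):
        sched = FrameSchedule(start=np.arange(4.0), end=np.arange(4.0) + 1.0)
        tac = TimeActivityCurve("r", sched, np.ones(4))
        with pytest.raises(ValueError, match="frames"):
            fit_tissue_model(tac, truth_input, "1TCM")


class TestMacroparameters:
    def test_slow_clearance_vt(self):
        params = KineticParameters(K1=0.0135, k2=0.0039608, model_kind="1TCM")
        out = derive_macroparameters(params)
        assert out["V_T"] == pytest.approx(3.408, abs=2e-3)
        assert out["clearance_half_life"] == pytest.approx(175.0, rel=1e-3)

    def test_2tcm_vt(self):
        params = KineticParameters(K1=0.02, k2=0.01, k3=0.005, k4=0.005,
                                   model_kind="2TCM")
        assert derive_macroparameters(params)["V_T"] == pytest.approx(4.0)

    def test_2ticm_ki(self):
        params = KineticParameters(K1=0.01, k2=0.01, k3=0.01, model_kind="2TiCM")
        assert derive_macroparameters(params)["K_i"] == pytest.approx(0.005)

    def test_vt_undefined_for_irreversible_model(self):
        params = KineticParameters(K1=0.01, k2=0.01, k3=0.01, model_kind="2TiCM")
        with pytest.raises(ValueError, match="undefined"):
            vt_or_raise(params)

    def test_zero_k2_flags_infinite_vt(self):
        params = KineticParameters(K1=0.01, k2=0.0, model_kind="1TCM")
        out = derive_macroparameters(params)
        assert np.isinf(out["V_T"]) and "V_T_flag" in out


def test_parameter_validation():
    with pytest.raises(ValueError):
        KineticParameters(K1=-0.01, k2=0.01)
    with pytest.raises(ValueError):
        KineticParameters(K1=0.01, k2=0.01, k3=0.01, model_kind="1TCM")
    with pytest.raises(ValueError):
        KineticParameters(K1=0.01, k2=0.01, k4=0.01, model_kind="2TiCM")
    with pytest.raises(ValueError):
        KineticParameters(K1=0.01, k2=0.01, vb=0.5)


def test_default_schedule_is_45_frames_over_180min():
    sched = FrameSchedule.default_180min()
    assert len(sched) == 45
    assert sched.end[-1] == pytest.approx(180.0)
    assert sched.duration[:6] == pytest.approx(np.full(6, 0.5))
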