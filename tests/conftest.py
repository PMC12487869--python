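import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from petkin import FrameSchedule, KineticParameters
from petkin.simulate import SyntheticStudyConfig, generate_input


@pytest.fixture(scope="session")
def noiseless_config():
    return SyntheticStudyConfig(tac_noise_cv=0.0, blood_noise_cv=0.0,
                                pf_noise_sd=0.0)


@pytest.fixture(scope="session")
def truth_input(noiseless_config):
    """Continuous ground-truth input function of the default study."""
    _, _, truth = generate_input(0, noiseless_config)
    return truth


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default_180min()


def rk4_ode_tac(params: KineticParameters, input_fn, schedule, h: float = 0.01):
    """Independent oracle: brute-force RK4 integration of the compartment ODEs
    on an ``h``-min grid, then trapezoid frame averaging."""
    t_end = float(schedule.end[-1])
    n = int(round(t_end / h))
    t = np.linspace(0.0, t_end, n + 1)
    cp = np.asarray(input_fn.corrected_plasma(t - params.delta_t), float)
    cp_half = np.asarray(
        input_fn.corrected_plasma(t[:-1] + h / 2 - params.delta_t), float)
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    A = np.array([[-(k2 + k3), k4], [k3, -k4]])
    b = np.array([K1, 0.0])
    y = np.zeros((n + 1, 2))
    for i in range(n):
        def f(state, c):
            return A @ state + b * c
        k_1 = f(y[i], cp[i])
        k_2 = f(y[i] + h / 2 * k_1, cp_half[i])
        k_3 = f(y[i] + h / 2 * k_2, cp_half[i])
        k_4 = f(y[i] + h * k_3, cp[i + 1])
        y[i + 1] = y[i] + h / 6 * (k_1 + 2 * k_2 + 2 * k_3 + k_4)
    ct = y.sum(axis=1)
    wb = np.asarray(input_fn.whole_blood(t - params.delta_t), float)
    curve = (1.0 - params.vb) * ct + params.vb * wb
    F = cumulative_trapezoid(curve, t, initial=0.0)
    Fs = np.interp(schedule.start, t, F)
    Fe = np.interp(schedule.end, t, F)
    return (Fe - Fs) / schedule.duration
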