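"""Tissue compartment models: forward prediction, delay estimation and
weighted nonlinear least-squares fitting.

Three models are supported, each with a fractional blood-volume term V_b and a
time delay dt between the blood sampling site and the brain:

* 1TCM  — one tissue compartment, impulse response K1*exp(-k2 t);
* 2TCM  — reversible two-tissue model (k4 > 0), bi-exponential impulse
  response with macro-rates a1, a2 = 0.5*[(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2
  - 4 k2 k4)];
* 2TiCM — irreversible two-tissue model (k4 = 0 fixed).

The measured PET concentration is modelled as

    C(t) = (1 - V_b) * C_T(t) + V_b * C_wb(t - dt)

with C_T the compartmental response to the metabolite-corrected plasma input
C_p(t - dt).  Predictions are computed by exact convolution of the exponential
impulse response with a piecewise-linear sampling of the input on a fine grid
(default 0.05 min), then averaged over each frame by the trapezoid rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .selection import aic as _aic

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "KineticParameters",
    "ModelFitResult",
    "predict_tac",
    "predict_tissue_curve",
    "estimate_delay",
    "fit_tissue_model",
    "derive_macroparameters",
    "frame_weights",
    "MODEL_KINDS",
]

MODEL_KINDS = ("1TCM", "2TCM", "2TiCM")

#: default parameter bounds: K1 (mL/min/cm^3), rate constants (1/min), V_b
DEFAULT_BOUNDS = {
    "K1": (0.0, 0.5),
    "k2": (0.0, 1.0),
    "k3": (0.0, 1.0),
    "k4": (0.0, 1.0),
    "vb": (0.0, 0.2),
}

DEFAULT_GRID_STEP = 0.05  # minutes


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class FrameSchedule:
    """Frame start/end times in minutes; non-overlapping and increasing."""

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.start, dtype=float)
        e = np.asarray(self.end, dtype=float)
        if len(s) != len(e):
            raise ValueError("start and end must have equal length")
        if np.any(e <= s):
            raise ValueError("every frame must end after it starts")
        if np.any(s[1:] < e[:-1] - 1e-9):
            raise ValueError("frames must be non-overlapping and increasing")
        object.__setattr__(self, "start", s)
        object.__setattr__(self, "end", e)

    def __len__(self):
        return len(self.start)

    @property
    def mid(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def duration(self) -> np.ndarray:
        return self.end - self.start

    @classmethod
    def default_180min(cls) -> "FrameSchedule":
        """45-frame, 180-min dynamic schedule: 6 x 30 s, 3 x 1 min,
        2 x 2 min, 34 x 5 min."""
        durations = np.concatenate(
            [np.full(6, 0.5), np.full(3, 1.0), np.full(2, 2.0), np.full(34, 5.0)]
        )
        ends = np.cumsum(durations)
        return cls(start=ends - durations, end=ends)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged regional activity (kBq/cm^3) with optional fit
    weights."""

    roi_name: str
    schedule: FrameSchedule
    activity: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        a = np.asarray(self.activity, dtype=float)
        if len(a) != len(self.schedule):
            raise ValueError("one activity value per frame required")
        object.__setattr__(self, "activity", a)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != len(a):
                raise ValueError("one weight per frame required")
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
            object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class KineticParameters:
    """Microparameters of a compartment model fit.

    K1 in mL*min^-1*cm^-3 (reported externally as uL*min^-1*cm^-3, x1000);
    k2..k4 in min^-1; vb is the blood volume fraction; delta_t in minutes
    (positive = tissue lags the blood sampling site).
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    vb: float = 0.0
    delta_t: float = 0.0
    model_kind: str = "1TCM"

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.vb <= 0.2:
            raise ValueError("vb must be in [0, 0.2]")
        if self.model_kind == "1TCM" and (self.k3 != 0 or self.k4 != 0):
            raise ValueError("1TCM requires k3 = k4 = 0")
        if self.model_kind == "2TiCM" and self.k4 != 0:
            raise ValueError("2TiCM requires k4 = 0")

    @property
    def K1_uL(self) -> float:
        """K1 in uL*min^-1*cm^-3 (reporting convention for slow tracers)."""
        return self.K1 * 1000.0


_FREE_PARAMS = {
    "1TCM": ("K1", "k2", "vb"),
    "2TCM": ("K1", "k2", "k3", "k4", "vb"),
    "2TiCM": ("K1", "k2", "k3", "vb"),
}


@dataclass
class ModelFitResult:
    """Weighted NLS fit of one compartment model to one TAC."""

    parameters: KineticParameters
    free_names: tuple
    estimates: np.ndarray
    covariance: np.ndarray
    wrss: float
    n_frames: int
    n_free: int
    aic: float
    rse: dict = field(default_factory=dict)   # percent, per free parameter
    vt: float | None = None
    vt_rse: float | None = None
    ki: float | None = None
    ki_rse: float | None = None
    clearance_half_life: float | None = None
    converged: bool = True
    message: str = ""

    @property
    def primary_parameter(self) -> str:
        return "ki" if self.parameters.model_kind == "2TiCM" else "vt"

    @property
    def primary_rse(self) -> float | None:
        return self.ki_rse if self.primary_parameter == "ki" else self.vt_rse


# ---------------------------------------------------------------------------
# forward model


def _exp_conv(cp: np.ndarray, h: float, theta: float) -> np.ndarray:
    """Exact convolution of exp(-theta t) with a piecewise-linear signal
    sampled at step h: y(t_n) = int_0^{t_n} exp(-theta (t_n - s)) cp(s) ds."""
    th = theta * h
    if th > 1e-8:
        E = math.exp(-th)
        i0 = -math.expm1(-th) / theta          # int exp(-theta s) ds over [0,h]
        i1 = (1.0 - E * (1.0 + th)) / theta ** 2
    else:
        E = math.exp(-th)
        i0 = h * (1.0 - th / 2.0)
        i1 = h * h * (0.5 - th / 3.0)
    c1 = cp
    c0 = np.concatenate([[cp[0]], cp[:-1]])
    b = c1 * i0 + (c0 - c1) * (i1 / h)
    b[0] = 0.0
    return signal.lfilter([1.0], [1.0, -E], b)


def _impulse_terms(params: KineticParameters):
    """(amplitude, rate) pairs of the tissue impulse response K1 * sum_j
    phi_j exp(-a_j t)."""
    k2, k3, k4 = params.k2, params.k3, params.k4
    if params.model_kind == "1TCM":
        return [(params.K1, k2)]
    s = k2 + k3 + k4
    disc = max(s * s - 4.0 * k2 * k4, 0.0)
    root = math.sqrt(disc)
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    if a2 - a1 < 1e-12:
        a2 = a1 + 1e-12
    phi1 = (k3 + k4 - a1) / (a2 - a1)
    phi2 = (a2 - k3 - k4) / (a2 - a1)
    return [(params.K1 * phi1, a1), (params.K1 * phi2, a2)]


def predict_tissue_curve(params: KineticParameters, input_fn, t_grid: np.ndarray,
                         include_blood: bool = True) -> np.ndarray:
    """Instantaneous model concentration on a uniform time grid."""
    h = float(t_grid[1] - t_grid[0])
    cp = np.asarray(input_fn.corrected_plasma(t_grid - params.delta_t), dtype=float)
    ct = np.zeros_like(cp)
    for amp, rate in _impulse_terms(params):
        if amp == 0.0:
            continue
        ct += amp * _exp_conv(cp, h, rate)
    if not include_blood:
        return ct
    wb = np.asarray(input_fn.whole_blood(t_grid - params.delta_t), dtype=float)
    return (1.0 - params.vb) * ct + params.vb * wb


def _frame_average(curve: np.ndarray, t_grid: np.ndarray,
                   schedule: FrameSchedule) -> np.ndarray:
    from scipy.integrate import cumulative_trapezoid

    F = cumulative_trapezoid(curve, t_grid, initial=0.0)
    Fs = np.interp(schedule.start, t_grid, F)
    Fe = np.interp(schedule.end, t_grid, F)
    return (Fe - Fs) / schedule.duration


def predict_tac(params: KineticParameters, input_fn, schedule: FrameSchedule,
                grid_step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Frame-averaged model prediction for a TAC on the given schedule."""
    t_end = float(schedule.end[-1])
    n = int(round(t_end / grid_step)) + 1
    t_grid = np.linspace(0.0, t_end, n)
    curve = predict_tissue_curve(params, input_fn, t_grid)
    return _frame_average(curve, t_grid, schedule)


# ---------------------------------------------------------------------------
# weights


def frame_weights(schedule: FrameSchedule, scheme: str = "duration",
                  activity: np.ndarray | None = None) -> np.ndarray:
    """Fit weights, normalized to mean 1 (estimates and rSE are invariant to
    overall weight scale; normalizing also keeps AIC comparable across
    schemes).

    duration            w_i ~ frame duration (default)
    uniform             w_i ~ 1
    duration_sq_over_activity   w_i ~ duration^2 / max(activity, eps)
    """
    d = schedule.duration
    if scheme == "duration":
        w = d.copy()
    elif scheme == "uniform":
        w = np.ones_like(d)
    elif scheme == "duration_sq_over_activity":
        if activity is None:
            raise ValueError("activity required for duration_sq_over_activity")
        floor = max(1e-6, 0.01 * float(np.max(np.abs(activity))))
        w = d ** 2 / np.maximum(np.abs(activity), floor)
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    return w * len(w) / w.sum()


# ---------------------------------------------------------------------------
# delay estimation


def estimate_delay(whole_brain_tac: TimeActivityCurve, input_fn,
                   t_max: float = 10.0, delay_bounds: tuple = (-3.0, 3.0),
                   grid_step: float = DEFAULT_GRID_STEP) -> float:
    """Blood-to-brain time delay from the first ``t_max`` minutes of the
    whole-brain TAC, fitted to a 3-parameter irreversible uptake model
    (K1, V_b, dt; k2 = 0 — washout is negligible this early)."""
    sched = whole_brain_tac.schedule
    keep = sched.end <= t_max + 1e-9
    if keep.sum() < 5:
        raise ValueError(
            f"need at least 5 frames ending within {t_max} min, got {int(keep.sum())}"
        )
    early = FrameSchedule(start=sched.start[keep], end=sched.end[keep])
    y = whole_brain_tac.activity[keep]
    w = frame_weights(early, "duration")
    sw = np.sqrt(w)

    t_end = float(early.end[-1])
    n = int(round(t_end / grid_step)) + 1
    t_grid = np.linspace(0.0, t_end, n)

    from scipy.integrate import cumulative_trapezoid

    def model(x):
        K1, vb, dt = x
        cp = np.asarray(input_fn.corrected_plasma(t_grid - dt), dtype=float)
        wb = np.asarray(input_fn.whole_blood(t_grid - dt), dtype=float)
        uptake = cumulative_trapezoid(cp, t_grid, initial=0.0)
        curve = (1.0 - vb) * K1 * uptake + vb * wb
        return _frame_average(curve, t_grid, early)

    def resid(x):
        return sw * (model(x) - y)

    lo = [0.0, 0.0, delay_bounds[0]]
    hi = [DEFAULT_BOUNDS["K1"][1], DEFAULT_BOUNDS["vb"][1], delay_bounds[1]]
    best = None
    for dt0 in (-1.0, 0.0, 1.0):
        for K10 in (1e-3, 1e-2):
            res = optimize.least_squares(
                resid, [K10, 0.05, dt0], bounds=(lo, hi), x_scale=[1e-2, 0.05, 1.0],
                xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=1000,
            )
            if best is None or res.cost < best.cost:
                best = res
    return float(best.x[2])


# ---------------------------------------------------------------------------
# model fitting


def _start_grid(model_kind: str, n_starts: int = 8):
    """Deterministic multistart grid, log-spaced over the interior of the
    bounds."""
    K1s = (0.003, 0.03)
    k2s = (0.003, 0.03)
    starts = []
    if model_kind == "1TCM":
        k2s4 = (0.001, 0.005, 0.02, 0.1)
        for K1 in K1s:
            for k2 in k2s4:
                starts.append([K1, k2, 0.04])
    elif model_kind == "2TCM":
        for K1 in K1s:
            for k2 in k2s:
                for k3 in (0.003, 0.03):
                    starts.append([K1, k2, k3, 0.01, 0.04])
    else:  # 2TiCM
        for K1 in K1s:
            for k2 in k2s:
                for k3 in (0.003, 0.03):
                    starts.append([K1, k2, k3, 0.04])
    return starts[:n_starts]


def _macro_with_rse(params: KineticParameters, free_names, estimates, cov):
    """Macroparameters and delta-method rSEs from the free-parameter
    covariance."""
    kind = params.model_kind

    def macro_of(x):
        p = {name: val for name, val in zip(free_names, x)}
        K1 = p.get("K1", params.K1)
        k2 = p.get("k2", params.k2)
        k3 = p.get("k3", params.k3)
        k4 = p.get("k4", params.k4)
        if kind == "1TCM":
            return K1 / k2 if k2 > 0 else np.inf
        if kind == "2TCM":
            if k2 <= 0 or k4 <= 0:
                return np.inf
            return (K1 / k2) * (1.0 + k3 / k4)
        return K1 * k3 / (k2 + k3) if (k2 + k3) > 0 else 0.0

    value = macro_of(estimates)
    if not np.isfinite(value):
        return value, None
    # central-difference gradient
    g = np.zeros(len(estimates))
    for i, x in enumerate(estimates):
        step = max(1e-6, 1e-4 * abs(x))
        xp = estimates.copy(); xp[i] += step
        xm = estimates.copy(); xm[i] = max(xm[i] - step, 0.0)
        g[i] = (macro_of(xp) - macro_of(xm)) / (xp[i] - xm[i])
    if not np.all(np.isfinite(g)) or not np.all(np.isfinite(cov)):
        return value, None
    var = float(g @ cov @ g)
    if var < 0 or value == 0:
        return value, None
    return value, 100.0 * math.sqrt(var) / abs(value)


def fit_tissue_model(
    tac: TimeActivityCurve,
    input_fn,
    model_kind: str = "1TCM",
    fixed_delay: float = 0.0,
    weight_scheme: str = "duration",
    bounds: dict | None = None,
    n_starts: int = 8,
    grid_step: float = DEFAULT_GRID_STEP,
) -> ModelFitResult:
    """Weighted nonlinear least-squares fit of one compartment model.

    The delay is fixed (estimated once per scan from the early whole-brain
    curve); free parameters are K1, k2, V_b plus k3 (2TiCM) and k3, k4 (2TCM).
    Multistart from a fixed log-spaced grid; ties broken by lowest WRSS then
    smallest parameter norm.  Non-convergence from every start is flagged on
    the result rather than raised.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    free_names = _FREE_PARAMS[model_kind]
    n_free = len(free_names)
    n_frames = len(tac.schedule)
    if n_frames < n_free + 2:
        raise ValueError(
            f"{model_kind} needs at least {n_free + 2} frames, got {n_frames}"
        )

    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.array([b[nm][0] for nm in free_names])
    hi = np.array([b[nm][1] for nm in free_names])

    sched = tac.schedule
    y = tac.activity
    if tac.weights is not None:
        w = tac.weights * n_frames / tac.weights.sum()
    else:
        w = frame_weights(sched, weight_scheme, activity=y)
    sw = np.sqrt(w)

    # input curves do not depend on the free parameters: precompute on the grid
    t_end = float(sched.end[-1])
    n = int(round(t_end / grid_step)) + 1
    t_grid = np.linspace(0.0, t_end, n)
    h = float(t_grid[1] - t_grid[0])
    cp = np.asarray(input_fn.corrected_plasma(t_grid - fixed_delay), dtype=float)
    wb = np.asarray(input_fn.whole_blood(t_grid - fixed_delay), dtype=float)

    def make_params(x) -> KineticParameters:
        p = dict(zip(free_names, x))
        return KineticParameters(
            K1=p["K1"], k2=p["k2"], k3=p.get("k3", 0.0), k4=p.get("k4", 0.0),
            vb=p["vb"], delta_t=fixed_delay, model_kind=model_kind,
        )

    def predict(x):
        params = make_params(x)
        ct = np.zeros_like(cp)
        for amp, rate in _impulse_terms(params):
            if amp != 0.0:
                ct += amp * _exp_conv(cp, h, rate)
        curve = (1.0 - params.vb) * ct + params.vb * wb
        return _frame_average(curve, t_grid, sched)

    def resid(x):
        return sw * (predict(x) - y)

    best, best_res = None, None
    x_scale = np.where(hi > 0.25, 0.05, 0.02)
    for x0 in _start_grid(model_kind, n_starts):
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        try:
            res = optimize.least_squares(
                resid, x0, bounds=(lo, hi), x_scale=x_scale,
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400 * n_free,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-15 or (
            abs(res.cost - best.cost) <= 1e-15
            and np.linalg.norm(res.x) < np.linalg.norm(best.x)
        ):
            best = res
    converged = best is not None and best.status > 0
    if best is None:
        raise RuntimeError(f"{model_kind} fit failed to run from any start")

    est = best.x
    params = make_params(est)
    wrss = float(2.0 * best.cost)
    dof = max(n_frames - n_free, 1)
    JtJ = best.jac.T @ best.jac
    cov = np.linalg.pinv(JtJ) * (wrss / dof)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    rse = {
        nm: (100.0 * s / abs(v) if v != 0 else np.inf)
        for nm, s, v in zip(free_names, se, est)
    }
    aic_value = _aic(max(wrss, 1e-300), n_frames, n_free)

    result = ModelFitResult(
        parameters=params, free_names=free_names, estimates=est, covariance=cov,
        wrss=wrss, n_frames=n_frames, n_free=n_free, aic=aic_value, rse=rse,
        converged=converged,
        message="" if converged else "no start converged; best WRSS reported",
    )
    macro, macro_rse = _macro_with_rse(params, free_names, est, cov)
    if model_kind == "2TiCM":
        result.ki, result.ki_rse = macro, macro_rse
    else:
        result.vt, result.vt_rse = macro, macro_rse
    if model_kind == "1TCM" and params.k2 > 0:
        result.clearance_half_life = math.log(2.0) / params.k2
    return result


# ---------------------------------------------------------------------------
# macroparameters


def derive_macroparameters(params: KineticParameters) -> dict:
    """V_T, K_i and clearance half-life from the microparameters.

    1TCM:  V_T = K1/k2.  2TCM: V_T = (K1/k2)(1 + k3/k4).  2TiCM:
    K_i = K1*k3/(k2+k3); V_T is undefined (irreversible trapping).
    """
    out: dict = {}
    kind = params.model_kind
    if kind == "2TiCM":
        out["K_i"] = (
            params.K1 * params.k3 / (params.k2 + params.k3)
            if (params.k2 + params.k3) > 0 else 0.0
        )
    elif kind == "1TCM":
        out["V_T"] = params.K1 / params.k2 if params.k2 > 0 else math.inf
    else:
        if params.k2 <= 0 or params.k4 <= 0:
            out["V_T"] = math.inf
        else:
            out["V_T"] = (params.K1 / params.k2) * (1.0 + params.k3 / params.k4)
    if params.k2 > 0:
        out["clearance_half_life"] = math.log(2.0) / params.k2
    else:
        out["clearance_half_life"] = math.inf
    if "V_T" in out and not math.isfinite(out["V_T"]):
        out["V_T_flag"] = "infinite (k2 or k4 is zero)"
    return out


def vt_or_raise(params: KineticParameters) -> float:
    """V_T for reversible models; explicit error for the irreversible model."""
    if params.model_kind == "2TiCM":
        raise ValueError("V_T is undefined for the irreversible 2TiCM")
    return derive_macroparameters(params)["V_T"]
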