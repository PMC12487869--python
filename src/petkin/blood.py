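"""Arterial blood processing: plasma / whole-blood curve models, metabolite
correction and the assembled input function.

Discrete arterial samples are turned into continuous-time models:

* total plasma and whole blood — piecewise-linear rise from zero through the
  observed peak, then a sum of decaying exponentials fitted to the post-peak
  samples (amplitudes solved by non-negative least squares, rates by bounded
  nonlinear least squares — a variable-projection fit);
* unchanged parent fraction — ``PF(t) = 1 - a * G(t; alpha, beta)`` with ``G``
  the gamma CDF, so PF(0) = 1, PF is monotone non-increasing and tends to
  ``1 - a``;
* the metabolite-corrected input function is the pointwise product of the
  fitted total-plasma curve and the parent-fraction curve.

All times are minutes post-injection; activities are kBq/cm^3 and assumed
decay-corrected to injection time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BloodSampleTable",
    "ParentFractionTable",
    "PlasmaCurveModel",
    "ParentFractionModel",
    "InputFunction",
    "fit_plasma_curve",
    "fit_parent_fraction",
    "make_input_function",
    "suv",
    "suv_to_activity",
]


# ---------------------------------------------------------------------------
# sample tables


@dataclass(frozen=True)
class BloodSampleTable:
    """Discrete arterial samples: time (min), whole-blood and plasma activity
    (kBq/cm^3)."""

    time_min: np.ndarray
    whole_blood_kBq_cc: np.ndarray
    plasma_kBq_cc: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        wb = np.asarray(self.whole_blood_kBq_cc, dtype=float)
        pl = np.asarray(self.plasma_kBq_cc, dtype=float)
        if not (len(t) == len(wb) == len(pl)):
            raise ValueError("blood table columns must have equal length")
        if len(t) < 4:
            raise ValueError(
                f"need at least 4 blood samples to fit any model, got {len(t)}"
            )
        if np.any(np.diff(t) <= 0):
            raise ValueError("blood sample times must be strictly increasing")
        if np.any(wb < 0) or np.any(pl < 0):
            raise ValueError("blood activities must be non-negative")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "whole_blood_kBq_cc", wb)
        object.__setattr__(self, "plasma_kBq_cc", pl)


@dataclass(frozen=True)
class ParentFractionTable:
    """Measured unchanged-parent fractions at discrete times."""

    time_min: np.ndarray
    parent_fraction: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        pf = np.asarray(self.parent_fraction, dtype=float)
        if len(t) != len(pf):
            raise ValueError("parent-fraction columns must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("parent-fraction times must be strictly increasing")
        if np.any(pf < 0) or np.any(pf > 1):
            raise ValueError("parent fractions must lie in [0, 1]")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "parent_fraction", pf)


# ---------------------------------------------------------------------------
# continuous-time models


@dataclass(frozen=True)
class PlasmaCurveModel:
    """Piecewise model of a blood/plasma concentration curve.

    Before ``peak_time`` the curve linearly interpolates ``(pre_times,
    pre_values)`` (zero at and before t = 0); from ``peak_time`` on it is
    ``sum_j A_j * exp(-lambda_j * (t - peak_time))``.  The last pre-peak node
    equals the exponential value at the peak, so the model is continuous.
    """

    peak_time: float
    pre_times: np.ndarray
    pre_values: np.ndarray
    amplitudes: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pre_times", np.asarray(self.pre_times, dtype=float))
        object.__setattr__(self, "pre_values", np.asarray(self.pre_values, dtype=float))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        if np.any(self.amplitudes < 0) or np.any(self.rates < 0):
            raise ValueError("amplitudes and rates must be non-negative")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pre = (t > 0) & (t < self.peak_time)
        post = t >= self.peak_time
        if pre.any():
            out[pre] = np.interp(t[pre], self.pre_times, self.pre_values)
        if post.any():
            tau = t[post, None] - self.peak_time
            out[post] = np.sum(
                self.amplitudes[None, :] * np.exp(-self.rates[None, :] * tau), axis=1
            )
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "kind": "plasma_curve",
            "peak_time_min": float(self.peak_time),
            "pre_times_min": self.pre_times.tolist(),
            "pre_values_kBq_cc": self.pre_values.tolist(),
            "amplitudes_kBq_cc": self.amplitudes.tolist(),
            "rates_per_min": self.rates.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlasmaCurveModel":
        return cls(
            peak_time=d["peak_time_min"],
            pre_times=d["pre_times_min"],
            pre_values=d["pre_values_kBq_cc"],
            amplitudes=d["amplitudes_kBq_cc"],
            rates=d["rates_per_min"],
        )


@dataclass(frozen=True)
class ParentFractionModel:
    """PF(t) = 1 - a * G(t; alpha, beta), G the gamma CDF (rate beta, 1/min).

    ``a`` is the asymptotic metabolized fraction, so PF decreases monotonically
    from 1 at t = 0 towards ``1 - a``.
    """

    a: float
    alpha: float
    beta: float

    def __post_init__(self):
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("a must be in [0, 1]")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = 1.0 - self.a * stats.gamma.cdf(np.clip(t, 0.0, None), self.alpha,
                                            scale=1.0 / self.beta)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "kind": "parent_fraction",
            "a": float(self.a),
            "alpha": float(self.alpha),
            "beta_per_min": float(self.beta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParentFractionModel":
        return cls(a=d["a"], alpha=d["alpha"], beta=d["beta_per_min"])


@dataclass(frozen=True)
class InputFunction:
    """Metabolite-corrected arterial input: fitted total plasma x parent
    fraction, plus the fitted whole-blood curve and the plasma free fraction."""

    plasma_model: PlasmaCurveModel
    parent_model: ParentFractionModel
    whole_blood_model: PlasmaCurveModel
    f_p: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.f_p <= 1.0:
            raise ValueError("f_p must be in (0, 1]")

    def plasma(self, t):
        return self.plasma_model(t)

    def parent_fraction(self, t):
        return self.parent_model(t)

    def corrected_plasma(self, t):
        return self.plasma_model(t) * self.parent_model(t)

    def whole_blood(self, t):
        return self.whole_blood_model(t)

    def to_dict(self) -> dict:
        return {
            "kind": "input_function",
            "plasma": self.plasma_model.to_dict(),
            "parent_fraction": self.parent_model.to_dict(),
            "whole_blood": self.whole_blood_model.to_dict(),
            "f_p": float(self.f_p),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InputFunction":
        return cls(
            plasma_model=PlasmaCurveModel.from_dict(d["plasma"]),
            parent_model=ParentFractionModel.from_dict(d["parent_fraction"]),
            whole_blood_model=PlasmaCurveModel.from_dict(d["whole_blood"]),
            f_p=d["f_p"],
        )


# ---------------------------------------------------------------------------
# fitting

_RATE_LO, _RATE_HI = 1e-9, 20.0


def _nnls_amplitudes(tau: np.ndarray, y: np.ndarray, rates: np.ndarray):
    basis = np.exp(-np.outer(tau, rates))
    amps, _ = optimize.nnls(basis, y)
    return amps, basis @ amps


def _fit_exponential_tail(tau, y, n_exp):
    """Variable-projection fit of sum_j A_j exp(-rate_j tau); amplitudes by
    NNLS, log-rates by bounded least squares from several deterministic
    starts."""

    def resid(log_rates):
        _, pred = _nnls_amplitudes(tau, y, np.exp(log_rates))
        return pred - y

    span = max(tau[-1], 1.0)
    # starts spread over fast/slow rate mixes; deterministic
    base_sets = [
        np.geomspace(3.0 / span, 2.0, n_exp),
        np.geomspace(0.5 / span, 0.5, n_exp),
        np.geomspace(10.0 / span, 5.0, n_exp),
        np.geomspace(0.1 / span, 0.05, n_exp) if n_exp > 1 else np.array([0.01]),
    ]
    best = None
    lo = np.full(n_exp, np.log(_RATE_LO))
    hi = np.full(n_exp, np.log(_RATE_HI))
    for rates0 in base_sets:
        rates0 = np.clip(np.sort(rates0)[::-1], _RATE_LO * 2, _RATE_HI / 2)
        try:
            res = optimize.least_squares(
                resid, np.log(rates0), bounds=(lo, hi), xtol=1e-14, ftol=1e-14,
                gtol=1e-14, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("exponential tail fit failed from every start")
    rates = np.exp(best.x)
    amps, _ = _nnls_amplitudes(tau, y, rates)
    order = np.argsort(-rates)
    return amps[order], rates[order], 2.0 * best.cost


def fit_plasma_curve(
    time_min,
    activity,
    n_exponentials: int | str = 3,
) -> PlasmaCurveModel:
    """Fit a plasma (or whole-blood) curve: exact piecewise-linear pre-peak,
    sum of ``n_exponentials`` decaying exponentials from the peak on.

    ``n_exponentials="auto"`` tries 1-3 terms and keeps the lowest-AIC tail.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(activity, dtype=float)
    if np.all(y == 0):
        raise ValueError("all activities are zero; nothing to fit")
    ipk = int(np.argmax(y))
    t_peak = t[ipk]
    tau = t[ipk:] - t_peak
    y_post = y[ipk:]

    if isinstance(n_exponentials, str):
        if n_exponentials != "auto":
            raise ValueError("n_exponentials must be 1-3 or 'auto'")
        candidates = [n for n in (1, 2, 3) if len(tau) >= n + 2]
        if not candidates:
            raise ValueError(
                f"need at least 3 post-peak samples, got {len(tau)}"
            )
        best_aic, best_fit = np.inf, None
        m = len(tau)
        # floor RSS at the numerical precision of the data so that nested
        # noiseless fits compare by parsimony, not by rounding noise
        rss_floor = m * (1e-8 * float(np.max(y_post))) ** 2
        for n in candidates:
            amps, rates, rss = _fit_exponential_tail(tau, y_post, n)
            aic = m * np.log(max(rss, rss_floor) / m) + 2 * (2 * n)
            if aic < best_aic:
                best_aic, best_fit = aic, (amps, rates)
        amps, rates = best_fit
    else:
        n = int(n_exponentials)
        if not 1 <= n <= 3:
            raise ValueError("n_exponentials must be between 1 and 3")
        if len(tau) < n + 2:
            raise ValueError(
                f"need at least {n + 2} samples at/after the peak for "
                f"{n} exponentials, got {len(tau)}"
            )
        amps, rates, _ = _fit_exponential_tail(tau, y_post, n)

    peak_value = float(np.sum(amps))
    pre_times = np.concatenate([[0.0], t[:ipk], [t_peak]])
    pre_values = np.concatenate([[0.0], y[:ipk], [peak_value]])
    keep = np.concatenate([[True], np.diff(pre_times) > 0])
    return PlasmaCurveModel(
        peak_time=t_peak,
        pre_times=pre_times[keep],
        pre_values=pre_values[keep],
        amplitudes=amps,
        rates=rates,
    )


def fit_parent_fraction(time_min, parent_fraction) -> ParentFractionModel:
    """Least-squares fit of PF(t) = 1 - a*G(t; alpha, beta) to measured
    fractions.  Noisy, locally non-monotone samples are allowed; the fitted
    curve is monotone by construction."""
    t = np.asarray(time_min, dtype=float)
    pf = np.asarray(parent_fraction, dtype=float)
    if len(t) < 3:
        raise ValueError(
            f"need at least 3 parent-fraction samples (3 free parameters), got {len(t)}"
        )
    if np.any(pf < 0) or np.any(pf > 1):
        raise ValueError("parent fractions must lie in [0, 1]")

    if np.allclose(pf, 1.0, atol=1e-12):
        return ParentFractionModel(a=0.0, alpha=2.0, beta=0.02)

    def resid(x):
        a, alpha, beta = x
        return (1.0 - a * stats.gamma.cdf(t, alpha, scale=1.0 / beta)) - pf

    lo = [0.0, 1e-3, 1e-6]
    hi = [1.0, 100.0, 10.0]
    starts = [
        (min(1.0, 1.2 * (1.0 - pf.min())), 2.0, 2.0 / max(t[-1], 1.0)),
        (0.5, 1.0, 0.05),
        (0.9, 4.0, 0.01),
        (0.2, 2.0, 0.1),
    ]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)
        res = optimize.least_squares(
            resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res
    a, alpha, beta = best.x
    return ParentFractionModel(a=float(a), alpha=float(alpha), beta=float(beta))


def make_input_function(
    plasma: PlasmaCurveModel,
    parent: ParentFractionModel,
    whole_blood: PlasmaCurveModel,
    f_p: float = 1.0,
) -> InputFunction:
    """Assemble the metabolite-corrected input function from fitted parts."""
    return InputFunction(
        plasma_model=plasma, parent_model=parent, whole_blood_model=whole_blood,
        f_p=f_p,
    )


# ---------------------------------------------------------------------------
# SUV


def suv(activity_kBq_cc, injected_dose_MBq: float, body_weight_kg: float):
    """Standardized uptake value: activity over injected dose per gram of body
    mass (tissue density taken as 1 g/cm^3)."""
    if injected_dose_MBq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    dose_kBq_per_g = injected_dose_MBq * 1000.0 / (body_weight_kg * 1000.0)
    return np.asarray(activity_kBq_cc, dtype=float) / dose_kBq_per_g


def suv_to_activity(suv_value, injected_dose_MBq: float, body_weight_kg: float):
    """Inverse of :func:`suv`."""
    if injected_dose_MBq <= 0 or body_weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    dose_kBq_per_g = injected_dose_MBq * 1000.0 / (body_weight_kg * 1000.0)
    return np.asarray(suv_value, dtype=float) * dose_kBq_per_g
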