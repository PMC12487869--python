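"""Binding metrics from regional V_T values: Lassen occupancy plots, BP_ND
and the Guo cross-tracer plot.

The Lassen (occupancy) plot regresses the baseline-minus-blocking V_T
difference on baseline V_T across regions; under a shared occupancy r and a
common nondisplaceable volume V_ND the points lie on

    dV_T = r * (V_T_base - V_ND),

so the slope estimates r and the x-intercept estimates V_ND.  BP_ND follows as
V_T / V_ND - 1.  The Guo plot regresses one tracer's regional baseline V_T on
another's; its slope equals f_p^A K_D^B / (f_p^B K_D^A), giving the affinity
ratio once the measured plasma free fractions are supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "OccupancyResult",
    "GuoResult",
    "lassen_fit",
    "compute_bpnd",
    "guo_fit",
]


@dataclass(frozen=True)
class OccupancyResult:
    """Occupancy r (fraction), V_ND (mL/cm^3) and their SEs from one
    baseline/blocking scan pair."""

    occupancy: float
    vnd: float
    se_occupancy: float
    se_vnd: float
    n_rois: int
    vnd_defined: bool = True
    note: str = ""


@dataclass(frozen=True)
class GuoResult:
    """Cross-tracer regression of baseline V_T values (tracer A on B)."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    kd_ratio: float            # K_D^B / K_D^A
    n_rois: int
    bp_ratio: float | None = None          # BP_ND^A / BP_ND^B
    intercept_over_vnd_a: float | None = None


def _tls_line(x: np.ndarray, y: np.ndarray):
    """Orthogonal (total) least-squares line through (x, y)."""
    xm, ym = x.mean(), y.mean()
    u = np.column_stack([x - xm, y - ym])
    _, _, vt = np.linalg.svd(u, full_matrices=False)
    nx, ny = vt[-1]  # normal vector of the best line
    if abs(ny) < 1e-300:
        raise ValueError("total least squares line is vertical")
    slope = -nx / ny
    return slope, ym - slope * xm


def lassen_fit(vt_baseline, vt_blocking, method: str = "ols",
               slope_tol: float = 1e-12) -> OccupancyResult:
    """Occupancy plot: regress dV_T = V_T_base - V_T_block on V_T_base.

    Slope = occupancy r; V_ND = -intercept / r (x-intercept).  SEs come from
    the OLS covariance, V_ND's by the delta method.  When the slope is
    (numerically) zero — no blocking effect — V_ND is undefined and flagged
    instead of propagating NaNs.  ``method="tls"`` uses orthogonal regression
    for the point estimates (both axes carry error); SEs are then from the
    OLS fit as an approximation.
    """
    x = np.asarray(vt_baseline, dtype=float)
    y = x - np.asarray(vt_blocking, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 paired ROIs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("baseline V_T values are all equal; no regression possible")

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    b, r = fit.params          # intercept, slope
    se_b, se_r = fit.bse
    cov_br = fit.cov_params()[0, 1]
    if method == "tls":
        r, b = _tls_line(x, y)
    elif method != "ols":
        raise ValueError(f"unknown method {method!r}")

    if abs(r) <= slope_tol:
        return OccupancyResult(
            occupancy=float(r), vnd=math.nan, se_occupancy=float(se_r),
            se_vnd=math.nan, n_rois=len(x), vnd_defined=False,
            note="slope ~ 0 (no blocking effect): V_ND undefined",
        )
    vnd = -b / r
    # delta method: var(-b/r) = var(b)/r^2 + b^2 var(r)/r^4 - 2 b cov(b,r)/r^3
    var_vnd = (se_b ** 2) / r ** 2 + (b ** 2) * (se_r ** 2) / r ** 4 \
        - 2.0 * b * cov_br / r ** 3
    se_vnd = math.sqrt(var_vnd) if var_vnd > 0 else math.nan
    return OccupancyResult(
        occupancy=float(r), vnd=float(vnd), se_occupancy=float(se_r),
        se_vnd=float(se_vnd), n_rois=len(x),
    )


def compute_bpnd(vt, vnd: float):
    """Nondisplaceable binding potential BP_ND = V_T / V_ND - 1."""
    if vnd <= 0:
        raise ValueError(
            f"V_ND must be positive to compute BP_ND (got {vnd}); "
            "negative estimates are unphysical"
        )
    return np.asarray(vt, dtype=float) / vnd - 1.0


def guo_fit(vt_a, vt_b, f_p_a: float, f_p_b: float,
            vnd_a=None, vnd_b=None) -> GuoResult:
    """Guo plot: OLS of tracer A's baseline regional V_T on tracer B's.

    slope = f_p^A K_D^B / (f_p^B K_D^A), so the affinity ratio
    K_D^B/K_D^A = slope * f_p^B / f_p^A.  When V_ND estimates for both
    tracers are supplied, the BP_ND ratio A/B = slope * mean(V_ND^B) /
    mean(V_ND^A) and the V_ND-normalized intercept are also reported.
    """
    xa = np.asarray(vt_a, dtype=float)
    xb = np.asarray(vt_b, dtype=float)
    if len(xa) != len(xb):
        raise ValueError("tracers must share the same ROI set")
    if len(xa) < 3:
        raise ValueError(f"need at least 3 shared ROIs, got {len(xa)}")
    if np.ptp(xb) == 0:
        raise ValueError("degenerate regressor: tracer-B V_T values all equal")
    if not (0 < f_p_a <= 1 and 0 < f_p_b <= 1):
        raise ValueError("free fractions must be in (0, 1]")

    fit = sm.OLS(xa, sm.add_constant(xb)).fit()
    intercept, slope = fit.params
    se_int, se_slope = fit.bse
    kd_ratio = slope * f_p_b / f_p_a

    bp_ratio = None
    intercept_norm = None
    if vnd_a is not None and vnd_b is not None:
        mean_vnd_a = float(np.mean(vnd_a))
        mean_vnd_b = float(np.mean(vnd_b))
        if mean_vnd_a > 0 and mean_vnd_b > 0:
            bp_ratio = slope * mean_vnd_b / mean_vnd_a
            intercept_norm = intercept / mean_vnd_a
    return GuoResult(
        slope=float(slope), intercept=float(intercept),
        se_slope=float(se_slope), se_intercept=float(se_int),
        kd_ratio=float(kd_ratio), n_rois=len(xa),
        bp_ratio=None if bp_ratio is None else float(bp_ratio),
        intercept_over_vnd_a=None if intercept_norm is None else float(intercept_norm),
    )
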