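"""Time-stability and rest-period ("broken scan") analysis.

Scan-time reduction is probed by truncating the TAC at successively earlier
endpoints (default 180 down to 60 min in 30-min steps) and refitting; a
rest period is modelled by removing the frames inside a gap and refitting.
Percent differences are reported against the full-scan estimate (the
denominator convention), and an endpoint passes when |dV_T| <= 10%.

The delay estimated from the full early scan is reused for every truncated or
gapped refit — the early frames are always retained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinetics import (FrameSchedule, TimeActivityCurve, fit_tissue_model)

__all__ = ["time_stability", "rest_period_analysis", "DEFAULT_ENDPOINTS"]

DEFAULT_ENDPOINTS = (180.0, 150.0, 120.0, 90.0, 60.0)

_N_FREE = {"1TCM": 3, "2TCM": 5, "2TiCM": 4}


def _subset_tac(tac: TimeActivityCurve, keep: np.ndarray) -> TimeActivityCurve:
    sched = FrameSchedule(start=tac.schedule.start[keep], end=tac.schedule.end[keep])
    return TimeActivityCurve(
        roi_name=tac.roi_name, schedule=sched, activity=tac.activity[keep],
        weights=None if tac.weights is None else tac.weights[keep],
    )


def _refit_row(tac, input_fn, keep, model_kind, fixed_delay, full_fit,
               label: dict, pass_band: float, **fit_kw) -> dict:
    row = dict(label)
    row.update(roi=tac.roi_name, n_frames=int(keep.sum()))
    if keep.sum() < _N_FREE[model_kind] + 2:
        row.update(error=f"only {int(keep.sum())} frames left; "
                         f"{model_kind} needs {_N_FREE[model_kind] + 2}")
        return row
    fit = fit_tissue_model(_subset_tac(tac, keep), input_fn, model_kind,
                           fixed_delay=fixed_delay, **fit_kw)
    primary = "ki" if model_kind == "2TiCM" else "vt"
    full_v = getattr(full_fit, primary)
    short_v = getattr(fit, primary)
    pct = 100.0 * (short_v - full_v) / full_v
    row.update({
        f"{primary}_full": full_v, f"{primary}_short": short_v,
        f"pct_diff_{primary}": pct,
        "k1_full": full_fit.parameters.K1, "k1_short": fit.parameters.K1,
        "pct_diff_k1": 100.0 * (fit.parameters.K1 - full_fit.parameters.K1)
                       / full_fit.parameters.K1,
        "pass_10pct": bool(abs(pct) <= pass_band),
        "error": "",
    })
    return row


def time_stability(tac: TimeActivityCurve, input_fn,
                   endpoints=DEFAULT_ENDPOINTS, model_kind: str = "1TCM",
                   fixed_delay: float = 0.0, pass_band: float = 10.0,
                   **fit_kw) -> pd.DataFrame:
    """Refit after truncating the TAC at each endpoint (minutes); report the
    percent difference of V_T (or K_i) and K1 against the full-scan fit."""
    scan_end = float(tac.schedule.end[-1])
    for ep in endpoints:
        if not 0.0 < ep <= scan_end + 1e-9:
            raise ValueError(f"endpoint {ep} min outside (0, {scan_end}]")
    full_fit = fit_tissue_model(tac, input_fn, model_kind,
                                fixed_delay=fixed_delay, **fit_kw)
    rows = []
    for ep in endpoints:
        keep = tac.schedule.end <= ep + 1e-9
        rows.append(_refit_row(tac, input_fn, keep, model_kind, fixed_delay,
                               full_fit, {"endpoint_min": float(ep)},
                               pass_band, **fit_kw))
    return pd.DataFrame(rows)


def rest_period_analysis(tac: TimeActivityCurve, input_fn,
                         gap_start: float, gap_duration: float,
                         model_kind: str = "1TCM", fixed_delay: float = 0.0,
                         pass_band: float = 10.0, **fit_kw) -> pd.DataFrame:
    """Remove the frames overlapping [gap_start, gap_start + gap_duration)
    and refit; report percent differences against the full-scan fit."""
    scan_end = float(tac.schedule.end[-1])
    if gap_duration < 0:
        raise ValueError("gap duration must be non-negative")
    if not 0.0 <= gap_start <= scan_end:
        raise ValueError(f"gap start {gap_start} min outside the scan")
    gap_end = gap_start + gap_duration
    keep = ~((tac.schedule.start < gap_end - 1e-9)
             & (tac.schedule.end > gap_start + 1e-9))
    full_fit = fit_tissue_model(tac, input_fn, model_kind,
                                fixed_delay=fixed_delay, **fit_kw)
    row = _refit_row(tac, input_fn, keep, model_kind, fixed_delay, full_fit,
                     {"gap_start_min": float(gap_start),
                      "gap_duration_min": float(gap_duration)},
                     pass_band, **fit_kw)
    return pd.DataFrame([row])
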