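"""Compartment-model selection: AIC, nested F-test and rSE-based reliability.

A more complex model is preferred over the 1TCM only when its F-test against
the 1TCM is significant (p <= alpha) AND it carries the lowest AIC of all
fitted models; otherwise selection falls back to the 1TCM.  The irreversible
2TiCM is not nested in the 1TCM (k4 = 0 vs k3 = 0), so that comparison uses
AIC alone; the F-test is computed for the properly nested pairs 1TCM<2TCM and
2TiCM<2TCM.  Reliability of the primary parameter (V_T, or K_i for 2TiCM) is
flagged when its relative standard error is at most ``rse_threshold`` percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

__all__ = ["aic", "f_test_nested", "ModelComparison", "select_model"]


def aic(wrss: float, n: int, p: int) -> float:
    """Akaike information criterion for a least-squares fit:
    AIC = n*ln(WRSS/n) + 2p (no small-sample correction)."""
    if wrss <= 0:
        raise ValueError("WRSS must be positive")
    if n <= p:
        raise ValueError("need more observations than free parameters")
    return n * math.log(wrss / n) + 2 * p


def aicc(wrss: float, n: int, p: int) -> float:
    """Small-sample corrected AIC; requires n > p + 1."""
    if n <= p + 1:
        raise ValueError("AICc requires n > p + 1")
    return aic(wrss, n, p) + 2.0 * p * (p + 1) / (n - p - 1)


def f_test_nested(wrss_simple: float, p_simple: int, wrss_complex: float,
                  p_complex: int, n: int) -> tuple:
    """F-test between nested least-squares fits.

    Returns (F, p_value) with df (p_complex - p_simple, n - p_complex).  A
    complex model that fits worse than the simple one (possible with bounded
    multistart optimization) yields F = 0, p = 1.
    """
    if p_complex <= p_simple:
        raise ValueError("complex model must have more free parameters")
    if n <= p_complex:
        raise ValueError("need more observations than complex-model parameters")
    if wrss_complex >= wrss_simple:
        return 0.0, 1.0
    df1 = p_complex - p_simple
    df2 = n - p_complex
    F = ((wrss_simple - wrss_complex) / df1) / (wrss_complex / df2)
    return float(F), float(stats.f.sf(F, df1, df2))


@dataclass
class ModelComparison:
    """Outcome of model selection for one TAC, with every intermediate flag
    needed to reproduce the choice."""

    chosen_model: str
    aics: dict
    wrss: dict
    n_free: dict
    primary_rse: dict
    f_pvalues: dict = field(default_factory=dict)  # e.g. {"1TCM_vs_2TCM": p}
    n_frames: int = 0
    f_test_significant: bool = False
    lowest_aic: bool = True
    rse_reliable: bool = False
    alpha: float = 0.05
    rse_threshold: float = 10.0


def select_model(fits: dict, alpha: float = 0.05,
                 rse_threshold: float = 10.0) -> ModelComparison:
    """Choose the best compartment model from fits keyed by model kind.

    ``fits`` maps "1TCM"/"2TCM"/"2TiCM" to fit results carrying ``wrss``,
    ``n_frames``, ``n_free``, ``aic`` and ``primary_rse`` (percent).  The
    1TCM fit must be present.
    """
    if not fits:
        raise ValueError("no fits supplied")
    if "1TCM" not in fits:
        raise ValueError("model selection requires a 1TCM fit")

    aics = {k: f.aic for k, f in fits.items()}
    wrss = {k: f.wrss for k, f in fits.items()}
    n_free = {k: f.n_free for k, f in fits.items()}
    rses = {k: f.primary_rse for k, f in fits.items()}
    n = fits["1TCM"].n_frames
    min_aic = min(aics.values())

    pvals = {}
    if "2TCM" in fits:
        _, pvals["1TCM_vs_2TCM"] = f_test_nested(
            wrss["1TCM"], n_free["1TCM"], wrss["2TCM"], n_free["2TCM"], n
        )
    if "2TiCM" in fits and "2TCM" in fits:
        _, pvals["2TiCM_vs_2TCM"] = f_test_nested(
            wrss["2TiCM"], n_free["2TiCM"], wrss["2TCM"], n_free["2TCM"], n
        )

    better = []
    if "2TCM" in fits and pvals.get("1TCM_vs_2TCM", 1.0) <= alpha \
            and aics["2TCM"] <= min_aic:
        better.append("2TCM")
    if "2TiCM" in fits and aics["2TiCM"] <= min_aic:
        better.append("2TiCM")  # non-nested vs 1TCM: AIC-only rule
    chosen = min(better, key=lambda k: aics[k]) if better else "1TCM"

    chosen_rse = rses.get(chosen)
    return ModelComparison(
        chosen_model=chosen,
        aics=aics,
        wrss=wrss,
        n_free=n_free,
        primary_rse=rses,
        f_pvalues=pvals,
        n_frames=n,
        f_test_significant=(
            chosen == "2TCM" and pvals.get("1TCM_vs_2TCM", 1.0) <= alpha
        ),
        lowest_aic=aics[chosen] <= min_aic,
        rse_reliable=(chosen_rse is not None and chosen_rse <= rse_threshold),
        alpha=alpha,
        rse_threshold=rse_threshold,
    )
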