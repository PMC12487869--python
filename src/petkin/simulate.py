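"""Synthetic study generator with known ground truth.

Emulates a slow, reversible GAT-1 radiotracer study in nonhuman primates:
a 45-frame / 180-min dynamic scan, 11 gray-matter ROIs with baseline V_T
between ~2.0 and 4.6 mL/cm^3, 1TCM kinetics with a tissue clearance half-life
of 175 min (k2 = ln 2 / 175), a blood-volume fraction of 0.036, slow
peripheral metabolism (parent fraction ~0.88/0.83/0.79 at 30/90/180 min) and
paired baseline/blocking scans sharing one occupancy and one V_ND per animal
(blocking V_T = V_ND + (1 - r)(V_T_base - V_ND), K1 unchanged).

Randomness comes from a single top-level seed expanded into named
``numpy.random.SeedSequence`` child streams, in a fixed documented order
(blood, parent fraction, then one stream per ROI TAC, per scan); the ground
truth written next to the data is sufficient to regenerate every curve
bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .blood import (BloodSampleTable, InputFunction, ParentFractionModel,
                    ParentFractionTable, PlasmaCurveModel)
from .kinetics import (FrameSchedule, KineticParameters, TimeActivityCurve,
                       predict_tac)

__all__ = [
    "ROI_BASELINE_VT",
    "SyntheticStudyConfig",
    "parent_model_from_anchors",
    "default_plasma_truth",
    "generate_input",
    "generate_tacs",
    "generate_study",
]

#: 11 gray-matter ROIs with realistic baseline V_T (mL/cm^3) for the lead
#: tracer; spans the ~2.0-4.6 range seen for this target.
ROI_BASELINE_VT = {
    "brain_stem": 2.61,
    "caudate": 2.25,
    "cerebellum": 3.36,
    "cingulate": 4.30,
    "frontal": 3.73,
    "hippocampus": 2.98,
    "insula": 4.46,
    "occipital": 4.55,
    "putamen": 2.71,
    "temporal": 4.48,
    "thalamus": 1.96,
}

K2_DEFAULT = np.log(2.0) / 175.0   # 1/min, clearance half-life 175 min
VB_DEFAULT = 0.036                 # mL/cm^3 blood volume fraction

#: metabolite-analysis sampling times (min)
PARENT_SAMPLE_TIMES = (5.0, 15.0, 30.0, 60.0, 90.0, 120.0, 180.0)

#: arterial blood sampling schedule (min): dense through the bolus, sparse late
BLOOD_SAMPLE_TIMES = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0, 12.0,
                      20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 150.0, 180.0)

#: parent-fraction anchor points PF(t) for the default (slow) metabolism
PARENT_ANCHORS = ((30.0, 0.88), (90.0, 0.83), (180.0, 0.79))


def parent_model_from_anchors(anchors=PARENT_ANCHORS) -> ParentFractionModel:
    """Solve (a, alpha, beta) of PF(t) = 1 - a*G(t; alpha, beta) so the curve
    passes through the anchor points (deterministic root solve)."""
    t = np.array([p[0] for p in anchors])
    pf = np.array([p[1] for p in anchors])

    def resid(x):
        a, alpha, beta = x
        return (1.0 - a * stats.gamma.cdf(t, alpha, scale=1.0 / beta)) - pf

    res = optimize.least_squares(
        resid, [0.3, 2.0, 0.02],
        bounds=([0.0, 1e-3, 1e-6], [1.0, 100.0, 10.0]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    a, alpha, beta = res.x
    return ParentFractionModel(a=float(a), alpha=float(alpha), beta=float(beta))


def default_plasma_truth(peak_time: float = 1.0,
                         amplitudes=(30.0, 6.0, 3.5),
                         rates=(0.8, 0.08, 0.0035)) -> PlasmaCurveModel:
    """Total-plasma truth: linear rise from zero to the bolus peak, then a
    tri-exponential decay."""
    peak_value = float(np.sum(amplitudes))
    return PlasmaCurveModel(
        peak_time=peak_time,
        pre_times=[0.0, peak_time],
        pre_values=[0.0, peak_value],
        amplitudes=amplitudes,
        rates=rates,
    )


@dataclass
class SyntheticStudyConfig:
    """Ground truth and noise settings for one synthetic study."""

    seed: int = 0
    n_animals: int = 3
    roi_vt: dict = field(default_factory=lambda: dict(ROI_BASELINE_VT))
    k2: float = K2_DEFAULT
    vb: float = VB_DEFAULT
    delta_t: float = 0.0
    occupancy: float | tuple = 0.68        # scalar or one value per animal
    vnd: float = 0.88                      # mL/cm^3, shared across ROIs
    f_p: float = 0.135
    injected_dose_MBq: float = 182.0
    body_weight_kg: float = 5.5
    tracer: str = "tracer44"
    tac_noise_cv: float = 0.05             # CV at the peak frame
    blood_noise_cv: float = 0.02           # multiplicative, blood samples
    pf_noise_sd: float = 0.01              # additive, clipped to [0, 1]
    blocking_plasma_scale: float = 1.3     # input elevation under blocking
    wb_over_plasma: float = 0.85           # whole-blood / total-plasma ratio
    plasma_peak_time: float = 1.0
    plasma_amplitudes: tuple = (30.0, 6.0, 3.5)
    plasma_rates: tuple = (0.8, 0.08, 0.0035)
    parent_anchors: tuple = PARENT_ANCHORS

    def __post_init__(self):
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        for name in ("tac_noise_cv", "blood_noise_cv", "pf_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def occupancy_for(self, animal: int) -> float:
        if np.isscalar(self.occupancy):
            return float(self.occupancy)
        return float(self.occupancy[animal])

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["occupancy"] = (float(self.occupancy) if np.isscalar(self.occupancy)
                          else list(map(float, self.occupancy)))
        return d


def _truth_input(config: SyntheticStudyConfig, condition: str) -> InputFunction:
    scale = config.blocking_plasma_scale if condition == "blocking" else 1.0
    plasma = default_plasma_truth(
        config.plasma_peak_time,
        tuple(a * scale for a in config.plasma_amplitudes),
        config.plasma_rates,
    )
    wb = default_plasma_truth(
        config.plasma_peak_time,
        tuple(a * scale * config.wb_over_plasma for a in config.plasma_amplitudes),
        config.plasma_rates,
    )
    parent = parent_model_from_anchors(config.parent_anchors)
    return InputFunction(plasma_model=plasma, parent_model=parent,
                         whole_blood_model=wb, f_p=config.f_p)


def generate_input(seed: int, config: SyntheticStudyConfig | None = None,
                   condition: str = "baseline"):
    """Sample blood and parent-fraction tables from the continuous truth.

    Returns (BloodSampleTable, ParentFractionTable, truth InputFunction).
    Multiplicative lognormal-free Gaussian noise with CV ``blood_noise_cv`` on
    activities; additive Gaussian noise (SD ``pf_noise_sd``) on fractions,
    clipped to [0, 1].
    """
    config = config or SyntheticStudyConfig()
    truth = _truth_input(config, condition)
    rng_blood, rng_pf = [np.random.default_rng(s)
                         for s in np.random.SeedSequence(seed).spawn(2)]

    t_blood = np.asarray(BLOOD_SAMPLE_TIMES)
    plasma = truth.plasma(t_blood)
    wb = truth.whole_blood(t_blood)
    if config.blood_noise_cv > 0:
        plasma = plasma * (1.0 + config.blood_noise_cv
                           * rng_blood.standard_normal(len(t_blood)))
        wb = wb * (1.0 + config.blood_noise_cv
                   * rng_blood.standard_normal(len(t_blood)))
    blood = BloodSampleTable(
        time_min=t_blood,
        whole_blood_kBq_cc=np.clip(wb, 0.0, None),
        plasma_kBq_cc=np.clip(plasma, 0.0, None),
    )

    t_pf = np.asarray(PARENT_SAMPLE_TIMES)
    pf = truth.parent_fraction(t_pf)
    if config.pf_noise_sd > 0:
        pf = pf + config.pf_noise_sd * rng_pf.standard_normal(len(t_pf))
    parent = ParentFractionTable(time_min=t_pf,
                                 parent_fraction=np.clip(pf, 0.0, 1.0))
    return blood, parent, truth


def _scan_truth_params(config: SyntheticStudyConfig, animal: int,
                       condition: str) -> dict:
    """Per-ROI 1TCM ground truth for one scan.  Blocking reduces specific
    binding: V_T_block = V_ND + (1 - r)(V_T_base - V_ND); K1 is unchanged, so
    k2 rises to K1 / V_T_block."""
    params = {}
    r = config.occupancy_for(animal)
    for roi, vt_base in config.roi_vt.items():
        K1 = vt_base * config.k2
        if condition == "blocking":
            vt = config.vnd + (1.0 - r) * (vt_base - config.vnd)
        else:
            vt = vt_base
        params[roi] = {"K1": K1, "k2": K1 / vt, "vt": vt, "vb": config.vb,
                       "delta_t": config.delta_t}
    return params


def generate_tacs(config: SyntheticStudyConfig, condition: str = "baseline",
                  animal: int = 0, seed: int | None = None):
    """Per-ROI TACs from the forward model plus frame-variance-scaled noise.

    Noise is zero-mean Gaussian with SD proportional to
    sqrt(prediction / frame duration) — the usual count-statistics surrogate —
    scaled so the CV at the peak frame equals ``tac_noise_cv``.  Returns
    (list of TimeActivityCurve, ground-truth dict).
    """
    schedule = FrameSchedule.default_180min()
    truth_input = _truth_input(config, condition)
    roi_truth = _scan_truth_params(config, animal, condition)
    seed = config.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(len(roi_truth))

    tacs = []
    for (roi, p), stream in zip(roi_truth.items(), streams):
        kp = KineticParameters(K1=p["K1"], k2=p["k2"], vb=p["vb"],
                               delta_t=p["delta_t"], model_kind="1TCM")
        pred = predict_tac(kp, truth_input, schedule)
        activity = pred
        if config.tac_noise_cv > 0:
            rng = np.random.default_rng(stream)
            rel = np.sqrt(np.clip(pred, 0.0, None) / schedule.duration)
            ipk = int(np.argmax(pred))
            sd = config.tac_noise_cv * pred[ipk] * rel / rel[ipk]
            activity = pred + sd * rng.standard_normal(len(pred))
        tacs.append(TimeActivityCurve(roi_name=roi, schedule=schedule,
                                      activity=activity))
    return tacs, {"rois": roi_truth, "condition": condition, "animal": animal,
                  "seed": int(seed)}


def generate_study(config: SyntheticStudyConfig, outdir, force: bool = False) -> Path:
    """Write a complete multi-animal baseline/blocking study to ``outdir``.

    Layout: one TAC/blood/parent CSV triple per scan, a ``manifest.csv``
    consumable by the quantification pipeline, and ``ground_truth.json``.
    Returns the manifest path.
    """
    from . import io as pio

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"{outdir} exists and is not empty; pass force=True to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)

    root_ss = np.random.SeedSequence(config.seed)
    # documented stream order: for each animal, for each condition
    # (baseline, blocking): blood/PF seed then TAC seed
    scan_seeds = root_ss.generate_state(config.n_animals * 4).astype(np.int64)

    manifest_rows = []
    truth = {"config": config.to_json_dict(), "scans": []}
    i = 0
    for animal in range(config.n_animals):
        for condition in ("baseline", "blocking"):
            blood_seed = int(scan_seeds[i]); tac_seed = int(scan_seeds[i + 1]); i += 2
            tag = f"m{animal + 1}_{condition}"
            blood, parent, truth_input = generate_input(
                blood_seed, config, condition)
            tacs, scan_truth = generate_tacs(config, condition, animal, tac_seed)

            tac_path = outdir / f"{tag}_tac.csv"
            blood_path = outdir / f"{tag}_blood.csv"
            parent_path = outdir / f"{tag}_parent.csv"
            pio.write_tac_csv(tac_path, tacs)
            pio.write_blood_csv(blood_path, blood)
            pio.write_parent_csv(parent_path, parent)

            manifest_rows.append({
                "animal": f"m{animal + 1}", "tracer": config.tracer,
                "condition": condition, "tac_file": tac_path.name,
                "blood_file": blood_path.name, "parent_file": parent_path.name,
                "f_p": config.f_p,
                "injected_dose_MBq": config.injected_dose_MBq,
                "body_weight_kg": config.body_weight_kg,
            })
            scan_truth.update(blood_seed=blood_seed, tac_seed=tac_seed,
                              input_truth=truth_input.to_dict())
            truth["scans"].append(scan_truth)

    manifest = pd.DataFrame(manifest_rows)
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return manifest_path
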