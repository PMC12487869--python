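"""Study-level orchestration: blood fits -> delay -> per-ROI model fits ->
model selection -> occupancy / BP_ND -> stability, driven by a manifest CSV.

The manifest has one row per scan: ``animal, tracer, condition
(baseline|blocking), tac_file, blood_file, parent_file, f_p,
injected_dose_MBq, body_weight_kg``; file paths are resolved relative to the
manifest.  Per-scan failures are isolated: the scan is recorded with its
error and the run continues, failing outright only when every scan fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .binding import compute_bpnd, lassen_fit
from .blood import fit_parent_fraction, fit_plasma_curve, make_input_function
from .kinetics import (TimeActivityCurve, estimate_delay, fit_tissue_model)
from .selection import select_model
from .stability import DEFAULT_ENDPOINTS, rest_period_analysis, time_stability

log = logging.getLogger("petkin")

__all__ = ["PipelineConfig", "run_quantify", "run_occupancy", "run_stability",
           "load_manifest"]


@dataclass
class PipelineConfig:
    """Tunable settings for the quantification pipeline."""

    models: tuple = ("1TCM", "2TCM", "2TiCM")
    n_plasma_exponentials: int | str = 3
    weight_scheme: str = "duration"
    alpha: float = 0.05
    rse_threshold: float = 10.0
    delay_t_max: float = 10.0
    grid_step: float = 0.05
    stability_endpoints: tuple = DEFAULT_ENDPOINTS
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "stability_endpoints"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()[:10]

    def comment(self) -> str:
        seed = "na" if self.seed is None else self.seed
        return f"petkin {__version__} config_hash={self.hash()} seed={seed}"


def load_manifest(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"animal", "tracer", "condition", "tac_file", "blood_file",
                "parent_file", "f_p", "injected_dose_MBq", "body_weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    bad = set(df["condition"]) - {"baseline", "blocking"}
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}")
    df.attrs["root"] = path.parent
    return df


def _whole_brain_tac(tacs: list) -> TimeActivityCurve:
    """Unweighted mean of the ROI TACs (no whole-brain column available)."""
    activity = np.mean([t.activity for t in tacs], axis=0)
    return TimeActivityCurve(roi_name="whole_brain", schedule=tacs[0].schedule,
                             activity=activity)


def quantify_scan(scan: dict, root: Path, config: PipelineConfig) -> dict:
    """Fit the input function, delay and all compartment models for one scan."""
    blood = pio.read_blood_csv(root / scan["blood_file"])
    parent = pio.read_parent_csv(root / scan["parent_file"])
    tacs = pio.read_tac_csv(root / scan["tac_file"])

    plasma = fit_plasma_curve(blood.time_min, blood.plasma_kBq_cc,
                              config.n_plasma_exponentials)
    wb = fit_plasma_curve(blood.time_min, blood.whole_blood_kBq_cc,
                          config.n_plasma_exponentials)
    pf = fit_parent_fraction(parent.time_min, parent.parent_fraction)
    input_fn = make_input_function(plasma, pf, wb, float(scan["f_p"]))

    # whole-brain column if present, else unweighted mean of the ROI TACs
    named = {t.roi_name: t for t in tacs}
    wb_tac = named.get("whole_brain", _whole_brain_tac(tacs))
    delay = estimate_delay(wb_tac, input_fn, t_max=config.delay_t_max,
                           grid_step=config.grid_step)

    fit_rows, sel_rows, fits_by_roi = [], [], {}
    for tac in tacs:
        if tac.roi_name == "whole_brain":
            continue
        fits = {}
        for kind in config.models:
            fit = fit_tissue_model(tac, input_fn, kind, fixed_delay=delay,
                                   weight_scheme=config.weight_scheme,
                                   grid_step=config.grid_step)
            fits[kind] = fit
            log.info("scan=%s/%s roi=%s model=%s converged=%s wrss=%.4g",
                     scan["animal"], scan["condition"], tac.roi_name, kind,
                     fit.converged, fit.wrss)
            p = fit.parameters
            fit_rows.append({
                "animal": scan["animal"], "tracer": scan["tracer"],
                "condition": scan["condition"], "roi": tac.roi_name,
                "model": kind, "K1_uL_min_cc": p.K1_uL, "k2_per_min": p.k2,
                "k3_per_min": p.k3, "k4_per_min": p.k4, "vb": p.vb,
                "delta_t_min": p.delta_t, "wrss": fit.wrss, "aic": fit.aic,
                "vt_mL_cc": fit.vt, "vt_rse_pct": fit.vt_rse,
                "ki_mL_min_cc": fit.ki, "ki_rse_pct": fit.ki_rse,
                "K1_rse_pct": fit.rse.get("K1"), "k2_rse_pct": fit.rse.get("k2"),
                "converged": fit.converged,
            })
        comparison = select_model(fits, config.alpha, config.rse_threshold)
        fits_by_roi[tac.roi_name] = fits
        sel_rows.append({
            "animal": scan["animal"], "tracer": scan["tracer"],
            "condition": scan["condition"], "roi": tac.roi_name,
            "chosen_model": comparison.chosen_model,
            **{f"aic_{k}": v for k, v in comparison.aics.items()},
            **{f"p_{k}": v for k, v in comparison.f_pvalues.items()},
            **{f"rse_{k}": v for k, v in comparison.primary_rse.items()},
            "f_test_significant": comparison.f_test_significant,
            "lowest_aic": comparison.lowest_aic,
            "rse_reliable": comparison.rse_reliable,
        })
    return {"fits": fit_rows, "selection": sel_rows, "delay": delay,
            "input_fn": input_fn, "fits_by_roi": fits_by_roi}


def run_quantify(manifest_path, outdir, config: PipelineConfig | None = None) -> dict:
    """Quantify every scan in the manifest; write fits.csv and selection.csv.

    Returns {"exit_code", "n_ok", "n_failed", "errors", "scans"}; exit code 0
    when all scans succeed, 2 on partial failure, 1 when every scan fails.
    """
    config = config or PipelineConfig()
    manifest = load_manifest(manifest_path)
    root = manifest.attrs["root"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fit_rows, sel_rows, errors, scans = [], [], {}, {}
    for _, scan in manifest.iterrows():
        key = f"{scan['animal']}_{scan['tracer']}_{scan['condition']}"
        try:
            result = quantify_scan(scan, root, config)
        except Exception as exc:  # per-scan fault isolation
            log.error("scan %s failed: %s", key, exc)
            errors[key] = str(exc)
            continue
        fit_rows += result["fits"]
        sel_rows += result["selection"]
        scans[key] = result

    comment = config.comment()
    if fit_rows:
        pio.write_csv_with_comment(pd.DataFrame(fit_rows), outdir / "fits.csv",
                                   comment)
        pio.write_csv_with_comment(pd.DataFrame(sel_rows),
                                   outdir / "selection.csv", comment)
    n_ok = len(scans)
    exit_code = 0 if not errors else (1 if n_ok == 0 else 2)
    return {"exit_code": exit_code, "n_ok": n_ok, "n_failed": len(errors),
            "errors": errors, "scans": scans}


def run_occupancy(fits: pd.DataFrame, outdir, model: str = "1TCM",
                  config: PipelineConfig | None = None) -> dict:
    """Per-animal Lassen fits and BP_ND tables from a quantification fits
    table (as written by run_quantify, one row per scan/ROI/model)."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sub = fits[fits["model"] == model]

    occ_rows, results = [], {}
    for (animal, tracer), grp in sub.groupby(["animal", "tracer"]):
        base = grp[grp["condition"] == "baseline"].set_index("roi")["vt_mL_cc"]
        block = grp[grp["condition"] == "blocking"].set_index("roi")["vt_mL_cc"]
        shared = base.index.intersection(block.index)
        if len(shared) < 3 or base.empty or block.empty:
            missing = "blocking" if block.empty else "baseline"
            raise ValueError(
                f"{animal}/{tracer}: unpaired scans (missing {missing} V_T "
                f"values; {len(shared)} shared ROIs)"
            )
        occ = lassen_fit(base[shared].to_numpy(), block[shared].to_numpy())
        results[(animal, tracer)] = occ
        occ_rows.append({
            "animal": animal, "tracer": tracer,
            "occupancy": occ.occupancy, "se_occupancy": occ.se_occupancy,
            "vnd_mL_cc": occ.vnd, "se_vnd": occ.se_vnd, "n_rois": occ.n_rois,
            "vnd_defined": occ.vnd_defined,
        })
    occ_df = pd.DataFrame(occ_rows)

    bpnd_rows = []
    notes = []
    for tracer, grp in occ_df.groupby("tracer"):
        defined = grp[grp["vnd_defined"] & (grp["vnd_mL_cc"] > 0)]
        if defined.empty:
            notes.append(f"{tracer}: no usable V_ND; BP_ND table skipped")
            continue
        mean_vnd = defined["vnd_mL_cc"].mean()
        if len(defined) < 2:
            notes.append(f"{tracer}: single animal; across-animal SD omitted")
        tsub = sub[sub["tracer"] == tracer]
        table = tsub.pivot_table(index="roi", columns="condition",
                                 values="vt_mL_cc", aggfunc="mean")
        for roi, row in table.iterrows():
            entry = {"tracer": tracer, "roi": roi, "vnd_mean": mean_vnd}
            for cond in ("baseline", "blocking"):
                if cond in row and np.isfinite(row[cond]):
                    entry[f"vt_{cond}"] = row[cond]
                    entry[f"bpnd_{cond}"] = float(compute_bpnd(row[cond], mean_vnd))
            bpnd_rows.append(entry)
    bpnd_df = pd.DataFrame(bpnd_rows)

    comment = config.comment()
    pio.write_csv_with_comment(occ_df, outdir / "occupancy.csv", comment)
    if not bpnd_df.empty:
        pio.write_csv_with_comment(bpnd_df, outdir / "bpnd.csv", comment)
    return {"occupancy": occ_df, "bpnd": bpnd_df, "results": results,
            "notes": notes}


def run_stability(manifest_path, outdir, config: PipelineConfig | None = None,
                  model: str = "1TCM", gaps: tuple = ()) -> pd.DataFrame:
    """Time-stability (and optional rest-period) analysis for every scan."""
    config = config or PipelineConfig()
    manifest = load_manifest(manifest_path)
    root = manifest.attrs["root"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    frames = []
    for _, scan in manifest.iterrows():
        result = quantify_scan(scan, root, config)
        input_fn, delay = result["input_fn"], result["delay"]
        for tac in pio.read_tac_csv(root / scan["tac_file"]):
            rep = time_stability(tac, input_fn, config.stability_endpoints,
                                 model, fixed_delay=delay,
                                 weight_scheme=config.weight_scheme,
                                 grid_step=config.grid_step)
            rep.insert(0, "animal", scan["animal"])
            rep.insert(1, "condition", scan["condition"])
            frames.append(rep)
            for gap_start, gap_dur in gaps:
                rep = rest_period_analysis(
                    tac, input_fn, gap_start, gap_dur, model,
                    fixed_delay=delay, weight_scheme=config.weight_scheme,
                    grid_step=config.grid_step)
                rep.insert(0, "animal", scan["animal"])
                rep.insert(1, "condition", scan["condition"])
                frames.append(rep)
    out = pd.concat(frames, ignore_index=True)
    pio.write_csv_with_comment(out, outdir / "stability.csv", config.comment())
    return out
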