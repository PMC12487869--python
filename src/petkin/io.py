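"""CSV / PMOD-style readers and writers, and JSON serialization of fitted
models.

Dialects (header row required, UTF-8, '.' decimal, times in minutes):

* blood CSV: ``time_min, whole_blood_kBq_cc, plasma_kBq_cc``
* parent-fraction CSV: ``time_min, parent_fraction``
* TAC CSV: ``frame_start_min, frame_end_min, <roi_1>, <roi_2>, ...``
  (activities in kBq/cm^3)
* PMOD-style ``.tac``: whitespace-delimited, first two columns are frame
  start/end; a ``start[seconds]`` / ``end[seconds]`` header dialect is
  converted to minutes.

Result CSVs written by the pipeline carry a ``#``-prefixed header comment
(package version, config hash, seed); all readers here skip ``#`` lines.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .blood import (BloodSampleTable, InputFunction, ParentFractionTable)
from .kinetics import FrameSchedule, TimeActivityCurve

__all__ = [
    "read_blood_csv", "write_blood_csv",
    "read_parent_csv", "write_parent_csv",
    "read_tac_csv", "write_tac_csv", "read_pmod_tac",
    "write_input_function_json", "read_input_function_json",
    "write_csv_with_comment",
]


def write_csv_with_comment(df: pd.DataFrame, path, comment: str = "") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_blood_csv(path) -> BloodSampleTable:
    df = pd.read_csv(path, comment="#")
    required = {"time_min", "whole_blood_kBq_cc", "plasma_kBq_cc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"blood CSV {path} missing columns {sorted(missing)}")
    return BloodSampleTable(
        time_min=df["time_min"].to_numpy(float),
        whole_blood_kBq_cc=df["whole_blood_kBq_cc"].to_numpy(float),
        plasma_kBq_cc=df["plasma_kBq_cc"].to_numpy(float),
    )


def write_blood_csv(path, table: BloodSampleTable, comment: str = "") -> None:
    df = pd.DataFrame({
        "time_min": table.time_min,
        "whole_blood_kBq_cc": table.whole_blood_kBq_cc,
        "plasma_kBq_cc": table.plasma_kBq_cc,
    })
    write_csv_with_comment(df, path, comment)


def read_parent_csv(path) -> ParentFractionTable:
    df = pd.read_csv(path, comment="#")
    required = {"time_min", "parent_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parent CSV {path} missing columns {sorted(missing)}")
    return ParentFractionTable(
        time_min=df["time_min"].to_numpy(float),
        parent_fraction=df["parent_fraction"].to_numpy(float),
    )


def write_parent_csv(path, table: ParentFractionTable, comment: str = "") -> None:
    df = pd.DataFrame({
        "time_min": table.time_min,
        "parent_fraction": table.parent_fraction,
    })
    write_csv_with_comment(df, path, comment)


def read_tac_csv(path) -> list[TimeActivityCurve]:
    """Read a TAC CSV into one TimeActivityCurve per ROI column."""
    df = pd.read_csv(path, comment="#")
    for col in ("frame_start_min", "frame_end_min"):
        if col not in df.columns:
            raise ValueError(f"TAC CSV {path} missing column {col}")
    schedule = FrameSchedule(
        start=df["frame_start_min"].to_numpy(float),
        end=df["frame_end_min"].to_numpy(float),
    )
    rois = [c for c in df.columns if c not in ("frame_start_min", "frame_end_min")]
    if not rois:
        raise ValueError(f"TAC CSV {path} has no ROI columns")
    return [
        TimeActivityCurve(roi_name=roi, schedule=schedule,
                          activity=df[roi].to_numpy(float))
        for roi in rois
    ]


def write_tac_csv(path, tacs: list, comment: str = "") -> None:
    sched = tacs[0].schedule
    data = {"frame_start_min": sched.start, "frame_end_min": sched.end}
    for tac in tacs:
        if len(tac.schedule) != len(sched) or not np.allclose(
                tac.schedule.start, sched.start):
            raise ValueError("all TACs must share one frame schedule")
        data[tac.roi_name] = tac.activity
    write_csv_with_comment(pd.DataFrame(data), path, comment)


def read_pmod_tac(path) -> list[TimeActivityCurve]:
    """Read a PMOD-style whitespace-delimited .tac file.

    The first two columns are frame start/end; when their headers contain
    ``[seconds]`` the times are converted to minutes.  Remaining columns are
    ROI activities.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    header = lines[0].split()
    if len(header) < 3:
        raise ValueError(f"{path}: expected start, end and >= 1 ROI column")
    to_minutes = 1.0 / 60.0 if "[seconds]" in (header[0] + header[1]).lower() else 1.0
    body = np.array([[float(v) for v in ln.split()] for ln in lines[1:]])
    schedule = FrameSchedule(start=body[:, 0] * to_minutes,
                             end=body[:, 1] * to_minutes)
    roi_names = [re.sub(r"\[.*?\]", "", h).strip("_") or f"roi_{i}"
                 for i, h in enumerate(header[2:], start=1)]
    return [
        TimeActivityCurve(roi_name=name, schedule=schedule, activity=body[:, j + 2])
        for j, name in enumerate(roi_names)
    ]


def write_input_function_json(path, input_fn: InputFunction,
                              extra: dict | None = None) -> None:
    doc = input_fn.to_dict()
    doc["units"] = {"time": "min", "activity": "kBq/cm^3", "rates": "1/min"}
    if extra:
        doc.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_input_function_json(path) -> InputFunction:
    with open(path, encoding="utf-8") as fh:
        return InputFunction.from_dict(json.load(fh))
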