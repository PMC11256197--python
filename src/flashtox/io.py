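"""CSV/JSON readers and writers for delivery logs, score tables, and QA files.

All formats are plain text:

* delivery log CSV — one row per spot event:
  ``spot_index,x_mm,y_mm,start_s,duration_s,dose_weight,painting``
* score table CSV — one row per observation:
  ``mouse_id,arm,dose_Gy,assay,time,grade`` (time in days for acute,
  weeks for fibrosis)
* alanine CSV — ``mouse_id,raw_dose_Gy,planned_dose_Gy``
* flags CSV — ``mouse_id,flag,stage``

Readers tolerate extra columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .delivery import DeliverySchedule, FieldPlan, Spot, SpotDelivery
from .qa import AlanineRecord, correct_alanine
from .toxicity import ToxicityRecord

__all__ = [
    "write_delivery_log", "read_delivery_log",
    "write_scores", "read_scores",
    "write_alanine", "read_alanine",
    "write_flags", "read_flags",
    "write_report", "read_config",
]


def write_delivery_log(schedule: DeliverySchedule, path: str | Path) -> None:
    pos = schedule.plan.positions()
    rows = [
        {
            "spot_index": e.spot_index,
            "x_mm": pos[e.spot_index, 0],
            "y_mm": pos[e.spot_index, 1],
            "start_s": e.start,
            "duration_s": e.duration,
            "dose_weight": e.dose_weight,
            "painting": e.painting,
        }
        for e in schedule.events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_delivery_log(
    path: str | Path, prescribed_dose: float, sigma: float, mean_pause: float = 0.0
) -> DeliverySchedule:
    """Rebuild a schedule from a delivery log.

    The log stores geometry and timing only; the prescribed dose and the
    spot sigma (not part of machine logs) are supplied by the caller. Spot
    weights are recovered from the summed dose weights per spot.
    """
    df = pd.read_csv(path)
    required = {"spot_index", "x_mm", "y_mm", "start_s", "duration_s", "dose_weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"delivery log missing columns: {sorted(missing)}")
    if "painting" not in df.columns:
        df["painting"] = 0

    per_spot = df.groupby("spot_index").agg(
        x_mm=("x_mm", "first"), y_mm=("y_mm", "first"), w=("dose_weight", "sum")
    )
    spots = tuple(
        Spot(x=float(r.x_mm), y=float(r.y_mm), weight=float(r.w), sigma=sigma)
        for r in per_spot.itertuples()
    )
    index_map = {orig: i for i, orig in enumerate(per_spot.index)}
    plan = FieldPlan(spots=spots, rows=1, cols=len(spots), spacing=np.nan, rim_factor=np.nan)

    df = df.sort_values("start_s")
    events = tuple(
        SpotDelivery(
            spot_index=index_map[int(r.spot_index)],
            start=float(r.start_s),
            duration=float(r.duration_s),
            dose_weight=float(r.dose_weight),
            painting=int(r.painting),
        )
        for r in df.itertuples()
    )
    n_repaints = int(df["painting"].max()) + 1
    return DeliverySchedule(
        plan=plan, events=events, prescribed_dose=prescribed_dose,
        n_repaints=n_repaints, mean_pause=mean_pause,
    )


def write_scores(records: Iterable[ToxicityRecord], path: str | Path) -> None:
    rows = [
        {
            "mouse_id": r.mouse_id, "arm": r.arm, "dose_Gy": r.dose,
            "assay": r.assay, "time": t, "grade": g,
        }
        for r in records
        for t, g in r.observations
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scores(path: str | Path) -> list[ToxicityRecord]:
    df = pd.read_csv(path)
    required = {"mouse_id", "arm", "dose_Gy", "assay", "time", "grade"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    records = []
    for (mid, arm, dose, assay), grp in df.groupby(
        ["mouse_id", "arm", "dose_Gy", "assay"], sort=True
    ):
        grp = grp.sort_values("time")
        records.append(
            ToxicityRecord(
                mouse_id=str(mid), arm=str(arm), dose=float(dose), assay=str(assay),
                observations=tuple(
                    (float(t), float(g)) for t, g in zip(grp["time"], grp["grade"])
                ),
            )
        )
    return records


def write_alanine(records: Iterable[AlanineRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"mouse_id": a.mouse_id, "raw_dose_Gy": a.raw_dose, "planned_dose_Gy": a.planned_dose}
            for a in records
        ]
    ).to_csv(path, index=False)


def read_alanine(path: str | Path, kq: float | None = None) -> list[AlanineRecord]:
    df = pd.read_csv(path)
    required = {"mouse_id", "raw_dose_Gy", "planned_dose_Gy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"alanine table missing columns: {sorted(missing)}")
    kwargs = {} if kq is None else {"kq": kq}
    return [
        correct_alanine(
            raw_dose=float(r.raw_dose_Gy), planned_dose=float(r.planned_dose_Gy),
            mouse_id=str(r.mouse_id), **kwargs,
        )
        for r in df.itertuples()
    ]


def write_flags(flags: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    pd.DataFrame(flags, columns=["mouse_id", "flag", "stage"]).to_csv(path, index=False)


def read_flags(path: str | Path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path)
    required = {"mouse_id", "flag", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"flags table missing columns: {sorted(missing)}")
    return [(str(r.mouse_id), str(r.flag), str(r.stage)) for r in df.itertuples()]


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def read_config(path: str | Path) -> dict:
    """Read a key-value (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a key-value mapping")
    return cfg
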