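"""CSV/JSON readers and writers for the pipeline's data objects.

Formats are deliberately plain: time courses as ``time,replicate,value``
CSV, snapshots as ``sample,time,intensity`` CSV, fits as JSON with fixed key
order and 12 significant digits so reruns diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .flow_fit import FlowFitResult
from .flow_sim import CellSnapshot, FlowParams
from .kinetics import KineticFit, KineticParams, TimeCourse

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "read_snapshots",
    "write_snapshots",
    "kinetic_fit_to_json",
    "kinetic_fit_from_json",
    "flow_fit_to_json",
    "comparison_to_frame",
]


def _fmt(x: float) -> float:
    """12 significant digits, for byte-stable JSON across reruns."""
    return float(f"{x:.12g}")


def read_timecourse(path, time_unit: str = "hours", label: str | None = None) -> TimeCourse:
    """Load a time course from ``time,replicate,value`` CSV."""
    df = pd.read_csv(path)
    required = {"time", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("time", "value"):
        if not np.issubdtype(pd.to_numeric(df[col], errors="coerce").dtype, np.number):
            raise ValueError(f"{path}: non-numeric entries in '{col}'")
        if pd.to_numeric(df[col], errors="coerce").isna().any():
            raise ValueError(f"{path}: non-numeric entries in '{col}'")
    if df.duplicated(subset=["time", "replicate"]).any():
        raise ValueError(f"{path}: duplicate (time, replicate) pairs")
    wide = df.pivot(index="replicate", columns="time", values="value").sort_index()
    wide = wide.reindex(sorted(wide.columns), axis=1)
    if wide.isna().any().any():
        raise ValueError(f"{path}: replicates do not share a common time grid")
    return TimeCourse(
        times=np.asarray(wide.columns, dtype=float),
        values=wide.to_numpy(dtype=float),
        label=label or Path(path).stem,
        time_unit=time_unit,
    )


def write_timecourse(tc: TimeCourse, path) -> None:
    records = [
        {"time": t, "replicate": r + 1, "value": tc.values[r, j]}
        for r in range(tc.n_replicates)
        for j, t in enumerate(tc.times)
    ]
    pd.DataFrame(records).to_csv(path, index=False)


def read_snapshots(path) -> list[CellSnapshot]:
    """Load snapshots from ``sample,time,intensity`` CSV (one row per cell)."""
    df = pd.read_csv(path)
    missing = {"sample", "time", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    snaps = []
    for (sample, t), grp in df.groupby(["sample", "time"], sort=True):
        snaps.append(
            CellSnapshot(time=float(t), intensities=grp["intensity"].to_numpy(float), sample=str(sample))
        )
    return snaps


def write_snapshots(snapshots: list[CellSnapshot], path) -> None:
    frames = [
        pd.DataFrame(
            {"sample": s.sample, "time": s.time, "intensity": s.intensities}
        )
        for s in snapshots
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def kinetic_fit_to_json(fit: KineticFit, path=None) -> str:
    doc = {
        "onset_time": _fmt(fit.params.onset_time),
        "production_rate": _fmt(fit.params.production_rate),
        "degradation_rate": _fmt(fit.params.degradation_rate),
        "rmsd": _fmt(fit.rmsd),
        "onset_fixed_zero": fit.onset_fixed_zero,
        "n_starts": fit.n_starts,
        "seed": fit.seed,
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def kinetic_fit_from_json(path) -> KineticFit:
    doc = json.loads(Path(path).read_text())
    return KineticFit(
        params=KineticParams(doc["onset_time"], doc["production_rate"], doc["degradation_rate"]),
        rmsd=doc["rmsd"],
        onset_fixed_zero=doc["onset_fixed_zero"],
        n_starts=doc["n_starts"],
        seed=doc["seed"],
    )


def flow_fit_to_json(result: FlowFitResult, path=None) -> str:
    def params_doc(p: FlowParams) -> dict:
        return {k: _fmt(v) for k, v in zip(
            ("k_t", "theta_t", "k_x", "theta_x", "noise_mean", "noise_var"), p.as_tuple()
        )}

    doc = {
        "params": params_doc(result.params),
        "objective": _fmt(result.objective),
        "mean_activation_time": _fmt(result.mean_activation_time),
        "mean_expression_rate": _fmt(result.mean_expression_rate),
        "param_ranges": {k: [_fmt(v[0]), _fmt(v[1])] for k, v in result.param_ranges.items()},
        "restart_log": [
            {
                "start": params_doc(rec.start_params),
                "final": params_doc(rec.final_params),
                "objective": _fmt(rec.objective),
            }
            for rec in result.restart_log
        ],
    }
    if result.config is not None:
        doc["config"] = {
            "n_restarts": result.config.n_restarts,
            "top_k": result.config.top_k,
            "n_sim_cells": result.config.n_sim_cells,
            "snapshot_times": list(result.config.snapshot_times),
            "seed": result.config.seed,
            "objective_mode": result.config.objective_mode,
        }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def comparison_to_frame(table) -> pd.DataFrame:
    """Comparison table as a tidy DataFrame (strain, metric, value)."""
    return pd.DataFrame(table.rows, columns=["strain", "metric", "value"])
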