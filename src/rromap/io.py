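"""Result serialization: delimited tables plus JSON provenance.

Trajectories go to a four-column CSV (t, z, Z, S) with the generating
parameters in a JSON sidecar; sweeps go to a long-form CSV plus a JSON
summary.  Floats are written with 17 significant digits so that reads
round-trip bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .experiments import SweepResult

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_sweep",
    "read_sweep",
]

_FLOAT_FMT = "%.17g"


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write (t, z, Z, S) as CSV with a JSON provenance sidecar."""
    path = Path(path)
    t = np.arange(traj.t0, traj.t0 + len(traj))
    df = pd.DataFrame({"t": t, "z": traj.z, "Z": traj.Z, "S": traj.S})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    _meta_path(path).write_text(json.dumps({"t0": traj.t0, "meta": traj.meta}, indent=1))
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    side = _meta_path(path)
    info = json.loads(side.read_text()) if side.exists() else {"t0": int(df["t"].iloc[0]), "meta": {}}
    return Trajectory(
        z=df["z"].to_numpy(),
        Z=df["Z"].to_numpy(np.int64),
        S=df["S"].to_numpy(),
        t0=int(info["t0"]),
        meta=info["meta"],
    )


def write_sweep(sweep: SweepResult, directory: str | Path, stem: str) -> list[Path]:
    """Write a sweep as long-form CSV table(s) plus a JSON summary.

    The JSON carries the axis definitions, per-trial seeds and the full
    provenance needed to regenerate the scan.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    table_path = directory / f"{stem}.csv"
    sweep.table.to_csv(table_path, index=False, float_format=_FLOAT_FMT)
    paths.append(table_path)
    if sweep.points is not None:
        pts_path = directory / f"{stem}_points.csv"
        sweep.points.to_csv(pts_path, index=False, float_format=_FLOAT_FMT)
        paths.append(pts_path)
    summary = {
        "axis1_name": sweep.axis1_name,
        "axis1_grid": np.asarray(sweep.axis1_grid).tolist(),
        "axis2_name": sweep.axis2_name,
        "axis2_grid": None if sweep.axis2_grid is None else np.asarray(sweep.axis2_grid).tolist(),
        "trials": sweep.trials,
        "seeds": sweep.seeds,
        "provenance": sweep.provenance,
        "has_points": sweep.points is not None,
    }
    json_path = directory / f"{stem}.json"
    json_path.write_text(json.dumps(summary, indent=1))
    paths.append(json_path)
    return paths


def read_sweep(directory: str | Path, stem: str) -> SweepResult:
    directory = Path(directory)
    summary = json.loads((directory / f"{stem}.json").read_text())
    table = pd.read_csv(directory / f"{stem}.csv", float_precision="round_trip")
    points = None
    if summary.get("has_points"):
        points = pd.read_csv(directory / f"{stem}_points.csv", float_precision="round_trip")
    return SweepResult(
        axis1_name=summary["axis1_name"],
        axis1_grid=np.asarray(summary["axis1_grid"], dtype=float),
        table=table,
        axis2_name=summary["axis2_name"],
        axis2_grid=None
        if summary["axis2_grid"] is None
        else np.asarray(summary["axis2_grid"], dtype=float),
        points=points,
        trials=summary["trials"],
        seeds=list(summary["seeds"]),
        provenance=summary["provenance"],
    )
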