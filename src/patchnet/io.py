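"""File formats: JSON-lines trajectories, point-set CSV, observables CSV.

A trajectory file holds one metadata record (parameters, schedule, seed,
code version) followed by one record per frame::

    {"step": 2500, "box_side": 34.0, "particles": [[x, y, orient, s0, s1, s2], ...]}

Floats are serialized at full precision so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .mc import MoveSchedule, Trajectory
from .model import Configuration, ModelParams

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_observables",
    "read_points_csv",
    "write_points_csv",
]


def _params_dict(p: ModelParams) -> dict:
    d = dataclasses.asdict(p)
    d.pop("n_patches", None)
    return d


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        meta = {
            "format": "patchnet-trajectory",
            "version": traj.version,
            "params": _params_dict(traj.params),
            "schedule": dataclasses.asdict(traj.schedule),
            "seed": traj.seed,
            "record_every": traj.record_every,
        }
        fh.write(json.dumps(meta, sort_keys=True) + "\n")
        for fr in traj.frames:
            rec = {
                "step": fr.step_index,
                "box_side": fr.box_side,
                "particles": [
                    [float(fr.pos[i, 0]), float(fr.pos[i, 1]),
                     float(fr.orient[i]), int(fr.states[i, 0]),
                     int(fr.states[i, 1]), int(fr.states[i, 2])]
                    for i in range(len(fr))
                ],
            }
            fh.write(json.dumps(rec) + "\n")


def read_trajectory(path: Union[str, Path]) -> Trajectory:
    path = Path(path)
    with path.open() as fh:
        meta = json.loads(fh.readline())
        if meta.get("format") != "patchnet-trajectory":
            raise ValueError(f"{path} is not a patchnet trajectory")
        params = ModelParams(**meta["params"])
        schedule = MoveSchedule(**meta["schedule"])
        traj = Trajectory(params=params, schedule=schedule, seed=meta["seed"],
                          record_every=meta["record_every"],
                          version=meta.get("version", "unknown"))
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            arr = np.asarray(rec["particles"], dtype=float).reshape(-1, 6)
            traj.frames.append(Configuration(
                arr[:, :2], arr[:, 2], arr[:, 3:6].astype(np.int8),
                rec["box_side"], step_index=rec["step"]))
    return traj


def write_observables(traj: Trajectory, path: Union[str, Path]) -> None:
    if traj.observables is None:
        raise ValueError("trajectory carries no observables")
    traj.observables.to_csv(path, index=False)


def read_points_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a detected-centres table (columns frame, x_nm, y_nm[, confidence])."""
    df = pd.read_csv(path)
    missing = {"x_nm", "y_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"points CSV lacks columns: {sorted(missing)}")
    if "frame" not in df.columns:
        df.insert(0, "frame", 0)
    return df


def write_points_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False)
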