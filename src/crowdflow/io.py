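"""Columnar text I/O for trajectories and stress series.

The native trajectory format is a CSV with columns
``frame, time_ns, molecule_id, x, y, z`` (Å) plus a JSON sidecar for the
box and any generator ground truth.  Readers record provenance (path,
frame range, stride) on the returned object.  Adapters for binary MD
formats are deliberately out of scope here; the analysis operates on the
synthetic generators and on pre-extracted COM tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BoxSpec, Trajectory
from .viscosity import StressSeries

__all__ = ["write_trajectory", "read_trajectory",
           "write_stress", "read_stress"]


def write_trajectory(traj: Trajectory, path) -> None:
    path = Path(path)
    F, M, _ = traj.com_positions.shape
    frame = np.repeat(np.arange(F), M)
    mol = np.tile(np.arange(M), F)
    df = pd.DataFrame({
        "frame": frame,
        "time_ns": traj.times[frame],
        "molecule_id": mol,
        "x": traj.com_positions[frame, mol, 0],
        "y": traj.com_positions[frame, mol, 1],
        "z": traj.com_positions[frame, mol, 2],
    })
    df.to_csv(path, index=False)
    sidecar = {
        "box_edge": traj.box.edge_length,
        "wrapped": traj.wrapped,
        "ground_truth": traj.ground_truth,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_trajectory(path, start: int = 0, stop=None, stride: int = 1
                    ) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    frames = np.sort(df["frame"].unique())[start:stop:stride]
    sub = df[df["frame"].isin(frames)].sort_values(["frame", "molecule_id"])
    M = sub["molecule_id"].nunique()
    F = len(frames)
    pos = sub[["x", "y", "z"]].to_numpy().reshape(F, M, 3)
    times = sub["time_ns"].to_numpy().reshape(F, M)[:, 0]
    return Trajectory(
        times=times, com_positions=pos, box=BoxSpec(meta["box_edge"]),
        wrapped=meta["wrapped"], ground_truth=meta.get("ground_truth", {}),
        provenance={"path": str(path), "start": start, "stop": stop,
                    "stride": stride},
    )


def write_stress(series: StressSeries, path) -> None:
    path = Path(path)
    cols = {f"ch{i}_bar": series.channels[i]
            for i in range(series.channels.shape[0])}
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {"dt_ns": series.dt, "volume_A3": series.volume,
            "temperature_K": series.temperature,
            "replica_id": series.replica_id}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_stress(path) -> StressSeries:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return StressSeries(dt=meta["dt_ns"], channels=df.to_numpy().T,
                        volume=meta["volume_A3"],
                        temperature=meta["temperature_K"],
                        replica_id=meta.get("replica_id", 0))
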