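"""Trajectory and sweep file formats.

The package's native trajectory container is a plain-text *frame table*:
CSV with columns ``time_ns, ion_id, x, y, z`` (Å), one row per tracked ion
per frame, uniform timestep.  Standard binary trajectory formats
(XTC/DCD/TRR) can be adapted through MDAnalysis when it is installed; the
adapter extracts a coordinate selection into the same in-memory
:class:`~porepass.permeation.IonTrajectory`.

Patch-clamp sweeps travel as CSV with columns
``time_s, current_pA, pressure_mmHg, voltage_mV``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ephys import SweepTrace
from .permeation import IonTrajectory, PermeationError
from .structure_io import ChannelAxis

__all__ = [
    "read_frame_table",
    "write_frame_table",
    "read_sweep_csv",
    "write_sweep_csv",
    "trajectory_from_mdanalysis",
]


def write_frame_table(traj: IonTrajectory, path: str | Path) -> None:
    """Write an IonTrajectory as the native frame-table CSV."""
    rows = []
    for i, t in enumerate(traj.times):
        for j, ion in enumerate(traj.ion_ids):
            x, y, z = traj.ion_positions[i, j]
            rows.append((t, ion, x, y, z))
    pd.DataFrame(rows, columns=["time_ns", "ion_id", "x", "y", "z"]).to_csv(
        path, index=False
    )


def read_frame_table(
    path: str | Path,
    axis: ChannelAxis | None = None,
    ion_charge: float = -1.0,
    box=None,
) -> IonTrajectory:
    """Read the native frame-table CSV into an IonTrajectory.

    Every ion must appear at every timestep; the axis defaults to z through
    the origin.
    """
    df = pd.read_csv(path)
    need = {"time_ns", "ion_id", "x", "y", "z"}
    if not need.issubset(df.columns):
        raise PermeationError(f"frame table needs columns {sorted(need)}")
    times = np.sort(df["time_ns"].unique())
    ions = list(pd.unique(df["ion_id"]))
    pivot = df.set_index(["time_ns", "ion_id"])
    if len(pivot) != len(times) * len(ions):
        raise PermeationError("frame table is ragged: every ion must appear each frame")
    pos = np.empty((len(times), len(ions), 3))
    for i, t in enumerate(times):
        block = pivot.loc[t]
        pos[i] = block.loc[ions, ["x", "y", "z"]].to_numpy()
    if axis is None:
        axis = ChannelAxis(origin=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))
    return IonTrajectory(
        times=times, ion_positions=pos, axis=axis, ion_charge=ion_charge,
        ion_ids=ions, box=box,
    )


def trajectory_from_mdanalysis(
    universe,
    selection: str,
    axis: ChannelAxis,
    ion_charge: float = -1.0,
    time_scale: float = 1e-3,
) -> IonTrajectory:
    """Adapt an MDAnalysis Universe (topology + XTC/DCD/TRR frames).

    ``selection`` is an MDAnalysis atom selection for the tracked ions;
    ``time_scale`` converts the trajectory's time unit (ps by default) to
    ns.  Requires the optional MDAnalysis dependency.
    """
    group = universe.select_atoms(selection)
    times, frames = [], []
    box = None
    for ts in universe.trajectory:
        times.append(ts.time * time_scale)
        frames.append(group.positions.copy())
        if ts.dimensions is not None:
            box = np.asarray(ts.dimensions[:3], dtype=float)
    return IonTrajectory(
        times=np.asarray(times),
        ion_positions=np.asarray(frames),
        axis=axis,
        ion_charge=ion_charge,
        ion_ids=[int(i) for i in group.ids],
        box=box,
    )


def write_sweep_csv(sweep: SweepTrace, path: str | Path) -> None:
    n = len(sweep.time)
    volt = sweep.voltage
    if volt is None:
        volt = np.full(n, np.nan)
    df = pd.DataFrame(
        {
            "time_s": sweep.time,
            "current_pA": sweep.current,
            "pressure_mmHg": sweep.pressure if sweep.pressure is not None else np.zeros(n),
            "voltage_mV": np.broadcast_to(np.asarray(volt, dtype=float), (n,)),
        }
    )
    df.to_csv(path, index=False)


def read_sweep_csv(path: str | Path) -> SweepTrace:
    df = pd.read_csv(path)
    volt = df["voltage_mV"].to_numpy() if "voltage_mV" in df else None
    if volt is not None and len(np.unique(volt)) == 1:
        volt = float(volt[0])
    return SweepTrace(
        time=df["time_s"].to_numpy(),
        current=df["current_pA"].to_numpy(),
        pressure=df["pressure_mmHg"].to_numpy() if "pressure_mmHg" in df else None,
        voltage=volt,
    )
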