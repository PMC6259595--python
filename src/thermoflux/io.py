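"""CSV/JSON input and output shared by the library and the CLI.

CSV dialect: comma separator, dot decimal, mandatory header row.
Floats are written with 10 significant digits so identical runs
produce byte-identical files while round-tripping within 1e-9 relative.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .iv import IVDataset
from .membrane import Trajectory

__all__ = [
    "read_iv_csv",
    "write_iv_csv",
    "read_traj_csv",
    "write_traj_csv",
    "write_json",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.10g"

_IV_COLUMNS = ("voltage_mV", "current_pA")


class CSVFormatError(ValueError):
    """Malformed CSV input (wrong header or unparseable values)."""


def read_iv_csv(path) -> IVDataset:
    """Read a two-column (voltage_mV, current_pA) CSV into an IVDataset."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CSVFormatError(f"{path}: {exc}") from exc
    missing = [c for c in _IV_COLUMNS if c not in df.columns]
    if missing:
        raise CSVFormatError(
            f"{path}: missing column(s) {missing}; header must contain {_IV_COLUMNS}"
        )
    df = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = df[list(_IV_COLUMNS)].isna().any(axis=1)
    if bad.any():
        raise CSVFormatError(
            f"{path}: unparseable value at data line {int(np.nonzero(bad.values)[0][0]) + 2}"
        )
    return IVDataset(
        label=path.stem,
        voltages=df["voltage_mV"].to_numpy(float),
        currents=df["current_pA"].to_numpy(float),
    )


def write_iv_csv(path, dataset: IVDataset) -> None:
    df = pd.DataFrame({
        "voltage_mV": dataset.voltages,
        "current_pA": dataset.currents,
    })
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_traj_csv(path, trajectory: Trajectory) -> None:
    """Write a trajectory as t_ms, one column per state, one per current."""
    cols = {"t_ms": trajectory.times}
    rename = {"v": "v_mV", "w": "w", "c": "c_uM"}
    for name, arr in trajectory.states.items():
        cols[rename.get(name, name)] = arr
    for name, arr in trajectory.currents.items():
        cols[name] = arr
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_traj_csv(path) -> Trajectory:
    """Read a trajectory CSV back (without the dense interpolant)."""
    path = Path(path)
    df = pd.read_csv(path)
    if "t_ms" not in df.columns:
        raise CSVFormatError(f"{path}: missing 't_ms' column")
    states, currents = {}, {}
    unrename = {"v_mV": "v", "w": "w", "c_uM": "c"}
    for col in df.columns:
        if col == "t_ms":
            continue
        if col in unrename:
            states[unrename[col]] = df[col].to_numpy(float)
        elif col.startswith("J_"):
            currents[col] = df[col].to_numpy(float)
    return Trajectory(
        times=df["t_ms"].to_numpy(float), states=states, currents=currents,
        meta={"source": str(path)},
    )


def write_json(path, payload: dict) -> None:
    """Write a JSON document with stable key order and 9-digit floats."""

    def round_floats(obj):
        if isinstance(obj, float):
            return float(f"{obj:.9g}")
        if isinstance(obj, dict):
            return {k: round_floats(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [round_floats(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        json.dump(round_floats(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
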