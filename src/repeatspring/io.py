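"""Reading and writing force-distance curves and analysis reports.

FDCs travel either as delimited text with a header
(``separation_nm  force_pN  cycle  direction``), one or many sweeps per
file, or as an HDF5 container with one group per sweep.  Ensemble
snapshots and pipeline reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .engine import EnsembleSnapshot, ForceDistanceCurve

_COLUMNS = ["separation_nm", "force_pN", "cycle", "direction"]


def fdcs_to_frame(fdcs) -> pd.DataFrame:
    frames = []
    for i, c in enumerate(fdcs):
        frames.append(
            pd.DataFrame(
                {
                    "separation_nm": c.separation,
                    "force_pN": c.force,
                    "cycle": c.cycle if c.cycle is not None else i,
                    "direction": c.direction or "stretch",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_fdcs(frame: pd.DataFrame, pulling_speed=None) -> list[ForceDistanceCurve]:
    out = []
    for (cycle, direction), grp in frame.groupby(["cycle", "direction"], sort=True):
        out.append(
            ForceDistanceCurve(
                grp["separation_nm"].to_numpy(),
                grp["force_pN"].to_numpy(),
                pulling_speed=pulling_speed,
                cycle=int(cycle),
                direction=str(direction),
            )
        )
    return out


def write_fdc_text(path, fdcs, sep: str = "\t") -> None:
    """Write one or many FDC sweeps as delimited text with header."""
    if isinstance(fdcs, ForceDistanceCurve):
        fdcs = [fdcs]
    fdcs_to_frame(fdcs).to_csv(path, sep=sep, index=False)


def read_fdc_text(path, sep: str = "\t") -> list[ForceDistanceCurve]:
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in _COLUMNS[:2] if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "cycle" not in frame.columns:
        frame["cycle"] = 0
    if "direction" not in frame.columns:
        frame["direction"] = "stretch"
    return frame_to_fdcs(frame)


def write_fdc_h5(path, fdcs) -> None:
    """Binary-table container: one HDF5 group per sweep."""
    if isinstance(fdcs, ForceDistanceCurve):
        fdcs = [fdcs]
    with h5py.File(path, "w") as h5:
        for i, c in enumerate(fdcs):
            grp = h5.create_group(f"sweep_{i:04d}")
            grp.create_dataset("separation_nm", data=c.separation)
            grp.create_dataset("force_pN", data=c.force)
            grp.attrs["cycle"] = c.cycle if c.cycle is not None else i
            grp.attrs["direction"] = c.direction or "stretch"
            if c.pulling_speed is not None:
                grp.attrs["pulling_speed_nm_per_s"] = c.pulling_speed


def read_fdc_h5(path) -> list[ForceDistanceCurve]:
    out = []
    with h5py.File(path, "r") as h5:
        for name in sorted(h5):
            grp = h5[name]
            out.append(
                ForceDistanceCurve(
                    np.asarray(grp["separation_nm"]),
                    np.asarray(grp["force_pN"]),
                    pulling_speed=grp.attrs.get("pulling_speed_nm_per_s"),
                    cycle=int(grp.attrs.get("cycle", 0)),
                    direction=str(grp.attrs.get("direction", "stretch")),
                )
            )
    return out


def read_fdcs(path) -> list[ForceDistanceCurve]:
    """Dispatch on extension: .h5/.hdf5 binary, anything else text."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        return read_fdc_h5(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return read_fdc_text(path, sep=sep)


def write_snapshot_json(path, snapshot: EnsembleSnapshot) -> None:
    Path(path).write_text(json.dumps(snapshot.to_dict(), indent=2))


def write_report_json(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
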