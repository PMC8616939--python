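"""Reading and writing trajectories and result files.

Trajectories travel as TSV/CSV with time (fs) in the first column and one
named channel per remaining column; a ``:unit`` suffix on a header tags the
channel unit (``C2:au``, ``hbond:A``, ``angle:deg``), defaulting to atomic
units. Results are written as JSON with a configuration echo, package
version, and an input checksum so every file is traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .trajectory import KNOWN_UNITS, Trajectory, TrajectoryError


def _split_header(header: str) -> tuple[str, str]:
    if ":" in header:
        name, unit = header.rsplit(":", 1)
        if unit in KNOWN_UNITS:
            return name, unit
    return header, "au"


def read_trajectory(path: str | Path, format: str | None = None) -> Trajectory:
    """Read a columnar trajectory file.

    Parameters
    ----------
    path
        TSV or CSV file; first column is time in fs, header row names the
        channels with optional ``:unit`` suffixes.
    format
        ``"tsv"`` or ``"csv"``; inferred from the file suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "\t" if format == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except ValueError as exc:
        raise TrajectoryError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise TrajectoryError(f"{path}: need a time column plus >= 1 channel")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise TrajectoryError(
                f"{path}: non-numeric cell at row {row}, column {col!r}"
            )
        df[col] = coerced
    times = df.iloc[:, 0].to_numpy(float)
    data, units = {}, {}
    for col in df.columns[1:]:
        name, unit = _split_header(str(col))
        data[name] = df[col].to_numpy(float)
        units[name] = unit
    return Trajectory.from_arrays(
        times, data, units, meta={"source": str(path), "format": format}
    )


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str | None = None) -> None:
    """Write a trajectory in the columnar TSV/CSV layout read by
    :func:`read_trajectory`."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "\t" if format == "tsv" else ","
    cols = {"t_fs": traj.times}
    for name, ch in traj.channels.items():
        cols[f"{name}:{ch.unit}"] = ch.values
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False,
                              float_format="%.17g")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    raise TypeError(f"cannot serialize field of type {type(obj).__name__}")


def input_checksum(data: Any) -> str:
    """SHA-256 checksum of a JSON-serializable payload (or raw bytes)."""
    if isinstance(data, (bytes, bytearray)):
        raw = bytes(data)
    elif isinstance(data, (str, Path)) and Path(str(data)).is_file():
        raw = Path(str(data)).read_bytes()
    else:
        raw = json.dumps(_jsonable(data), sort_keys=True).encode()
    return hashlib.sha256(raw).hexdigest()


def write_result(obj: Any, path: str | Path,
                 config: RunConfig | None = None,
                 input_ref: Any | None = None) -> None:
    """Serialize a finished result object to JSON.

    The envelope carries the result type name, the package version, the run
    configuration, and a checksum of the input the result was computed from
    (a file path, a trajectory, or any serializable object).
    """
    payload = {
        "result_type": type(obj).__name__,
        "version": __version__,
        "config": (config or RunConfig()).to_dict(),
        "input_checksum": (input_checksum(input_ref)
                           if input_ref is not None else None),
        "result": _jsonable(obj),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_result(path: str | Path) -> dict:
    """Read back a result envelope as a plain dictionary."""
    return json.loads(Path(path).read_text())
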