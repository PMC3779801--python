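"""Delimited-text and JSON I/O with stable, diffable formatting.

All tabular exports are comma-delimited with one header line and a
deterministic row order; floats are printed with 9 significant digits so
that re-running a configuration reproduces outputs byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .day import DayResult
from .fitting import ObservationTable, FitResult, OBS_COLUMNS
from .passage import DifferenceMap, EquilibriumResult, Timecourse

__all__ = [
    "read_observations",
    "write_observations",
    "write_trajectory",
    "write_map",
    "write_timecourse",
    "write_results",
    "format_float",
]

FLOAT_FMT = "%.9g"


def format_float(x: float) -> str:
    return FLOAT_FMT % x


def read_observations(path) -> ObservationTable:
    """Read an observation table; header must match the documented columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise IOError(f"cannot read observations from {path}: {exc}") from exc
    return ObservationTable(df)


def write_observations(obs: ObservationTable, path) -> None:
    _write_frame(obs.df[OBS_COLUMNS], path)


def write_trajectory(day: DayResult, path) -> None:
    """Columns t_h, N_R_per_ul, N_S_per_ul, A_ug_ml, time-ordered."""
    _write_frame(day.to_frame(), path)


def write_map(diffmap: DifferenceMap, path, condition_id: str = "c0") -> None:
    _write_frame(diffmap.to_frame(condition_id), path)


def write_timecourse(tc: Timecourse, path, condition_id: str = "c0",
                     protocol=None) -> None:
    df = pd.DataFrame({
        "day": np.arange(1, len(tc.fractions) + 1),
        "f": tc.fractions,
    })
    if protocol is not None:
        df.insert(0, "condition_id", condition_id)
        df.insert(1, "A_ug_ml", protocol.A_i)
        df.insert(2, "inhibitor_ng_ml", protocol.I)
        df.insert(3, "dilution", protocol.D)
    _write_frame(df, path)


def _write_frame(df: pd.DataFrame, path) -> None:
    path = Path(path)
    try:
        df.to_csv(path, index=False, float_format=FLOAT_FMT,
                  lineterminator="\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def _jsonable(obj: Any) -> Any:
    """Stable-order, 9-significant-digit JSON representation."""
    if isinstance(obj, float) or isinstance(obj, np.floating):
        return float(format_float(float(obj)))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, EquilibriumResult):
        return _jsonable(obj.to_dict())
    if isinstance(obj, FitResult):
        return _jsonable(obj.to_dict())
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj


def write_results(result: Any, path) -> None:
    """Serialize a result object (or dict) as diffable JSON.

    Field order is stable (insertion order of the object's dict form)
    and floats carry 9 significant digits, so writing the same result
    twice yields byte-identical files.
    """
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_jsonable(result), fh, indent=2, ensure_ascii=False)
            fh.write("\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
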