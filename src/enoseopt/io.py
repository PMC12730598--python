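"""CSV persistence for response cycles and feature tables.

Dataset dialect: one row per time point with columns
``cycle_id, temperature_C, label, time_s, S1..S10`` (UTF-8, "." decimal,
header mandatory).  Feature tables are long-format:
``cycle_id, temperature_C, label, sensor, p_max, p_min, t_eq, area, t1, t2, t3``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import SENSOR_IDS
from .simulate import ResponseCycle

__all__ = ["SchemaError", "write_cycles", "read_cycles"]

_META_COLUMNS = ("cycle_id", "temperature_C", "label", "time_s")
_KNOWN_TEMPERATURES = (4.0, 12.0, 20.0, 28.0)


class SchemaError(ValueError):
    """Raised when a CSV file does not match the documented dialect."""


def write_cycles(cycles: list[ResponseCycle], path) -> None:
    """Write cycles in the long dataset dialect."""
    frames = []
    for cyc in cycles:
        df = pd.DataFrame({
            "cycle_id": cyc.cycle_id,
            "temperature_C": cyc.temperature,
            "label": cyc.label,
            "time_s": cyc.t,
        })
        for i, sid in enumerate(cyc.sensor_ids):
            df[sid] = cyc.readings[i]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cycles(path, expected_length: int = 300,
                allowed_temperatures=_KNOWN_TEMPERATURES) -> list[ResponseCycle]:
    """Read and validate a dataset CSV, reporting offending rows by line number.

    Raises
    ------
    SchemaError
        On missing columns, non-uniform/wrong-length time grids, or
        temperature values outside the experiment's conditions.
    """
    df = pd.read_csv(path)
    missing = [c for c in (*_META_COLUMNS, *SENSOR_IDS) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    bad_temp = df.loc[~df["temperature_C"].isin(allowed_temperatures)]
    if len(bad_temp):
        line = int(bad_temp.index[0]) + 2  # header + 1-based
        raise SchemaError(
            f"{path}: unknown temperature value {bad_temp['temperature_C'].iloc[0]!r} "
            f"at line {line}; expected one of {tuple(allowed_temperatures)}"
        )

    cycles = []
    for cid, grp in df.groupby("cycle_id", sort=False):
        t = grp["time_s"].to_numpy(dtype=float)
        if expected_length is not None and t.size != expected_length:
            raise SchemaError(
                f"{path}: cycle {cid!r} has {t.size} samples; "
                f"expected a {expected_length}-point 1 Hz grid"
            )
        dt = np.diff(t)
        if t.size > 1 and not np.allclose(dt, dt[0]):
            line = int(grp.index[np.argmax(~np.isclose(dt, dt[0])) + 1]) + 2
            raise SchemaError(f"{path}: cycle {cid!r} time grid non-uniform near line {line}")
        temps = grp["temperature_C"].unique()
        labels = grp["label"].unique()
        if len(temps) > 1 or len(labels) > 1:
            raise SchemaError(f"{path}: cycle {cid!r} mixes temperatures or labels")
        cycles.append(
            ResponseCycle(
                cycle_id=str(cid),
                temperature=float(temps[0]),
                label=int(labels[0]),
                t=t,
                readings=grp[list(SENSOR_IDS)].to_numpy(dtype=float).T,
            )
        )
    return cycles
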