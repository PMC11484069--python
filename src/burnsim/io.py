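"""Readers and writers for the package's CSV/YAML artifacts.

All times are hours post-burn; CSVs are UTF-8 with a header row and '.'
decimals. Readers validate schemas strictly and report the offending row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .core import SubjectProfile
from .fit import VARIABLES, MeasurementSet
from .sim import InfusionSchedule, SimulationResult

__all__ = ["write_schedule", "read_schedule", "write_measurements",
           "read_measurements", "write_profile", "read_profile",
           "write_result", "read_result"]


class SchemaError(ValueError):
    """A file does not match the expected schema."""


def write_schedule(path, schedule: InfusionSchedule) -> None:
    pd.DataFrame({
        "time_h": schedule.breakpoints,
        "rate_mL_per_h": schedule.rates,
        "fluid_type": [schedule.fluid] * len(schedule.rates),
    }).to_csv(path, index=False)


def read_schedule(path) -> InfusionSchedule:
    df = pd.read_csv(path)
    required = {"time_h", "rate_mL_per_h"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: missing columns "
                          f"{sorted(required - set(df.columns))}")
    times = df["time_h"].to_numpy(dtype=float)
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            raise SchemaError(f"{path}: non-increasing time at row {i + 2}")
    rates = df["rate_mL_per_h"].to_numpy(dtype=float)
    for i, r in enumerate(rates):
        if r < 0 or not np.isfinite(r):
            raise SchemaError(f"{path}: invalid rate at row {i + 2}")
    fluid = str(df["fluid_type"].iloc[0]) if "fluid_type" in df else "LR"
    return InfusionSchedule(breakpoints=list(times), rates=list(rates),
                            fluid=fluid)


def write_measurements(path, meas: MeasurementSet) -> None:
    rows = []
    for var, (t, v) in meas.data.items():
        for ti, vi in zip(t, v):
            rows.append((float(ti), var, float(vi)))
    rows.sort(key=lambda r: (r[1], r[0]))
    pd.DataFrame(rows, columns=["time_h", "variable", "value"]) \
        .to_csv(path, index=False)


def read_measurements(path, normalization: dict | None = None,
                      subject_id: str = "") -> MeasurementSet:
    df = pd.read_csv(path)
    required = {"time_h", "variable", "value"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: missing columns "
                          f"{sorted(required - set(df.columns))}")
    data = {}
    for var, grp in df.groupby("variable", sort=True):
        if var not in VARIABLES:
            row = int(grp.index[0]) + 2
            raise SchemaError(f"{path}: unknown variable {var!r} at row {row}")
        t = grp["time_h"].to_numpy(dtype=float)
        v = grp["value"].to_numpy(dtype=float)
        bad = np.where(np.diff(t) <= 0.0)[0]
        if bad.size:
            row = int(grp.index[bad[0] + 1]) + 2
            raise SchemaError(f"{path}: non-increasing time for {var!r} "
                              f"at row {row}")
        data[str(var)] = (t, v)
    return MeasurementSet(data, normalization=normalization or {},
                          subject_id=subject_id)


def write_profile(path, profile: SubjectProfile) -> None:
    doc = {"species": profile.species, "weight": profile.weight,
           "tbsa": profile.tbsa, "hct0": profile.hct0,
           "injury_time": profile.injury_time,
           "subject_id": profile.subject_id}
    if profile.co0 is not None:
        doc["co0"] = profile.co0
    if profile.map0 is not None:
        doc["map0"] = profile.map0
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_profile(path) -> SubjectProfile:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return SubjectProfile(**doc)
    except (TypeError, ValueError) as err:
        raise SchemaError(f"{path}: invalid profile ({err})") from err


def write_result(path, result: SimulationResult) -> None:
    # %.17g guarantees exact float64 round-trips
    result.data.to_csv(path, index=False, float_format="%.17g")


def read_result(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise SchemaError(f"{path}: missing time_h column")
    return df
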