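"""CSV/JSON reading and writing for assay tables, trajectories and reports."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .estimate import ASSAY_COLUMNS, ASSAY_TYPES
from .types import ResetEvent, ResetSchedule, Trajectory

__all__ = [
    "validate_assay_table",
    "read_assay_table",
    "write_assay_table",
    "read_assay_dir",
    "write_trajectory",
    "read_trajectory",
    "parse_reset_spec",
    "format_reset_spec",
]


def validate_assay_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and row invariants; returns a normalised copy."""
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assay table missing columns: {missing}")
    df = df.copy()
    for col in ("n0", "n_final", "duration_days", "competitor_density"):
        df[col] = df[col].astype(float)
    df["n_herbivores"] = df["n_herbivores"].astype(int)
    df["reset_times"] = df["reset_times"].fillna("").astype(str).replace("nan", "")
    bad = set(df["assay_type"]) - set(ASSAY_TYPES)
    if bad:
        raise ValueError(f"unknown assay types: {sorted(bad)}")
    if (df["n0"] <= 0).any():
        raise ValueError("n0 must be > 0 in every record")
    if (df["n_final"] < 0).any():
        raise ValueError("n_final must be >= 0")
    if (df["duration_days"] <= 0).any():
        raise ValueError("duration_days must be > 0")
    if (df["competitor_density"] < 0).any():
        raise ValueError("competitor_density must be >= 0")
    if (df["n_herbivores"] < 0).any():
        raise ValueError("n_herbivores must be >= 0")
    return df


def read_assay_table(path: str | Path) -> pd.DataFrame:
    return validate_assay_table(pd.read_csv(path, keep_default_na=False, na_values=[]))


def write_assay_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_assay_table(df).to_csv(path, index=False)


def read_assay_dir(path: str | Path) -> pd.DataFrame:
    """Read a fixture directory of per-assay CSVs into one table."""
    path = Path(path)
    frames = []
    missing = []
    for assay in ASSAY_TYPES:
        f = path / f"{assay}.csv"
        if f.exists():
            frames.append(pd.read_csv(f, keep_default_na=False, na_values=[]))
        else:
            missing.append(f.name)
    if missing:
        raise FileNotFoundError(f"assay directory {path} missing: {missing}")
    return validate_assay_table(pd.concat(frames, ignore_index=True))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        t=df["t"].to_numpy(),
        N1=df["N1"].to_numpy(),
        N2=df["N2"].to_numpy(),
        event_flag=df["event_flag"].to_numpy(),
    )


def parse_reset_spec(spec: str) -> ResetSchedule:
    """Parse "time:species:value" triples separated by ';'.

    Example: "2:1:100;5:1:100" resets species 1 to 100 on days 2 and 5.
    """
    events = []
    for part in spec.split(";"):
        part = part.strip()
        if not part:
            continue
        bits = part.split(":")
        if len(bits) != 3:
            raise ValueError(f"malformed reset event {part!r}, expected time:species:value")
        try:
            t, sp, val = float(bits[0]), int(bits[1]), float(bits[2])
        except ValueError as exc:
            raise ValueError(f"malformed reset event {part!r}: {exc}") from None
        events.append(ResetEvent(t, sp, val))
    return ResetSchedule(events)


def format_reset_spec(schedule: ResetSchedule) -> str:
    return ";".join(f"{e.time:g}:{e.species}:{e.value:g}" for e in schedule)
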