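"""CSV readers and writers for epoch streams, dose schedules and cohorts.

All files are comma-separated UTF-8 with a header row, "." decimal and
ISO-8601 timestamps.  Validation errors name the offending column or line.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dat_model import LABELS, validate_cohort
from .epoch_features import DoseSchedule, EpochSeries, FEATURE_COLUMNS

__all__ = [
    "read_epoch_series",
    "write_epoch_series",
    "read_dose_schedule",
    "write_dose_schedule",
    "read_cohort",
    "write_cohort",
]

EPOCH_COLUMNS = ("timestamp", "bks", "dks", "tremor", "worn")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")


def _parse_timestamps(raw: pd.Series, path) -> np.ndarray:
    try:
        ts = pd.to_datetime(raw, format="ISO8601")
    except (ValueError, TypeError) as exc:
        bad = pd.to_datetime(raw, format="ISO8601", errors="coerce")
        lines = (np.flatnonzero(bad.isna()) + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: malformed timestamp(s) at line(s) {lines}") from exc
    return ts.to_numpy().astype("datetime64[s]")


def read_epoch_series(path, subject_id: str | None = None) -> EpochSeries:
    """Read one recording; the filename stem is the default subject id."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, EPOCH_COLUMNS, path)
    ts = _parse_timestamps(df["timestamp"], path)
    if ts.size > 1 and (np.diff(ts).astype(int) <= 0).any():
        raise ValueError(f"{path}: timestamps not increasing")
    bad = df[["bks", "dks"]].isna().any(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()
        raise ValueError(f"{path}: malformed score row(s) at line(s) {lines}")
    return EpochSeries(
        subject_id=subject_id or path.stem,
        timestamps=ts,
        bks=df["bks"].to_numpy(float),
        dks=df["dks"].to_numpy(float),
        tremor=df["tremor"].to_numpy().astype(bool),
        worn=df["worn"].to_numpy().astype(bool),
        artifact=df["artifact"].to_numpy().astype(bool) if "artifact" in df.columns else None,
    )


def write_epoch_series(series: EpochSeries, path) -> None:
    df = pd.DataFrame(
        {
            "timestamp": np.datetime_as_string(series.timestamps, unit="s"),
            "bks": series.bks,
            "dks": series.dks,
            "tremor": series.tremor.astype(int),
            "worn": series.worn.astype(int),
            "artifact": series.artifact.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_dose_schedule(path, recording_days: int) -> DoseSchedule:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("timestamp", "acknowledged"), path)
    ts = _parse_timestamps(df["timestamp"], path)
    return DoseSchedule(
        reminder_times=ts,
        acknowledged=df["acknowledged"].to_numpy().astype(bool),
        recording_days=recording_days,
    )


def write_dose_schedule(schedule: DoseSchedule, path) -> None:
    pd.DataFrame(
        {
            "timestamp": np.datetime_as_string(schedule.reminder_times, unit="s"),
            "acknowledged": schedule.acknowledged.astype(int),
        }
    ).to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table; lax about label case."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("subject_id", "label", *FEATURE_COLUMNS), path)
    labels = df["label"].astype(str)
    upper = labels.str.upper()
    if (upper != labels).any():
        warnings.warn(f"{path}: normalized lowercase label(s) to upper case")
        df = df.assign(label=upper)
    unknown = set(df["label"]) - set(LABELS)
    if unknown:
        raise ValueError(f"{path}: unknown label(s): {sorted(unknown)}")
    return validate_cohort(df)


def write_cohort(table: pd.DataFrame, path) -> None:
    validate_cohort(table).to_csv(path, index=False)
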