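"""File readers/writers, timestamp handling, configs and run manifests.

Movement files are delimited tabular text in one of two dialects: the
simulator dialect (id, day, step, x, y) and a timestamped GPS dialect
(id, ISO-8601 UTC timestamp, x, y) from which integer day labels and
within-day step indices are derived.  Coordinates are either projected
metres or lon/lat degrees; the convention is declared, never guessed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from importlib.metadata import version as _pkg_version

import numpy as np
import pandas as pd
import yaml

from .config import SimConfig
from .datasets import CORE_COLUMNS, TrackingDataset

log = logging.getLogger("movenull")

DAY_STEP_COLUMNS = {"id": "id", "day": "day", "step": "step", "x": "x", "y": "y"}
TIMESTAMP_COLUMNS = {"id": "id", "timestamp": "timestamp", "x": "x", "y": "y"}


@dataclass
class MovementFileDialect:
    """Declared file conventions for movement tables."""

    coords: str = "projected_metres"   # or 'lonlat_degrees'
    time: str = "day_step"             # or 'timestamp'
    delimiter: str = ","
    columns: dict = field(default_factory=dict)
    day_start_hour: int = 0            # day boundary for timestamped data

    def __post_init__(self):
        if self.coords not in ("projected_metres", "lonlat_degrees"):
            raise ValueError("coords must be 'projected_metres' or 'lonlat_degrees'")
        if self.time not in ("day_step", "timestamp"):
            raise ValueError("time must be 'day_step' or 'timestamp'")
        defaults = (DAY_STEP_COLUMNS if self.time == "day_step"
                    else TIMESTAMP_COLUMNS)
        self.columns = {**defaults, **self.columns}


def read_movement(path, dialect: MovementFileDialect | None = None) -> TrackingDataset:
    """Read a movement file into a TrackingDataset.

    Timestamped files get integer day labels (days since the first
    observation date, honouring ``day_start_hour``) and within-day step
    indices in chronological order.  Duplicate (id, time) rows and
    malformed rows are rejected with the offending line numbers.
    """
    dialect = dialect or MovementFileDialect()
    cols = dialect.columns
    # round_trip parsing keeps write->read lossless for float coordinates
    df = pd.read_csv(path, sep=dialect.delimiter, float_precision="round_trip")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    rename = {v: k for k, v in cols.items()}
    df = df.rename(columns=rename)

    if dialect.time == "timestamp":
        ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
        bad = ts.isna() & df["timestamp"].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]  # +2: header and 1-basing
            raise ValueError(f"{path}: unparseable timestamps at lines {lines}")
        df["timestamp"] = ts
        dup = df.duplicated(subset=["id", "timestamp"])
        if dup.any():
            lines = (df.index[dup] + 2).tolist()[:5]
            raise ValueError(f"{path}: duplicate (id, timestamp) rows at lines {lines}")
        df = df.sort_values(["id", "timestamp"], kind="mergesort")
        shifted = df["timestamp"] - pd.Timedelta(hours=dialect.day_start_hour)
        dates = shifted.dt.normalize()
        df["day"] = (dates - dates.min()).dt.days.astype(int) + 1
        df["step"] = df.groupby(["id", "day"]).cumcount() + 1
    else:
        dup = df.duplicated(subset=["id", "day", "step"])
        if dup.any():
            lines = (df.index[dup] + 2).tolist()[:5]
            raise ValueError(f"{path}: duplicate (id, day, step) rows at lines {lines}")
        for c in ("day", "step"):
            vals = pd.to_numeric(df[c], errors="coerce")
            bad = vals.isna()
            if bad.any():
                lines = (df.index[bad] + 2).tolist()[:5]
                raise ValueError(f"{path}: malformed '{c}' values at lines {lines}")
            df[c] = vals.astype(int)

    for c in ("x", "y"):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]
            raise ValueError(f"{path}: malformed '{c}' values at lines {lines}")
        df[c] = vals.astype(float)

    if len(df) == 0:
        log.warning("%s: empty movement file", path)
    keep = [c for c in ("id", "day", "step", "x", "y", "timestamp", "orig_day")
            if c in df.columns]
    meta = {"dialect": asdict(dialect), "source": str(path)}
    return TrackingDataset(df[keep].reset_index(drop=True), metadata=meta)


def write_movement(data: TrackingDataset, path,
                   dialect: MovementFileDialect | None = None) -> None:
    """Write a TrackingDataset as delimited text (lossless round trip)."""
    dialect = dialect or MovementFileDialect(
        time="timestamp" if data.has_timestamps else "day_step")
    df = data.fixes.copy()
    cols = list(CORE_COLUMNS)
    if dialect.time == "timestamp":
        if not data.has_timestamps:
            raise ValueError("dataset has no timestamps to write")
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        cols = ["id", "timestamp", "x", "y"]
    if "orig_day" in df.columns:
        cols = cols + ["orig_day"]
    rename = {k: v for k, v in dialect.columns.items() if k in cols}
    df[cols].rename(columns=rename).to_csv(path, sep=dialect.delimiter, index=False)


def attach_timestamps(data: TrackingDataset, start: str = "2022-05-15",
                      interval: float = 600.0) -> TrackingDataset:
    """Give day/step-indexed data ISO timestamps for GPS tooling interop.

    Day d, step j maps to ``start + (d-1) days + (j-1) * interval`` (UTC).
    """
    if not {"day", "step"} <= set(data.fixes.columns):
        raise ValueError("dataset lacks day/step indexing")
    df = data.fixes.copy()
    t0 = pd.Timestamp(start, tz="UTC")
    df["timestamp"] = (t0 + pd.to_timedelta(df["day"] - 1, unit="D")
                       + pd.to_timedelta((df["step"] - 1) * interval, unit="s"))
    return TrackingDataset(df, metadata=dict(data.metadata))


def regularize_timestamps(data: TrackingDataset, interval: float = 600.0,
                          tolerance: float = 120.0) -> TrackingDataset:
    """Snap timestamps to a regular grid.

    Timestamps within ``tolerance`` seconds of the nearest multiple of
    ``interval`` (anchored at the epoch) are snapped to it; others are
    dropped.  When several fixes of one individual snap to the same grid
    point, the nearest is kept.  Drop counts are recorded in the returned
    dataset's metadata.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if not data.has_timestamps:
        raise ValueError("dataset has no timestamps to regularize")
    df = data.fixes.copy()
    epoch = pd.Timestamp("1970-01-01", tz="UTC")
    secs = (df["timestamp"] - epoch).dt.total_seconds()
    grid = np.rint(secs / interval) * interval
    offset = np.abs(secs - grid)
    within = offset <= tolerance
    n_dropped = int((~within).sum())
    df = df[within].copy()
    df["timestamp"] = epoch + pd.to_timedelta(grid[within], unit="s")
    df["_off"] = offset[within]
    df = (df.sort_values("_off")
            .drop_duplicates(subset=["id", "timestamp"], keep="first")
            .drop(columns="_off"))
    n_collided = len(data.fixes) - n_dropped - len(df)
    # re-derive the day/step index on the regular grid
    df = df.sort_values(["id", "timestamp"], kind="mergesort")
    dates = df["timestamp"].dt.normalize()
    if len(df):
        df["day"] = (dates - dates.min()).dt.days.astype(int) + 1
        df["step"] = df.groupby(["id", "day"]).cumcount() + 1
    if n_dropped or n_collided:
        log.info("regularize_timestamps: dropped %d off-grid and %d colliding fixes",
                 n_dropped, n_collided)
    meta = dict(data.metadata)
    meta.update(regularized={"interval_s": interval, "tolerance_s": tolerance,
                             "dropped": n_dropped, "collided": n_collided})
    return TrackingDataset(df.reset_index(drop=True), metadata=meta)


# -- configs and manifests ----------------------------------------------------

def load_sim_config(path) -> SimConfig:
    """Load a SimConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of SimConfig fields")
    return SimConfig.from_dict(raw)


def save_sim_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically."""

    command: str
    config: dict
    seed: int | None
    software_version: str = ""
    record_counts: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def __post_init__(self):
        if not self.software_version:
            try:
                self.software_version = _pkg_version("movenull")
            except Exception:
                self.software_version = "unknown"
        if not self.started:
            self.started = datetime.now(timezone.utc).isoformat()

    def finish(self) -> "RunManifest":
        self.finished = datetime.now(timezone.utc).isoformat()
        return self

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
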