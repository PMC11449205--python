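"""Movement-track containers shared by the simulator, randomizers and network builders.

A :class:`TrackingDataset` is a tidy table of GPS-style fixes — one row per
(individual, day, step) with planar or geographic coordinates — plus light
metadata.  Days are integer labels (calendar slots); steps order the fixes
within a day.  Empirical, timestamped data carry an extra ``timestamp``
column alongside the derived (day, step) index.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

CORE_COLUMNS = ("id", "day", "step", "x", "y")


class TrackingDataset:
    """Time-indexed positions of many tracked individuals.

    Parameters
    ----------
    fixes : pandas.DataFrame
        Must contain columns ``id, day, step, x, y``; may carry extra
        columns (``timestamp`` for empirical data, ``orig_day`` for
        randomization provenance).  At most one fix per (id, day, step).
    metadata : dict, optional
        Free-form run information (time unit, drop counts, config snapshot).
    """

    def __init__(self, fixes: pd.DataFrame, metadata: dict | None = None):
        missing = [c for c in CORE_COLUMNS if c not in fixes.columns]
        if missing:
            raise ValueError(f"fixes table is missing required columns: {missing}")
        dup = fixes.duplicated(subset=["id", "day", "step"])
        if dup.any():
            rows = fixes.index[dup].tolist()[:5]
            raise ValueError(
                f"duplicate (id, day, step) fixes at rows {rows}; "
                "each individual may have at most one fix per time point"
            )
        self.fixes = (
            fixes.sort_values(["id", "day", "step"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.metadata = dict(metadata or {})

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def individuals(self) -> np.ndarray:
        """Sorted array of individual identifiers."""
        return np.sort(self.fixes["id"].unique())

    @property
    def has_timestamps(self) -> bool:
        return "timestamp" in self.fixes.columns

    def tracked_days(self, individual) -> np.ndarray:
        """Sorted unique day labels on which ``individual`` has fixes."""
        mask = self.fixes["id"] == individual
        return np.sort(self.fixes.loc[mask, "day"].unique())

    def tracked_day_sets(self) -> dict:
        """Per-individual set of tracked days."""
        return {
            ind: set(days)
            for ind, days in self.fixes.groupby("id")["day"].unique().items()
        }

    def trajectory(self, individual) -> pd.DataFrame:
        """All fixes of one individual in chronological order."""
        mask = self.fixes["id"] == individual
        return self.fixes.loc[mask].sort_values(["day", "step"], kind="mergesort")

    def with_fixes(self, fixes: pd.DataFrame) -> "TrackingDataset":
        """New dataset with the same metadata but a different fix table."""
        return TrackingDataset(fixes, metadata=dict(self.metadata))

    def equals(self, other: "TrackingDataset") -> bool:
        cols = list(CORE_COLUMNS)
        a = self.fixes[cols].reset_index(drop=True)
        b = other.fixes[cols].reset_index(drop=True)
        return a.equals(b)

    # -- dense views -------------------------------------------------------

    def positions_panel(self):
        """Dense (time, individual) view of the coordinates.

        Returns
        -------
        times : pandas.DataFrame
            One row per observed (day, step) pair, chronologically sorted.
        ids : numpy.ndarray
            Sorted individual identifiers (column order of ``xy``).
        xy : numpy.ndarray, shape (n_times, n_individuals, 2)
            Coordinates, NaN where an individual has no fix at a time point.
        """
        ids = self.individuals
        times = (
            self.fixes[["day", "step"]]
            .drop_duplicates()
            .sort_values(["day", "step"])
            .reset_index(drop=True)
        )
        t_index = pd.MultiIndex.from_frame(times)
        wide_x = (
            self.fixes.pivot(index=["day", "step"], columns="id", values="x")
            .reindex(index=t_index, columns=ids)
        )
        wide_y = (
            self.fixes.pivot(index=["day", "step"], columns="id", values="y")
            .reindex(index=t_index, columns=ids)
        )
        xy = np.stack([wide_x.to_numpy(float), wide_y.to_numpy(float)], axis=-1)
        return times, ids, xy


def dataset_from_arrays(ids: Iterable, days: Iterable, steps: Iterable,
                        x: Iterable, y: Iterable,
                        metadata: dict | None = None) -> TrackingDataset:
    """Convenience constructor from parallel columns."""
    fixes = pd.DataFrame({
        "id": np.asarray(list(ids)),
        "day": np.asarray(list(days), dtype=int),
        "step": np.asarray(list(steps), dtype=int),
        "x": np.asarray(list(x), dtype=float),
        "y": np.asarray(list(y), dtype=float),
    })
    return TrackingDataset(fixes, metadata=metadata)
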