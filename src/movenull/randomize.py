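"""Trajectory data-stream randomizations.

Two reference models decouple the temporal synchrony of individuals while
keeping each individual's within-day movement untouched:

* **path shuffling** — per individual, permute the order of whole tracked
  days uniformly at random (optionally within contiguous windows);
* **wrap-around** — per individual, shift the whole trajectory by a random
  integer number of days drawn uniformly from [-s, +s] and re-attach the
  overhang at the other end, like a conveyor belt.  This preserves
  day-to-day path continuity everywhere except at a single junction, so
  each individual suffers at most one artificial "teleportation".

Both operate on day *labels* only: the multiset of within-day coordinate
sequences per individual is exactly conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import TrackingDataset


@dataclass
class ShiftPlan:
    """Per-individual wrap-around shifts.

    ``shifts[ind]`` is the integer number of days individual ``ind`` was
    shifted (drawn from [-s, +s]); ``slot_maps[ind]`` maps each calendar
    slot (day label) to the original day label whose data now fills it.
    """

    s: int
    shifts: dict = field(default_factory=dict)
    slot_maps: dict = field(default_factory=dict)

    def original_day_sequence(self, individual) -> list:
        """Original day labels in calendar-slot order for one individual."""
        slots = sorted(self.slot_maps[individual])
        return [self.slot_maps[individual][slot] for slot in slots]


@dataclass
class ShufflePlan:
    """Per-individual day permutations; ``slot_maps`` as in ShiftPlan."""

    window: int | None = None
    slot_maps: dict = field(default_factory=dict)

    def original_day_sequence(self, individual) -> list:
        slots = sorted(self.slot_maps[individual])
        return [self.slot_maps[individual][slot] for slot in slots]


@dataclass
class RandomizedDataset:
    """A randomized TrackingDataset together with the plan that made it."""

    dataset: TrackingDataset
    plan: object


def _apply_slot_maps(observed: TrackingDataset, plan) -> TrackingDataset:
    """Relabel days according to a plan; keep provenance in ``orig_day``.

    If the data are timestamped, timestamps move with their day so that
    time-of-day is preserved on the new calendar slot.
    """
    fixes = observed.fixes.copy()
    # invert: original day -> new slot, per individual
    new_day = np.empty(len(fixes), dtype=fixes["day"].dtype)
    for ind, slot_map in plan.slot_maps.items():
        inv = {orig: slot for slot, orig in slot_map.items()}
        mask = (fixes["id"] == ind).to_numpy()
        new_day[mask] = fixes.loc[mask, "day"].map(inv).to_numpy()
    fixes["orig_day"] = fixes["day"]
    fixes["day"] = new_day
    if "timestamp" in fixes.columns:
        shift_days = (fixes["day"] - fixes["orig_day"]).astype("int64")
        fixes["timestamp"] = fixes["timestamp"] + pd.to_timedelta(shift_days, unit="D")
    return observed.with_fixes(fixes)


def wrap_around(observed: TrackingDataset, s: int, rng: np.random.Generator,
                mode: str = "tracked") -> RandomizedDataset:
    """Wrap-around randomization.

    Per individual, a shift ``k`` is drawn uniformly from the integers
    [-s, +s] (0 included); the data of the i-th tracked day move to slot
    ``(i - 1 + k) mod n + 1`` in that individual's own day sequence.

    Parameters
    ----------
    s : int
        Maximum absolute shift in days (time-shift range 2s).
    mode : {'tracked', 'calendar'}
        'tracked' (default) wraps each individual around its own tracked
        days, skipping gaps; 'calendar' wraps over the full integer day
        range of the dataset, shifting trajectories across untracked days.
    """
    if s < 0:
        raise ValueError("shift range s must be >= 0")
    if mode not in ("tracked", "calendar"):
        raise ValueError("mode must be 'tracked' or 'calendar'")
    plan = ShiftPlan(s=int(s))
    if len(observed) == 0:
        return RandomizedDataset(observed.with_fixes(observed.fixes.copy()), plan)
    if mode == "calendar":
        all_days = observed.fixes["day"]
        lo, hi = int(all_days.min()), int(all_days.max())
        calendar = np.arange(lo, hi + 1)
    for ind in observed.individuals:
        tracked = observed.tracked_days(ind)
        days = calendar if mode == "calendar" else tracked
        n = len(days)
        k = int(rng.integers(-s, s + 1))
        plan.shifts[ind] = k
        tracked_set = set(tracked)
        slot_map = {}
        for i, orig in enumerate(days):
            if orig not in tracked_set:
                continue
            slot_map[days[(i + k) % n]] = orig
        plan.slot_maps[ind] = slot_map
    return RandomizedDataset(_apply_slot_maps(observed, plan), plan)


def path_shuffle(observed: TrackingDataset, rng: np.random.Generator,
                 window: int | None = None) -> RandomizedDataset:
    """Path-shuffling randomization: per-individual uniform permutation of
    tracked-day labels, optionally within contiguous windows of ``window``
    days (last window may be shorter)."""
    if window is not None and window <= 0:
        raise ValueError("window must be a positive number of days")
    plan = ShufflePlan(window=window)
    for ind in observed.individuals:
        days = observed.tracked_days(ind)
        n = len(days)
        w = n if window is None else int(window)
        slot_map = {}
        for start in range(0, n, w):
            seg = days[start:start + w]
            perm = rng.permutation(len(seg))
            for slot, j in zip(seg, perm):
                slot_map[slot] = seg[j]
        plan.slot_maps[ind] = slot_map
    return RandomizedDataset(_apply_slot_maps(observed, plan), plan)


def count_teleportations(r: RandomizedDataset) -> dict:
    """Number of day-to-day discontinuities introduced per individual.

    A teleportation is an adjacent pair of calendar slots whose original
    days were not consecutive in the individual's original day order.
    Wrap-around yields at most one (zero only for an effective zero
    shift); unwindowed shuffling can yield up to n - 1.
    """
    plan = getattr(r, "plan", None)
    if plan is None or not getattr(plan, "slot_maps", None):
        raise ValueError("randomized dataset carries no provenance plan")
    counts = {}
    for ind, slot_map in plan.slot_maps.items():
        rank = {d: i for i, d in enumerate(sorted(slot_map.values()))}
        orig_seq = [rank[slot_map[slot]] for slot in sorted(slot_map)]
        counts[ind] = sum(
            1 for a, b in zip(orig_seq, orig_seq[1:]) if b != a + 1
        )
    return counts


def downsample(observed: TrackingDataset, points_per_day: int) -> TrackingDataset:
    """Thin each day to ``points_per_day`` evenly spaced fixes.

    Retains within-day step indices ``ceil(1 + (j - 1) * S / p)`` for
    j = 1..p, where S is the number of steps per day (stride S/p starting
    at the first step; exact stride when p divides S).
    """
    if points_per_day < 1:
        raise ValueError("points_per_day must be >= 1")
    steps = np.sort(observed.fixes["step"].unique())
    S = len(steps)
    if points_per_day > S:
        raise ValueError(
            f"points_per_day ({points_per_day}) exceeds available steps per day ({S})"
        )
    j = np.arange(1, points_per_day + 1)
    idx = np.ceil(1 + (j - 1) * S / points_per_day).astype(int) - 1
    keep = set(steps[idx])
    fixes = observed.fixes[observed.fixes["step"].isin(keep)].reset_index(drop=True)
    return observed.with_fixes(fixes)
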