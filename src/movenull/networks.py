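"""Interaction detection and proximity-based social networks.

Interactions are detected from proximity: *co-location* (a pair closer
than a distance threshold at one time point), *co-movement* (closer than
the threshold at two consecutive within-day time points), and, for
timestamped empirical data, *in-flight* interactions (both individuals
moving faster than a speed floor and within a distance ceiling for a run
of consecutive sampling intervals).  Records aggregate into a weighted
undirected network, with raw-count or simple-ratio-index (SRI) edge
weights, from which per-node degree and strength are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .config import SimConfig
from .datasets import TrackingDataset

RECORD_COLUMNS = ["id_a", "id_b", "day", "step", "rule"]

EARTH_RADIUS_M = 6_371_000.0


def interaction_threshold(cfg: SimConfig) -> float:
    """Co-location distance threshold: twice the mean agent step length."""
    return 2.0 * cfg.step_mean


def great_circle_distance(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in metres between lon/lat degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _pair_distances(data: TrackingDataset, coords: str = "projected"):
    """Dense per-time pairwise distances.

    Returns (times, ids, pair index arrays (ia, ib), distances (T, P)).
    Distances involving a missing fix are NaN.
    """
    times, ids, xy = data.positions_panel()
    n = len(ids)
    ia, ib = np.triu_indices(n, 1)
    if coords == "lonlat":
        d = great_circle_distance(xy[:, ia, 0], xy[:, ia, 1],
                                  xy[:, ib, 0], xy[:, ib, 1])
    else:
        d = np.hypot(xy[:, ia, 0] - xy[:, ib, 0], xy[:, ia, 1] - xy[:, ib, 1])
    return times, ids, (ia, ib), d


def _records_from_hits(times, ids, pair_idx, hits, rule: str) -> pd.DataFrame:
    ia, ib = pair_idx
    t_idx, p_idx = np.nonzero(hits)
    rec = pd.DataFrame({
        "id_a": ids[ia[p_idx]],
        "id_b": ids[ib[p_idx]],
        "day": times["day"].to_numpy()[t_idx],
        "step": times["step"].to_numpy()[t_idx],
        "rule": rule,
    })
    return rec


def detect_colocation(data: TrackingDataset, threshold: float) -> pd.DataFrame:
    """Pairs strictly closer than ``threshold`` at each time point.

    Returns one row per unordered pair per time point (ids in canonical
    sorted order); pairs with a missing fix at a time point are skipped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    times, ids, pair_idx, d = _pair_distances(data)
    with np.errstate(invalid="ignore"):
        hits = d < threshold
    return _records_from_hits(times, ids, pair_idx, hits, "colocation")


def detect_comovement(data: TrackingDataset, threshold: float) -> pd.DataFrame:
    """Pairs within ``threshold`` at two consecutive within-day time points.

    A record is emitted at the second time point.  Day boundaries do not
    chain: the last step of one day and the first of the next never form
    a co-movement, since days are the randomization unit.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    times, ids, pair_idx, d = _pair_distances(data)
    with np.errstate(invalid="ignore"):
        close = d < threshold
    day = times["day"].to_numpy()
    both = np.zeros_like(close)
    both[1:] = close[1:] & close[:-1] & (day[1:] == day[:-1])[:, None]
    return _records_from_hits(times, ids, pair_idx, both, "comovement")


def detect_flight_interactions(data: TrackingDataset,
                               speed_min: float = 5.0,
                               dist_max: float = 1000.0,
                               n_consecutive: int = 2,
                               interval: float = 600.0,
                               coords: str = "projected") -> pd.DataFrame:
    """In-flight interactions from timestamped tracking data.

    Two individuals interact when both move faster than ``speed_min``
    (m/s, computed from the displacement since each one's previous fix)
    and are within ``dist_max`` (m) of each other for ``n_consecutive``
    successive sampling intervals of length ``interval`` seconds.  A
    record is emitted at the last interval of each qualifying run.

    ``coords`` declares the coordinate convention: 'projected' (metres,
    Euclidean) or 'lonlat' (degrees, great-circle distances).  Timestamps
    must already sit on a regular grid (see ``regularize_timestamps``).
    """
    if coords not in ("projected", "lonlat"):
        raise ValueError("coords must be 'projected' or 'lonlat'")
    if not data.has_timestamps:
        raise ValueError("flight interactions require timestamped data")
    fixes = data.fixes
    per_ind = fixes.groupby("id")["timestamp"]
    if not per_ind.apply(lambda s: s.is_monotonic_increasing).all():
        raise ValueError("timestamps must be sorted within each individual")

    ts = fixes["timestamp"]
    t0 = ts.min()
    rel = (ts - t0).dt.total_seconds().to_numpy()
    slots = rel / interval
    if not np.allclose(slots, np.rint(slots), atol=1e-6):
        raise ValueError(
            "timestamps are not on a regular grid; regularize them first")
    slots = np.rint(slots).astype(np.int64)

    ids = data.individuals
    id_col = {ind: j for j, ind in enumerate(ids)}
    n = len(ids)
    T = int(slots.max()) + 1
    xy = np.full((T, n, 2), np.nan)
    cols = fixes["id"].map(id_col).to_numpy()
    xy[slots, cols, 0] = fixes["x"].to_numpy(float)
    xy[slots, cols, 1] = fixes["y"].to_numpy(float)

    # per-individual speed at slot t: displacement from slot t-1 / interval
    if coords == "lonlat":
        seg = great_circle_distance(xy[:-1, :, 0], xy[:-1, :, 1],
                                    xy[1:, :, 0], xy[1:, :, 1])
    else:
        seg = np.hypot(xy[1:, :, 0] - xy[:-1, :, 0],
                       xy[1:, :, 1] - xy[:-1, :, 1])
    speed = np.full((T, n), np.nan)
    speed[1:] = seg / interval
    with np.errstate(invalid="ignore"):
        flying = speed > speed_min

    ia, ib = np.triu_indices(n, 1)
    if coords == "lonlat":
        d = great_circle_distance(xy[:, ia, 0], xy[:, ia, 1],
                                  xy[:, ib, 0], xy[:, ib, 1])
    else:
        d = np.hypot(xy[:, ia, 0] - xy[:, ib, 0], xy[:, ia, 1] - xy[:, ib, 1])
    with np.errstate(invalid="ignore"):
        cond = (d <= dist_max) & flying[:, ia] & flying[:, ib]

    run = np.zeros_like(cond, dtype=np.int32)
    if T > 0:
        run[0] = cond[0]
        for t in range(1, T):
            run[t] = np.where(cond[t], run[t - 1] + 1, 0)
    hits = run >= n_consecutive

    t_idx, p_idx = np.nonzero(hits)
    grid = t0 + pd.to_timedelta(np.arange(T) * interval, unit="s")
    return pd.DataFrame({
        "id_a": ids[ia[p_idx]],
        "id_b": ids[ib[p_idx]],
        "timestamp": grid[t_idx],
        "rule": "flight",
    })


# -- networks ----------------------------------------------------------------

@dataclass
class SocialNetwork:
    """Weighted undirected interaction network over individuals."""

    graph: nx.Graph
    weighting: str  # 'count' or 'sri'

    @property
    def nodes(self):
        return list(self.graph.nodes)

    def edge_weights(self) -> dict:
        return {
            tuple(sorted((u, v))): d["weight"]
            for u, v, d in self.graph.edges(data=True)
        }


@dataclass
class NodeMetrics:
    """Per-node degree (unique partners) and strength (sum of weights)."""

    degree: dict
    strength: dict
    mean_degree: float
    mean_strength: float


def tracked_periods(data: TrackingDataset) -> dict:
    """Per-individual set of observation periods.

    Periods are timestamps when the data are timestamped, (day, step)
    pairs otherwise; used as the SRI denominator.
    """
    if data.has_timestamps:
        return {ind: set(g) for ind, g in data.fixes.groupby("id")["timestamp"]}
    keys = list(zip(data.fixes["day"], data.fixes["step"]))
    out: dict = {}
    for ind, key in zip(data.fixes["id"], keys):
        out.setdefault(ind, set()).add(key)
    return out


def build_network(records: pd.DataFrame, tracking=None,
                  weighting: str = "count", nodes=None) -> SocialNetwork:
    """Aggregate interaction records into a weighted network.

    ``weighting='count'`` sets each edge weight to the number of records
    for the pair; ``'sri'`` divides by the number of periods during which
    both individuals were tracked (simple ratio index).  ``tracking`` is
    a TrackingDataset or a per-individual dict of period sets; required
    for SRI, and its individuals are included as (possibly isolated) nodes.
    """
    if weighting not in ("count", "sri"):
        raise ValueError("weighting must be 'count' or 'sri'")
    periods = None
    if tracking is not None:
        periods = (tracked_periods(tracking)
                   if isinstance(tracking, TrackingDataset) else dict(tracking))
    if weighting == "sri" and periods is None:
        raise ValueError("SRI weighting requires per-individual tracking periods")

    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    if periods is not None:
        g.add_nodes_from(periods.keys())
    if len(records):
        a = np.minimum(records["id_a"], records["id_b"])
        b = np.maximum(records["id_a"], records["id_b"])
        counts = pd.Series(1, index=pd.MultiIndex.from_arrays([a, b])).groupby(
            level=[0, 1]).sum()
        for (u, v), c in counts.items():
            if u == v:
                raise ValueError("self-interaction record encountered")
            if weighting == "sri":
                joint = len(periods[u] & periods[v])
                if joint == 0:
                    raise ValueError(
                        f"pair ({u}, {v}) has records but no jointly tracked periods")
                w = c / joint
            else:
                w = float(c)
            g.add_node(u)
            g.add_node(v)
            g.add_edge(u, v, weight=w)
    return SocialNetwork(graph=g, weighting=weighting)


def node_metrics(net: SocialNetwork) -> NodeMetrics:
    """Degree, strength, and their population means (isolates included)."""
    g = net.graph
    degree = {}
    strength = {}
    for v in g.nodes:
        inc = [d["weight"] for _, _, d in g.edges(v, data=True) if d["weight"] > 0]
        degree[v] = len(inc)
        strength[v] = float(sum(inc))
    n = len(degree)
    mean_deg = sum(degree.values()) / n if n else 0.0
    mean_str = sum(strength.values()) / n if n else 0.0
    return NodeMetrics(degree=degree, strength=strength,
                       mean_degree=mean_deg, mean_strength=mean_str)


def network_means(data: TrackingDataset, threshold: float,
                  rule: str = "colocation") -> tuple[float, float]:
    """Population mean degree and mean strength in one pass.

    Equivalent to detect → build_network(count) → node_metrics, but
    computed directly from the dense pair-hit array; every individual in
    the dataset counts toward the means, including isolates.
    """
    times, ids, (ia, ib), d = _pair_distances(data)
    with np.errstate(invalid="ignore"):
        close = d < threshold
    if rule == "comovement":
        day = times["day"].to_numpy()
        hits = np.zeros_like(close)
        hits[1:] = close[1:] & close[:-1] & (day[1:] == day[:-1])[:, None]
    elif rule == "colocation":
        hits = close
    else:
        raise ValueError("rule must be 'colocation' or 'comovement'")
    n = len(ids)
    pair_counts = hits.sum(axis=0)          # records per pair
    pair_any = pair_counts > 0
    deg = np.zeros(n)
    stren = np.zeros(n)
    np.add.at(deg, ia, pair_any)
    np.add.at(deg, ib, pair_any)
    np.add.at(stren, ia, pair_counts)
    np.add.at(stren, ib, pair_counts)
    return float(deg.mean()), float(stren.mean())
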