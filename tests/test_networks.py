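"""Interaction detection and network construction, checked against brute
force over pairs and adjacency sums."""

import itertools

import numpy as np
import pandas as pd
import pytest

from movenull import (SimConfig, TrackingDataset, build_network,
                      detect_colocation, detect_comovement,
                      detect_flight_interactions, great_circle_distance,
                      interaction_threshold, network_means, node_metrics)

from conftest import make_day_dataset


def fixes_from(rows):
    return TrackingDataset(pd.DataFrame(
        rows, columns=["id", "day", "step", "x", "y"]))


def brute_force_colocation(data, threshold):
    """O(pairs x times) reference implementation."""
    out = []
    f = data.fixes
    for (day, step), g in f.groupby(["day", "step"]):
        g = g.sort_values("id")
        for (_, a), (_, b) in itertools.combinations(g.iterrows(), 2):
            if np.hypot(a.x - b.x, a.y - b.y) < threshold:
                out.append((a.id, b.id, day, step))
    return sorted(out)


class TestThreshold:
    @pytest.mark.parametrize("step_mean, expected", [
        (7.0, 14.0), (0.5, 1.0), (10.0, 20.0)])
    def test_twice_mean_step_length(self, step_mean, expected):
        cfg = SimConfig(step_mean=step_mean)
        assert interaction_threshold(cfg) == expected


class TestColocation:
    def test_strictly_closer_counts(self):
        data = fixes_from([(0, 1, 1, 0.0, 0.0), (1, 1, 1, 13.9, 0.0)])
        assert len(detect_colocation(data, 14.0)) == 1

    def test_boundary_distance_excluded(self):
        data = fixes_from([(0, 1, 1, 0.0, 0.0), (1, 1, 1, 14.0, 0.0)])
        assert len(detect_colocation(data, 14.0)) == 0

    def test_three_mutually_close_agents_give_three_records(self):
        data = fixes_from([(0, 1, 1, 0.0, 0.0), (1, 1, 1, 1.0, 0.0),
                           (2, 1, 1, 0.0, 1.0)])
        rec = detect_colocation(data, 14.0)
        assert len(rec) == 3
        assert (rec["id_a"] < rec["id_b"]).all()

    def test_missing_fix_skips_pair(self):
        data = fixes_from([(0, 1, 1, 0.0, 0.0), (1, 1, 2, 0.0, 0.0)])
        assert len(detect_colocation(data, 14.0)) == 0

    def test_matches_brute_force_on_random_data(self, rng):
        data = make_day_dataset(4, 3, steps_per_day=4, rng=rng)
        # coordinates are spread by individual; use a wide threshold
        rec = detect_colocation(data, 150.0)
        got = sorted(zip(rec.id_a, rec.id_b, rec.day, rec.step))
        assert got == brute_force_colocation(data, 150.0)

    def test_monotone_in_threshold(self, rng):
        data = make_day_dataset(4, 2, steps_per_day=3, rng=rng)
        small = detect_colocation(data, 100.0)
        large = detect_colocation(data, 250.0)
        small_set = set(zip(small.id_a, small.id_b, small.day, small.step))
        large_set = set(zip(large.id_a, large.id_b, large.day, large.step))
        assert small_set <= large_set


class TestComovement:
    def test_two_consecutive_steps_emit_at_second(self):
        data = fixes_from([(0, 1, 3, 0, 0), (0, 1, 4, 1, 0),
                           (1, 1, 3, 2, 0), (1, 1, 4, 2, 0)])
        rec = detect_comovement(data, 14.0)
        assert len(rec) == 1
        assert rec.iloc[0]["step"] == 4

    def test_single_step_path_crossing_excluded(self):
        data = fixes_from([(0, 1, 3, 0, 0), (0, 1, 4, 100, 0),
                           (1, 1, 3, 2, 0), (1, 1, 4, 200, 0)])
        assert len(detect_comovement(data, 14.0)) == 0

    def test_day_boundary_does_not_chain(self):
        data = fixes_from([(0, 1, 2, 0, 0), (0, 2, 1, 0, 0),
                           (1, 1, 2, 1, 0), (1, 2, 1, 1, 0)])
        assert len(detect_comovement(data, 14.0)) == 0

    def test_comovement_subset_of_colocation(self, rng):
        data = make_day_dataset(4, 3, steps_per_day=5, rng=rng)
        co = detect_colocation(data, 150.0)
        cm = detect_comovement(data, 150.0)
        co_set = set(zip(co.id_a, co.id_b, co.day, co.step))
        cm_set = set(zip(cm.id_a, cm.id_b, cm.day, cm.step))
        assert cm_set <= co_set


class TestFlightInteractions:
    @staticmethod
    def track(ind, start, xs, y):
        """Fixes every 10 min from `start`, x positions `xs`, fixed y."""
        t0 = pd.Timestamp(start, tz="UTC")
        return pd.DataFrame({
            "id": ind,
            "day": 1,
            "step": np.arange(1, len(xs) + 1),
            "x": xs,
            "y": y,
            "timestamp": [t0 + pd.Timedelta(minutes=10 * i)
                          for i in range(len(xs))],
        })

    def build(self, speed_a=6.0, speed_b=6.0, dy=800.0):
        # three fixes (11:50, 12:00, 12:10); speeds in m/s over 600 s
        xs_a = np.array([0, speed_a * 600, 2 * speed_a * 600])
        xs_b = np.array([0, speed_b * 600, 2 * speed_b * 600])
        f = pd.concat([self.track(0, "2022-06-01 11:50", xs_a, 0.0),
                       self.track(1, "2022-06-01 11:50", xs_b, dy)],
                      ignore_index=True)
        return TrackingDataset(f)

    def test_two_consecutive_intervals_one_record(self):
        rec = detect_flight_interactions(self.build())
        assert len(rec) == 1
        assert rec.iloc[0]["timestamp"] == pd.Timestamp("2022-06-01 12:10", tz="UTC")

    def test_slow_bird_is_not_flying(self):
        assert len(detect_flight_interactions(self.build(speed_b=4.0))) == 0

    def test_single_interval_insufficient(self):
        data = self.build()
        f = data.fixes.drop(index=[2, 5]).reset_index(drop=True)  # drop 12:10
        assert len(detect_flight_interactions(TrackingDataset(f))) == 0

    def test_distance_ceiling(self):
        assert len(detect_flight_interactions(self.build(dy=1500.0))) == 0

    def test_irregular_timestamps_rejected(self):
        data = self.build()
        f = data.fixes.copy()
        f.loc[0, "timestamp"] += pd.Timedelta(minutes=3)
        f = f.sort_values(["id", "timestamp"])
        with pytest.raises(ValueError):
            detect_flight_interactions(TrackingDataset(f))

    def test_great_circle_distance_known_value(self):
        # one degree of latitude is ~111.2 km on the sphere
        d = great_circle_distance(35.0, 31.0, 35.0, 32.0)
        assert d == pytest.approx(111_195, rel=0.001)


def records(pairs):
    return pd.DataFrame([{"id_a": a, "id_b": b, "day": 1, "step": i, "rule": "colocation"}
                         for i, (a, b) in enumerate(pairs)])


class TestBuildNetwork:
    def test_count_weighting(self):
        net = build_network(records([("a", "b")] * 5), weighting="count")
        assert net.edge_weights() == {("a", "b"): 5.0}

    def test_sri_weighting(self):
        tracking = {"a": set(range(10)), "b": set(range(10))}
        net = build_network(records([("a", "b")] * 3), tracking=tracking,
                            weighting="sri")
        assert net.edge_weights()[("a", "b")] == pytest.approx(0.3)

    def test_sri_requires_tracking(self):
        with pytest.raises(ValueError):
            build_network(records([("a", "b")]), weighting="sri")

    def test_no_records_gives_edgeless_network_over_tracked_nodes(self):
        tracking = {"a": {1}, "b": {1}, "c": {2}}
        net = build_network(records([])[0:0], tracking=tracking)
        assert set(net.nodes) == {"a", "b", "c"}
        assert net.graph.number_of_edges() == 0

    def test_sri_bounded_by_one(self):
        tracking = {"a": set(range(4)), "b": set(range(4))}
        net = build_network(records([("a", "b")] * 4), tracking=tracking,
                            weighting="sri")
        w = net.edge_weights()[("a", "b")]
        assert 0 <= w <= 1


class TestNodeMetrics:
    def test_degree_and_strength(self):
        rec = pd.concat([records([("A", "B")] * 2), records([("A", "C")])])
        m = node_metrics(build_network(rec))
        assert m.degree["A"] == 2 and m.strength["A"] == 3.0
        assert m.degree["B"] == 1 and m.strength["B"] == 2.0

    def test_empty_network_all_zero(self):
        m = node_metrics(build_network(records([])[0:0], tracking={"a": {1}}))
        assert m.degree == {"a": 0} and m.strength == {"a": 0.0}
        assert m.mean_degree == 0.0 and m.mean_strength == 0.0

    def test_complete_graph_brute_force(self):
        pairs = list(itertools.combinations("wxyz", 2))
        m = node_metrics(build_network(records(pairs)))
        for v in "wxyz":
            assert m.degree[v] == 3 and m.strength[v] == 3.0
        assert m.mean_degree == 3.0 and m.mean_strength == 3.0

    def test_handshake_identity(self, rng):
        data = make_day_dataset(5, 3, steps_per_day=4, rng=rng)
        rec = detect_colocation(data, 200.0)
        net = build_network(rec, tracking=data)
        m = node_metrics(net)
        n_edges = net.graph.number_of_edges()
        total_w = sum(net.edge_weights().values())
        assert sum(m.degree.values()) == 2 * n_edges
        assert sum(m.strength.values()) == pytest.approx(2 * total_w)

    def test_network_means_matches_record_pipeline(self, rng):
        data = make_day_dataset(5, 4, steps_per_day=5, rng=rng)
        for rule in ("colocation", "comovement"):
            detect = detect_colocation if rule == "colocation" else detect_comovement
            rec = detect(data, 150.0)
            m = node_metrics(build_network(rec, tracking=data))
            deg, stren = network_means(data, 150.0, rule=rule)
            assert deg == pytest.approx(m.mean_degree)
            assert stren == pytest.approx(m.mean_strength)
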