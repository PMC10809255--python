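import itertools

import numpy as np
import pytest

from dyesorb.dimers import (
    DimerConfig,
    DimerEvent,
    classify_event,
    detect_dimers,
    detect_trimers,
    dimer_statistics,
    stacking_contact,
)
from dyesorb.states import StateSegment

CFG = DimerConfig()


def grid(n, dt=0.01):
    return np.arange(n) * dt


def arrays(times, pairs, far=50.0):
    f, p = len(times), len(pairs)
    return np.full((f, p), far), np.full((f, p), 90.0)


class TestDetection:
    def test_never_in_contact(self):
        t = grid(500)
        pairs = [("a", "b")]
        dist, ang = arrays(t, pairs)
        assert detect_dimers(t, pairs, dist, ang, CFG) == []

    def test_scripted_episode_duration(self):
        """A pair stacked from 36 to 80 ns yields one ~44 ns event."""
        t = grid(10000, 0.01)
        pairs = [("a", "b")]
        dist, ang = arrays(t, pairs)
        sel = (t >= 36.0) & (t < 80.0)
        dist[sel, 0] = 4.0
        ang[sel, 0] = 175.0  # antiparallel normals stack too
        events = detect_dimers(t, pairs, dist, ang, CFG)
        assert len(events) == 1
        assert events[0].start == pytest.approx(36.0)
        assert events[0].duration == pytest.approx(44.0, abs=0.011)

    def test_too_short_contact_dropped(self):
        t = grid(1000, 0.01)
        pairs = [("a", "b")]
        dist, ang = arrays(t, pairs)
        sel = (t >= 1.0) & (t < 1.5)  # below the 1 ns minimum
        dist[sel, 0] = 4.0
        ang[sel, 0] = 0.0
        assert detect_dimers(t, pairs, dist, ang, CFG) == []

    def test_angle_folding(self):
        c = stacking_contact(np.array([4.0, 4.0, 4.0]),
                             np.array([10.0, 170.0, 90.0]), CFG)
        assert list(c) == [True, True, False]

    def test_exclusivity_three_stacked_dyes(self):
        """In an a–b–c chain only the closest pair forms the dimer."""
        dyes = ["a", "b", "c"]
        pairs = list(itertools.combinations(dyes, 2))
        t = grid(300, 0.01)
        dist, ang = arrays(t, pairs)
        by_pair = {("a", "b"): 4.0, ("b", "c"): 4.4, ("a", "c"): 8.4}
        for k, pair in enumerate(pairs):
            dist[:, k] = by_pair[pair]
            ang[:, k] = 5.0
        events = detect_dimers(t, pairs, dist, ang, CFG)
        assert [e.pair for e in events] == [("a", "b")]

        # brute-force oracle: per frame, best exclusive assignment by distance
        for frame in (0, 150):
            best, best_d = None, np.inf
            for subset in itertools.combinations(range(len(pairs)), 1):
                d = dist[frame, subset[0]]
                if d <= CFG.core_distance_cutoff and d < best_d:
                    best, best_d = pairs[subset[0]], d
            assert best == ("a", "b")

    def test_no_dye_in_two_simultaneous_events(self):
        rng = np.random.default_rng(0)
        dyes = [f"d{i}" for i in range(4)]
        pairs = list(itertools.combinations(dyes, 2))
        t = grid(2000, 0.01)
        dist = rng.uniform(3.0, 9.0, size=(len(t), len(pairs)))
        ang = rng.uniform(0.0, 40.0, size=(len(t), len(pairs)))
        cfg = DimerConfig(min_dimer_duration=0.01, gap_tolerance=0.0)
        events = detect_dimers(t, pairs, dist, ang, cfg)
        for a, b in itertools.combinations(events, 2):
            if set(a.pair) & set(b.pair):
                assert a.end < b.start or b.end < a.start

    def test_total_dimer_time_bound(self):
        rng = np.random.default_rng(1)
        dyes = [f"d{i}" for i in range(5)]
        pairs = list(itertools.combinations(dyes, 2))
        t = grid(1000, 0.01)
        dist = rng.uniform(3.0, 7.0, size=(len(t), len(pairs)))
        ang = rng.uniform(0.0, 60.0, size=(len(t), len(pairs)))
        cfg = DimerConfig(min_dimer_duration=0.01, gap_tolerance=0.0)
        events = detect_dimers(t, pairs, dist, ang, cfg)
        total = sum(e.duration for e in events)
        assert total <= (t[-1] - t[0]) * (len(dyes) // 2) + 1e-9


class TestTrimers:
    def test_no_third_contact(self):
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        t = grid(500, 0.01)
        dist, ang = arrays(t, pairs)
        dist[:, 0] = 4.0
        ang[:, 0] = 0.0
        events = detect_dimers(t, pairs, dist, ang, CFG)
        assert detect_trimers(events, t, pairs, dist, ang, CFG) == []

    def test_scripted_transient_trimer(self):
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        t = grid(2000, 0.01)
        dist, ang = arrays(t, pairs)
        dist[:, 0] = 4.0
        ang[:, 0] = 0.0
        third = (t >= 5.0) & (t < 10.0)
        dist[third, 2] = 4.5  # c touches b for 5 ns
        ang[third, 2] = 10.0
        events = detect_dimers(t, pairs, dist, ang, CFG)
        trimers = detect_trimers(events, t, pairs, dist, ang, CFG)
        assert len(trimers) == 1
        tr = trimers[0]
        assert tr.members == ("a", "b", "c")
        assert tr.transient
        assert tr.end - tr.start == pytest.approx(5.0, abs=0.011)

    def test_member_exchange(self):
        """A trimer contact followed by a dimer with swapped membership."""
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        t = grid(3000, 0.01)
        dist, ang = arrays(t, pairs)
        first = t < 15.0
        dist[first, 0] = 4.0
        ang[first, 0] = 0.0
        overlap = (t >= 12.0) & (t < 15.0)
        dist[overlap, 2] = 4.5
        ang[overlap, 2] = 5.0
        swapped = t >= 15.0
        dist[swapped, 2] = 4.0
        ang[swapped, 2] = 0.0
        events = detect_dimers(t, pairs, dist, ang, CFG)
        assert [e.pair for e in events] == [("a", "b"), ("b", "c")]
        trimers = detect_trimers(events, t, pairs, dist, ang, CFG)
        assert len(trimers) == 1 and trimers[0].members == ("a", "b", "c")


class TestClassification:
    def _times(self):
        return grid(10000, 0.01)

    def test_censored_at_final_frame(self):
        t = self._times()
        ev = DimerEvent(pair=("a", "b"), start=90.0, end=t[-1])
        surf = np.full(len(t), 30.0)
        out = classify_event(ev, t, surf, [], CFG)
        assert out.end_reason == "censored"
        assert out.location == "solute"

    def test_matrix_location_from_median(self):
        t = self._times()
        ev = DimerEvent(pair=("a", "b"), start=10.0, end=20.0)
        surf = np.full(len(t), 30.0)
        surf[(t >= 10.0) & (t <= 20.0)] = 3.0
        out = classify_event(ev, t, surf, [], CFG)
        assert out.location == "matrix"

    def test_desorption_intact_pair_leaves(self):
        t = self._times()
        ev = DimerEvent(pair=("a", "b"), start=10.0, end=20.0)
        surf = np.full(len(t), 30.0)
        sel = (t >= 10.0) & (t <= 18.0)
        surf[sel] = 3.0
        leaving = (t > 18.0) & (t <= 20.0)
        surf[leaving] = 12.0  # beyond 2× the matrix threshold while intact
        out = classify_event(ev, t, surf, [], CFG)
        assert out.end_reason == "desorption"

    def test_dissociation_with_prompt_adsorption(self):
        t = self._times()
        ev = DimerEvent(pair=("a", "b"), start=10.0, end=20.0)
        surf = np.full(len(t), 30.0)
        surf[(t >= 10.0) & (t <= 20.0)] = 6.0  # near but off the matrix
        partner = StateSegment("a", "n", "A", 20.5, 40.0, 2.0, 1.0, 0.0)
        out = classify_event(ev, t, surf, [partner], CFG)
        assert out.end_reason == "dissociation"
        assert out.location == "solute"


class TestStatistics:
    def test_no_events(self):
        s = dimer_statistics({"r1": []})
        assert (s.mean_dimer_count, s.total_time, s.mean_lifetime) == (0, 0, 0)

    def test_single_run_hand_arithmetic(self):
        evs = [
            DimerEvent(("a", "b"), 0.0, 10.0),
            DimerEvent(("c", "d"), 50.0, 70.0),
        ]
        s = dimer_statistics({"r1": evs})
        assert s.mean_dimer_count == 2
        assert s.total_time == pytest.approx(30.0)
        assert s.mean_lifetime == pytest.approx(15.0)

    def test_four_run_mean_count(self):
        runs = {
            f"r{i}": [DimerEvent(("a", "b"), j, j + 1.0) for j in range(c)]
            for i, c in enumerate([5, 4, 5, 5])
        }
        s = dimer_statistics(runs)
        assert s.mean_dimer_count == pytest.approx(4.75)

    def test_pooled_lifetime_consistency_single_run(self):
        evs = [DimerEvent(("a", "b"), 0.0, 4.0), DimerEvent(("a", "b"), 10.0, 12.0)]
        s = dimer_statistics({"only": evs})
        assert s.mean_lifetime * len(evs) == pytest.approx(s.total_time)
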