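import itertools

import numpy as np
import pytest

from tilescope import segmentation as seg
from tilescope.types import IntensityMatrix, Probe


def build_matrix(values):
    values = np.asarray(values, dtype=float)
    n = values.shape[1] // 2
    return IntensityMatrix(
        probe_ids=[f"p{i}" for i in range(values.shape[0])],
        values=values,
        conditions=["reference"] * n + ["treated"] * n,
        replicates=list(range(1, n + 1)) * 2,
    )


def naive_cost(values, n_rep, first, last):
    """RSS around the per-condition mean, computed directly."""
    cost = 0.0
    for cols in (slice(0, n_rep), slice(n_rep, None)):
        block = values[first : last + 1, cols].ravel()
        cost += float(np.sum((block - block.mean()) ** 2))
    return cost


def brute_force_min_cost(values, n_rep, penalty):
    """Exhaustive minimum of the penalised segmentation cost over all
    2^(n-1) contiguous partitions."""
    n = values.shape[0]
    seg_cost = {
        (i, j): naive_cost(values, n_rep, i, j)
        for i in range(n)
        for j in range(i, n)
    }
    best = np.inf
    for mask in range(2 ** (n - 1)):
        bounds = [0] + [k + 1 for k in range(n - 1) if mask >> k & 1] + [n]
        cost = sum(
            seg_cost[(a, b - 1)] for a, b in zip(bounds[:-1], bounds[1:])
        ) + penalty * (len(bounds) - 1)
        best = min(best, cost)
    return best


def dp_total_cost(segments, values, n_rep, penalty):
    cost = penalty * len(segments)
    for s in segments:
        cost += naive_cost(values, n_rep, min(s), max(s))
    return cost


class TestDPOptimality:
    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(1234)
        for trial in range(50):
            n = int(rng.integers(2, 13))
            n_rep = int(rng.integers(2, 4))
            values = rng.normal(9, 1.5, size=(n, 2 * n_rep))
            if trial % 2:  # half the trials get a genuine step
                k = int(rng.integers(1, n))
                values[k:, :] += rng.normal(0, 2)
            m = build_matrix(values)
            starts = list(range(1, 14 * n, 14))
            penalty = float(rng.uniform(0.5, 10))
            segments = seg.segment_series(list(range(n)), starts, m, penalty=penalty)
            got = dp_total_cost(segments, values, n_rep, penalty)
            want = brute_force_min_cost(values, n_rep, penalty)
            assert got == pytest.approx(want, abs=1e-8)

    def test_step_boundary_found(self):
        rng = np.random.default_rng(7)
        values = rng.normal(9.0, 0.2, size=(12, 10))
        values[6:, :] += 3.0  # step after probe 6 (index 5)
        m = build_matrix(values)
        starts = list(range(1, 14 * 12, 14))
        segments = seg.segment_series(list(range(12)), starts, m, penalty=5.0)
        assert [sorted(s) for s in segments] == [list(range(6)), list(range(6, 12))]

    def test_constant_series_single_segment(self):
        rng = np.random.default_rng(8)
        values = rng.normal(7.5, 0.2, size=(30, 10))
        m = build_matrix(values)
        starts = list(range(1, 14 * 30, 14))
        segments = seg.segment_series(list(range(30)), starts, m, penalty=6.0)
        assert len(segments) == 1

    def test_single_probe_run(self):
        values = np.full((1, 10), 9.0)
        m = build_matrix(values)
        segments = seg.segment_series([0], [100], m, penalty=6.0)
        assert segments == [[0]]

    def test_max_gap_splits_runs(self):
        values = np.full((4, 4), 9.0)
        m = build_matrix(values)
        starts = [1, 15, 200, 214]  # 185 nt jump: untiled sequence
        segments = seg.segment_series([0, 1, 2, 3], starts, m, penalty=6.0, max_gap=60)
        assert sorted(map(sorted, segments)) == [[0, 1], [2, 3]]

    def test_segment_count_non_increasing_in_penalty(self):
        rng = np.random.default_rng(9)
        values = rng.normal(9, 1, size=(40, 10))
        values[10:20] += 2.5
        values[30:] -= 2.0
        m = build_matrix(values)
        starts = list(range(1, 14 * 40, 14))
        counts = [
            len(seg.segment_series(list(range(40)), starts, m, penalty=lam))
            for lam in (0.5, 1, 2, 4, 8, 16, 32)
        ]
        assert counts == sorted(counts, reverse=True)


class TestScoreRegion:
    def _layout(self, n, strand="+"):
        return [Probe(f"p{i}", 1 + 14 * i, 25 + 14 * i, strand) for i in range(n)]

    def test_identical_conditions_null(self):
        values = np.tile(np.linspace(9, 10, 4)[:, None], (1, 10))
        m = build_matrix(values)
        r = seg.score_region([0, 1, 2, 3], self._layout(4), m, "r1")
        assert r.p_score == 0.0 and r.log2_fold_change == 0.0

    def test_floor_rule_presence_flags(self):
        values = np.full((3, 10), 8.0)
        m = build_matrix(values)
        r = seg.score_region([0, 1, 2], self._layout(3), m, "r1", floor=9.0)
        assert not r.present_reference and not r.present_treated

    def test_fold_change_definition(self):
        values = np.empty((3, 10))
        values[:, :5] = 10.0
        values[:, 5:] = 12.5
        m = build_matrix(values)
        r = seg.score_region([0, 1, 2], self._layout(3), m, "r1")
        assert r.log2_fold_change == pytest.approx(2.5)
        assert (r.start, r.end) == (1, 53)  # first probe start .. last probe end


class TestCallRegions:
    def _region(self, length, p, fc, present=(True, True)):
        from tilescope.types import Region

        return Region(
            "r", "+", 1000, 1000 + length - 1, 10, 10 + fc, p, fc, *present, 5
        )

    def test_short_differential_dropped(self):
        diff, sim = seg.call_regions([self._region(24, 0.99, 2.0)])
        assert diff == [] and sim == []

    def test_minimum_differential_length_kept(self):
        diff, _ = seg.call_regions([self._region(25, 0.99, 2.0)])
        assert len(diff) == 1 and diff[0].call == "differential"

    def test_long_non_significant_is_similar(self):
        diff, sim = seg.call_regions([self._region(40, 0.5, 0.1)])
        assert diff == [] and len(sim) == 1
        assert sim[0].call == "similar_expressed"

    def test_expressed_length_must_exceed_35(self):
        _, sim = seg.call_regions([self._region(35, 0.5, 0.1)])
        assert sim == []

    def test_unexpressed_regions_excluded(self):
        _, sim = seg.call_regions([self._region(100, 0.99, 2.0, (False, False))])
        assert sim == []

    def test_negative_fold_change_is_differential(self):
        diff, _ = seg.call_regions([self._region(40, 0.99, -2.0)])
        assert len(diff) == 1


class TestExpressedNucleotides:
    def _region(self, start, end, strand="+", present=(True, True)):
        from tilescope.types import Region

        return Region("r", strand, start, end, 10, 10, 0.5, 0, *present, 3)

    def test_overlapping_union(self):
        regions = [self._region(1, 10), self._region(5, 14)]
        assert seg.count_expressed_nucleotides(regions, "reference") == 14

    def test_disjoint_sum(self):
        regions = [self._region(1, 10), self._region(21, 30)]
        assert seg.count_expressed_nucleotides(regions, "reference") == 20

    def test_absent_condition_excluded(self):
        regions = [self._region(1, 10, present=(True, False))]
        assert seg.count_expressed_nucleotides(regions, "treated") == 0

    def test_matches_boolean_array_oracle(self):
        rng = np.random.default_rng(77)
        genome = 100_000
        for _ in range(10):
            regions = []
            arrays = {"+": np.zeros(genome + 1, bool), "-": np.zeros(genome + 1, bool)}
            for _ in range(60):
                start = int(rng.integers(1, genome - 500))
                end = start + int(rng.integers(0, 500))
                strand = "+" if rng.random() < 0.5 else "-"
                present = rng.random() < 0.7
                regions.append(
                    self._region(start, end, strand, (present, present))
                )
                if present:
                    arrays[strand][start : end + 1] = True
            want = int(arrays["+"].sum() + arrays["-"].sum())
            assert seg.count_expressed_nucleotides(regions, "reference") == want
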