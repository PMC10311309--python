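"""Minimizer extraction, minimizer pairing, support counting and the
weighted-interval-scheduling NOMP selection."""

import itertools

import numpy as np
import pytest

from isoformgraph.seeding import (
    NompInterval,
    compute_minimizer_pairs,
    compute_minimizers,
    count_support,
    solve_wis,
)

from conftest import random_sequence


def brute_force_minimizers(seq: str, k: int, w: int) -> list[tuple[str, int]]:
    """Independent oracle: scan every window start, take the smallest fully
    contained k-mer (leftmost tie-break), deduplicate."""
    out = []
    for p in range(len(seq) - w + 1):
        best = None
        for i in range(p, p + w - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            if best is None or kmer < best[0]:
                best = (kmer, i)
        if best is not None and best not in out:
            out.append(best)
    return sorted(out, key=lambda m: m[1])


class TestComputeMinimizers:
    def test_worked_example(self):
        ms = compute_minimizers("ACGGATCAC", k=2, w=4)
        assert [m.astuple() for m in ms] == [
            ("AC", 0),
            ("CG", 1),
            ("AT", 4),
            ("AC", 7),
        ]

    def test_homopolymer_single_minimizer(self):
        assert [m.astuple() for m in compute_minimizers("AAAA", 2, 4)] == [("AA", 0)]

    def test_read_shorter_than_window_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert compute_minimizers("ACG", k=2, w=4) == []

    def test_kmers_containing_n_are_ineligible(self):
        ms = compute_minimizers("ANNNACGT", k=2, w=4)
        assert all("N" not in m.kmer for m in ms)

    def test_matches_brute_force_on_random_reads(self, rng):
        for _ in range(1000):
            k = int(rng.integers(2, 16))
            w = int(rng.integers(k, 31))
            length = int(rng.integers(max(20, w), 501))
            seq = random_sequence(rng, length)
            got = [m.astuple() for m in compute_minimizers(seq, k, w)]
            assert got == brute_force_minimizers(seq, k, w)

    def test_positions_point_at_kmer(self, rng):
        seq = random_sequence(rng, 200)
        for m in compute_minimizers(seq, 5, 12):
            assert seq[m.position : m.position + 5] == m.kmer


class TestComputeMinimizerPairs:
    def test_worked_example(self):
        ms = compute_minimizers("ACGGATCAC", k=2, w=4)
        pairs = compute_minimizer_pairs(ms, x_min=2, x_max=4)
        assert [(p.kmer_pair, p.start) for p in pairs] == [
            (("AC", "AT"), 0),
            (("CG", "AT"), 1),
            (("AT", "AC"), 4),
        ]
        # interval extent: [p_i, p_j + k - 1] inclusive
        assert [(p.start, p.end) for p in pairs] == [(0, 5), (1, 5), (4, 8)]

    def test_single_minimizer_yields_nothing(self):
        ms = compute_minimizers("AAAA", 2, 4)
        assert compute_minimizer_pairs(ms, 1, 10) == []

    def test_matches_all_pairs_filter_oracle(self, rng):
        for _ in range(50):
            seq = random_sequence(rng, int(rng.integers(40, 200)))
            ms = compute_minimizers(seq, 3, 8)
            x_min, x_max = 3, 6
            got = {(p.kmer_pair, p.start, p.end) for p in
                   compute_minimizer_pairs(ms, x_min, x_max)}
            expected = {
                ((a.kmer, b.kmer), a.position, b.position + 2)
                for a, b in itertools.permutations(ms, 2)
                if x_min <= b.position - a.position <= x_max
            }
            assert got == expected

    def test_pair_count_monotone_in_x_max(self, rng):
        seq = random_sequence(rng, 300)
        ms = compute_minimizers(seq, 4, 9)
        counts = [len(compute_minimizer_pairs(ms, 5, x)) for x in range(5, 60, 5)]
        assert counts == sorted(counts)


class TestCountSupport:
    def _intervals(self, pairs):
        return [NompInterval(kmer_pair=p, start=s, end=e) for p, s, e in pairs]

    def test_three_reads_sharing_a_pair(self):
        batch = {
            f"r{i}": self._intervals([(("AC", "AT"), 0, 5)]) for i in range(3)
        }
        support = count_support(batch)
        assert support[("AC", "AT")] == 3

    def test_per_read_counting_caps_at_one(self):
        batch = {
            "r1": self._intervals([(("AC", "AT"), 0, 5), (("AC", "AT"), 20, 25)]),
            "r2": self._intervals([(("AC", "AT"), 3, 8)]),
        }
        assert count_support(batch)[("AC", "AT")] == 2

    def test_weight_is_span_times_support(self):
        batch = {
            "r1": self._intervals([(("AC", "AT"), 0, 5)]),
            "r2": self._intervals([(("AC", "AT"), 10, 15)]),
        }
        count_support(batch)
        for ivs in batch.values():
            for iv in ivs:
                assert iv.weight == iv.span * 2

    def test_matches_recount_oracle_on_random_batch(self, rng):
        batch = {}
        for i in range(5):
            seq = random_sequence(rng, 150)
            ms = compute_minimizers(seq, 3, 6)
            batch[f"r{i}"] = compute_minimizer_pairs(ms, 2, 10)
        support = count_support(batch)
        for pair, count in support.items():
            recount = sum(
                1 for ivs in batch.values() if any(iv.kmer_pair == pair for iv in ivs)
            )
            assert count == recount


def exhaustive_wis_optimum(intervals) -> float:
    """Independent oracle: enumerate all conflict-free subsets recursively."""

    def go(i, chosen):
        if i == len(intervals):
            return sum(iv.weight for iv in chosen)
        best = go(i + 1, chosen)
        if all(not intervals[i].overlaps(c) for c in chosen):
            best = max(best, go(i + 1, chosen + [intervals[i]]))
        return best

    return go(0, [])


def random_wis_instance(rng, max_n=15):
    n = int(rng.integers(0, max_n + 1))
    out = []
    for _ in range(n):
        start = int(rng.integers(0, 60))
        end = start + int(rng.integers(1, 20))
        iv = NompInterval(kmer_pair=("AA", "TT"), start=start, end=end)
        iv.weight = float(rng.integers(1, 10))
        out.append(iv)
    return out


class TestSolveWis:
    def test_three_interval_example(self):
        ivs = []
        for s, e, wgt in [(0, 5, 4), (3, 8, 5), (6, 10, 3)]:
            iv = NompInterval(kmer_pair=("A", "B"), start=s, end=e)
            iv.weight = wgt
            ivs.append(iv)
        chosen = solve_wis(ivs)
        assert [(iv.start, iv.end) for iv in chosen] == [(0, 5), (6, 10)]
        assert sum(iv.weight for iv in chosen) == 7

    def test_non_overlapping_input_kept_entirely(self, rng):
        ivs = []
        for i in range(6):
            iv = NompInterval(kmer_pair=("A", "B"), start=10 * i, end=10 * i + 5)
            iv.weight = 1 + i
            ivs.append(iv)
        assert len(solve_wis(ivs)) == 6

    def test_identical_intervals_pick_heavier(self):
        a = NompInterval(kmer_pair=("A", "B"), start=0, end=5)
        a.weight = 2
        b = NompInterval(kmer_pair=("A", "B"), start=0, end=5)
        b.weight = 5
        chosen = solve_wis([a, b])
        assert len(chosen) == 1 and chosen[0].weight == 5

    def test_empty_input(self):
        assert solve_wis([]) == []

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(100):
            ivs = random_wis_instance(rng, max_n=12)
            chosen = solve_wis(ivs)
            # solution is feasible and drawn from the input
            for a, b in itertools.combinations(chosen, 2):
                assert not a.overlaps(b)
            assert all(any(c is iv for iv in ivs) for c in chosen)
            assert sum(iv.weight for iv in chosen) == pytest.approx(
                exhaustive_wis_optimum(ivs)
            )
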