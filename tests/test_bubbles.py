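"""Bubble detection, verification, consensus-based poppability and
iterative popping."""

import numpy as np

from isoformgraph.bubbles import (
    PopParams,
    find_candidate_bubbles,
    is_poppable,
    linearize_bubble,
    path_consensus,
    pop_iteratively,
    verify_bubble,
)
from isoformgraph.graph import SINK, build_graph
from isoformgraph.isoforms import extract_isoforms
from isoformgraph.seeding import NompInterval, Read, SeedingParams, seed_batch
from isoformgraph.simeval import simulate_reads

from conftest import make_read, random_sequence


def nomp(pair, start, end):
    return NompInterval(kmer_pair=pair, start=start, end=end)


def chain(pairs, start=0, span=20, gap=5):
    out, pos = [], start
    for p in pairs:
        out.append(nomp(p, pos, pos + span - 1))
        pos += span + gap
    return out


def two_path_bubble_graph(mid1=("B", "B'"), mid2=("D", "D'"), n1=1, n2=1):
    """Reads sharing first/last NOMPs but different middles."""
    per_read = {}
    for i in range(n1):
        per_read[f"p{i}"] = chain([("S", "S'"), mid1, ("T", "T'")])
    for i in range(n2):
        per_read[f"q{i}"] = chain([("S", "S'"), mid2, ("T", "T'")])
    return build_graph(per_read, delta=3)


class TestFindCandidateBubbles:
    def test_linear_graph_has_no_candidates(self):
        g = build_graph({"r": chain([("A", "a"), ("B", "b"), ("C", "c")])}, delta=3)
        assert find_candidate_bubbles(g) == []

    def test_single_internal_divergence_yields_one_candidate(self):
        g = two_path_bubble_graph()
        cands = find_candidate_bubbles(g)
        assert len(cands) == 1
        s, t = cands[0]
        assert g.g.out_degree(s) == 2 and g.g.in_degree(t) == 2

    def test_divergent_tails_bubble_at_sink(self):
        # two reads share their first NOMP then diverge and never rejoin:
        # the only bubble closes at the global sink
        g = build_graph(
            {
                "r1": chain([("S", "S'"), ("B", "b")]),
                "r2": chain([("S", "S'"), ("D", "d")]),
            },
            delta=3,
        )
        cands = find_candidate_bubbles(g)
        assert len(cands) == 1
        (s, t), = cands
        assert g.kmer_pair(s) == ("S", "S'") and t == SINK


class TestVerifyBubble:
    def test_disjoint_internal_paths_verify(self):
        g = two_path_bubble_graph()
        (s, t), = find_candidate_bubbles(g)
        b = verify_bubble(g, s, t)
        assert b is not None
        assert len(b.paths) == 2
        assert set(b.paths[0]).isdisjoint(b.paths[1])

    def test_partially_shared_paths_are_ignored(self):
        # r1: S A B C T ; r2: S A D C T -> internal paths share A and C
        g = build_graph(
            {
                "r1": chain([("S", "s"), ("A", "a"), ("B", "b"), ("C", "c"), ("T", "t")]),
                "r2": chain([("S", "s"), ("A", "a"), ("D", "d"), ("C", "c"), ("T", "t")]),
            },
            delta=3,
        )
        vS = [v for v in g.internal_vertices() if g.kmer_pair(v) == ("S", "s")][0]
        vT = [v for v in g.internal_vertices() if g.kmer_pair(v) == ("T", "t")][0]
        assert verify_bubble(g, vS, vT) is None

    def test_three_mutually_disjoint_paths(self):
        per_read = {
            "r1": chain([("S", "s"), ("B", "b"), ("T", "t")]),
            "r2": chain([("S", "s"), ("D", "d"), ("T", "t")]),
            "r3": chain([("S", "s"), ("E", "e"), ("T", "t")]),
        }
        g = build_graph(per_read, delta=3)
        (s, t), = find_candidate_bubbles(g)
        b = verify_bubble(g, s, t)
        assert b is not None and len(b.paths) == 3


class TestPathConsensus:
    def test_single_read_identity(self):
        assert path_consensus(["ACGT"]) == "ACGT"

    def test_identical_subsequences(self):
        assert path_consensus(["ACGTAC"] * 3) == "ACGTAC"

    def test_majority_vote_property(self, rng):
        import edlib

        truth = random_sequence(rng, 100)
        copies = []
        for _ in range(5):
            c = list(truth)
            for pos in rng.choice(100, size=2, replace=False):
                c[pos] = rng.choice([b for b in "ACGT" if b != truth[pos]])
            copies.append("".join(c))
        cons = path_consensus(copies)
        d = edlib.align(cons, truth)["editDistance"]
        assert all(d <= edlib.align(c, truth)["editDistance"] for c in copies)


class TestIsPoppable:
    def test_identical_sequences(self, rng):
        s = random_sequence(rng, 150)
        assert is_poppable(s, s, delta=3, alpha=0.9)

    def test_long_insertion_keeps_exon(self, rng):
        s = random_sequence(rng, 200)
        with_exon = s[:100] + random_sequence(rng, 50) + s[100:]
        assert not is_poppable(s, with_exon, delta=3, alpha=0.9)

    def test_single_substitution_in_200nt(self, rng):
        s = random_sequence(rng, 200)
        t = s[:80] + ("A" if s[80] != "A" else "C") + s[81:]
        # identity 199/200 = 0.995 > alpha, run length 1 <= delta
        assert is_poppable(s, t, delta=3, alpha=0.9)

    def test_empty_consensus_pops_only_within_delta(self):
        assert is_poppable("", "AC", delta=3, alpha=0.9)
        assert not is_poppable("", "ACGTACGT", delta=3, alpha=0.9)


class TestLinearizeBubble:
    def _graph_with_distances(self):
        # two single-vertex paths; B sits 10 nt after S on its read,
        # D sits 30 nt after S on its read
        per_read = {
            "r1": [nomp(("S", "s"), 0, 19), nomp(("B", "b"), 30, 49), nomp(("T", "t"), 60, 79)],
            "r2": [nomp(("S", "s"), 0, 19), nomp(("D", "d"), 50, 69), nomp(("T", "t"), 80, 99)],
        }
        return build_graph(per_read, delta=3)

    def test_chain_ordered_by_mean_read_distance(self):
        g = self._graph_with_distances()
        (s, t), = find_candidate_bubbles(g)
        b = verify_bubble(g, s, t)
        reads = {
            "r1": make_read("r1", "A" * 100),
            "r2": make_read("r2", "A" * 100),
        }
        assert linearize_bubble(g, b, reads)
        # both reads now spell the same chain; B (distance 10) precedes D (30)
        p1, p2 = g.read_paths["r1"], g.read_paths["r2"]
        assert p1 == p2
        internal_pairs = [g.kmer_pair(v) for v in p1[2:-2]]
        assert internal_pairs == [("B", "b"), ("D", "d")]
        g.validate()

    def test_edge_count_does_not_increase(self):
        g = self._graph_with_distances()
        before = g.g.number_of_edges()
        (s, t), = find_candidate_bubbles(g)
        b = verify_bubble(g, s, t)
        reads = {r: make_read(r, "A" * 100) for r in ("r1", "r2")}
        assert linearize_bubble(g, b, reads)
        assert g.g.number_of_edges() <= before

    def test_pop_preserves_read_path_validity(self, rng):
        g = self._graph_with_distances()
        (s, t), = find_candidate_bubbles(g)
        b = verify_bubble(g, s, t)
        reads = {r: make_read(r, "A" * 100) for r in ("r1", "r2")}
        assert linearize_bubble(g, b, reads)
        g.validate()
        assert g.is_dag()


def _two_isoform_batch(error_rate, seed, abundance=8):
    rng = np.random.default_rng(3)
    shared_l = "".join(rng.choice(list("ACGT"), size=200))
    exon = "".join(rng.choice(list("ACGT"), size=50))
    shared_r = "".join(rng.choice(list("ACGT"), size=200))
    iso_a = shared_l + shared_r
    iso_b = shared_l + exon + shared_r
    reads, truth_of = simulate_reads(
        [("A", iso_a), ("B", iso_b)],
        [abundance, abundance],
        error_rate,
        np.random.default_rng(seed),
    )
    return reads, truth_of


class TestPopIteratively:
    def test_linear_graph_unchanged(self):
        g = build_graph({"r": chain([("A", "a"), ("B", "b")])}, delta=3)
        edges_before = sorted(g.g.edges)
        pop_iteratively(g, {"r": make_read("r", "A" * 60)}, PopParams())
        assert sorted(g.g.edges) == edges_before

    def test_exon_difference_survives_at_zero_error(self):
        reads, _ = _two_isoform_batch(error_rate=0.0, seed=5)
        by_id = {r.read_id: r for r in reads}
        nomps = seed_batch(reads, SeedingParams())
        g = build_graph({r: n for r, n in nomps.items() if n}, delta=3)
        pop_iteratively(g, by_id, PopParams())
        groups = extract_isoforms(g)
        assert len(groups) == 2
        # groups split cleanly by isoform
        for read_ids, _path in groups:
            assert len({rid.split("_")[0] for rid in read_ids}) == 1

    def test_edge_count_non_increasing_and_dag_preserved(self):
        reads, _ = _two_isoform_batch(error_rate=0.01, seed=5)
        by_id = {r.read_id: r for r in reads}
        nomps = seed_batch(reads, SeedingParams())
        g = build_graph({r: n for r, n in nomps.items() if n}, delta=3)
        before = g.g.number_of_edges()
        paths_before = len({tuple(p) for p in g.read_paths.values()})
        pop_iteratively(g, by_id, PopParams())
        assert g.g.number_of_edges() <= before
        assert g.is_dag()
        g.validate()
        paths_after = len({tuple(p) for p in g.read_paths.values()})
        assert paths_after <= paths_before
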