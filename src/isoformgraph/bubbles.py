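"""Iterative bubble popping on the NOMP graph.

Sequencing errors and SNPs between reads create *bubbles*: two (or more)
internally node-disjoint paths between a shared source s' and sink t'.
A bubble is popped — its paths merged into a single chain — when the
consensus sequences of its paths are near-identical: no contiguous
mismatch/indel stretch longer than ``delta`` and identity above ``alpha``.
Exon-level differences produce indel runs far longer than ``delta`` and
survive; error-level differences are erased.  Popping repeats until fewer
than ``n_stop`` previously unseen bubbles are detected in an iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .align import semiglobal_align
from .consensus import consensus
from .graph import SINK, SOURCE, NompGraph
from .seeding import Read

logger = logging.getLogger(__name__)

__all__ = [
    "Bubble",
    "PopParams",
    "find_candidate_bubbles",
    "verify_bubble",
    "path_consensus",
    "is_poppable",
    "linearize_bubble",
    "pop_iteratively",
]


@dataclass(frozen=True)
class PopParams:
    delta: int = 3
    alpha: float = 0.9
    n_stop: int = 1
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.n_stop < 1:
            raise ValueError("n_stop must be >= 1")


@dataclass
class Bubble:
    """A read-supported bubble: >=2 internally disjoint s'->t' paths."""

    source: str
    sink: str
    paths: list[tuple[str, ...]]
    path_reads: list[set[str]]

    @property
    def size(self) -> int:
        """Distinct internal vertices over all paths (sorting key)."""
        return len({v for p in self.paths for v in p})

    @property
    def region(self) -> set[str]:
        return {self.source, self.sink, *(v for p in self.paths for v in p)}

    def key(self) -> tuple:
        return (
            self.source,
            self.sink,
            frozenset(frozenset(p) for p in self.paths),
        )


# --------------------------------------------------------------------- #
# detection


def _vertex_index(graph: NompGraph) -> dict[str, dict[str, int]]:
    """vertex -> {read_id -> position of the vertex on that read's path}."""
    idx: dict[str, dict[str, int]] = {}
    for rid, path in graph.read_paths.items():
        for pos, v in enumerate(path):
            idx.setdefault(v, {})[rid] = pos
    return idx


def find_candidate_bubbles(
    graph: NompGraph,
    vindex: Mapping[str, Mapping[str, int]] | None = None,
) -> list[tuple[str, str]]:
    """Candidate (s', t') pairs: s' with out-degree > 1, t' with in-degree
    > 1, s' before t' in topological order, and at least two reads whose
    paths traverse s' before t'.  Ordered by topological rank (the popping
    loop re-sorts verified bubbles by size)."""
    if vindex is None:
        vindex = _vertex_index(graph)
    rank = graph.topo_rank()
    sources = [v for v in graph.g.nodes if graph.g.out_degree(v) > 1]
    sinks = [v for v in graph.g.nodes if graph.g.in_degree(v) > 1]
    out: list[tuple[str, str]] = []
    for s in sources:
        s_reads = vindex.get(s, {})
        for t in sinks:
            if rank[s] >= rank[t]:
                continue
            t_reads = vindex.get(t, {})
            n_through = sum(
                1 for r, ps in s_reads.items() if r in t_reads and ps < t_reads[r]
            )
            if n_through >= 2:
                out.append((s, t))
    out.sort(key=lambda st: (rank[st[0]], rank[st[1]]))
    return out


def verify_bubble(
    graph: NompGraph,
    source: str,
    sink: str,
    vindex: Mapping[str, Mapping[str, int]] | None = None,
) -> Bubble | None:
    """Follow the supporting reads from s' to t'; group them by identical
    internal vertex sequence.  A bubble requires >=2 groups with pairwise
    disjoint internal vertex sets; overlapping (but not identical) paths
    mean a smaller bubble exists between the reads and the candidate is
    ignored."""
    if vindex is None:
        vindex = _vertex_index(graph)
    s_reads = vindex.get(source, {})
    t_reads = vindex.get(sink, {})
    groups: dict[tuple[str, ...], set[str]] = {}
    for rid, ps in s_reads.items():
        pt = t_reads.get(rid)
        if pt is None or ps >= pt:
            continue
        internal = tuple(graph.read_paths[rid][ps + 1 : pt])
        groups.setdefault(internal, set()).add(rid)
    if len(groups) < 2:
        return None
    paths = sorted(groups)
    for i in range(len(paths)):
        for j in range(i + 1, len(paths)):
            if set(paths[i]) & set(paths[j]):
                return None  # overlapping paths: a smaller bubble exists
    # deterministic path order: descending read support, then path id
    paths.sort(key=lambda p: (-len(groups[p]), p))
    return Bubble(
        source=source,
        sink=sink,
        paths=[tuple(p) for p in paths],
        path_reads=[set(groups[p]) for p in paths],
    )


# --------------------------------------------------------------------- #
# read-space extraction


def _left_anchor_end(graph: NompGraph, rid: str, pos: int) -> int:
    """End coordinate on read ``rid`` of its nearest occurrence at or
    before path position ``pos`` (-1 when anchored at the global source)."""
    path = graph.read_paths[rid]
    for i in range(pos, -1, -1):
        v = path[i]
        if v == SOURCE:
            return -1
        occ = graph.occurrences(v).get(rid)
        if occ is not None:
            return occ[1]
    return -1


def _right_anchor_start(graph: NompGraph, rid: str, pos: int, read_len: int) -> int:
    path = graph.read_paths[rid]
    for i in range(pos, len(path)):
        v = path[i]
        if v == SINK:
            return read_len
        occ = graph.occurrences(v).get(rid)
        if occ is not None:
            return occ[0]
    return read_len


def _bubble_subsequence(
    graph: NompGraph, reads: Mapping[str, Read], rid: str, source: str, sink: str
) -> str:
    """The read's sequence strictly between its s' and t' anchors."""
    path_pos = {v: i for i, v in enumerate(graph.read_paths[rid])}
    lo = _left_anchor_end(graph, rid, path_pos[source])
    hi = _right_anchor_start(graph, rid, path_pos[sink], len(reads[rid]))
    if hi <= lo:
        return ""
    return reads[rid].sequence[lo + 1 : hi]


def path_consensus(subsequences: Sequence[str]) -> str:
    """Consensus of the read subsequences supporting one bubble path."""
    return consensus(list(subsequences))


# --------------------------------------------------------------------- #
# poppability


def is_poppable(cons_a: str, cons_b: str, delta: int, alpha: float) -> bool:
    """Two path consensuses merge when their semiglobal alignment has no
    mismatch/indel run longer than ``delta`` and identity above ``alpha``.
    Terminal gaps count: between fixed anchors a length difference is a
    real indel."""
    if not cons_a or not cons_b:
        return max(len(cons_a), len(cons_b)) <= delta
    view = semiglobal_align(cons_a, cons_b)
    if view.longest_difference_run(internal_only=False) > delta:
        return False
    return view.identity() > alpha


# --------------------------------------------------------------------- #
# linearization


def linearize_bubble(
    graph: NompGraph,
    bubble: Bubble,
    reads: Mapping[str, Read] | None = None,
) -> bool:
    """Merge the bubble's paths into a single s'->...->t' chain.

    Internal vertices are ordered by their mean read-space distance from
    s' (ties by vertex id); the bubble-path edges are replaced by chain
    edges and every affected read path is rewritten onto the chain.  If
    the new chain would close a cycle through vertices outside the bubble
    the mutation is rolled back and False is returned.
    """
    src, snk = bubble.source, bubble.sink
    internals = sorted({v for p in bubble.paths for v in p})
    support = set().union(*bubble.path_reads)

    # mean distance (in read coordinates) from the end of s' to each vertex
    dist: dict[str, float] = {}
    for v in internals:
        samples: list[int] = []
        occ = graph.occurrences(v)
        for rid, (start, _end) in occ.items():
            path = graph.read_paths.get(rid)
            if path is None or src not in path:
                continue
            pos_s = path.index(src)
            if v not in path[pos_s + 1 :]:
                continue
            samples.append(start - _left_anchor_end(graph, rid, pos_s))
        if samples:
            dist[v] = sum(samples) / len(samples)
        else:  # no usable occurrence: fall back to topological rank
            dist[v] = float(graph.topo_rank()[v])
    chain = [src] + sorted(internals, key=lambda v: (dist[v], v)) + [snk]

    # snapshot for rollback
    saved_g = graph.g.copy()
    saved_paths = {r: list(p) for r, p in graph.read_paths.items()}

    # drop the bubble-path edges, then lay down the chain
    removed: set[tuple[str, str]] = set()
    for p in bubble.paths:
        full = [src, *p, snk]
        removed.update(zip(full, full[1:]))
    for u, v in removed:
        if graph.g.has_edge(u, v):
            graph.g.remove_edge(u, v)
    def _occ(v: str, rid: str) -> tuple[int, int] | None:
        if v in (SOURCE, SINK):
            return None
        return graph.occurrences(v).get(rid)

    for u, v in zip(chain, chain[1:]):
        gaps: dict[str, int] = {}
        for rid in support:
            ou, ov = _occ(u, rid), _occ(v, rid)
            if ou is not None and ov is not None:
                gaps[rid] = ov[0] - (ou[1] + 1)
        if not graph.g.has_edge(u, v):
            graph.g.add_edge(u, v, gaps=gaps)
        else:
            graph.g.edges[u, v]["gaps"].update(gaps)
    graph._invalidate()

    # rewrite affected read paths: replace each maximal run of bubble-region
    # vertices with the corresponding chain slice
    region = bubble.region
    chain_idx = {v: i for i, v in enumerate(chain)}
    for rid, path in list(graph.read_paths.items()):
        if not any(v in region for v in path):
            continue
        new_path: list[str] = []
        i = 0
        while i < len(path):
            if path[i] in region:
                j = i
                while j + 1 < len(path) and path[j + 1] in region:
                    j += 1
                a, b = chain_idx[path[i]], chain_idx[path[j]]
                if a > b:  # read order contradicts chain order: bail out
                    graph.g = saved_g
                    graph.read_paths = saved_paths
                    graph._invalidate()
                    return False
                new_path.extend(chain[a : b + 1])
                i = j + 1
            else:
                new_path.append(path[i])
                i += 1
        graph.read_paths[rid] = new_path

    if not graph.is_dag():
        graph.g = saved_g
        graph.read_paths = saved_paths
        graph._invalidate()
        return False
    return True


# --------------------------------------------------------------------- #
# iteration


def pop_iteratively(
    graph: NompGraph,
    reads: Mapping[str, Read],
    params: PopParams,
) -> NompGraph:
    """Repeat detect -> verify -> consensus-test -> linearize until fewer
    than ``n_stop`` previously unseen bubbles appear in an iteration.

    Unpoppable bubbles are remembered (keyed by endpoints and frozen path
    vertex sets) and skipped until a later pop touches one of their
    endpoint vertices.  Bubbles overlapping a bubble already modified in
    the current iteration are deferred to the next iteration.
    """
    unpoppable: set[tuple] = set()
    seen: set[tuple] = set()
    for iteration in range(params.max_iterations):
        vindex = _vertex_index(graph)
        candidates = find_candidate_bubbles(graph, vindex)
        bubbles = []
        for s, t in candidates:
            b = verify_bubble(graph, s, t, vindex)
            if b is not None:
                bubbles.append(b)
        bubbles.sort(key=lambda b: (b.size, b.source, b.sink))
        n_new = sum(1 for b in bubbles if b.key() not in seen)
        seen.update(b.key() for b in bubbles)
        logger.info(
            "popping iteration %d: %d candidates, %d bubbles (%d new)",
            iteration,
            len(candidates),
            len(bubbles),
            n_new,
        )

        modified: set[str] = set()
        n_popped = 0
        for bubble in bubbles:
            if bubble.key() in unpoppable:
                continue
            if bubble.region & modified:
                continue  # deferred to the next iteration
            if _try_pop(graph, bubble, reads, params):
                n_popped += 1
                modified |= bubble.region
                unpoppable = {
                    k for k in unpoppable if k[0] not in modified and k[1] not in modified
                }
            else:
                unpoppable.add(bubble.key())
        logger.info("popping iteration %d: popped %d bubbles", iteration, n_popped)
        if n_new < params.n_stop:
            return graph
    raise RuntimeError(
        f"bubble popping did not converge within {params.max_iterations} iterations"
    )


def _try_pop(
    graph: NompGraph,
    bubble: Bubble,
    reads: Mapping[str, Read],
    params: PopParams,
) -> bool:
    """Consensus-test the bubble's paths pairwise (descending read support)
    and linearize the subset of paths that merge.  Returns True on a pop."""
    subseqs = [
        [
            _bubble_subsequence(graph, reads, rid, bubble.source, bubble.sink)
            for rid in sorted(reads_of_path)
        ]
        for reads_of_path in bubble.path_reads
    ]
    merged_idx = [0]
    merged_seqs = list(subseqs[0])
    cons = path_consensus(merged_seqs)
    for i in range(1, len(bubble.paths)):
        cons_i = path_consensus(subseqs[i])
        if is_poppable(cons, cons_i, params.delta, params.alpha):
            merged_idx.append(i)
            merged_seqs.extend(subseqs[i])
            cons = path_consensus(merged_seqs)
    if len(merged_idx) < 2:
        return False
    sub = Bubble(
        source=bubble.source,
        sink=bubble.sink,
        paths=[bubble.paths[i] for i in merged_idx],
        path_reads=[bubble.path_reads[i] for i in merged_idx],
    )
    return linearize_bubble(graph, sub, reads)
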