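"""Directed acyclic graph over the NOMPs of a read batch.

Vertices house NOMP occurrences (a NOMP shared between reads is one
vertex); edges connect NOMPs that are neighbours on some read, and carry
the per-read gap (nucleotides between the two NOMPs).  A global source
``s`` and sink ``t`` bracket every read, so each read spells an s->t path.

Three rules keep the graph acyclic and fuzz-tolerant when an occurrence is
attached to an existing vertex, applied in this order:

1. *acyclicity* — if merging would close a cycle, a fresh vertex is made;
2. *span* — occurrences whose spans differ by more than ``delta`` from all
   of a candidate vertex's occurrences go to a fresh vertex (several
   candidates: the closest span wins);
3. *gap* — if the incoming edge's gap differs by more than ``delta`` from
   the gap already recorded between the same vertex pair, the successor is
   split into a fresh vertex.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .seeding import NompInterval

logger = logging.getLogger(__name__)

SOURCE = "__s__"
SINK = "__t__"

__all__ = ["GraphParams", "NompGraph", "build_graph", "SOURCE", "SINK"]


@dataclass(frozen=True)
class GraphParams:
    """``delta``: maximum tolerated nucleotide discrepancy (span and gap)."""

    delta: int = 3

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


class NompGraph:
    """DAG of NOMP vertices with global source/sink and per-read paths.

    Thin wrapper around a :class:`networkx.DiGraph`; vertex attributes hold
    the k-mer pair and the occurrence map ``read_id -> (start, end)``, edge
    attributes hold ``gaps: read_id -> gap length``.
    """

    def __init__(self, delta: int = 3) -> None:
        self.delta = delta
        self.g = nx.DiGraph()
        self.g.add_node(SOURCE)
        self.g.add_node(SINK)
        self.read_paths: dict[str, list[str]] = {}
        # vertices per kmer_pair, in creation order (merge candidates)
        self._by_pair: dict[tuple[str, str], list[str]] = {}
        self._counter = itertools.count()
        self._topo: list[str] | None = None

    # ------------------------------------------------------------------ #
    # basic accessors

    @property
    def source(self) -> str:
        return SOURCE

    @property
    def sink(self) -> str:
        return SINK

    def internal_vertices(self) -> list[str]:
        return [v for v in self.g.nodes if v not in (SOURCE, SINK)]

    def occurrences(self, v: str) -> dict[str, tuple[int, int]]:
        return self.g.nodes[v]["occ"]

    def kmer_pair(self, v: str) -> tuple[str, str]:
        return self.g.nodes[v]["kmer_pair"]

    def spans(self, v: str) -> list[int]:
        return [e - s + 1 for s, e in self.g.nodes[v]["occ"].values()]

    def topological_order(self) -> list[str]:
        """Topological order with SOURCE first and SINK last.

        Cached between mutations; a cycle raises ``RuntimeError`` (invariant
        breach — construction is supposed to keep the graph acyclic).
        """
        if self._topo is None:
            try:
                order = list(nx.lexicographical_topological_sort(
                    self.g, key=lambda v: (v == SINK, str(v))
                ))
            except nx.NetworkXUnfeasible as exc:
                raise RuntimeError("NOMP graph contains a cycle") from exc
            # force s first, t last (lexicographic sort already keys SINK last)
            order.remove(SOURCE)
            order.insert(0, SOURCE)
            self._topo = order
        return self._topo

    def topo_rank(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.topological_order())}

    def is_dag(self) -> bool:
        return nx.is_directed_acyclic_graph(self.g)

    def _invalidate(self) -> None:
        self._topo = None

    # ------------------------------------------------------------------ #
    # construction

    def _new_vertex(self, kmer_pair: tuple[str, str]) -> str:
        vid = f"v{next(self._counter)}"
        self.g.add_node(vid, kmer_pair=kmer_pair, occ={})
        self._by_pair.setdefault(kmer_pair, []).append(vid)
        self._invalidate()
        return vid

    def _add_edge_occurrence(self, u: str, v: str, read_id: str, gap: int) -> None:
        if self.g.has_edge(u, v):
            self.g.edges[u, v]["gaps"][read_id] = gap
        else:
            self.g.add_edge(u, v, gaps={read_id: gap})
            self._invalidate()

    def attach_nomp(
        self,
        read_id: str,
        nomp: NompInterval,
        predecessor: str,
        gap: int,
    ) -> str:
        """Attach one NOMP occurrence, merging into an existing vertex when
        the acyclicity/span/gap rules allow, else creating a fresh vertex.

        Returns the vertex now housing the occurrence.
        """
        delta = self.delta
        target: str | None = None
        candidates = self._by_pair.get(nomp.kmer_pair, ())
        # rank candidates by span proximity so the closest-span vertex wins
        ranked = sorted(
            candidates,
            key=lambda v: (
                min(abs(nomp.span - s) for s in self.spans(v)),
                v,
            ),
        )
        for cand in ranked:
            occ = self.g.nodes[cand]["occ"]
            if read_id in occ:
                continue  # repeat within the read: must not collapse
            # rule 1: acyclicity — edge predecessor -> cand must not close a cycle
            if cand == predecessor or (
                self.g.has_node(cand)
                and nx.has_path(self.g, cand, predecessor)
            ):
                continue
            # rule 2: span fuzziness
            if min(abs(nomp.span - s) for s in self.spans(cand)) > delta:
                continue
            # rule 3: gap fuzziness on the shared edge (between neighbouring
            # NOMPs only — the offset from the global source is 5' raggedness,
            # not structure)
            if predecessor != SOURCE and self.g.has_edge(predecessor, cand):
                gaps = self.g.edges[predecessor, cand]["gaps"].values()
                if gaps and min(abs(gap - x) for x in gaps) > delta:
                    continue
            target = cand
            break
        if target is None:
            target = self._new_vertex(nomp.kmer_pair)
        self.g.nodes[target]["occ"][read_id] = (nomp.start, nomp.end)
        self._add_edge_occurrence(predecessor, target, read_id, gap)
        return target

    def add_read(self, read_id: str, nomps: Sequence[NompInterval]) -> None:
        if not nomps:
            logger.warning("read %s has no NOMPs; dropped from graph", read_id)
            return
        path = [SOURCE]
        prev = SOURCE
        prev_end = -1
        for i, nomp in enumerate(nomps):
            gap = nomp.start if i == 0 else nomp.start - (prev_end + 1)
            v = self.attach_nomp(read_id, nomp, prev, gap)
            path.append(v)
            prev, prev_end = v, nomp.end
        self._add_edge_occurrence(prev, SINK, read_id, 0)
        path.append(SINK)
        self.read_paths[read_id] = path

    # ------------------------------------------------------------------ #
    # diagnostics

    def validate(self) -> None:
        """Assert the structural invariants (DAG, replayable read paths)."""
        if not self.is_dag():
            raise RuntimeError("NOMP graph contains a cycle")
        for rid, path in self.read_paths.items():
            if path[0] != SOURCE or path[-1] != SINK:
                raise RuntimeError(f"read {rid}: path does not run s->t")
            for u, v in zip(path, path[1:]):
                if not self.g.has_edge(u, v):
                    raise RuntimeError(f"read {rid}: missing edge {u}->{v}")

    def to_dot(self) -> str:
        """GraphViz DOT export for debugging (vertex = kmer pair + #occ)."""
        lines = ["digraph nomp {"]
        for v in self.g.nodes:
            if v in (SOURCE, SINK):
                label = "s" if v == SOURCE else "t"
            else:
                kp = self.kmer_pair(v)
                label = f"{kp[0]}|{kp[1]} ({len(self.occurrences(v))})"
            lines.append(f'  "{v}" [label="{label}"];')
        for u, v in self.g.edges:
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)


def build_graph(
    per_read_nomps: Mapping[str, Sequence[NompInterval]],
    delta: int = 3,
) -> NompGraph:
    """Build the NOMP graph by inserting reads in mapping order.

    Reads with zero NOMPs are dropped with a warning.  An empty batch
    yields a graph containing only the global source and sink.
    """
    graph = NompGraph(delta=delta)
    for read_id, nomps in per_read_nomps.items():
        graph.add_read(read_id, nomps)
    return graph
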