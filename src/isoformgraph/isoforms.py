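"""Isoform extraction, consensus calling, end-variability merging and the
per-cluster batch pipeline.

After bubble popping, reads sharing an identical source-to-sink path form
one isoform prediction; its sequence is the consensus of the member reads.
Predictions differing only at their 3'/5' ends (common with degraded RNA
and variable transcription start/termination) are merged shortest-into-
longest.  Large clusters are processed in batches of ``batch_size`` reads
and the per-batch predictions merged afterwards with the same end-merging
rule.  Predictions supported by fewer than ``min_support`` reads go to a
secondary (low-abundance) output.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .align import infix_align
from .bubbles import PopParams, pop_iteratively
from .consensus import consensus
from .graph import build_graph
from .seeding import Read, SeedingParams, seed_batch

logger = logging.getLogger(__name__)

CONSENSUS_QUAL = "I"

# smallest exon scale the tool must keep apart; used as the window for the
# local difference-density gate in end-variability merging
EXON_WINDOW = 20

__all__ = [
    "IsoformPrediction",
    "OutputParams",
    "compress_polyA",
    "extract_isoforms",
    "isoform_consensus",
    "merge_end_variability",
    "run_batch_pipeline",
    "PipelineResult",
]


@dataclass
class IsoformPrediction:
    isoform_id: str
    consensus: str
    read_ids: set[str]
    batch_id: int = 0
    cluster_id: str = ""

    @property
    def abundance(self) -> int:
        return len(self.read_ids)


@dataclass(frozen=True)
class OutputParams:
    min_support: int = 5
    batch_size: int = 1000
    polyA_window: int = 100
    polyA_run: int = 12

    def __post_init__(self) -> None:
        for name in ("min_support", "batch_size", "polyA_window", "polyA_run"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def compress_polyA(read: Read, window: int = 100, max_run: int = 12) -> Read:
    """Collapse each run of more than ``max_run`` consecutive A's within the
    last ``window`` nucleotides into a single A (quality compressed in
    lockstep); the rest of the read is untouched."""
    seq = read.sequence
    cut = max(0, len(seq) - window)
    head, tail = seq[:cut], seq[cut:]
    qhead, qtail = read.quality[:cut], read.quality[cut:]
    pattern = re.compile("A{%d,}" % (max_run + 1))
    out_seq: list[str] = []
    out_qual: list[str] = []
    last = 0
    for m in pattern.finditer(tail):
        out_seq.append(tail[last : m.start()] + "A")
        out_qual.append(qtail[last : m.start()] + qtail[m.start()])
        last = m.end()
    out_seq.append(tail[last:])
    out_qual.append(qtail[last:])
    new_seq = head + "".join(out_seq)
    if new_seq == seq:
        return read
    return Read(
        read_id=read.read_id,
        sequence=new_seq,
        quality=qhead + "".join(out_qual),
        cluster_id=read.cluster_id,
    )


def extract_isoforms(graph) -> list[tuple[set[str], tuple[str, ...]]]:
    """Partition reads by identical s->t vertex path.

    Reads sharing a path share all vertices and edges, so deterministic
    grouping by the stored path is equivalent to picking an arbitrary read
    and tracing it through the graph.  Groups are ordered by descending
    size then path for determinism.
    """
    groups: dict[tuple[str, ...], set[str]] = {}
    for rid, path in graph.read_paths.items():
        groups.setdefault(tuple(path), set()).add(rid)
    out = [(reads, path) for path, reads in groups.items()]
    out.sort(key=lambda g: (-len(g[0]), g[1]))
    return out


def isoform_consensus(sequences: Sequence[str]) -> str:
    """Consensus over the full-length member reads of one isoform group."""
    return consensus(list(sequences))


def _mergeable(shorter: str, longer: str, delta: int, alpha: float = 0.9) -> bool:
    """True when the shorter prediction differs from the longer one only
    at the ends.

    End variability means the shorter consensus is a (slightly ragged)
    truncated copy of the longer one, so the test is containment: an
    infix alignment fits the whole shorter sequence inside the longer,
    leaving the longer's 3'/5' overhangs free.  The fit must contain no
    mismatch/indel run longer than ``delta``, no exon-scale window with
    more than ``delta`` differences (unrelated stretches stay dense in
    differences even when coincidental matches keep each run short), and
    identity above ``alpha``.  A containment alignment is used rather than
    a free-end (semiglobal) one because a score-optimal free-end alignment may shift
    the shorter sequence's terminus into an unrelated region, disguising
    an internal exon difference as terminal overhang; under containment
    every base of the shorter sequence is accounted for."""
    view = infix_align(longer, shorter)
    if view.longest_difference_run() > delta:
        return False
    if view.max_differences_in_window(EXON_WINDOW) > delta:
        return False
    return view.identity() > alpha


def merge_end_variability(
    predictions: list[IsoformPrediction],
    reads: Mapping[str, Read],
    delta: int = 3,
    alpha: float = 0.9,
) -> list[IsoformPrediction]:
    """Merge predictions that differ only in 3'/5' end variability.

    Iterates predictions shortest to longest; each is folded into the first
    (shortest) surviving longer prediction with no internal difference
    larger than ``delta``.  Consensus sequences of read sets that changed
    are recomputed at the end.  The operation is idempotent.
    """
    preds = sorted(predictions, key=lambda p: (len(p.consensus), p.isoform_id))
    dropped: set[str] = set()
    changed: set[str] = set()
    for i, shorter in enumerate(preds):
        if shorter.isoform_id in dropped:
            continue
        for longer in preds[i + 1 :]:
            if longer.isoform_id in dropped:
                continue
            if len(longer.consensus) < len(shorter.consensus):
                continue
            if _mergeable(shorter.consensus, longer.consensus, delta, alpha):
                longer.read_ids |= shorter.read_ids
                dropped.add(shorter.isoform_id)
                changed.add(longer.isoform_id)
                break
    merged = [p for p in preds if p.isoform_id not in dropped]
    for p in merged:
        if p.isoform_id in changed:
            p.consensus = isoform_consensus(
                [reads[r].sequence for r in sorted(p.read_ids)]
            )
    merged.sort(key=lambda p: (-p.abundance, p.isoform_id))
    return merged


@dataclass
class PipelineResult:
    predictions: list[IsoformPrediction]
    low_abundance: list[IsoformPrediction]
    dropped_reads: list[str]  # reads without NOMPs, excluded from the graph


def run_batch_pipeline(
    cluster_reads: Sequence[Read],
    seeding_params: SeedingParams | None = None,
    pop_params: PopParams | None = None,
    output_params: OutputParams | None = None,
    cluster_id: str = "",
    debug_graph_dir: str | None = None,
) -> PipelineResult:
    """Full per-cluster pipeline.

    Poly-A compression, batching in file order, per-batch seeding / graph
    construction / bubble popping / extraction / consensus / end-merging,
    then a cross-batch end-merge, and finally the abundance split: final
    predictions need ``min_support`` reads, the rest are reported as
    low-abundance records.  With ``debug_graph_dir`` the popped graph of
    each batch is exported in GraphViz DOT format.
    """
    seeding_params = seeding_params or SeedingParams()
    pop_params = pop_params or PopParams()
    output_params = output_params or OutputParams()

    compressed = [
        compress_polyA(r, output_params.polyA_window, output_params.polyA_run)
        for r in cluster_reads
    ]
    by_id = {r.read_id: r for r in compressed}

    predictions: list[IsoformPrediction] = []
    dropped: list[str] = []
    bs = output_params.batch_size
    batches = [compressed[i : i + bs] for i in range(0, len(compressed), bs)]
    for batch_id, batch in enumerate(batches):
        nomps = seed_batch(batch, seeding_params)
        dropped.extend(rid for rid, n in nomps.items() if not n)
        graph = build_graph(
            {rid: n for rid, n in nomps.items() if n}, delta=pop_params.delta
        )
        pop_iteratively(graph, by_id, pop_params)
        if debug_graph_dir is not None:
            from pathlib import Path

            dot_dir = Path(debug_graph_dir)
            dot_dir.mkdir(parents=True, exist_ok=True)
            name = f"{cluster_id or 'cluster'}_batch{batch_id}.dot"
            (dot_dir / name).write_text(graph.to_dot())
        groups = extract_isoforms(graph)
        batch_preds = []
        for gi, (read_ids, _path) in enumerate(groups):
            cons = isoform_consensus([by_id[r].sequence for r in sorted(read_ids)])
            batch_preds.append(
                IsoformPrediction(
                    isoform_id=f"{cluster_id or 'cluster'}_b{batch_id}_i{gi}",
                    consensus=cons,
                    read_ids=set(read_ids),
                    batch_id=batch_id,
                    cluster_id=cluster_id,
                )
            )
        predictions.extend(
            merge_end_variability(batch_preds, by_id, pop_params.delta, pop_params.alpha)
        )

    if len(batches) > 1:
        predictions = merge_end_variability(
            predictions, by_id, pop_params.delta, pop_params.alpha
        )

    final = [p for p in predictions if p.abundance >= output_params.min_support]
    low = [p for p in predictions if p.abundance < output_params.min_support]
    logger.info(
        "cluster %s: %d predictions (%d low-abundance, %d dropped reads)",
        cluster_id,
        len(final),
        len(low),
        len(dropped),
    )
    return PipelineResult(predictions=final, low_abundance=low, dropped_reads=dropped)
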