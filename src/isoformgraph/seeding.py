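"""Fuzzy seeding of reads with non-overlapping minimizer pairs (NOMPs).

Each read is reduced to an ordered set of *minimizer pairs*: pairs of
positional minimizers separated by ``x_min``–``x_max`` nucleotides.  A pair
spans an interval on the read; intervals are weighted by ``span x support``
(support = number of reads in the batch containing the same k-mer pair) and
a weighted interval scheduling (WIS) problem selects, per read, the
maximum-weight set of pairwise non-overlapping intervals.  The selected
intervals are the read's NOMPs — the vertices of the gene graph.

Minimizer windows are windows of ``w`` consecutive nucleotides; the
minimizer of a window is the lexicographically smallest k-mer *fully
contained* in it (ties broken by leftmost position).  k-mers containing N
are never minimizers.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Read",
    "PositionalMinimizer",
    "NompInterval",
    "SeedingParams",
    "compute_minimizers",
    "compute_minimizer_pairs",
    "count_support",
    "solve_wis",
    "seed_batch",
]


@dataclass(frozen=True)
class Read:
    """A sense-oriented, adapter-trimmed cDNA read."""

    read_id: str
    sequence: str
    quality: str
    cluster_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id!r}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PositionalMinimizer:
    """A minimizer k-mer together with its 0-based start on the read."""

    kmer: str
    position: int

    def astuple(self) -> tuple[str, int]:
        return (self.kmer, self.position)


@dataclass
class NompInterval:
    """A minimizer pair viewed as a weighted interval on one read.

    The interval occupies positions ``[start, end]`` inclusive, where
    ``start`` is the position of the first minimizer and ``end`` the last
    base of the second minimizer (``p_j + k - 1``).
    """

    kmer_pair: tuple[str, str]
    start: int
    end: int
    weight: float = 0.0
    support: int = 0

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "NompInterval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class SeedingParams:
    k: int = 9
    w: int = 10
    x_min: int = 14
    x_max: int = 80

    def __post_init__(self) -> None:
        if not (1 <= self.k <= self.w):
            raise ValueError(f"need 1 <= k <= w, got k={self.k}, w={self.w}")
        if not (0 < self.x_min <= self.x_max):
            raise ValueError(
                f"need 0 < x_min <= x_max, got x_min={self.x_min}, x_max={self.x_max}"
            )


def compute_minimizers(read: Read | str, k: int, w: int) -> list[PositionalMinimizer]:
    """Extract the positional minimizers M(r) of a read.

    For every window of ``w`` consecutive nucleotides, the lexicographically
    smallest k-mer fully contained in the window is a minimizer; ties go to
    the leftmost occurrence.  Consecutive windows picking the identical
    (kmer, position) contribute a single entry.  k-mers containing N are
    ineligible.
    """
    seq = read.sequence if isinstance(read, Read) else read
    n = len(seq)
    if not (1 <= k <= w):
        raise ValueError(f"need 1 <= k <= w, got k={k}, w={w}")
    if n < w:
        warnings.warn(
            f"read of length {n} shorter than window w={w}; no minimizers",
            stacklevel=2,
        )
        return []

    # eligible k-mer starts, pre-filtered for N
    kmers = [seq[i : i + k] for i in range(n - k + 1)]
    ok = ["N" not in km for km in kmers]

    out: list[PositionalMinimizer] = []
    seen: set[tuple[str, int]] = set()
    for p in range(n - w + 1):
        # k-mers fully contained in window [p, p+w): starts in [p, p+w-k]
        best: tuple[str, int] | None = None
        for i in range(p, p + w - k + 1):
            if not ok[i]:
                continue
            if best is None or kmers[i] < best[0]:
                best = (kmers[i], i)
        if best is not None and best not in seen:
            seen.add(best)
            out.append(PositionalMinimizer(*best))
    out.sort(key=lambda m: m.position)
    return out


def compute_minimizer_pairs(
    minimizers: Sequence[PositionalMinimizer],
    x_min: int,
    x_max: int,
    k: int | None = None,
) -> list[NompInterval]:
    """Form all minimizer pairs separated by ``x_min``–``x_max`` nucleotides.

    Returns intervals ordered by (p_i, p_j).  ``k`` (the minimizer length)
    fixes each interval's inclusive end at ``p_j + k - 1``; if omitted it is
    inferred from the first minimizer's k-mer.
    """
    if len(minimizers) < 2:
        return []
    if k is None:
        k = len(minimizers[0].kmer)
    positions = [m.position for m in minimizers]
    out: list[NompInterval] = []
    for i, mi in enumerate(minimizers):
        # positions are sorted: restrict j to the [x_min, x_max] band
        lo = bisect_right(positions, mi.position + x_min - 1, lo=i + 1)
        hi = bisect_right(positions, mi.position + x_max, lo=lo)
        for j in range(lo, hi):
            mj = minimizers[j]
            out.append(
                NompInterval(
                    kmer_pair=(mi.kmer, mj.kmer),
                    start=mi.position,
                    end=mj.position + k - 1,
                )
            )
    return out


def count_support(
    all_reads_intervals: Mapping[str, Sequence[NompInterval]],
) -> Counter:
    """Count, per k-mer pair, the number of distinct reads containing it.

    A read contributes at most 1 to a pair's support regardless of how many
    times the pair occurs in it.  As a side effect every interval's weight
    is set to ``span x support``.
    """
    support: Counter = Counter()
    for intervals in all_reads_intervals.values():
        support.update({iv.kmer_pair for iv in intervals})
    for intervals in all_reads_intervals.values():
        for iv in intervals:
            iv.support = support[iv.kmer_pair]
            iv.weight = iv.span * iv.support
    return support


def solve_wis(intervals: Sequence[NompInterval]) -> list[NompInterval]:
    """Select a maximum-weight set of pairwise non-overlapping intervals.

    Classic O(n log n) dynamic program over intervals sorted by end
    position.  Intervals are inclusive: two intervals are compatible iff
    one ends strictly before the other starts.  The returned NOMPs are
    sorted by start position.
    """
    if not intervals:
        return []
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].end, intervals[i].start))
    ends = [intervals[i].end for i in order]
    n = len(order)
    # p[j]: rightmost interval (in end-order) ending before intervals[order[j]] starts
    best = [0.0] * (n + 1)
    take: list[bool] = [False] * n
    pred: list[int] = [0] * n
    for j in range(n):
        iv = intervals[order[j]]
        p = bisect_right(ends, iv.start - 1, hi=j)  # count of compatible predecessors
        pred[j] = p
        with_j = best[p] + iv.weight
        if with_j > best[j]:
            best[j + 1] = with_j
            take[j] = True
        else:
            best[j + 1] = best[j]
    chosen: list[NompInterval] = []
    j = n
    while j > 0:
        if take[j - 1]:
            chosen.append(intervals[order[j - 1]])
            j = pred[j - 1]
        else:
            j -= 1
    chosen.sort(key=lambda iv: iv.start)
    return chosen


def seed_batch(
    reads: Sequence[Read], params: SeedingParams
) -> dict[str, list[NompInterval]]:
    """Run seeding end to end for one batch: minimizers, pairs, support, WIS.

    Returns the ordered NOMP list per read id.  Reads yielding zero NOMPs
    are returned with an empty list (the graph stage drops them with a
    warning).
    """
    per_read_pairs: dict[str, list[NompInterval]] = {}
    for read in reads:
        mins = compute_minimizers(read, params.k, params.w) if len(read) >= params.w else []
        per_read_pairs[read.read_id] = compute_minimizer_pairs(
            mins, params.x_min, params.x_max, k=params.k
        )
    count_support(per_read_pairs)
    nomps = {rid: solve_wis(ivs) for rid, ivs in per_read_pairs.items()}
    logger.debug(
        "seeded %d reads: %d NOMPs total",
        len(reads),
        sum(len(v) for v in nomps.values()),
    )
    return nomps
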