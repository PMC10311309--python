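"""Pairwise alignment helpers shared by bubble popping, end merging and
evaluation.

Scored alignments use affine gaps with match +2, mismatch -2, gap open 12
and gap extension 1.  Semiglobal alignment leaves terminal gaps unpenalized
(suited to sequences with ragged 3'/5' ends); global alignment penalizes
them; infix alignment is an edit-distance fit of one sequence wholly
inside another (containment tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio import Align

__all__ = [
    "MATCH",
    "MISMATCH",
    "GAP_OPEN",
    "GAP_EXTEND",
    "AlignmentView",
    "semiglobal_align",
    "global_align",
    "semiglobal_score",
    "infix_align",
]

MATCH = 2
MISMATCH = -2
GAP_OPEN = 12
GAP_EXTEND = 1


def _make_aligner(semiglobal: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=MATCH,
        mismatch_score=-abs(MISMATCH),
        open_gap_score=-(GAP_OPEN + GAP_EXTEND),
        extend_gap_score=-GAP_EXTEND,
    )
    if semiglobal:
        aligner.end_gap_score = 0.0
    return aligner


_SEMIGLOBAL = _make_aligner(semiglobal=True)
_GLOBAL = _make_aligner(semiglobal=False)


@dataclass
class AlignmentView:
    """A pairwise alignment reduced to its two gapped strings."""

    a: str  # gapped first sequence
    b: str  # gapped second sequence
    score: float

    def __post_init__(self) -> None:
        assert len(self.a) == len(self.b)

    @property
    def columns(self) -> int:
        return len(self.a)

    @property
    def matches(self) -> int:
        return sum(1 for x, y in zip(self.a, self.b) if x == y and x != "-")

    def identity(self) -> float:
        """Matches over alignment columns (terminal gaps included)."""
        return self.matches / self.columns if self.columns else 1.0

    def _difference_runs(self) -> list[tuple[int, int]]:
        """Maximal runs of non-match columns as (start, end) half-open."""
        runs: list[tuple[int, int]] = []
        start = None
        for i, (x, y) in enumerate(zip(self.a, self.b)):
            if x != y:  # mismatch or gap column
                if start is None:
                    start = i
            elif start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, self.columns))
        return runs

    def longest_difference_run(self, internal_only: bool = False) -> int:
        """Length of the longest contiguous mismatch/indel stretch.

        With ``internal_only`` terminal gap runs (pure-gap runs touching
        either alignment end) are ignored — those are the 3'/5' overhangs a
        semiglobal alignment leaves unpenalized.
        """
        best = 0
        for s, e in self._difference_runs():
            if internal_only and (s == 0 or e == self.columns):
                segment = list(zip(self.a[s:e], self.b[s:e]))
                if all(x == "-" or y == "-" for x, y in segment):
                    continue
            best = max(best, e - s)
        return best

    def max_differences_in_window(self, window: int) -> int:
        """Largest number of difference columns inside any sliding window
        of ``window`` alignment columns.

        Measures local difference density: two unrelated stretches differ
        in roughly two thirds of their columns even though coincidental
        matches keep every contiguous run short, whereas residual
        consensus errors are sparse at any scale.
        """
        diffs = [1 if x != y else 0 for x, y in zip(self.a, self.b)]
        if len(diffs) <= window:
            return sum(diffs)
        cur = sum(diffs[:window])
        best = cur
        for i in range(window, len(diffs)):
            cur += diffs[i] - diffs[i - window]
            best = max(best, cur)
        return best

    def unaligned_overhangs(self) -> tuple[int, int]:
        """(left, right) counts of first-sequence bases in terminal gap runs
        of the second sequence — the part of ``a`` not covered by ``b``."""
        left = right = 0
        i = 0
        while i < self.columns and self.b[i] == "-":
            if self.a[i] != "-":
                left += 1
            i += 1
        j = self.columns
        while j > 0 and self.b[j - 1] == "-":
            if self.a[j - 1] != "-":
                right += 1
            j -= 1
        if i >= j:  # degenerate: b entirely gaps
            return (left, 0)
        return (left, right)


def _align(aligner: Align.PairwiseAligner, a: str, b: str) -> AlignmentView:
    if not a or not b:
        # degenerate: represent as all-gap columns against the other
        n = max(len(a), len(b))
        return AlignmentView(a=a or "-" * n, b=b or "-" * n, score=0.0)
    aln = aligner.align(a, b)[0]
    return AlignmentView(a=str(aln[0]), b=str(aln[1]), score=aln.score)


def semiglobal_align(a: str, b: str) -> AlignmentView:
    """Align with terminal gaps free at both ends of both sequences."""
    return _align(_SEMIGLOBAL, a, b)


def global_align(a: str, b: str) -> AlignmentView:
    """End-to-end alignment; terminal gaps penalized."""
    return _align(_GLOBAL, a, b)


def semiglobal_score(a: str, b: str) -> float:
    if not a or not b:
        return float("-inf")
    return _SEMIGLOBAL.score(a, b)


def infix_align(container: str, contained: str) -> AlignmentView:
    """Fit ``contained`` wholly inside ``container`` (edit-distance infix
    alignment; the container's terminal overhangs are free and excluded
    from the view).  Used for containment tests such as end-variability
    merging."""
    if not contained or not container:
        n = max(len(container), len(contained))
        return AlignmentView(a=container or "-" * n, b=contained or "-" * n, score=0.0)
    res = edlib.align(contained, container, mode="HW", task="path")
    start = res["locations"][0][0]
    a_parts: list[str] = []
    b_parts: list[str] = []
    qp, tp = 0, start
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch in "=X":
            a_parts.append(container[tp : tp + ln])
            b_parts.append(contained[qp : qp + ln])
            qp += ln
            tp += ln
        elif ch == "I":  # bases only in `contained`
            a_parts.append("-" * ln)
            b_parts.append(contained[qp : qp + ln])
            qp += ln
        elif ch == "D":  # bases only in `container`
            a_parts.append(container[tp : tp + ln])
            b_parts.append("-" * ln)
            tp += ln
    return AlignmentView(
        a="".join(a_parts), b="".join(b_parts), score=float(-res["editDistance"])
    )
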