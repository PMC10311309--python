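"""Synthetic isoform/read generation and prediction evaluation.

The simulator emulates the input this tool expects from its upstream
clustering and error-correction stages: one gene, a reference transcript
partitioned left-to-right into exons of length 20/50/100/200 nt, ``n``
isoforms formed by subsampling ordered exon subsets, and full-length
sense-strand reads per isoform at abundances of 8/16/32/64 with a residual
per-base error rate (``0.01`` mimics error-corrected reads, ``0.07`` the
raw-read regime).  Errors are substitutions, insertions and deletions in a
1:1:1 ratio.

The evaluator matches each prediction to its best-aligning truth under
semiglobal scoring; per truth the best prediction is a true positive,
redundant ones false positives, and unmatched truths false negatives.
Identity is computed from the global alignment (so incomplete ends are
penalized) and a prediction is *complete* when it reconstructs at least
95% of its truth's length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import global_align, semiglobal_align, semiglobal_score
from .seeding import Read

logger = logging.getLogger(__name__)

BASES = "ACGT"
EXON_LENGTHS = (20, 50, 100, 200)
ABUNDANCE_CHOICES = (8, 16, 32, 64)

__all__ = [
    "SimConfig",
    "EvalResult",
    "partition_exons",
    "simulate_isoforms",
    "simulate_reads",
    "evaluate",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated gene cluster."""

    reference_length: int = 800
    n_isoforms: int = 3
    error_rate: float = 0.01
    seed: int = 1
    exon_lengths: tuple[int, ...] = EXON_LENGTHS
    abundance_choices: tuple[int, ...] = ABUNDANCE_CHOICES
    min_isoform_length: int = 100
    min_pairwise_exon_diff: int = 20
    reject_substrings: bool = True
    exon_inclusion_prob: float = 0.5
    error_mix: tuple[float, float, float] = (1.0, 1.0, 1.0)  # sub:ins:del
    polyA_length: int = 0  # optional appended tail

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_isoforms < 1:
            raise ValueError("n_isoforms must be >= 1")


def random_reference(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def partition_exons(
    reference: str, rng: np.random.Generator, exon_lengths: Sequence[int] = EXON_LENGTHS
) -> list[str]:
    """Split the reference left to right into exons with lengths sampled
    from ``exon_lengths``; a final remainder shorter than the sampled
    length becomes the last exon."""
    exons: list[str] = []
    pos = 0
    n = len(reference)
    while pos < n:
        length = int(rng.choice(exon_lengths))
        exons.append(reference[pos : min(pos + length, n)])
        pos += length
    return exons


def simulate_isoforms(
    config: SimConfig,
    reference: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Generate ``n_isoforms`` distinct isoforms by subsampling ordered
    exon subsets of the reference.

    Returns ``(isoforms, exons)`` where isoforms are (id, sequence) pairs.
    Candidates shorter than ``min_isoform_length``, duplicates, and
    candidates whose exon-level difference to an accepted isoform is below
    ``min_pairwise_exon_diff`` nt are rejected and resampled; failure to
    produce ``n_isoforms`` valid isoforms within the retry budget raises.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if reference is None:
        reference = random_reference(config.reference_length, rng)
    exons = partition_exons(reference, rng, config.exon_lengths)
    chosen: list[frozenset[int]] = []
    max_tries = 2000 * config.n_isoforms
    for _ in range(max_tries):
        if len(chosen) == config.n_isoforms:
            break
        mask = rng.random(len(exons)) < config.exon_inclusion_prob
        subset = frozenset(np.flatnonzero(mask).tolist())
        if not subset:
            continue
        length = sum(len(exons[i]) for i in subset)
        if length < config.min_isoform_length:
            continue
        if any(
            sum(len(exons[i]) for i in subset ^ prev) < config.min_pairwise_exon_diff
            for prev in chosen
        ):
            continue
        if config.reject_substrings:
            # perfect-substring isoforms confound best-match evaluation (and
            # are legitimately collapsed by end-variability merging), so the
            # ground truth excludes them
            seq = "".join(exons[i] for i in sorted(subset))
            prev_seqs = [
                "".join(exons[i] for i in sorted(p)) for p in chosen
            ]
            if any(seq in p or p in seq for p in prev_seqs):
                continue
        chosen.append(subset)
    if len(chosen) < config.n_isoforms:
        raise ValueError(
            f"could not generate {config.n_isoforms} distinct isoforms "
            f"from {len(exons)} exons within {max_tries} attempts"
        )
    isoforms = [
        (f"isoform_{i}", "".join(exons[j] for j in sorted(subset)))
        for i, subset in enumerate(chosen)
    ]
    return isoforms, exons


def _mutate(seq: str, error_rate: float, mix: np.ndarray, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    out: list[str] = []
    for base in seq:
        if rng.random() >= error_rate:
            out.append(base)
            continue
        op = rng.choice(3, p=mix)
        if op == 0:  # substitution
            out.append(rng.choice([b for b in BASES if b != base]))
        elif op == 1:  # insertion (keep the base, add a random one)
            out.append(base)
            out.append(str(rng.choice(list(BASES))))
        # op == 2: deletion — emit nothing
    return "".join(out)


def simulate_reads(
    isoforms: Sequence[tuple[str, str]],
    abundances: Sequence[int],
    error_rate: float,
    rng: np.random.Generator | int,
    error_mix: tuple[float, float, float] = (1.0, 1.0, 1.0),
    polyA_length: int = 0,
    cluster_id: str = "sim",
) -> tuple[list[Read], dict[str, str]]:
    """Simulate full-length sense-strand reads.

    Per isoform, ``abundance`` error-spiked copies (optionally with an
    appended poly-A tail); the pooled reads are shuffled.  Returns the
    reads and the read->truth assignment.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    mix = np.asarray(error_mix, dtype=float)
    mix = mix / mix.sum()
    reads: list[Read] = []
    truth_of: dict[str, str] = {}
    for (iso_id, seq), abundance in zip(isoforms, abundances):
        template = seq + "A" * polyA_length
        for i in range(abundance):
            mutated = _mutate(template, error_rate, mix, rng)
            if not mutated:
                mutated = "A"
            rid = f"{iso_id}_read{i}"
            reads.append(
                Read(
                    read_id=rid,
                    sequence=mutated,
                    quality="I" * len(mutated),
                    cluster_id=cluster_id,
                )
            )
            truth_of[rid] = iso_id
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]
    return reads, truth_of


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    identities: dict[str, float]  # prediction id -> global-alignment identity
    complete: dict[str, bool]  # prediction id -> >=95% of truth length
    best_truth: dict[str, str]  # prediction id -> matched truth id

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fraction_complete(self) -> float | None:
        if not self.complete:
            return None
        return sum(self.complete.values()) / len(self.complete)


def evaluate(
    predictions: Sequence[tuple[str, str]],
    truths: Sequence[tuple[str, str]],
    completeness_threshold: float = 0.95,
) -> EvalResult:
    """Score predictions against ground-truth isoforms.

    All-vs-all semiglobal alignment assigns each prediction its best truth;
    per truth the highest-scoring assigned prediction is the TP, the rest
    are FPs; truths with no assigned prediction are FNs.  Identity comes
    from the global alignment; completeness from the semiglobal alignment's
    coverage of the truth.
    """
    if not truths:
        raise ValueError("need at least one ground-truth isoform")
    assigned: dict[str, list[tuple[float, str]]] = {}
    best_truth: dict[str, str] = {}
    identities: dict[str, float] = {}
    complete: dict[str, bool] = {}
    for pid, pseq in predictions:
        scores = [(semiglobal_score(tseq, pseq), tid, tseq) for tid, tseq in truths]
        score, tid, tseq = max(scores, key=lambda x: (x[0], x[1]))
        best_truth[pid] = tid
        assigned.setdefault(tid, []).append((score, pid))
        identities[pid] = global_align(tseq, pseq).identity()
        view = semiglobal_align(tseq, pseq)
        left, right = view.unaligned_overhangs()
        covered = len(tseq) - left - right
        complete[pid] = covered >= completeness_threshold * len(tseq)
    tp = len(assigned)
    fp = sum(len(v) - 1 for v in assigned.values())
    fn = len(truths) - tp
    return EvalResult(
        tp=tp,
        fp=fp,
        fn=fn,
        identities=identities,
        complete=complete,
        best_truth=best_truth,
    )
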