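"""FASTQ input/output (Phred+33, 4-line records) via Biopython."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seeding import Read

logger = logging.getLogger(__name__)

__all__ = ["read_fastq", "write_fastq"]


def read_fastq(path: str | Path, cluster_id: str | None = None) -> list[Read]:
    """Read one per-cluster FASTQ file; malformed records are skipped with
    a warning rather than aborting the cluster."""
    path = Path(path)
    if cluster_id is None:
        cluster_id = path.stem
    reads: list[Read] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        try:
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            reads.append(
                Read(
                    read_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    quality=qual,
                    cluster_id=cluster_id,
                )
            )
        except ValueError as exc:
            logger.warning("skipping unreadable record %s: %s", rec.id, exc)
    return reads


def write_fastq(records: Iterable[tuple[str, str, str, str]], path: str | Path) -> None:
    """Write (id, description, sequence, quality) tuples as FASTQ."""
    seq_records = []
    for rid, desc, seq, qual in records:
        rec = SeqRecord(Seq(seq), id=rid, description=desc)
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        seq_records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fastq")
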