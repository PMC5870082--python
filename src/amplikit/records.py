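"""Core sequence records shared across the pipeline.

A CCS (circular consensus sequence) read is a consensus over multiple polymerase
passes around a circular amplicon template; its per-base Phred quality values (QVs)
encode the predicted per-base error probability, QV = -10*log10(P_error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

#: Phred cap used when writing FASTQ (Sanger encoding, offset 33).
MAX_QV = 93


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CCSRead:
    """A circular consensus read with parallel per-base quality values.

    ``predicted_accuracy`` is the proportion of bases predicted to match the
    template, derived from the QVs as 1 - mean(10**(-qv/10)). This is a proxy for
    the instrument's internal consensus model, which is not available offline.
    """

    id: str
    sequence: str
    qvs: np.ndarray

    def __post_init__(self) -> None:
        self.qvs = np.asarray(self.qvs, dtype=np.int64)
        if len(self.qvs) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.qvs)} QVs for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def predicted_accuracy(self) -> float:
        if len(self.qvs) == 0:
            return 0.0
        return float(1.0 - np.mean(np.power(10.0, -self.qvs / 10.0)))

    @property
    def mean_qv(self) -> float:
        return float(np.mean(self.qvs)) if len(self.qvs) else 0.0

    def reverse_complement(self) -> "CCSRead":
        return CCSRead(self.id, reverse_complement(self.sequence), self.qvs[::-1].copy())

    def slice(self, start: int, stop: int) -> "CCSRead":
        """Sub-read over [start, stop) keeping sequence and QVs in register."""
        return CCSRead(self.id, self.sequence[start:stop], self.qvs[start:stop].copy())

    def to_seqrecord(self) -> SeqRecord:
        rec = SeqRecord(Seq(self.sequence), id=self.id, description="")
        rec.letter_annotations["phred_quality"] = [
            int(min(q, MAX_QV)) for q in self.qvs
        ]
        return rec


@dataclass
class ReferenceRecord:
    """A Sanger-grade reference barcode (COI-like, 643-658 bp)."""

    id: str
    taxon_label: str
    sequence: str
    gc_fraction: float = field(default=0.0)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - set("ACGT"):
            raise ValueError(f"reference {self.id!r}: non-ACGT symbols present")
        self.sequence = seq
        n = len(seq)
        self.gc_fraction = (seq.count("G") + seq.count("C")) / n if n else 0.0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TruthRecord:
    """Ground truth for one simulated read (simulator bookkeeping).

    ``n_hp_indels`` counts the subset of injected indels that fell inside a
    homopolymer run; only the truth table can attribute errors positionally,
    since alignment merges multiple in-run slippage events into one net event.
    """

    read_id: str
    source_well: str
    source_reference: str
    n_substitutions: int
    n_indels: int
    orientation: str  # "forward" | "reverse"
    umi_intact: bool
    n_hp_indels: int = 0


def read_fastq(path: str | Path) -> Iterator[CCSRead]:
    """Stream CCS reads from a Sanger-encoded FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield CCSRead(
            rec.id,
            str(rec.seq).upper(),
            np.array(rec.letter_annotations["phred_quality"], dtype=np.int64),
        )


def write_fastq(reads: Iterable[CCSRead], path: str | Path) -> int:
    return SeqIO.write((r.to_seqrecord() for r in reads), str(path), "fastq")


def read_fasta(path: str | Path) -> list[ReferenceRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(ReferenceRecord(rec.id, rec.description or rec.id, str(rec.seq)))
    return out


def write_fasta(refs: Iterable[ReferenceRecord], path: str | Path) -> int:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.taxon_label) for r in refs
    ]
    return SeqIO.write(recs, str(path), "fasta")


def qv_for_error_probability(p_error: float) -> int:
    """Phred QV for a per-base error probability, capped at MAX_QV."""
    if p_error <= 0:
        return MAX_QV
    return min(MAX_QV, int(round(-10.0 * math.log10(p_error))))
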