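"""Accuracy partitioning, barcode-frame trimming, QV filtering, dereplication.

Reads are partitioned by predicted consensus accuracy (99% / 99.9% / 99.99%,
nested), trimmed to the 648-bp barcode analysis frame (30 bp excised from each
terminus to remove the 25/26-bp primers, then truncated), filtered on QV and
length, and dereplicated on perfect string identity. A separate, laxer
four-criterion score mirrors Sanger-style sequence-recovery success.

Boundary semantics follow the strict inequalities of the filter definitions:
mean QV exactly 40 passes, length exactly 500 passes, a QV<20 fraction of
exactly 1% passes; the recovery length criterion is inclusive at 493 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import CCSRead

PRIMER_EXCISION = 30  # bp removed from each terminus
BARCODE_FRAME = 648  # bp retained from the 5' end after excision
DEFAULT_PARTITIONS = (0.99, 0.999, 0.9999)


def partition_by_accuracy(
    reads: Sequence[CCSRead],
    thresholds: Sequence[float] = DEFAULT_PARTITIONS,
) -> dict[float, list[CCSRead]]:
    """Nested partitions {threshold: reads with predicted_accuracy >= threshold}.

    Thresholds must be strictly increasing; the partitions then nest:
    partition[0.9999] is a subset of partition[0.999] is a subset of
    partition[0.99].
    """
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    acc = [r.predicted_accuracy for r in reads]
    return {
        t: [r for r, a in zip(reads, acc) if a >= t] for t in thresholds
    }


def trim_to_barcode(read: CCSRead) -> CCSRead:
    """Excise 30 bp from each terminus, then truncate to 648 bp from the 5' end.

    Applies to the primer+COI segment (post hard-trim for tagged libraries, the
    raw CCS for untagged ones). Applied exactly once per read; QVs stay in
    register. Input shorter than 60 bp yields an empty read.
    """
    stop = max(len(read) - PRIMER_EXCISION, PRIMER_EXCISION)
    trimmed = read.slice(PRIMER_EXCISION, stop)
    if len(trimmed) > BARCODE_FRAME:
        trimmed = trimmed.slice(0, BARCODE_FRAME)
    return trimmed


@dataclass
class FilterVerdict:
    """Outcome of the three CCS exclusion rules; passed iff no reason fired."""

    read_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)


def filter_ccs(
    read: CCSRead,
    min_mean_qv: float = 40.0,
    min_length: int = 500,
    max_frac_qv20: float = 0.01,
) -> FilterVerdict:
    """Exclude reads with mean QV < 40, length < 500, or > 1% of bases at QV < 20."""
    reasons: list[str] = []
    if read.mean_qv < min_mean_qv:
        reasons.append("mean_qv_lt_40")
    if len(read) < min_length:
        reasons.append("len_lt_500")
    frac_low = float(np.mean(read.qvs < 20)) if len(read) else 1.0
    if frac_low > max_frac_qv20:
        reasons.append("frac_qv20_gt_1pct")
    return FilterVerdict(read.id, passed=not reasons, reasons=reasons)


def dereplicate(
    reads: Sequence[CCSRead],
) -> list[tuple[str, int, list[str]]]:
    """Group reads by perfect string identity.

    Returns (sequence, count, member read ids) sorted by descending count then
    lexicographic sequence; groups are disjoint and cover the input.
    """
    groups: dict[str, list[str]] = {}
    for r in reads:
        groups.setdefault(r.sequence, []).append(r.id)
    return sorted(
        ((seq, len(ids), ids) for seq, ids in groups.items()),
        key=lambda t: (-t[1], t[0]),
    )


def recovery_success(
    sequence: str, qvs: Sequence[int]
) -> tuple[bool, list[str]]:
    """Four-criterion Sanger-style recovery score for a barcode sequence.

    1) mean QV > 35; 2) < 1% of bases with QV < 10; 3) < 5% of bases with
    QV < 20; 4) length >= 493 bp (75% of the 658-bp barcode region).
    """
    qv = np.asarray(qvs, dtype=np.float64)
    if len(qv) != len(sequence):
        raise ValueError("sequence and QVs differ in length")
    failed: list[str] = []
    if len(qv) == 0 or qv.mean() <= 35:
        failed.append("mean_qv")
    if len(qv) == 0 or float(np.mean(qv < 10)) >= 0.01:
        failed.append("frac_qv10")
    if len(qv) == 0 or float(np.mean(qv < 20)) >= 0.05:
        failed.append("frac_qv20")
    if len(sequence) < 493:
        failed.append("length")
    return not failed, failed
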