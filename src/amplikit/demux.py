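"""Well assignment of CCS reads under the perfect-match UMI policy.

Because sequencing of a circular SMRTbell template can start from either
strand, roughly half the reads must be reverse-complemented before the UMIs
can be scored. A read is assigned to a well only when the 16-bp window at each
terminus (after cosmetic removal of the 5-bp pad) exactly equals one UMI-F at
the 5' end and the reverse complement of one UMI-R at the 3' end; any erosion
or miscall in either tag leaves the read unassigned. Assigned reads then lose
a hard 46 bp from each end (16 bp UMI + 30 bp adapter), leaving primers + COI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .records import CCSRead
from .scheme import UMIScheme

HARD_TRIM = 46  # 16 bp UMI + 30 bp adapter, each end


@dataclass
class WellAssignment:
    read_id: str
    f_index: int | None = None
    r_index: int | None = None
    well: str | None = None
    orientation: str = "forward"
    status: str = "unassigned"  # "assigned" | "unassigned"
    reason: str = "ok"  # "ok" | "no_umi_f" | "no_umi_r" | "no_well" | "too_short"


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _match_umi(window: str, umis: list[str], exact_lookup, tolerance: int) -> int | None:
    """Index of the unique UMI matching ``window`` within ``tolerance`` mismatches."""
    if tolerance == 0:
        return exact_lookup(window)
    hits = [i for i, u in enumerate(umis) if _hamming(window, u) <= tolerance]
    return hits[0] if len(hits) == 1 else None


def _strip_pad_5p(seq: str, pad: str) -> str:
    return seq[len(pad):] if seq.startswith(pad) else seq


def _umi_f_at_start(read: CCSRead, scheme: UMIScheme, tolerance: int) -> bool:
    seq = _strip_pad_5p(read.sequence, scheme.pad)
    window = seq[: scheme.umi_len]
    if len(window) < scheme.umi_len:
        return False
    return (
        _match_umi(window, scheme.umi_f, scheme.lookup_umi_f, tolerance) is not None
    )


def orient_read(
    read: CCSRead, scheme: UMIScheme, tolerance: int = 0
) -> tuple[CCSRead, str]:
    """Return the read with pad+UMI-F at the 5' terminus, plus its strand.

    When neither orientation shows a perfect UMI-F prefix (after pad removal)
    the read is returned unchanged as "forward"; downstream assignment fails.
    """
    if _umi_f_at_start(read, scheme, tolerance):
        return read, "forward"
    rc = read.reverse_complement()
    if _umi_f_at_start(rc, scheme, tolerance):
        return rc, "reverse"
    return read, "forward"


def trim_pad(read: CCSRead, scheme: UMIScheme) -> CCSRead:
    """Remove the pad where it is an exact terminal prefix/suffix (cosmetic)."""
    from .records import reverse_complement

    start = len(scheme.pad) if read.sequence.startswith(scheme.pad) else 0
    pad_rc = reverse_complement(scheme.pad)
    stop = len(read) - (len(scheme.pad) if read.sequence.endswith(pad_rc) else 0)
    return read.slice(start, stop)


def assign_well(
    read: CCSRead,
    scheme: UMIScheme,
    orientation: str = "forward",
    tolerance: int = 0,
) -> WellAssignment:
    """Score both terminal UMI windows on an oriented read.

    Failures are data outcomes (unassigned with the first failing reason), not
    exceptions. The pad, when present as an exact terminal match, is skipped
    before the 16-bp UMI window is read; a missing pad alone does not reject.
    """
    wa = WellAssignment(read_id=read.id, orientation=orientation)
    trimmed = trim_pad(read, scheme)
    seq = trimmed.sequence
    k = scheme.umi_len

    window_f = seq[:k]
    f_index = (
        _match_umi(window_f, scheme.umi_f, scheme.lookup_umi_f, tolerance)
        if len(window_f) == k
        else None
    )
    if f_index is None:
        wa.reason = "no_umi_f"
        return wa
    wa.f_index = f_index

    window_r = seq[-k:] if len(seq) >= 2 * k else ""
    from .records import reverse_complement

    if tolerance == 0:
        r_index = (
            scheme.lookup_umi_r_rc(window_r) if len(window_r) == k else None
        )
    else:
        r_index = (
            _match_umi(
                reverse_complement(window_r),
                scheme.umi_r,
                lambda w: scheme.lookup_umi_r_rc(reverse_complement(w)),
                tolerance,
            )
            if len(window_r) == k
            else None
        )
    if r_index is None:
        wa.reason = "no_umi_r"
        return wa
    wa.r_index = r_index

    well = scheme.well_for(f_index, r_index)
    if well is None:
        wa.reason = "no_well"
        return wa
    wa.well = well
    wa.status = "assigned"
    return wa


def hard_trim(read: CCSRead) -> CCSRead:
    """Cut HARD_TRIM (46) bases and their QVs from each end of a pad-trimmed read."""
    if len(read) < 2 * HARD_TRIM:
        raise ValueError(
            f"read {read.id!r} is {len(read)} bp, shorter than "
            f"{2 * HARD_TRIM} bp; cannot hard-trim"
        )
    return read.slice(HARD_TRIM, len(read) - HARD_TRIM)


@dataclass
class DemuxResult:
    per_well: dict[str, list[CCSRead]] = field(default_factory=dict)
    unassigned: list[CCSRead] = field(default_factory=list)
    assignments: list[WellAssignment] = field(default_factory=list)

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.per_well.values())

    @property
    def summary(self) -> dict:
        reasons: dict[str, int] = {}
        for wa in self.assignments:
            if wa.status != "assigned":
                reasons[wa.reason] = reasons.get(wa.reason, 0) + 1
        total = len(self.assignments)
        assigned = self.n_assigned
        return {
            "total": total,
            "assigned": assigned,
            "unassigned": total - assigned,
            "unassigned_fraction": (total - assigned) / total if total else 0.0,
            "reasons": reasons,
        }


def demultiplex(
    reads: Iterable[CCSRead],
    scheme: UMIScheme,
    tolerance: int = 0,
) -> DemuxResult:
    """Orient, assign and hard-trim every read; partition by well.

    Every input read appears in exactly one output set (its well, or the
    unassigned pool). Assigned reads are returned pad- and hard-trimmed, i.e.
    as primers + COI.
    """
    result = DemuxResult()
    for read in reads:
        oriented, orientation = orient_read(read, scheme, tolerance)
        wa = assign_well(oriented, scheme, orientation, tolerance)
        if wa.status == "assigned":
            trimmed = trim_pad(oriented, scheme)
            try:
                trimmed = hard_trim(trimmed)
            except ValueError:
                wa.status = "unassigned"
                wa.reason = "too_short"
                wa.well = None
                result.assignments.append(wa)
                result.unassigned.append(read)
                continue
            result.per_well.setdefault(wa.well, []).append(trimmed)
        else:
            result.unassigned.append(read)
        result.assignments.append(wa)
    return result
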