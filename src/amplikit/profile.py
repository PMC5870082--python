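"""Positional error profiling along the barcode frame.

Substitution and indel incidence is summarised in 5-bp sliding windows (step 1)
over the reference, with windows annotated for overlap with homopolymer tracts
(maximal single-nucleotide runs >= 6 bp, the classic hotspot for polymerase
slippage and consensus indels). A separate tract-resolution estimator recovers
the homopolymer indel-rate multiplier without the geometric dilution that
window averaging introduces at tract edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .align import AlignmentResult
from .records import ReferenceRecord

#: Scoring used when aligning reads for error attribution. The heavier gap
#: penalty stops pairs of nearby substitutions from realigning as a
#: higher-scoring deletion+insertion (which silently converts substitution
#: mass into indel mass); classification keeps the lighter default scheme,
#: where identity is robust to the choice.
PROFILING_SCORING = (1, -1, -2)


@dataclass(frozen=True)
class HomopolymerTract:
    """A maximal run of one nucleotide; start is a 0-based reference coordinate."""

    base: str
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class WindowProfile:
    window_start: int
    window_len: int
    indel_rate_per_bp: float
    substitution_rate_per_bp: float
    gc_fraction: float
    homopolymer_flag: bool


def detect_homopolymers(sequence: str, min_len: int = 6) -> list[HomopolymerTract]:
    """All maximal single-base runs of length >= min_len, sorted by start."""
    if not sequence:
        raise ValueError("sequence is empty")
    tracts: list[HomopolymerTract] = []
    seq = sequence.upper()
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            if i - start >= min_len:
                tracts.append(HomopolymerTract(seq[start], start, i - start))
            start = i
    return tracts


def homopolymer_mask(sequence: str, min_len: int = 6) -> np.ndarray:
    """Boolean mask, True at positions inside a homopolymer tract."""
    mask = np.zeros(len(sequence), dtype=bool)
    for t in detect_homopolymers(sequence, min_len):
        mask[t.start:t.end] = True
    return mask


def gc_content(sequence: str) -> float:
    """GC content in percent."""
    if not sequence:
        raise ValueError("sequence is empty")
    seq = sequence.upper()
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def per_read_error_counts(alignment: AlignmentResult) -> tuple[int, int]:
    """(n_substitutions, n_indel_events); a contiguous gap run is one event."""
    return len(alignment.substitution_positions), len(alignment.indel_events)


def window_profile(
    alignments: Sequence[AlignmentResult],
    reference: ReferenceRecord,
    window: int = 5,
    hp_min_len: int = 6,
) -> list[WindowProfile]:
    """Per-bp substitution and indel rates in sliding windows over the reference.

    Events from all alignments falling in a window are summed and divided by
    (actual window width x number of alignments). Windows truncated at the
    reference end keep their actual width to avoid edge-rate inflation.
    Insertions are attributed to the reference base preceding the gap; a
    deletion event is attributed to its starting reference position.
    """
    ref_seq = reference.sequence
    L = len(ref_seq)
    n_aln = len(alignments)
    if n_aln == 0:
        raise ValueError("no alignments supplied")
    for a in alignments:
        if a.ref_id != reference.id:
            raise ValueError(
                f"alignment {a.query_id!r} is against {a.ref_id!r}, "
                f"not {reference.id!r}"
            )

    subs = np.zeros(L, dtype=np.int64)
    indels = np.zeros(L, dtype=np.int64)
    for a in alignments:
        for p in a.substitution_positions:
            subs[p] += 1
        for (pos, _length, _kind) in a.indel_events:
            indels[min(max(pos, 0), L - 1)] += 1

    hp = homopolymer_mask(ref_seq, hp_min_len)
    gc = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
    is_gc = (gc == ord("G")) | (gc == ord("C"))

    out: list[WindowProfile] = []
    for start in range(L):
        stop = min(start + window, L)
        width = stop - start
        denom = width * n_aln
        out.append(
            WindowProfile(
                window_start=start,
                window_len=width,
                indel_rate_per_bp=float(indels[start:stop].sum()) / denom,
                substitution_rate_per_bp=float(subs[start:stop].sum()) / denom,
                gc_fraction=float(is_gc[start:stop].mean()),
                homopolymer_flag=bool(hp[start:stop].any()),
            )
        )
    return out


def homopolymer_indel_ratio(
    alignments: Sequence[AlignmentResult],
    reference: ReferenceRecord,
    hp_min_len: int = 6,
) -> tuple[float, float, float]:
    """(ratio, rate_inside, rate_outside) of per-bp indel rates w.r.t. tracts.

    Computed at tract resolution (events per tract-base vs per non-tract-base)
    rather than from window averages, which blur tract edges. Tract membership
    is widened by 1 bp on each side because alignment gap placement inside a
    run is ambiguous up to the run boundary.
    """
    ref_seq = reference.sequence
    L = len(ref_seq)
    mask = homopolymer_mask(ref_seq, hp_min_len)
    widened = mask.copy()
    widened[:-1] |= mask[1:]
    widened[1:] |= mask[:-1]
    n_in = int(widened.sum())
    n_out = L - n_in
    if n_in == 0:
        raise ValueError("reference has no homopolymer tract")
    events_in = 0
    events_out = 0
    for a in alignments:
        for (pos, _length, _kind) in a.indel_events:
            p = min(max(pos, 0), L - 1)
            if widened[p]:
                events_in += 1
            else:
                events_out += 1
    rate_in = events_in / (n_in * len(alignments))
    rate_out = events_out / (n_out * len(alignments))
    ratio = rate_in / rate_out if rate_out > 0 else float("inf")
    return ratio, rate_in, rate_out


def pcr_error_expectation(
    length_bp: int, cycles: int, error_rate: float, compound: bool = False
) -> float:
    """Expected percentage of final amplicons carrying >= 1 PCR error.

    The linear model multiplies amplicon length, cycle count and per-base
    per-cycle polymerase error rate (658 x 40 x 2.28e-5 = 60.01%); it is an
    upper (union) bound on the compound Bernoulli probability
    100*(1 - (1-rate)**(length*cycles)), returned when ``compound`` is True.
    """
    if length_bp < 0 or cycles < 0 or error_rate < 0:
        raise ValueError("length, cycles and rate must be nonnegative")
    if compound:
        return 100.0 * (1.0 - (1.0 - error_rate) ** (length_bp * cycles))
    return 100.0 * length_bp * cycles * error_rate


def profiles_to_rows(profiles: Iterable[WindowProfile]) -> list[dict]:
    """Plot-ready long-format rows (for TSV/DataFrame export)."""
    return [
        {
            "window_start": p.window_start,
            "window_len": p.window_len,
            "indel_rate": p.indel_rate_per_bp,
            "sub_rate": p.substitution_rate_per_bp,
            "gc": p.gc_fraction,
            "hp_flag": p.homopolymer_flag,
        }
        for p in profiles
    ]
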