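"""Global alignment and reference classification.

Each distinct CCS is compared to the Sanger-grade reference barcodes with a
k-mer prescreen followed by verification through global Needleman-Wunsch
alignment. A read with > 98% identity to a reference over > 80% overlap is
'target'; lower identity is 'non-target'; insufficient overlap leaves the read
unassessed. Reads from a well whose best identity to every reference falls
below 98% (divergence > 2%) seed molecular operational taxonomic units (MOTUs).

Conventions (documented, configurable): scoring match +1 / mismatch -1 /
gap -1 (linear); traceback ties prefer diagonal, then up (query base against a
reference gap), then left; identity excludes terminal-gap columns from the
denominator but counts internal gap columns as non-matches; overlap is the
number of paired (both-base) columns over the longer sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import ReferenceRecord

try:  # numba accelerates the DP fill ~100x; the numpy path is the fallback
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

_ENCODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i + 1
    _ENCODE[_b + 32] = _i + 1


def _encode(seq: str, sentinel: int) -> np.ndarray:
    """Map to 1..4 for ACGT; non-ACGT become a per-sequence sentinel so that
    ambiguous symbols behave as universal mismatches (even against themselves)."""
    codes = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()
    codes[codes == 0] = sentinel
    return codes


# Scores are scaled by _SCALE and co-optimal alignments are canonicalised by
# three tie-break tiers: each gap run pays an _OPEN_TIE surcharge (prefer fewer
# runs), each match earns _MATCH_TIE (prefer more matches), and each terminal
# gap column - a gap move along a DP edge, necessarily part of a leading or
# trailing gap run - earns +1 (prefer end gaps over internal ones). Because
# the exact linear-gap score together with the match count fixes the mismatch
# and gap-column counts (2*(matches+mismatches) + gaps = len(a)+len(b)), and
# the terminal-gap bonus then fixes the core span, the canonical alignment has
# a unique (identity, overlap) pair - so identity(a,b) == identity(b,a) - and
# a substring query aligns with clean end gaps (identity 100%). Tier totals
# stay below the next tier's unit for combined lengths up to _MAX_COMBINED.
_SCALE = 1 << 33
_OPEN_TIE = 1 << 22
_MATCH_TIE = 1 << 11
_MAX_COMBINED = 2000
_NEG = np.int64(-(1 << 60))


def _gotoh_fill_py(a, b, match, mismatch, gap):
    n, m = a.size, b.size
    open_ = gap * _SCALE + _OPEN_TIE
    ext = gap * _SCALE
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in ref (up)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in query (left)
    M[0, 0] = 0
    for i in range(1, n + 1):  # leading query-consuming gaps: edge bonus +1/col
        X[i, 0] = -(open_ - 1) - (i - 1) * (ext - 1)
    for j in range(1, m + 1):  # leading deletions: edge bonus +1/col
        Y[0, j] = -(open_ - 1) - (j - 1) * (ext - 1)
    jj = np.arange(m, dtype=np.int64) * ext
    jj_edge = np.arange(m, dtype=np.int64) * (ext - 1)
    for i in range(1, n + 1):
        eq = b == a[i - 1]
        s = np.where(eq, match * _SCALE + _MATCH_TIE, mismatch * _SCALE).astype(
            np.int64
        )
        prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev[:-1] + s
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - open_, X[i - 1, 1:] - ext
        )
        # trailing insertions run down the j == m edge: +1 per column
        X[i, m] = max(
            max(M[i - 1, m], Y[i - 1, m]) - open_ + 1, X[i - 1, m] - ext + 1
        )
        # left-gap chains: prefix max of openable scores along the row
        A = np.maximum(M[i, :-1], X[i, :-1])
        if i == n:  # trailing deletions run along the i == n edge
            Y[i, 1:] = (
                np.maximum.accumulate(A + jj_edge) - jj_edge - (open_ - 1)
            )
        else:
            Y[i, 1:] = np.maximum.accumulate(A + jj) - jj - open_
        # Y->Y extension from Y[i,0] is impossible (Y[i,0] = -inf)
    return M, X, Y


if _HAVE_NUMBA:

    @njit(cache=True)
    def _gotoh_fill_nb(a, b, match, mismatch, gap):  # pragma: no cover - jitted
        n = a.size
        m = b.size
        scale = np.int64(_SCALE)
        neg = _NEG
        open_ = gap * scale + np.int64(_OPEN_TIE)
        ext = gap * scale
        mtie = np.int64(_MATCH_TIE)
        M = np.full((n + 1, m + 1), neg, dtype=np.int64)
        X = np.full((n + 1, m + 1), neg, dtype=np.int64)
        Y = np.full((n + 1, m + 1), neg, dtype=np.int64)
        M[0, 0] = 0
        for i in range(1, n + 1):  # leading edge: +1 per terminal gap column
            X[i, 0] = -(open_ - 1) - (i - 1) * (ext - 1)
        for j in range(1, m + 1):
            Y[0, j] = -(open_ - 1) - (j - 1) * (ext - 1)
        for i in range(1, n + 1):
            ai = a[i - 1]
            for j in range(1, m + 1):
                if ai == b[j - 1]:
                    s = match * scale + mtie
                else:
                    s = mismatch * scale
                p = M[i - 1, j - 1]
                if X[i - 1, j - 1] > p:
                    p = X[i - 1, j - 1]
                if Y[i - 1, j - 1] > p:
                    p = Y[i - 1, j - 1]
                M[i, j] = p + s
                e = np.int64(1) if j == m else np.int64(0)
                x = M[i - 1, j] - open_ + e
                t = X[i - 1, j] - ext + e
                if t > x:
                    x = t
                t = Y[i - 1, j] - open_ + e
                if t > x:
                    x = t
                X[i, j] = x
                e = np.int64(1) if i == n else np.int64(0)
                y = M[i, j - 1] - open_ + e
                t = Y[i, j - 1] - ext + e
                if t > y:
                    y = t
                t = X[i, j - 1] - open_ + e
                if t > y:
                    y = t
                Y[i, j] = y
        return M, X, Y

    _gotoh_fill = _gotoh_fill_nb
else:  # pragma: no cover
    _gotoh_fill = _gotoh_fill_py


@dataclass
class AlignmentResult:
    """Outcome of one global query-vs-reference alignment.

    ``substitution_positions`` are 0-based reference coordinates of mismatch
    columns; ``indel_events`` are (reference position, length, kind) with a
    contiguous gap run counted as one event and insertions attributed to the
    reference base preceding the gap. Terminal gap runs (overlap, not error)
    are excluded from columns, identity and events. ``overlap_fraction`` is
    the count of paired (both-base) columns over the longer sequence length.
    """

    query_id: str
    ref_id: str
    identity_pct: float
    overlap_fraction: float
    substitution_positions: list[int]
    indel_events: list[tuple[int, int, str]]
    aligned_columns: int
    score: int = 0
    query_length: int = 0
    ref_length: int = 0

    @property
    def divergence_pct(self) -> float:
        return 100.0 - self.identity_pct


def global_align(
    a: str,
    b: str,
    scoring: tuple[int, int, int] = (1, -1, -1),
    query_id: str = "query",
    ref_id: str = "ref",
) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch) alignment of query ``a`` vs reference ``b``.

    ``scoring`` is (match, mismatch, gap) with gap given as a (negative) score
    per gapped column; linear gap cost.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    if len(a) + len(b) > _MAX_COMBINED:
        raise ValueError(
            f"combined length {len(a) + len(b)} exceeds {_MAX_COMBINED}; "
            "this aligner is tuned for amplicon-scale sequences"
        )
    match, mismatch, gap_score = scoring
    gap = -gap_score
    if gap < 0:
        raise ValueError("gap score must be <= 0")
    ca = _encode(a, sentinel=5)
    cb = _encode(b, sentinel=6)
    M, X, Y = _gotoh_fill(ca, cb, match, mismatch, gap)
    open_ = gap * _SCALE + _OPEN_TIE
    ext = gap * _SCALE

    # deterministic traceback over the three layers: on ties prefer diagonal
    # (M), then up (X: query base against a reference gap), then left (Y)
    ops: list[tuple[str, int]] = []  # (op, ref coordinate), reversed order
    i, j = len(ca), len(cb)
    finals = (M[i, j], X[i, j], Y[i, j])
    layer = int(np.argmax(finals))  # argmax returns the first (M>X>Y) on ties
    while i > 0 or j > 0:
        if layer == 0:  # diagonal: consumed a[i-1] vs b[j-1]
            if ca[i - 1] == cb[j - 1]:
                s = match * _SCALE + _MATCH_TIE
            else:
                s = mismatch * _SCALE
            ops.append(("M" if ca[i - 1] == cb[j - 1] else "X", j - 1))
            prev = M[i, j] - s
            i -= 1
            j -= 1
            if M[i, j] == prev:
                layer = 0
            elif X[i, j] == prev:
                layer = 1
            else:
                layer = 2
        elif layer == 1:  # up: gap in reference after ref base j-1 (insertion)
            ops.append(("I", j - 1))
            cur = X[i, j]
            e = 1 if (j == len(cb) or j == 0) else 0  # terminal-gap bonus
            i -= 1
            if M[i, j] - open_ + e == cur:
                layer = 0
            elif X[i, j] - ext + e == cur:
                layer = 1
            else:
                layer = 2
        else:  # left: deletion of reference base j-1
            ops.append(("D", j - 1))
            cur = Y[i, j]
            e = 1 if (i == len(ca) or i == 0) else 0  # terminal-gap bonus
            j -= 1
            if M[i, j] - open_ + e == cur:
                layer = 0
            elif X[i, j] - open_ + e == cur:
                layer = 1
            else:
                layer = 2
    ops.reverse()

    # trim terminal gap runs from both ends
    lo, hi = 0, len(ops)
    while lo < hi and ops[lo][0] in ("I", "D"):
        lo += 1
    while hi > lo and ops[hi - 1][0] in ("I", "D"):
        hi -= 1
    core = ops[lo:hi]

    matches = sum(1 for op, _ in core if op == "M")
    subs = [pos for op, pos in core if op == "X"]
    indels: list[tuple[int, int, str]] = []
    k = 0
    while k < len(core):
        op, pos = core[k]
        if op in ("I", "D"):
            run = 1
            while k + run < len(core) and core[k + run][0] == op:
                run += 1
            kind = "insertion" if op == "I" else "deletion"
            indels.append((pos, run, kind))
            k += run
        else:
            k += 1

    cols = len(core)
    identity = 100.0 * matches / cols if cols else 0.0
    # overlap: paired (both-base) columns over the longer sequence, so a short
    # fragment is capped at min(len)/max(len) no matter how gaps are arranged
    overlap = sum(1 for op, _ in core if op in ("M", "X")) / max(len(a), len(b))
    # exact linear-gap optimum, reconstructed from the full op list
    n_match = sum(1 for op, _ in ops if op == "M")
    n_mm = sum(1 for op, _ in ops if op == "X")
    n_gap = len(ops) - n_match - n_mm
    score = n_match * match + n_mm * mismatch + n_gap * gap_score
    return AlignmentResult(
        query_id=query_id,
        ref_id=ref_id,
        identity_pct=identity,
        overlap_fraction=overlap,
        substitution_positions=subs,
        indel_events=indels,
        aligned_columns=cols,
        score=int(score),
        query_length=len(a),
        ref_length=len(b),
    )


# -- k-mer prescreen ---------------------------------------------------------


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


class KmerIndex:
    """Distinct-k-mer sets for a reference panel, built once per panel."""

    def __init__(self, refs: Sequence[ReferenceRecord], k: int = 8):
        if k < 4:
            raise ValueError("k must be >= 4")
        if not refs:
            raise ValueError("reference panel is empty")
        self.k = k
        self.refs = list(refs)
        self.sets = [_kmer_set(r.sequence, k) for r in refs]

    def candidates(self, query: str, top_n: int = 5) -> list[ReferenceRecord]:
        if len(query) < self.k:
            return []
        q = _kmer_set(query.upper(), self.k)
        scores = [len(q & s) for s in self.sets]
        order = sorted(range(len(self.refs)), key=lambda i: (-scores[i], i))
        return [self.refs[i] for i in order[:top_n] if scores[i] > 0]


def kmer_prescreen(
    query: str,
    refs: Sequence[ReferenceRecord],
    k: int = 8,
    top_n: int = 5,
    index: KmerIndex | None = None,
) -> list[ReferenceRecord]:
    """Rank references by shared distinct k-mers; ties broken by input order."""
    if index is None:
        index = KmerIndex(refs, k)
    return index.candidates(query, top_n)


# -- classification ----------------------------------------------------------


@dataclass
class Classification:
    query_id: str
    label: str  # "target" | "non-target" | "unassessed"
    best_ref: str | None
    identity_pct: float
    overlap_fraction: float


def classify_target(
    query: str,
    refs: Sequence[ReferenceRecord],
    well_ref: Sequence[ReferenceRecord] | None = None,
    identity_threshold: float = 98.0,
    overlap_threshold: float = 0.80,
    k: int = 8,
    top_n: int = 5,
    index: KmerIndex | None = None,
    query_id: str = "query",
) -> Classification:
    """Label a query against the reference panel (or a well-restricted subset).

    Only alignments with overlap above ``overlap_threshold`` are assessed; the
    best such identity above ``identity_threshold`` makes the query 'target'.
    """
    if not refs and not well_ref:
        raise ValueError("reference panel is empty")
    if well_ref is not None:
        candidates = list(well_ref)
    else:
        candidates = kmer_prescreen(query, refs, k=k, top_n=top_n, index=index)
        if not candidates:  # no shared k-mer: still verify by alignment
            candidates = list(refs[:top_n])

    best: AlignmentResult | None = None
    for ref in candidates:
        aln = global_align(query, ref.sequence, query_id=query_id, ref_id=ref.id)
        if aln.overlap_fraction <= overlap_threshold:
            continue
        if best is None or aln.identity_pct > best.identity_pct:
            best = aln
    if best is None:
        return Classification(query_id, "unassessed", None, 0.0, 0.0)
    label = "target" if best.identity_pct > identity_threshold else "non-target"
    return Classification(
        query_id, label, best.ref_id, best.identity_pct, best.overlap_fraction
    )


# -- MOTU assignment ---------------------------------------------------------


@dataclass
class MOTU:
    motu_id: str
    representative: str
    members: list[str] = field(default_factory=list)
    nearest_ref: str | None = None
    divergence_pct: float = 0.0


def assign_motu(
    queries: Sequence[tuple[str, str, int]],
    refs: Sequence[ReferenceRecord],
    divergence_threshold: float = 2.0,
    k: int = 8,
    top_n: int = 5,
) -> list[MOTU]:
    """Cluster reference-divergent queries into MOTUs.

    ``queries`` are dereplicated (query_id, sequence, abundance) triples.
    Queries within ``divergence_threshold`` percent of any reference are
    excluded; the remainder are greedily clustered in descending-abundance seed
    order at the same threshold (divergence = 100 - global-alignment identity).
    """
    index = KmerIndex(refs, k)
    novel: list[tuple[str, str, int, str | None, float]] = []
    for qid, seq, count in queries:
        candidates = index.candidates(seq, top_n) or list(refs[:top_n])
        best_div, best_ref = float("inf"), None
        for ref in candidates:
            aln = global_align(seq, ref.sequence, query_id=qid, ref_id=ref.id)
            if aln.divergence_pct < best_div:
                best_div, best_ref = aln.divergence_pct, ref.id
        if best_div > divergence_threshold:
            novel.append((qid, seq, count, best_ref, best_div))

    novel.sort(key=lambda t: (-t[2], t[1]))
    motus: list[MOTU] = []
    for qid, seq, _count, near_ref, div in novel:
        placed = False
        for motu in motus:
            aln = global_align(seq, motu.representative)
            if aln.divergence_pct <= divergence_threshold:
                motu.members.append(qid)
                placed = True
                break
        if not placed:
            motus.append(
                MOTU(
                    motu_id=f"MOTU_{len(motus) + 1:03d}",
                    representative=seq,
                    members=[qid],
                    nearest_ref=near_ref,
                    divergence_pct=div,
                )
            )
    return motus
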