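"""Synthetic amplicon-sequencing runs with a ground-truth table.

The generator emulates the statistical structure the analysis pipeline assumes:

* COI-like reference barcodes (643-658 bp, AT-rich, GC 15-45%) carrying
  requested homopolymer tracts (>= 6 bp single-base runs);
* well-tagged amplicon constructs (pad + UMI + adapter + primer + barcode,
  811 bp for a full-length insert);
* PCR error accrual over ``L x cycles`` independent base-copy events at the
  polymerase error rate, with slippage indels confined to homopolymer runs;
* CCS consensus noise: per-base substitutions (~0.5%/bp) and indels
  (~0.1%/bp, inflated ~30-fold inside homopolymer runs), terminal erosion that
  removes the pad and clips into the UMI (~40% of reads), ~50% reverse-strand
  emission, and Phred QVs consistent with the injected error rate.

Every read receives exactly one TruthRecord, so demultiplexing accuracy,
error-rate recovery and classification recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .profile import detect_homopolymers, homopolymer_mask
from .records import (
    CCSRead,
    MAX_QV,
    ReferenceRecord,
    TruthRecord,
    qv_for_error_probability,
    reverse_complement,
)
from .scheme import UMIScheme

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_QV_JITTER_SD = 2.0  # narrow spread around the implied Phred value


@dataclass
class SimulationParams:
    """Tunable rates of the simulated run (all rates per base)."""

    pcr_cycles: int = 40
    pcr_error_rate: float = 2.28e-5  # Platinum Taq fidelity, per base per cycle
    sub_rate: float = 0.005
    indel_rate: float = 0.001
    hp_indel_multiplier: float = 30.0
    hp_min_len: int = 6
    erosion_rate: float = 0.40
    rc_prob: float = 0.5
    mean_reads_per_well: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pcr_error_rate", "sub_rate", "indel_rate",
                     "erosion_rate", "rc_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.hp_indel_multiplier < 1:
            raise ValueError("hp_indel_multiplier must be >= 1")
        if self.pcr_cycles < 0 or self.hp_min_len < 1:
            raise ValueError("pcr_cycles and hp_min_len must be nonnegative")
        if self.mean_reads_per_well < 0:
            raise ValueError("mean_reads_per_well must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


# -- references --------------------------------------------------------------


def _random_sequence_with_gc(rng: np.random.Generator, length: int,
                             gc: float) -> np.ndarray:
    """Byte array of ACGT with exactly round(gc*length) G/C bases, shuffled."""
    n_gc = int(round(gc * length))
    arr = np.empty(length, dtype=np.uint8)
    gc_bases = _BASES[rng.integers(1, 3, size=n_gc)]  # C or G
    at_bases = _BASES[rng.integers(0, 2, size=length - n_gc) * 3]  # A or T
    arr[:n_gc] = gc_bases
    arr[n_gc:] = at_bases
    rng.shuffle(arr)
    return arr


def _resolve_position(position, length: int, run_length: int) -> int:
    if isinstance(position, str):
        frac = {"start": 0.05, "mid": 0.5, "end": 0.95}.get(position)
        if frac is None:
            raise ValueError(f"unknown position keyword {position!r}")
        return int(frac * (length - run_length))
    if isinstance(position, float):
        if not 0.0 <= position <= 1.0:
            raise ValueError("fractional position outside [0, 1]")
        return int(position * (length - run_length))
    return int(position)


def _hamming_identity_pct(a: np.ndarray, b: np.ndarray) -> float:
    n = min(a.size, b.size)
    return 100.0 * float((a[:n] == b[:n]).sum()) / n


def generate_references(
    n: int,
    length_range: tuple[int, int] = (643, 658),
    gc_range: tuple[float, float] = (0.15, 0.45),
    homopolymer_spec: Sequence[tuple[str, int, object]] = (),
    seed: int = 0,
    max_pairwise_identity: float | None = 94.0,
) -> list[ReferenceRecord]:
    """Random COI-like references with controlled GC and homopolymer tracts.

    ``homopolymer_spec`` lists (base, run_length, approximate_position) runs to
    plant in every reference; positions may be "start"/"mid"/"end", a fraction
    in [0,1], or an integer coordinate. Each reference hits its drawn GC target
    within +-2 percentage points (achieved exactly by construction) and, unless
    ``max_pairwise_identity`` is None, stays below that identity to every other
    reference (Hamming proxy on the common prefix). Infeasible GC/homopolymer
    combinations raise rather than silently degrade.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= gc_range[0] <= gc_range[1] <= 1.0):
        raise ValueError("gc_range must be within [0, 1] and ordered")
    rng = np.random.default_rng(seed)
    refs: list[ReferenceRecord] = []
    arrays: list[np.ndarray] = []
    for i in range(n):
        for _attempt in range(200):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            gc = float(rng.uniform(gc_range[0], gc_range[1]))
            arr = _random_sequence_with_gc(rng, length, gc)
            try:
                arr = _plant_homopolymers(rng, arr, homopolymer_spec, gc)
            except ValueError:
                raise
            if max_pairwise_identity is not None and any(
                _hamming_identity_pct(arr, prev) >= max_pairwise_identity
                for prev in arrays
            ):
                continue
            break
        else:  # pragma: no cover - would need adversarial settings
            raise RuntimeError("could not satisfy pairwise-divergence constraint")
        arrays.append(arr)
        refs.append(
            ReferenceRecord(
                id=f"REF_{i + 1:04d}",
                taxon_label=f"taxon_{i + 1:04d}",
                sequence=arr.tobytes().decode(),
            )
        )
    return refs


def _plant_homopolymers(
    rng: np.random.Generator,
    arr: np.ndarray,
    spec: Sequence[tuple[str, int, object]],
    gc_target: float,
) -> np.ndarray:
    """Overwrite requested runs, isolate their flanks, and restore the GC count."""
    if not spec:
        return arr
    arr = arr.copy()
    length = arr.size
    protected = np.zeros(length, dtype=bool)
    for base, run_length, position in spec:
        base_u = base.upper().encode()[0]
        if run_length > length:
            raise ValueError("homopolymer run longer than the sequence")
        start = _resolve_position(position, length, run_length)
        start = max(0, min(start, length - run_length))
        arr[start:start + run_length] = base_u
        protected[start:start + run_length] = True
        # break the run at its flanks so the planted length is maximal-exact
        others = [b for b in _BASES if b != base_u]
        for flank in (start - 1, start + run_length):
            if 0 <= flank < length and arr[flank] == base_u:
                arr[flank] = others[int(rng.integers(0, len(others)))]

    # restore the GC count by swapping bases at unprotected positions
    want_gc = int(round(gc_target * length))
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    delta = int(is_gc.sum()) - want_gc
    free = np.flatnonzero(~protected)
    if delta > 0:
        pool = free[is_gc[free]]
        if pool.size < delta:
            raise ValueError("infeasible GC/homopolymer combination")
        pick = rng.choice(pool, size=delta, replace=False)
        arr[pick] = _BASES[rng.integers(0, 2, size=delta) * 3]  # A or T
    elif delta < 0:
        pool = free[~is_gc[free]]
        if pool.size < -delta:
            raise ValueError("infeasible GC/homopolymer combination")
        pick = rng.choice(pool, size=-delta, replace=False)
        arr[pick] = _BASES[rng.integers(1, 3, size=-delta)]  # C or G
    return arr


def perturb_sequence(sequence: str, divergence_pct: float, seed: int = 0) -> str:
    """Substitute a fixed fraction of positions (for low-divergence test pairs)."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    n_mut = int(round(divergence_pct / 100.0 * arr.size))
    pos = rng.choice(arr.size, size=n_mut, replace=False)
    for p in pos:
        choices = [b for b in _BASES if b != arr[p]]
        arr[p] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


# -- constructs --------------------------------------------------------------


def build_construct(
    ref: ReferenceRecord | str,
    scheme: UMIScheme,
    well: str | None = None,
    tagged: bool = True,
) -> str:
    """Forward-strand amplicon construct for a well.

    Tagged: pad + UMI-F + AF + primer-F + insert + rc(primer-R) + rc(AR) +
    rc(UMI-R) + rc(pad); 811 bp for a 658-bp insert. Untagged: primer-F +
    insert + rc(primer-R); 709 bp for a 658-bp insert.
    """
    insert = ref.sequence if isinstance(ref, ReferenceRecord) else ref
    if not tagged:
        return (
            scheme.primer_f + insert + reverse_complement(scheme.primer_r)
        )
    if well is None:
        raise ValueError("tagged constructs require a well label")
    match = [(f, r) for (f, r), w in scheme.well_map.items() if w == well]
    if not match:
        raise KeyError(f"well {well!r} not present in the scheme's well map")
    f, r = match[0]
    return (
        scheme.pad
        + scheme.umi_f[f]
        + scheme.adapter_f
        + scheme.primer_f
        + insert
        + reverse_complement(scheme.primer_r)
        + reverse_complement(scheme.adapter_r)
        + reverse_complement(scheme.umi_r[r])
        + reverse_complement(scheme.pad)
    )


# -- PCR ---------------------------------------------------------------------


def simulate_pcr_pool(
    construct: str,
    params: SimulationParams,
    n_molecules: int,
    seed: int | None = None,
) -> list[tuple[str, int]]:
    """Final-pool molecules after error accrual over L x cycles copy events.

    Each molecule independently accumulates k ~ Binomial(L*cycles, rate)
    errors; an error landing inside a homopolymer run (>= hp_min_len) becomes a
    1-bp slippage indel, elsewhere a substitution. The fraction of molecules
    with >= 1 change therefore follows 1 - (1-rate)^(L*cycles), which the
    linear expectation L*cycles*rate approximates (and bounds) when small.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    L = len(construct)
    hp = homopolymer_mask(construct, params.hp_min_len)
    trials = L * params.pcr_cycles
    counts = rng.binomial(trials, params.pcr_error_rate, size=n_molecules)
    base_arr = np.frombuffer(construct.encode(), dtype=np.uint8)
    pool: list[tuple[str, int]] = []
    for k in counts:
        if k == 0:
            pool.append((construct, 0))
            continue
        arr = base_arr.copy()
        positions = np.sort(rng.integers(0, L, size=k))[::-1]  # apply high->low
        seq_list = None
        for pos in positions:
            pos = int(pos)
            if seq_list is not None:
                pos = min(pos, len(seq_list) - 1)  # duplicates after a deletion
            if hp[pos if seq_list is None else min(pos, L - 1)]:
                if seq_list is None:
                    seq_list = list(arr)
                if rng.random() < 0.5 and len(seq_list) > 1:
                    del seq_list[pos]  # slippage contraction
                else:
                    seq_list.insert(pos, seq_list[pos])  # slippage expansion
            else:
                target = seq_list if seq_list is not None else arr
                choices = [b for b in _BASES if b != target[pos]]
                target[pos] = choices[int(rng.integers(0, 3))]
        if seq_list is not None:
            seq = bytes(seq_list).decode()
        else:
            seq = arr.tobytes().decode()
        pool.append((seq, int(k)))
    return pool


# -- CCS reads ---------------------------------------------------------------


def _draw_qvs(rng: np.random.Generator, length: int, p_error: float) -> np.ndarray:
    qv0 = qv_for_error_probability(p_error)
    qvs = np.rint(rng.normal(qv0, _QV_JITTER_SD, size=length))
    return np.clip(qvs, 3, MAX_QV).astype(np.int64)


def simulate_ccs_reads(
    pool: Sequence[tuple[str, int]],
    params: SimulationParams,
    seed: int | None = None,
    well: str = "well",
    reference_id: str = "ref",
    id_prefix: str = "read",
) -> tuple[list[CCSRead], list[TruthRecord]]:
    """One CCS read per pool molecule, with consensus noise and a truth table.

    Substitutions arrive per base at ``sub_rate``; 1-bp indels at
    ``indel_rate`` inflated ``hp_indel_multiplier``-fold inside homopolymer
    runs. With probability ``erosion_rate`` one terminus loses the 5-bp pad
    plus 1-16 UMI bases (6-21 bp total), which under the perfect-match policy
    always voids the well assignment; with probability ``rc_prob`` the read is
    emitted reverse-complemented. QVs are drawn narrowly around the Phred value
    implied by sub_rate + indel_rate. Truth counts are CCS-stage errors only.
    """
    if not pool:
        raise ValueError("pool is empty")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    reads: list[CCSRead] = []
    truths: list[TruthRecord] = []
    p_err = params.sub_rate + params.indel_rate
    for i, (molecule, _pcr_errors) in enumerate(pool):
        arr = np.frombuffer(molecule.encode(), dtype=np.uint8).copy()
        L = arr.size
        hp = homopolymer_mask(molecule, params.hp_min_len)

        n_sub = int(rng.binomial(L, params.sub_rate)) if params.sub_rate else 0
        if n_sub:
            for p in rng.choice(L, size=min(n_sub, L), replace=False):
                choices = [b for b in _BASES if b != arr[p]]
                arr[p] = choices[int(rng.integers(0, 3))]

        p_indel = np.where(
            hp, params.indel_rate * params.hp_indel_multiplier, params.indel_rate
        )
        hits = np.flatnonzero(rng.random(L) < p_indel)
        n_indel = hits.size
        n_hp_indel = int(hp[hits].sum()) if n_indel else 0
        if n_indel:
            seq_list = list(arr)
            for p in hits[::-1]:
                p = int(p)
                if rng.random() < 0.5 and len(seq_list) > 1:
                    del seq_list[p]
                else:
                    seq_list.insert(p, seq_list[p])
            seq = bytes(seq_list).decode()
        else:
            seq = arr.tobytes().decode()

        umi_intact = True
        if params.erosion_rate and rng.random() < params.erosion_rate:
            umi_intact = False
            depth = int(rng.integers(6, 22))  # pad (5) + 1..16 UMI bases
            if rng.random() < 0.5:
                seq = seq[depth:]
            else:
                seq = seq[: max(len(seq) - depth, 0)]

        orientation = "forward"
        if params.rc_prob and rng.random() < params.rc_prob:
            orientation = "reverse"
            seq = reverse_complement(seq)

        qvs = _draw_qvs(rng, len(seq), p_err)
        read_id = f"{id_prefix}{i:06d}"
        reads.append(CCSRead(read_id, seq, qvs))
        truths.append(
            TruthRecord(
                read_id=read_id,
                source_well=well,
                source_reference=reference_id,
                n_substitutions=n_sub,
                n_indels=int(n_indel),
                orientation=orientation,
                umi_intact=umi_intact,
                n_hp_indels=n_hp_indel,
            )
        )
    return reads, truths


# -- whole runs --------------------------------------------------------------


def simulate_run(
    refs: Sequence[ReferenceRecord],
    scheme: UMIScheme,
    params: SimulationParams,
    seed: int | None = None,
    with_pcr: bool = True,
) -> tuple[list[CCSRead], list[TruthRecord], dict[str, str]]:
    """A full multi-well run: constructs, PCR pools, CCS reads, truth, well map.

    References are dealt round-robin over the scheme's wells (sorted order);
    per-well read depth is Poisson(mean_reads_per_well). Returns the reads,
    the truth table and the well -> reference assignment.
    """
    base_seed = params.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    wells = sorted(scheme.well_map.items())
    well_to_ref: dict[str, str] = {}
    reads: list[CCSRead] = []
    truths: list[TruthRecord] = []
    for w_idx, ((_f, _r), well) in enumerate(wells):
        ref = refs[w_idx % len(refs)]
        well_to_ref[well] = ref.id
        n_reads = int(rng.poisson(params.mean_reads_per_well))
        if n_reads == 0:
            continue
        construct = build_construct(ref, scheme, well)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if with_pcr:
            pool = simulate_pcr_pool(construct, params, n_reads, seed=sub_seed)
        else:
            pool = [(construct, 0)] * n_reads
        ccs_seed = int(rng.integers(0, 2**31 - 1))
        well_reads, well_truths = simulate_ccs_reads(
            pool,
            params,
            seed=ccs_seed,
            well=well,
            reference_id=ref.id,
            id_prefix=f"{well}_",
        )
        reads.extend(well_reads)
        truths.extend(well_truths)
    return reads, truths, well_to_ref


def write_truth_table(truths: Sequence[TruthRecord], path: str | Path) -> None:
    lines = [
        "read_id\twell\treference\tn_sub\tn_indel\tn_hp_indel\t"
        "orientation\tumi_intact"
    ]
    for t in truths:
        lines.append(
            f"{t.read_id}\t{t.source_well}\t{t.source_reference}\t"
            f"{t.n_substitutions}\t{t.n_indels}\t{t.n_hp_indels}\t"
            f"{t.orientation}\t{int(t.umi_intact)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
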