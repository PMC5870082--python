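"""Dual-UMI tagging scheme: construct architecture and multiplexing arithmetic.

The tagging construct is, on the forward strand::

    pad + UMI-F + AF + primer-F + insert + rc(primer-R) + rc(AR) + rc(UMI-R) + rc(pad)

with a 5 bp pad (GGTAG) protecting each 16 bp well-identifying UMI from end
damage, 30 bp adapters (AF/AR) bridging to the 25/26 bp amplification primers,
and a ~658 bp COI barcode insert. Asymmetric tagging pairs independent forward
and reverse UMI sets, so n_F x n_R wells need only n_F + n_R tagged primers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import reverse_complement

DEFAULT_PAD = "GGTAG"
DEFAULT_ADAPTER_F = "GCAGTCGAACATGTAGCTGACTCAGGTCAC"
DEFAULT_ADAPTER_R = "TGGATCACTTGTGCAAGCATCACATCGTAC"
# Folmer COI primers: LCO1490 (25 bp) and HCO2198 (26 bp).
DEFAULT_PRIMER_F = "GGTCAACAAATCATAAAGATATTGG"
DEFAULT_PRIMER_R = "TAAACTTCAGGGTGACCAAAAAATCA"

UMI_LEN = 16


def scheme_capacity(n_f: int, n_r: int, mode: str = "asymmetric_pairs") -> int:
    """Number of wells discriminable by a UMI set.

    ``asymmetric_pairs``: independent forward/reverse sets give n_f * n_r ordered
    combinations (e.g. 96 x 96 = 9216). ``all_unordered_pairs``: a single pool of
    n tags deployed in every unordered pairing gives n*(n-1)/2 (e.g. 384 tags ->
    73,536 amplicons); requires n_f == n_r.
    """
    if n_f < 1 or n_r < 1:
        raise ValueError("tag counts must be >= 1")
    if mode == "asymmetric_pairs":
        return n_f * n_r
    if mode == "all_unordered_pairs":
        if n_f != n_r:
            raise ValueError("all_unordered_pairs requires n_f == n_r")
        return n_f * (n_f - 1) // 2
    raise ValueError(f"unknown capacity mode {mode!r}")


@dataclass
class UMIScheme:
    """Pad, UMI sets, adapters, primer lengths and the well map."""

    umi_f: list[str]
    umi_r: list[str]
    pad: str = DEFAULT_PAD
    adapter_f: str = DEFAULT_ADAPTER_F
    adapter_r: str = DEFAULT_ADAPTER_R
    primer_f: str = DEFAULT_PRIMER_F
    primer_r: str = DEFAULT_PRIMER_R
    well_map: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.umi_f = [u.upper() for u in self.umi_f]
        self.umi_r = [u.upper() for u in self.umi_r]
        self.pad = self.pad.upper()
        self.adapter_f = self.adapter_f.upper()
        self.adapter_r = self.adapter_r.upper()
        self.primer_f = self.primer_f.upper()
        self.primer_r = self.primer_r.upper()
        if not self.pad or not self.adapter_f or not self.adapter_r:
            raise ValueError("pad and adapters must be nonempty")
        for name, umis in (("umi_f", self.umi_f), ("umi_r", self.umi_r)):
            if not umis:
                raise ValueError(f"{name} is empty")
            lens = {len(u) for u in umis}
            if len(lens) != 1:
                raise ValueError(f"{name} UMIs are not of equal length")
            if len(set(umis)) != len(umis):
                raise ValueError(f"{name} UMIs are not unique")
        for (fi, ri) in self.well_map:
            if not (0 <= fi < len(self.umi_f) and 0 <= ri < len(self.umi_r)):
                raise ValueError(f"well_map key ({fi},{ri}) out of UMI-list bounds")
        self._umi_f_index = {u: i for i, u in enumerate(self.umi_f)}
        # UMI-R is stored in primer orientation; on the forward strand it is
        # sought as its reverse complement at the 3' terminus.
        self._umi_r_rc_index = {
            reverse_complement(u): i for i, u in enumerate(self.umi_r)
        }

    @property
    def umi_len(self) -> int:
        return len(self.umi_f[0])

    @property
    def primer_len_f(self) -> int:
        return len(self.primer_f)

    @property
    def primer_len_r(self) -> int:
        return len(self.primer_r)

    def lookup_umi_f(self, window: str) -> int | None:
        return self._umi_f_index.get(window)

    def lookup_umi_r_rc(self, window: str) -> int | None:
        """Index of the UMI-R whose reverse complement equals ``window``."""
        return self._umi_r_rc_index.get(window)

    def well_for(self, f_index: int, r_index: int) -> str | None:
        return self.well_map.get((f_index, r_index))

    @property
    def capacity(self) -> int:
        return scheme_capacity(len(self.umi_f), len(self.umi_r))

    # -- serialisation -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        obj = {
            "pad": self.pad,
            "umi_f": self.umi_f,
            "umi_r": self.umi_r,
            "adapter_f": self.adapter_f,
            "adapter_r": self.adapter_r,
            "primer_f": self.primer_f,
            "primer_r": self.primer_r,
            "well_map": [
                {"f_index": f, "r_index": r, "well": w}
                for (f, r), w in sorted(self.well_map.items())
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "UMIScheme":
        obj = json.loads(Path(path).read_text())
        well_map = {
            (int(e["f_index"]), int(e["r_index"])): str(e["well"])
            for e in obj.get("well_map", [])
        }
        return cls(
            umi_f=obj["umi_f"],
            umi_r=obj["umi_r"],
            pad=obj.get("pad", DEFAULT_PAD),
            adapter_f=obj.get("adapter_f", DEFAULT_ADAPTER_F),
            adapter_r=obj.get("adapter_r", DEFAULT_ADAPTER_R),
            primer_f=obj.get("primer_f", DEFAULT_PRIMER_F),
            primer_r=obj.get("primer_r", DEFAULT_PRIMER_R),
            well_map=well_map,
        )


def load_well_map(path: str | Path) -> dict[tuple[int, int], str]:
    """Read a TSV well map with columns f_index, r_index, well (header optional)."""
    well_map: dict[tuple[int, int], str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] in ("f_index", "umi_f"):
            continue
        well_map[(int(parts[0]), int(parts[1]))] = parts[2]
    return well_map


def save_well_map(well_map: dict[tuple[int, int], str], path: str | Path) -> None:
    lines = ["f_index\tr_index\twell"]
    for (f, r), w in sorted(well_map.items()):
        lines.append(f"{f}\t{r}\t{w}")
    Path(path).write_text("\n".join(lines) + "\n")


def random_umis(n: int, length: int = UMI_LEN, seed: int = 0,
                min_distance: int = 5) -> list[str]:
    """Draw ``n`` distinct UMIs with pairwise Hamming distance >= min_distance.

    Rejection sampling; 16 bp tags at distance 5 are easily found for n in the
    hundreds.
    """
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n:
        cand = bases[rng.integers(0, 4, size=length)]
        if all(int((cand != c).sum()) >= min_distance for c in chosen):
            chosen.append(cand)
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("could not find enough well-separated UMIs")
    return [c.tobytes().decode() for c in chosen]


def default_scheme(n_f: int = 8, n_r: int = 8, seed: int = 0) -> UMIScheme:
    """A ready-to-use asymmetric scheme with a full n_f x n_r well map.

    Wells are labelled like plate coordinates: well(f,r) = "F{f:02d}R{r:02d}".
    """
    umi_f = random_umis(n_f, seed=seed * 2 + 1)
    umi_r = random_umis(n_r, seed=seed * 2 + 2)
    well_map = {
        (f, r): f"F{f:02d}R{r:02d}" for f in range(n_f) for r in range(n_r)
    }
    return UMIScheme(umi_f=umi_f, umi_r=umi_r, well_map=well_map)
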