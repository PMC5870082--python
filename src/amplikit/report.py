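"""Per-well aggregation: recovery, contamination and run-level statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .demux import WellAssignment


@dataclass
class WellSummary:
    well: str
    ccs_count: int = 0
    target_count: int = 0
    nontarget_count: int = 0
    dominant_class: str = "empty"  # "target" | "non-target" | "empty"
    recovered: bool = False
    is_negative_control: bool = False


@dataclass
class RunReport:
    wells: list[WellSummary]
    mean_ccs: float
    sd_ccs: float
    cv_pct: float
    recovery_fraction: float
    negative_control_reads: int
    partition_sizes: dict = field(default_factory=dict)


def total_reactions(n_samples: int, n_controls: int) -> int:
    """Reactions on a plate set: samples plus negative controls (e.g. 9830+102=9932)."""
    if n_samples < 0 or n_controls < 0:
        raise ValueError("counts must be nonnegative")
    return n_samples + n_controls


def summarize_wells(
    assignments: Sequence[WellAssignment],
    classifications: Mapping[str, str],
    recovery: Mapping[str, bool],
    controls: set[str] | frozenset[str] = frozenset(),
    all_wells: Sequence[str] | None = None,
) -> list[WellSummary]:
    """One summary per well, including empty wells.

    ``classifications`` maps read_id -> "target"/"non-target"/"unassessed" for
    assigned reads; ``recovery`` maps read_id -> whether that read meets the
    four recovery criteria. A well is recovered iff at least one of its target
    reads passes recovery. Dominant class is by majority count, ties -> target.
    Supplying a classification for an unassigned read is an error.
    """
    assigned_wells: dict[str, list[str]] = {}
    assigned_ids = set()
    for wa in assignments:
        if wa.status == "assigned":
            assigned_wells.setdefault(wa.well, []).append(wa.read_id)
            assigned_ids.add(wa.read_id)
    for read_id in classifications:
        if read_id not in assigned_ids:
            raise ValueError(
                f"classification supplied for unassigned read {read_id!r}"
            )

    wells = list(all_wells) if all_wells is not None else sorted(
        set(assigned_wells) | set(controls)
    )
    out: list[WellSummary] = []
    for well in wells:
        ids = assigned_wells.get(well, [])
        target = sum(1 for i in ids if classifications.get(i) == "target")
        nontarget = sum(
            1 for i in ids if classifications.get(i) == "non-target"
        )
        if not ids:
            dominant = "empty"
        elif target >= nontarget:
            dominant = "target"
        else:
            dominant = "non-target"
        recovered = any(
            classifications.get(i) == "target" and recovery.get(i, False)
            for i in ids
        )
        out.append(
            WellSummary(
                well=well,
                ccs_count=len(ids),
                target_count=target,
                nontarget_count=nontarget,
                dominant_class=dominant,
                recovered=recovered,
                is_negative_control=well in controls,
            )
        )
    return out


def ccs_count_stats(
    summaries: Sequence[WellSummary],
    include_empty: bool = False,
    include_controls: bool = False,
) -> tuple[float, float, float]:
    """(mean, SD, CV%) of per-well CCS counts.

    By convention the CV is computed over non-control wells with >= 1 read
    (mirroring a per-taxon framing); pass ``include_empty`` to keep zero-count
    wells. Sample SD (ddof=1) when more than one well.
    """
    counts = np.array(
        [
            s.ccs_count
            for s in summaries
            if (include_controls or not s.is_negative_control)
            and (include_empty or s.ccs_count > 0)
        ],
        dtype=np.float64,
    )
    if counts.size == 0 or counts.mean() == 0:
        raise ValueError("CV undefined: no nonzero counts")
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    return mean, sd, 100.0 * sd / mean


def run_report(
    summaries: Sequence[WellSummary],
    partition_sizes: Mapping[float, int] | None = None,
) -> RunReport:
    non_control = [s for s in summaries if not s.is_negative_control]
    mean, sd, cv = ccs_count_stats(summaries)
    recovered = sum(1 for s in non_control if s.recovered)
    neg_reads = sum(s.ccs_count for s in summaries if s.is_negative_control)
    return RunReport(
        wells=list(summaries),
        mean_ccs=mean,
        sd_ccs=sd,
        cv_pct=cv,
        recovery_fraction=recovered / len(non_control) if non_control else 0.0,
        negative_control_reads=neg_reads,
        partition_sizes=dict(partition_sizes or {}),
    )


@dataclass
class PlatformComparison:
    both_success: int
    a_only: int
    b_only: int
    both_fail: int
    rate_a: float
    rate_b: float
    chi2: float | None = None
    p_value: float | None = None
    group_rates: dict = field(default_factory=dict)


def compare_platforms(
    status_a: Mapping[str, bool],
    status_b: Mapping[str, bool],
    groups: Mapping[str, str] | None = None,
) -> PlatformComparison:
    """2x2 success contingency between two platforms over the same well set.

    With ``groups`` (well -> e.g. taxon order), per-group recovery rates are
    reported for both platforms and a Pearson chi-square (no continuity
    correction) tests heterogeneity of platform-A success across groups.
    Without groups, the chi-square is the 2x2 association test between the two
    platforms' outcomes.
    """
    if set(status_a) != set(status_b):
        raise ValueError("platform comparisons require identical well sets")
    wells = sorted(status_a)
    a = np.array([status_a[w] for w in wells], dtype=bool)
    b = np.array([status_b[w] for w in wells], dtype=bool)
    both = int((a & b).sum())
    a_only = int((a & ~b).sum())
    b_only = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    out = PlatformComparison(
        both_success=both,
        a_only=a_only,
        b_only=b_only,
        both_fail=neither,
        rate_a=float(a.mean()) if a.size else 0.0,
        rate_b=float(b.mean()) if b.size else 0.0,
    )
    if groups is not None:
        labels = sorted(set(groups[w] for w in wells))
        table = []
        for g in labels:
            mask = np.array([groups[w] == g for w in wells])
            n_g = int(mask.sum())
            succ = int(a[mask].sum())
            table.append([succ, n_g - succ])
            out.group_rates[g] = {
                "n": n_g,
                "rate_a": float(a[mask].mean()) if n_g else 0.0,
                "rate_b": float(b[mask].mean()) if n_g else 0.0,
            }
        chi2, p, _, _ = stats.chi2_contingency(np.array(table), correction=False)
        out.chi2, out.p_value = float(chi2), float(p)
    else:
        table = np.array([[both, a_only], [b_only, neither]])
        if table.sum() and all(table.sum(axis=0)) and all(table.sum(axis=1)):
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            out.chi2, out.p_value = float(chi2), float(p)
    return out
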