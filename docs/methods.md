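# Methods

This note records the models, parameter choices and numerical conventions
behind `amplikit`, in the spirit of the methods documentation of simulation
and statistics packages. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Construct model

A tagged amplicon is assembled on the forward strand as

```
pad (5) + UMI-F (16) + AF (30) + primer-F (25) + insert (643-658)
        + rc(primer-R) (26) + rc(AR) (30) + rc(UMI-R) (16) + rc(pad) (5)
```

giving 811 bp for a full-length 658-bp COI insert and 709 bp for the untagged
product (primers + insert). The default pad is `GGTAG`; the default AF adapter
is the 30-mer `GCAGTCGAACATGTAGCTGACTCAGGTCAC`. The commonly circulated AR
adapter sequence is 29 bp although the architecture requires 30 bp on each
side for the arithmetic above to close; the default here appends one terminal
base (`...CGTAC`) and treats the 29-mer as a truncated transcription. The
default primers are the canonical Folmer COI pair LCO1490 (25 bp) and HCO2198
(26 bp), which have exactly the primer lengths the construct model requires.
All of these are fields of `UMIScheme` and can be replaced.

## Synthetic-data generator

The generator's defaults *are* the stated world of the analysis; they are not
tuned against test outcomes.

| parameter | default | meaning |
| --- | --- | --- |
| `pcr_cycles` | 40 | amplification cycles contributing errors |
| `pcr_error_rate` | 2.28e-5 /bp/cycle | Platinum-Taq-class polymerase fidelity |
| `sub_rate` | 0.005 /bp | CCS consensus substitution noise |
| `indel_rate` | 0.001 /bp | CCS consensus indel noise (outside tracts) |
| `hp_indel_multiplier` | 30 | indel-rate inflation inside homopolymer runs |
| `hp_min_len` | 6 bp | minimum run length treated as a tract |
| `erosion_rate` | 0.40 | fraction of reads losing pad + part of one UMI |
| `rc_prob` | 0.5 | probability a read is emitted reverse-complemented |
| `mean_reads_per_well` | 15 | Poisson depth per well |

**References.** Sequences are drawn with an exact G+C count for a GC target
uniform on the requested range (default 15–45%, the COI regime), lengths
uniform on 643–658 bp (full-length barcodes and naturally occurring 3–15-bp
deletions). Requested homopolymer runs are overwritten at their approximate
positions with flanks forced to a different base (so the planted length is
exact and maximal), and the G+C count is then restored by swapping bases
outside the runs; an unsatisfiable combination (e.g. a G-run in a GC-0
sequence) raises. AT-rich sequences also develop natural T/A runs, as real COI
does; tract annotation is always recomputed from the realised sequence, never
assumed from the request. A Hamming-identity guard keeps pairwise identity
below 94% (unrelated random sequences sit near 40%, so this rarely triggers).

**PCR.** Each final-pool molecule accrues `k ~ Binomial(L*cycles, rate)`
errors — independent per-base-copy events, not an explicit branching
genealogy. The probability that a molecule carries at least one change is
therefore exactly `1-(1-r)^(L*c)` (≈ 45.1% at 658 x 40 x 2.28e-5), which the
widely quoted linear product `L*c*r` (60.01%) approximates from above; both
forms are exposed by `pcr_error_expectation`. Whether the linear or compound
form is "the" expectation is left to the caller — the linear form is the
headline convention, the compound form is the exact one for this process. An
error landing inside a homopolymer run becomes a 1-bp slippage indel
(expansion or contraction, 1:1), elsewhere a substitution; slippage outside
runs does not occur, matching the observation that PCR length variants are a
homopolymer phenomenon.

**CCS reads.** Per base: substitutions at `sub_rate`; 1-bp indels at
`indel_rate`, multiplied by `hp_indel_multiplier` inside tracts of the
molecule being read. With probability `erosion_rate` one terminus loses
6–21 bp — the 5-bp pad plus 1–16 UMI bases. The erosion depth law is chosen so
that erosion *always* clips into the UMI: erosion is meant to model the
damage- and end-repair loss that voids the perfect-match policy, and a depth
that only removed the pad would leave the read assignable, silently decoupling
`erosion_rate` from the unassigned fraction. Because any UMI damage is fatal
under exact matching, nothing downstream depends on the precise depth law.
QVs are drawn from a narrow normal (sd 2) around the Phred value implied by
`sub_rate + indel_rate`, capped at 93 (Sanger encoding): only threshold
behaviour matters, as no instrument QV model is available offline.

Note a consequence owned honestly: the default noise (0.6%/bp ⇒ QV ≈ 22)
represents CCS-vs-reference divergence, while the QV *filters* (mean ≥ 40
etc.) were designed for real instrument QVs of 88–92. A default-noise
synthetic run therefore fails the QV filters wholesale; filter logic is tested
with explicitly constructed QV arrays, and the run-scale acceptance output
prints a note to this effect rather than inventing a prettier QV model.

**Truth.** Every read gets one `TruthRecord` (source well/reference, injected
substitution and indel counts, the in-tract indel subset, orientation, UMI
intactness). Only the truth table can attribute errors positionally; see
"Error profiling" for why that matters.

## Demultiplexing

Orientation is resolved by looking for a perfect UMI-F prefix (after removal
of an exactly matching terminal pad) on the read and then on its reverse
complement; assignment then requires the 5' 16-bp window to equal one UMI-F
and the 3' window to equal the reverse complement of one UMI-R, with the well
looked up in the (f, r) map. Failures are data outcomes with ordered reasons
(`no_umi_f`, `no_umi_r`, `no_well`), never exceptions. A missing pad alone
does not reject a read — the UMI window is still tested — because pad removal
is cosmetic, not diagnostic. A Hamming tolerance is exposed
(`tolerance=` / `--umi-mismatches`) but defaults to 0, the perfect-match
policy. Assigned reads lose a hard 46 bp (16-bp UMI + 30-bp adapter) from each
end, leaving primers + insert. Coordinates are 0-based, half-open throughout.

## Quality control

Predicted accuracy is derived from QVs as `1 - mean(10^(-qv/10))` — a stated
proxy for the instrument's consensus model, which is not reproducible offline.
Partition thresholds (0.99 / 0.999 / 0.9999) produce nested read sets. The
barcode frame is reached by excising 30 bp from each terminus (covering the
25/26-bp primers) and truncating to 648 bp; trimming is applied exactly once
per read, enforced by pipeline ordering, since a second application would
remove 60 further bases. Filter boundaries follow the strict inequalities as
written: mean QV exactly 40 passes, length exactly 500 passes, a QV<20
fraction of exactly 1% passes. The Sanger-style recovery score (mean QV > 35;
< 1% bases QV < 10; < 5% bases QV < 20; length ≥ 493 bp = 75% of the barcode)
reads its length bound inclusively. Dereplication groups on perfect string
identity and orders groups by descending count, then lexicographic sequence,
for determinism.

## Alignment and classification

The Needleman–Wunsch core is implemented directly (no suitable pairwise
aligner exposing per-column events was available in the environment) with
scoring match +1 / mismatch −1 / gap −1 (linear), configurable; identity and
overlap, not raw score, drive classification, which makes results robust to
this choice. Scores are computed in a scaled-integer Gotoh formulation whose
three tie-break tiers canonicalise the traceback *among score-optimal
alignments*: fewer gap runs, then more matches, then more terminal gap
columns, with residual ties broken diagonal > up > left. The tiers are sized
so the exact linear-gap optimum always dominates (guarded up to 2000 combined
bp — amplicon scale). Consequences, verified by property tests: a substring
query aligns with clean end gaps and identity 100; identity and overlap are
symmetric in the argument order; scores equal brute-force enumeration optima
and Biopython's `PairwiseAligner`.

Identity = matches / core columns, where the core excludes terminal gap runs
but counts internal gap columns as mismatches. Overlap = paired (both-base)
columns / longer sequence length, so a 400-bp fragment of a 648-bp reference
can never exceed 400/648 ≈ 0.62 regardless of gap placement. Classification:
candidates from a k-mer prescreen (distinct 8-mers, top 5, ties by panel
order; an empty prescreen falls back to alignment so "no shared k-mers" is
still verified rather than assumed) or from a caller-supplied per-well panel;
alignments at overlap ≤ 0.80 are discarded; best identity > 98% ⇒ target,
else non-target; no assessable alignment ⇒ unassessed. MOTU assignment
excludes queries within 2% of any reference, then greedily clusters the
remainder in descending-abundance seed order at the same threshold, with
divergence defined as 100 − identity.

## Error profiling

Window profiles slide a 5-bp window at step 1 along the reference; windows
truncated at the end keep their actual width (avoiding edge-rate inflation),
and a window is homopolymer-flagged when it overlaps any detected tract.
Substitutions contribute at their reference coordinate; an indel event is a
contiguous gap run (column counting is available via event lengths), with
insertions attributed to the reference base preceding the gap.

Two measurement subtleties are documented rather than hidden:

* **Profiling scoring.** Error attribution uses match +1 / mismatch −1 /
  gap −2 (`PROFILING_SCORING`): under the lighter default scheme two nearby
  substitutions can legitimately realign as a higher-scoring
  deletion+insertion pair, silently converting ~0.7% of substitution mass
  into indel mass. With the heavier gap penalty the windowed substitution
  rate recovers the injected rate to ~0.25%.
* **Homopolymer ratio.** Alignment merges co-occurring in-tract slippage
  events into one net event (an insertion and a deletion in the same run
  cancel entirely), so the alignment-observable in-tract rate understates the
  injected one by ~25–30% at the default multiplicity — a property of the
  observable, not an estimator defect, and independent of sample size. The
  unbiased multiplier is therefore recovered from the truth table's
  positional counts; `homopolymer_indel_ratio` reports the alignment-level
  ratio (tract-resolution, membership widened ±1 bp for gap-placement
  ambiguity), and window-level flagged/unflagged comparisons are additionally
  diluted geometrically at tract edges (a window overlapping an 11-bp tract
  by 1 bp mixes one part inflated with four parts baseline).

## Reporting

Per-well summaries count target/non-target reads (majority class, ties →
target), flag negative controls, and mark a well *recovered* when at least
one target-classified read passes the four recovery criteria. CV of CCS
counts is computed over non-control wells with ≥ 1 read by default (a
per-taxon framing); the zero-inclusive convention is available via a flag.
Platform comparison builds the both/A-only/B-only/neither contingency and,
when a grouping (e.g. taxon order) is supplied, per-group recovery rates with
a Pearson chi-square (no continuity correction) across groups.

## What a green test establishes — and what it does not

The generator emulates the *statistical* structure of a tagged CCS run:
error rates, tract inflation, erosion, strand balance, depth variation. It
does not model polymerase-specific error spectra, chimeras, NUMTs,
heteroplasmy, carry-over contamination, or real instrument QV behaviour
(non-target contamination can only be emulated as generic spike-in
sequences). Pipeline correctness established on synthetic data therefore
covers the bookkeeping, matching and rate-recovery logic — not the biological
realism of any particular error spectrum. Headline run-scale outcomes of real
sequencing experiments (per-partition read counts, ~90% recovery rates, CV
ranges) depend on instrument data and are deliberately not reproduced or
asserted at desk scale.
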