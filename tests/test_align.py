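"""Global alignment core, k-mer prescreen, classification and MOTUs."""

import random
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import amplikit as ak
from amplikit.align import KmerIndex, global_align


def brute_force_score(a, b, match=1, mismatch=-1, gap=-1):
    """Exhaustive-recursion optimum over all global alignments (oracle)."""

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == 0 and j == 0:
            return 0
        out = -(10**9)
        if i and j:
            s = match if a[i - 1] == b[j - 1] else mismatch
            out = max(out, best(i - 1, j - 1) + s)
        if i:
            out = max(out, best(i - 1, j) + gap)
        if j:
            out = max(out, best(i, j - 1) + gap)
        return out

    return best(len(a), len(b))


class TestGlobalAlign:
    def test_score_matches_bruteforce_oracle(self):
        rng = random.Random(1234)
        for _ in range(100):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
            assert global_align(a, b).score == brute_force_score(a, b)

    def test_score_matches_biopython_on_long_pairs(self):
        # independent cross-check against an established implementation
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        rng = random.Random(77)
        for _ in range(25):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(40, 150)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(40, 150)))
            assert global_align(a, b).score == aligner.score(a, b)

    def test_self_alignment(self):
        r = global_align("ACGTACGTAA", "ACGTACGTAA")
        assert r.identity_pct == 100.0
        assert r.indel_events == [] and r.substitution_positions == []
        assert r.overlap_fraction == 1.0

    def test_single_deletion_example(self):
        # one internal 1-bp gap: 7 matches over 8 columns
        r = global_align("ACGTACGT", "ACGTCGT")
        assert len(r.indel_events) == 1
        assert r.indel_events[0][1] == 1
        assert r.identity_pct == pytest.approx(100 * 7 / 8)

    def test_substring_query_gets_clean_end_gaps(self, ref648):
        q = ref648.sequence[10:600]
        r = global_align(q, ref648.sequence)
        assert r.identity_pct == 100.0
        assert r.indel_events == []
        assert r.overlap_fraction == pytest.approx(590 / 648)

    def test_gap_run_is_one_event(self):
        seq = "ACGTGCTTAGCATCGAGCTA"
        q = seq[:8] + seq[11:]  # 3-bp internal deletion
        r = global_align(q, seq)
        assert r.indel_events == [(8, 3, "deletion")]

    def test_non_acgt_is_universal_mismatch(self):
        r = global_align("ANAT", "ANAT")
        assert len(r.substitution_positions) == 1  # N never matches, even N vs N

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_identity_symmetry_and_self_identity(self, data):
        a = data.draw(st.text(alphabet="ACGT", min_size=3, max_size=60))
        b = data.draw(st.text(alphabet="ACGT", min_size=3, max_size=60))
        assert global_align(a, a).identity_pct == 100.0
        ab, ba = global_align(a, b), global_align(b, a)
        assert ab.identity_pct == pytest.approx(ba.identity_pct)
        assert ab.overlap_fraction == pytest.approx(ba.overlap_fraction)
        assert ab.score == ba.score


class TestKmerPrescreen:
    def test_identical_query_ranks_first(self, refs):
        hits = ak.kmer_prescreen(refs[2].sequence, refs)
        assert hits[0].id == refs[2].id

    def test_no_shared_kmers_gives_empty(self):
        panel = [ak.ReferenceRecord("r1", "r1", "CG" * 20)]
        assert ak.kmer_prescreen("A" * 20, panel, k=8) == []

    def test_short_query_gives_empty(self, refs):
        assert ak.kmer_prescreen("ACG", refs, k=8) == []

    def test_prescreen_agrees_with_exhaustive_best_hit(self, refs):
        # prescreen + align must pick the same best reference as align-all
        rng = np.random.default_rng(5)
        index = KmerIndex(refs)
        for i in range(50):
            src = refs[int(rng.integers(0, len(refs)))]
            q = ak.perturb_sequence(src.sequence, 1.0, seed=100 + i)
            pres = ak.classify_target(q, refs, index=index)
            best = max(
                (global_align(q, r.sequence, ref_id=r.id) for r in refs),
                key=lambda a: a.identity_pct,
            )
            assert pres.best_ref == best.ref_id
            assert pres.identity_pct == pytest.approx(best.identity_pct)


class TestClassifyTarget:
    def test_exact_reference_is_target(self, refs):
        c = ak.classify_target(refs[0].sequence, refs)
        assert c.label == "target" and c.best_ref == refs[0].id

    def test_three_percent_divergence_is_nontarget(self, refs):
        q = ak.perturb_sequence(refs[0].sequence, 3.0, seed=8)
        c = ak.classify_target(q, refs)
        assert c.label == "non-target"
        assert c.identity_pct < 98.0

    def test_short_fragment_is_unassessed(self, refs):
        q = refs[0].sequence[100:500]  # overlap ~0.62
        c = ak.classify_target(q, refs)
        assert c.label == "unassessed"

    def test_well_restricted_panel(self, refs):
        c = ak.classify_target(
            refs[1].sequence, refs, well_ref=[refs[1]]
        )
        assert c.label == "target" and c.best_ref == refs[1].id

    def test_low_divergence_pairs_never_cross_assigned(self):
        # species pairs 1.6-3.2% apart must resolve to their own reference
        base = ak.generate_references(1, length_range=(658, 658), seed=33)[0]
        panel = [base]
        for i, div in enumerate((1.6, 1.85, 2.0, 3.2)):
            panel.append(
                ak.ReferenceRecord(
                    id=f"LOWDIV_{i}",
                    taxon_label=f"lowdiv_{i}",
                    sequence=ak.perturb_sequence(base.sequence, div, seed=40 + i),
                )
            )
        for ref in panel:
            c = ak.classify_target(ref.sequence, panel)
            assert c.best_ref == ref.id
            assert c.identity_pct == 100.0


class TestAssignMotu:
    def test_queries_near_references_make_no_motu(self, refs):
        queries = [
            (f"q{i}", ak.perturb_sequence(r.sequence, 1.0, seed=50 + i), 3)
            for i, r in enumerate(refs[:3])
        ]
        assert ak.assign_motu(queries, refs) == []

    def test_novel_sequence_forms_singleton(self, refs):
        novel = ak.perturb_sequence(refs[0].sequence, 5.0, seed=60)
        motus = ak.assign_motu([("q1", novel, 4)], refs)
        assert len(motus) == 1
        assert motus[0].members == ["q1"]
        assert motus[0].divergence_pct > 2.0

    def test_close_novel_pair_shares_one_motu(self, refs):
        novel = ak.perturb_sequence(refs[0].sequence, 5.0, seed=61)
        sibling = ak.perturb_sequence(novel, 0.5, seed=62)
        motus = ak.assign_motu(
            [("a", novel, 5), ("b", sibling, 2)], refs
        )
        assert len(motus) == 1
        assert sorted(motus[0].members) == ["a", "b"]
        # the more abundant query seeds the cluster
        assert motus[0].representative == novel
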