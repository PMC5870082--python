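"""Synthetic-data generator: references, constructs, PCR pools, CCS reads."""

import numpy as np
import pytest

import amplikit as ak
from amplikit.profile import homopolymer_mask


class TestGenerateReferences:
    def test_zero_gc_forces_at_only(self):
        ref = ak.generate_references(1, gc_range=(0.0, 0.0), seed=1)[0]
        assert set(ref.sequence) <= {"A", "T"}
        assert ref.gc_fraction == 0.0

    def test_planted_homopolymer_present(self):
        ref = ak.generate_references(
            1, homopolymer_spec=[("T", 11, "mid")], seed=4
        )[0]
        tracts = ak.detect_homopolymers(ref.sequence, min_len=6)
        assert any(t.base == "T" and t.length == 11 for t in tracts)

    def test_gc_target_honoured(self):
        refs = ak.generate_references(
            5, gc_range=(0.30, 0.30), homopolymer_spec=[("T", 8, 0.3)], seed=6
        )
        for r in refs:
            assert abs(r.gc_fraction - 0.30) <= 0.02

    def test_seed_determinism(self):
        a = ak.generate_references(20, seed=11)
        b = ak.generate_references(20, seed=11)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_lengths_in_range(self):
        refs = ak.generate_references(20, length_range=(643, 658), seed=12)
        assert all(643 <= len(r) <= 658 for r in refs)

    def test_infeasible_gc_homopolymer_raises(self):
        with pytest.raises(ValueError):
            ak.generate_references(
                1, gc_range=(0.0, 0.0), homopolymer_spec=[("G", 8, "mid")], seed=1
            )

    def test_pairwise_divergence_guard(self):
        refs = ak.generate_references(10, seed=13)
        for i, a in enumerate(refs):
            for b in refs[i + 1:]:
                n = min(len(a), len(b))
                ident = 100.0 * sum(
                    1 for x, y in zip(a.sequence, b.sequence) if x == y
                ) / n
                assert ident < 94.0


class TestBuildConstruct:
    def test_full_length_tagged_construct(self, scheme):
        ref = ak.generate_references(1, length_range=(658, 658), seed=3)[0]
        construct = ak.build_construct(ref, scheme, "F00R01")
        assert len(construct) == 811

    def test_deletion_taxon_construct(self, scheme):
        ref = ak.generate_references(1, length_range=(643, 643), seed=3)[0]
        assert len(ak.build_construct(ref, scheme, "F02R03")) == 796

    def test_untagged_product(self, scheme):
        ref = ak.generate_references(1, length_range=(658, 658), seed=3)[0]
        assert len(ak.build_construct(ref, scheme, tagged=False)) == 709

    def test_unknown_well_raises_with_name(self, scheme):
        ref = ak.generate_references(1, seed=3)[0]
        with pytest.raises(KeyError, match="F99R99"):
            ak.build_construct(ref, scheme, "F99R99")

    def test_architecture_round_trip(self, scheme):
        ref = ak.generate_references(1, length_range=(658, 658), seed=3)[0]
        c = ak.build_construct(ref, scheme, "F03R02")
        assert c.startswith(scheme.pad + scheme.umi_f[3] + scheme.adapter_f)
        assert c.endswith(
            ak.reverse_complement(scheme.umi_r[2]) + ak.reverse_complement(scheme.pad)
        )
        assert ref.sequence in c


class TestSimulatePcrPool:
    def test_zero_rate_leaves_pool_identical(self, scheme, refs):
        construct = ak.build_construct(refs[0], scheme, "F00R00")
        params = ak.SimulationParams(pcr_error_rate=0.0)
        pool = ak.simulate_pcr_pool(construct, params, 50, seed=1)
        assert all(seq == construct and k == 0 for seq, k in pool)

    def test_errored_fraction_matches_compound_model(self):
        # 658 bp x 40 cycles x 2.28e-5: the exact Bernoulli process yields
        # 1-(1-r)^(L*c) ~ 0.451, below the linear expectation of 0.60
        seq = ak.generate_references(1, length_range=(658, 658), seed=7)[0]
        params = ak.SimulationParams()
        n = 30000
        pool = ak.simulate_pcr_pool(seq.sequence, params, n, seed=2)
        frac = sum(1 for _, k in pool if k > 0) / n
        expected = 1.0 - (1.0 - 2.28e-5) ** (658 * 40)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se
        assert expected < 0.6001  # linear model is an upper bound

    def test_slippage_confined_to_homopolymer_runs(self):
        # a run-free template can only acquire substitutions, never indels;
        # with a tract present, length changes do occur at elevated rates
        flat = "ACGT" * 160
        params = ak.SimulationParams(pcr_error_rate=1e-3)
        pool = ak.simulate_pcr_pool(flat, params, 300, seed=3)
        assert all(len(seq) == len(flat) for seq, _ in pool)

        tract = flat[:300] + "T" * 11 + flat[300:]
        pool2 = ak.simulate_pcr_pool(tract, params, 300, seed=3)
        changed = [len(seq) != len(tract) for seq, _ in pool2]
        assert any(changed)

    def test_single_base_single_cycle_limit(self):
        params = ak.SimulationParams(pcr_cycles=1, pcr_error_rate=0.3)
        pool = ak.simulate_pcr_pool("A", params, 20000, seed=4)
        frac = sum(1 for _, k in pool if k > 0) / len(pool)
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 20000)


class TestSimulateCcsReads:
    def test_zero_noise_reads_identical(self, refs, noise_free):
        pool = [(refs[0].sequence, 0)] * 20
        reads, truths = ak.simulate_ccs_reads(pool, noise_free, seed=1)
        assert all(r.sequence == refs[0].sequence for r in reads)
        assert all(
            t.n_substitutions == 0 and t.n_indels == 0 and t.umi_intact
            for t in truths
        )

    def test_mean_substitutions_match_binomial(self, ref648):
        params = ak.SimulationParams(
            indel_rate=0.0, erosion_rate=0.0, rc_prob=0.0, seed=0
        )
        pool = [(ref648.sequence, 0)] * 5000
        _, truths = ak.simulate_ccs_reads(pool, params, seed=2)
        mean = np.mean([t.n_substitutions for t in truths])
        expected = 648 * 0.005
        se = np.sqrt(expected / 5000)  # ~Poisson
        assert abs(mean - expected) < 3 * se

    def test_homopolymer_indel_inflation(self, ref648):
        params = ak.SimulationParams(
            sub_rate=0.0, erosion_rate=0.0, rc_prob=0.0
        )
        pool = [(ref648.sequence, 0)] * 4000
        _, truths = ak.simulate_ccs_reads(pool, params, seed=3)
        mask = homopolymer_mask(ref648.sequence)
        n_in, n_out = int(mask.sum()), len(ref648.sequence) - int(mask.sum())
        ev_in = sum(t.n_hp_indels for t in truths)
        ev_out = sum(t.n_indels - t.n_hp_indels for t in truths)
        ratio = (ev_in / n_in) / (ev_out / n_out)
        se = ratio * np.sqrt(1 / ev_in + 1 / ev_out)
        assert abs(ratio - 30.0) < 3 * se

    def test_orientation_balance(self, ref648):
        params = ak.SimulationParams(erosion_rate=0.0, seed=0)
        pool = [(ref648.sequence, 0)] * 4000
        _, truths = ak.simulate_ccs_reads(pool, params, seed=4)
        frac = np.mean([t.orientation == "reverse" for t in truths])
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_erosion_marks_umi_and_shortens(self, refs, scheme):
        construct = ak.build_construct(refs[0], scheme, "F00R00")
        params = ak.SimulationParams(
            sub_rate=0.0, indel_rate=0.0, rc_prob=0.0, erosion_rate=1.0
        )
        pool = [(construct, 0)] * 200
        reads, truths = ak.simulate_ccs_reads(pool, params, seed=5)
        assert all(not t.umi_intact for t in truths)
        # erosion removes the 5-bp pad plus 1-16 UMI bases
        losses = {len(construct) - len(r.sequence) for r in reads}
        assert losses <= set(range(6, 22))
        assert min(losses) >= 6 and max(losses) <= 21

    def test_count_conservation_and_determinism(self, ref648):
        params = ak.SimulationParams(seed=0)
        pool = [(ref648.sequence, 0)] * 300
        r1, t1 = ak.simulate_ccs_reads(pool, params, seed=6)
        r2, t2 = ak.simulate_ccs_reads(pool, params, seed=6)
        assert len(r1) == len(t1) == 300
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        assert all(
            np.array_equal(a.qvs, b.qvs) for a, b in zip(r1, r2)
        )
        assert t1 == t2

    def test_qvs_track_error_rate(self, ref648):
        params = ak.SimulationParams(erosion_rate=0.0, rc_prob=0.0)
        pool = [(ref648.sequence, 0)] * 50
        reads, _ = ak.simulate_ccs_reads(pool, params, seed=7)
        implied = -10 * np.log10(0.005 + 0.001)
        mean_qv = np.mean([r.mean_qv for r in reads])
        assert abs(mean_qv - implied) < 1.0


class TestSimulateRun:
    def test_fastq_and_truth_deterministic(self, refs, scheme, tmp_path):
        params = ak.SimulationParams(mean_reads_per_well=5, seed=9)
        r1, t1, m1 = ak.simulate_run(refs, scheme, params)
        r2, t2, m2 = ak.simulate_run(refs, scheme, params)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        ak.write_fastq(r1, p1)
        ak.write_fastq(r2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert t1 == t2 and m1 == m2

    def test_every_read_has_one_truth_record(self, refs, scheme):
        params = ak.SimulationParams(mean_reads_per_well=5, seed=10)
        reads, truths, _ = ak.simulate_run(refs, scheme, params)
        assert len(reads) == len(truths)
        assert {r.id for r in reads} == {t.read_id for t in truths}

    def test_truth_table_tsv(self, refs, scheme, tmp_path):
        params = ak.SimulationParams(mean_reads_per_well=3, seed=11)
        reads, truths, _ = ak.simulate_run(refs, scheme, params)
        path = tmp_path / "truth.tsv"
        ak.write_truth_table(truths, path)
        lines = path.read_text().splitlines()
        assert len(lines) == len(truths) + 1
        assert lines[0].split("\t")[0] == "read_id"
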