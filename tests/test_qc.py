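"""The six-rule cleaning cascade, filter by filter and end to end."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from poolmhc.qc import (
    QCParams,
    Read,
    Variant,
    assign_locus,
    dereplicate,
    drop_singletons,
    filter_frameshift,
    filter_length,
    filter_quality,
    run_qc_pipeline,
)
from poolmhc.simulate import SimulationConfig, default_loci, simulate_study

from oracles import nw_align_score


def mkread(bases, rid="r1", barcode="b1", q=None):
    quals = [q] * len(bases) if isinstance(q, int) else q
    return Read(rid, barcode, bases, quals)


class TestLengthFilter:
    def test_boundary_179_removed_180_retained(self):
        reads = [mkread("A" * 179, "short"), mkread("A" * 180, "exact")]
        kept = filter_length(reads)
        assert [r.id for r in kept] == ["exact"]

    def test_counted_fixture(self):
        reads = [mkread("A" * n, f"r{n}") for n in range(150, 331, 20)]
        assert len(filter_length(reads)) == 8


class TestLocusAssignment:
    def test_self_alignment(self, references):
        ref = references["MHC2ex2"]
        res = assign_locus(mkread(ref), references)
        assert res.locus == "MHC2ex2"
        assert res.identity == pytest.approx(1.0)
        assert res.net_indel_length == 0

    def test_reverse_complement_normalized(self, references):
        ref = references["MHC1ex3"]
        res = assign_locus(mkread(reverse_complement(ref)), references)
        assert res.locus == "MHC1ex3"
        assert res.strand == "-"
        assert res.oriented_bases == ref

    def test_random_read_rejected(self, references):
        rng = np.random.default_rng(42)
        junk = "".join(rng.choice(list("ACGT"), 261))
        res = assign_locus(mkread(junk), references)
        assert res.locus is None
        assert res.identity < 0.70

    def test_25_percent_substituted_still_assigned(self, references):
        ref = references["MHC2ex2"]
        rng = np.random.default_rng(1)
        pos = rng.choice(len(ref), size=len(ref) // 4, replace=False)
        mutant = list(ref)
        for p in pos:
            mutant[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutant[p]]
        res = assign_locus(mkread("".join(mutant)), references)
        assert res.locus == "MHC2ex2"
        assert res.identity == pytest.approx(0.75, abs=0.02)

    def test_empty_read_rejected(self, references):
        with pytest.raises(ValueError):
            assign_locus(mkread(""), references)

    def test_identity_agrees_with_dp_oracle_on_toys(self):
        rng = np.random.default_rng(7)
        ref = "".join(rng.choice(list("ACGT"), 36))
        for seed in range(10):
            r2 = np.random.default_rng(seed)
            read = list(ref)
            for p in r2.choice(36, size=int(r2.integers(0, 8)), replace=False):
                read[p] = r2.choice([b for b in "ACGT" if b != read[p]])
            read = "".join(read)
            res = assign_locus(mkread(read), {"toy": ref}, min_identity=0.0)
            _, oracle_identity = nw_align_score(ref, read)
            assert res.identity == pytest.approx(oracle_identity, abs=1e-9)


class TestDereplicate:
    def test_counting_and_order(self):
        reads = (
            [(mkread("AAAA", f"a{i}"), "L", "AAAA") for i in range(6)]
            + [(mkread("CCCC", f"c{i}"), "L", "CCCC") for i in range(3)]
            + [(mkread("GGGG", "g0"), "L", "GGGG")]
        )
        variants = dereplicate(reads)
        assert [(v.sequence, v.total_count) for v in variants] == [
            ("AAAA", 6),
            ("CCCC", 3),
            ("GGGG", 1),
        ]

    def test_quality_does_not_split_variants(self):
        reads = [
            (mkread("AAAA", "r1", q=40), "L", "AAAA"),
            (mkread("AAAA", "r2", q=10), "L", "AAAA"),
        ]
        assert len(dereplicate(reads)) == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        reads = [
            (mkread(s, f"r{i}", barcode=f"b{i % 3}"), "L", s)
            for i, s in enumerate(rng.choice(["AAAA", "CCCC", "GGGG"], 30))
        ]
        v1 = dereplicate(reads)
        rng.shuffle(reads)
        v2 = dereplicate(reads)
        assert [(v.sequence, v.counts) for v in v1] == [(v.sequence, v.counts) for v in v2]


class TestSingletons:
    def test_removed_everywhere_vs_per_barcode(self):
        v_gone = Variant("AAAA", "L", {"b1": 1}, {"b1": ["r1"]})
        v_partial = Variant("CCCC", "L", {"b1": 1, "b2": 5}, {"b1": ["r2"], "b2": ["r3"] * 5})
        out = drop_singletons([v_gone, v_partial])
        assert len(out) == 1
        assert out[0].counts == {"b2": 5}

    def test_fixture_counts(self):
        vs = [
            Variant(s, "L", {"b1": c})
            for s, c in zip(["AA", "CC", "GG", "TT", "AC"], [3, 2, 1, 1, 2])
        ]
        assert len(drop_singletons(vs)) == 3

    def test_global_scope(self):
        v = Variant("AAAA", "L", {"b1": 1, "b2": 1})
        assert drop_singletons([v], scope="global") == [v]
        assert drop_singletons([Variant("AAAA", "L", {"b1": 1})], scope="global") == []

    def test_idempotent(self):
        vs = [Variant("AA", "L", {"b1": 2, "b2": 1}), Variant("CC", "L", {"b1": 1})]
        once = drop_singletons(vs)
        twice = drop_singletons(once)
        assert [(v.sequence, v.counts) for v in once] == [
            (v.sequence, v.counts) for v in twice
        ]


class TestQualityFilter:
    def test_all_high_retained(self):
        assert len(filter_quality([mkread("A" * 100, q=40)])) == 1

    def test_fraction_below_threshold_removed(self):
        quals = [10] * 60 + [40] * 201
        assert filter_quality([mkread("A" * 261, q=quals)]) == []

    def test_boundary_exact_retained(self):
        quals = [40] * 208 + [10] * 52  # 208/260 = 0.80
        assert len(filter_quality([mkread("A" * 260, q=quals)])) == 1

    def test_missing_qualities(self):
        read = mkread("ACGT")
        with pytest.raises(ValueError):
            filter_quality([read])
        with pytest.warns(UserWarning):
            assert filter_quality([read], allow_missing=True) == [read]


class TestFrameshiftFilter:
    def test_one_bp_deletion_removed_three_bp_retained(self, references):
        ref = references["MHC2ex2"]
        del1 = ref[:100] + ref[101:]
        del3 = ref[:100] + ref[103:]
        vs = [
            Variant(ref, "MHC2ex2", {"b1": 5}),
            Variant(del1, "MHC2ex2", {"b1": 5}),
            Variant(del3, "MHC2ex2", {"b1": 5}),
        ]
        out = filter_frameshift(vs, references)
        assert [v.sequence for v in out] == [ref, del3]

    def test_insertions_also_checked(self, references):
        ref = references["MHC2ex2"]
        ins2 = ref[:100] + "AC" + ref[100:]
        out = filter_frameshift([Variant(ins2, "MHC2ex2", {"b1": 2})], references)
        assert out == []


@pytest.fixture(scope="module")
def noiseless():
    config = SimulationConfig(
        n_populations=3,
        individuals_per_population=5,
        depth_per_individual=8,
        substitution_error_rate=0.0,
        homopolymer_indel_rate=0.0,
        chimera_rate=0.0,
        theta=8.0,
        pool_size=30,
        seed=11,
    )
    reads, truth, manifest = simulate_study(config)
    return config, reads, truth, manifest


class TestPipeline:
    def test_truth_recovery_on_noiseless_reads(self, noiseless, references):
        config, reads, truth, manifest = noiseless
        flat = [r for rs in reads.values() for r in rs]
        variants, report = run_qc_pipeline(flat, references, set(manifest.barcodes))
        for bc in config.barcodes:
            for locus in references:
                truth_counts = truth.true_allele_counts(bc, locus)
                expected = {s for s, c in truth_counts.items() if c >= 2}
                got = {v.sequence for v in variants if v.locus == locus and bc in v.counts}
                assert got == expected

    def test_report_monotone_attrition(self, noiseless, references):
        _, reads, _, manifest = noiseless
        flat = [r for rs in reads.values() for r in rs]
        _, report = run_qc_pipeline(flat, references, set(manifest.barcodes))
        frame = report.to_frame()
        for unit in ("reads", "variants"):
            totals = frame[frame.unit == unit]["total"].tolist()
            assert totals == sorted(totals, reverse=True)
        assert 0 < report.retained_fraction <= 1

    def test_unknown_barcode_is_hard_error(self, references):
        read = Read("r1", "mystery", references["MHC2ex2"], [40] * 270)
        with pytest.raises(ValueError, match="mystery"):
            run_qc_pipeline([read], references, manifest_barcodes={"bc1"})

    def test_homopolymer_and_chimera_artifacts_removed(self, references):
        config = SimulationConfig(
            n_populations=2,
            individuals_per_population=6,
            depth_per_individual=12,
            substitution_error_rate=0.0,
            homopolymer_indel_rate=0.01,
            chimera_rate=0.01,
            theta=8.0,
            pool_size=24,
            seed=3,
            coastline_positions=(0.0, 500.0),
        )
        reads, truth, manifest = simulate_study(config)
        flat = [r for rs in reads.values() for r in rs]
        variants, _ = run_qc_pipeline(flat, references, set(manifest.barcodes))
        true_seqs = {
            locus: {s for bc in config.barcodes for s in truth.true_allele_sequences(bc, locus)}
            for locus in references
        }
        false_variants = [
            v for v in variants if v.sequence not in true_seqs[v.locus]
        ]
        assert false_variants == []
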