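import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from multisnp._seq import decode, encode, revcomp_str
from multisnp.simulate import (QualityModel, ReferenceGenome, TemplateSpec,
                               build_template, inject_variation, pair_count,
                               read_truth, sample_pe_reads)


class TestBuildTemplate:
    def test_zero_divergence_copies_identical(self):
        g = build_template(TemplateSpec(unit_length=500, copies=2,
                                        inter_copy_divergence=0.0, seed=7))
        s = g["template"]
        assert len(s) == 1000
        assert s[:500] == s[500:]

    def test_single_copy_length(self):
        g = build_template(TemplateSpec(unit_length=321, copies=1,
                                        inter_copy_divergence=0.5, seed=7))
        assert g.total_length == 321

    def test_divergence_matches_binomial_expectation(self):
        # Hamming distance between copies ~ Binomial(n, divergence)
        n, div = 10_000, 0.05
        dists = []
        for seed in range(5):
            g = build_template(TemplateSpec(unit_length=n, copies=2,
                                            inter_copy_divergence=div, seed=seed))
            a, b = g["template"][:n], g["template"][n:]
            dists.append(sum(x != y for x, y in zip(a, b)))
        sd = math.sqrt(n * div * (1 - div))
        assert abs(np.mean(dists) - n * div) < 3 * sd / math.sqrt(len(dists))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TemplateSpec(unit_length=0)
        with pytest.raises(ValueError):
            TemplateSpec(unit_length=10, inter_copy_divergence=1.5)

    def test_gc_fraction_respected(self):
        g = build_template(TemplateSpec(unit_length=50_000, gc_fraction=0.6, seed=3))
        s = g["template"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 0.6) < 0.01


class TestInjectVariation:
    def test_zero_rates_identity(self):
        g = build_template(TemplateSpec(unit_length=400, seed=1))
        sample = inject_variation(g, 0.0, 0.0, seed=2)
        h1, h2 = sample.haplotypes["template"]
        assert decode(h1) == g["template"] == decode(h2)
        assert sample.truth == []

    def test_single_locus_forced_het(self):
        g = ReferenceGenome({"s": "A"})
        sample = inject_variation(g, 1.0, 0.0, seed=5)
        (t,) = sample.truth
        assert t.zygosity == "het" and t.pos == 0 and t.ref == "A"
        h1, h2 = sample.haplotypes["s"]
        assert h1[0] != h2[0]
        assert "A" in t.genotype and t.genotype != "AA"
        # exactly one haplotype carries the alternative
        assert (decode(h1) == "A") != (decode(h2) == "A")

    def test_truth_entries_consistent_with_haplotypes(self):
        g = build_template(TemplateSpec(unit_length=4000, seed=1))
        sample = inject_variation(g, 0.01, 0.01, seed=9)
        h1, h2 = sample.haplotypes["template"]
        truth_pos = set()
        for t in sample.truth:
            truth_pos.add(t.pos)
            b1, b2 = decode(h1[t.pos:t.pos + 1]), decode(h2[t.pos:t.pos + 1])
            assert "".join(sorted(b1 + b2)) == t.genotype
            assert t.genotype != t.ref * 2
            if t.zygosity == "het":
                assert b1 != b2
            else:
                assert b1 == b2 != t.ref
        # all other loci are reference on both haplotypes
        ref = g.encoded("template")
        untouched = np.ones(len(ref), dtype=bool)
        untouched[list(truth_pos)] = False
        assert np.array_equal(h1[untouched], ref[untouched])
        assert np.array_equal(h2[untouched], ref[untouched])

    def test_mean_variant_count(self):
        # mean over replicates within 3*sigma/sqrt(R) of (het+hom)*|G|
        g = build_template(TemplateSpec(unit_length=20_000, seed=0))
        rate = 0.001
        counts = [len(inject_variation(g, rate / 2, rate / 2, seed=s).truth)
                  for s in range(20)]
        expected = rate * g.total_length
        sigma = math.sqrt(g.total_length * rate * (1 - rate))
        assert abs(np.mean(counts) - expected) < 3 * sigma / math.sqrt(len(counts))

    def test_invalid_rates(self):
        g = ReferenceGenome({"s": "ACGT"})
        with pytest.raises(ValueError):
            inject_variation(g, -0.1, 0.0)
        with pytest.raises(ValueError):
            inject_variation(g, 0.7, 0.7)


class TestSamplePEReads:
    @pytest.mark.parametrize("coverage,glen,rl,expected", [
        (50, 94_678, 36, 65_748),   # floor(50*94678/72)
        (10, 1000, 36, 138),
        (1, 72, 36, 1),
    ])
    def test_pair_count_formula(self, coverage, glen, rl, expected):
        assert pair_count(coverage, glen, rl) == expected

    def test_error_free_reads_are_haplotype_substrings(self):
        g = build_template(TemplateSpec(unit_length=2000, seed=4))
        sample = inject_variation(g, 0.005, 0.005, seed=5)
        reads = sample_pe_reads(sample, coverage=5, read_len=36, error_rate=0.0, seed=6)
        haps = [sample.haplotype_str("template", 0), sample.haplotype_str("template", 1)]
        for rid, mate, seq, qual in reads.records():
            assert len(seq) == len(qual) == 36
        for i in range(len(reads)):
            s = int(reads.origin_start[i])
            txt = decode(reads.seqs[i])
            if reads.origin_strand[i] == "-":
                txt = revcomp_str(txt)
            assert any(h[s:s + 36] == txt for h in haps)

    def test_empirical_error_rate(self):
        g = build_template(TemplateSpec(unit_length=12_000, copies=1, seed=4))
        sample = inject_variation(g, 0.0, 0.0, seed=5)
        rate = 0.001
        reads = sample_pe_reads(sample, coverage=100, read_len=36,
                                error_rate=rate, seed=8)
        total = 0
        mism = 0
        hap = sample.haplotypes["template"][0]
        for i in range(len(reads)):
            s = int(reads.origin_start[i])
            seq = reads.seqs[i]
            if reads.origin_strand[i] == "-":
                seq = encode(revcomp_str(decode(seq)))
            mism += int((seq != hap[s:s + 36]).sum())
            total += 36
        assert total >= 1_000_000
        sd = math.sqrt(total * rate * (1 - rate))
        assert abs(mism - total * rate) < 3 * sd

    def test_mates_share_ids_and_orientation(self):
        g = build_template(TemplateSpec(unit_length=3000, seed=4))
        sample = inject_variation(g, 0.0, 0.0, seed=5)
        reads = sample_pe_reads(sample, coverage=2, seed=6)
        assert len(reads) % 2 == 0
        for i in range(0, len(reads), 2):
            assert reads.ids[i] == reads.ids[i + 1]
            assert (reads.mate[i], reads.mate[i + 1]) == (1, 2)
            span = int(reads.origin_start[i + 1]) + 36 - int(reads.origin_start[i])
            assert 36 <= span <= 3000

    def test_insert_distribution(self):
        g = build_template(TemplateSpec(unit_length=20_000, seed=4))
        sample = inject_variation(g, 0.0, 0.0, seed=5)
        reads = sample_pe_reads(sample, coverage=10, insert_mean=250,
                                insert_sd=30, seed=6)
        spans = (reads.origin_start[1::2] + 36 - reads.origin_start[0::2])
        n = len(spans)
        assert abs(spans.mean() - 250) < 3 * 30 / math.sqrt(n)

    def test_degenerate_genome_rejected(self):
        g = ReferenceGenome({"s": "ACGTACGTAC"})
        sample = inject_variation(g, 0.0, 0.0, seed=1)
        with pytest.raises(RuntimeError):
            sample_pe_reads(sample, coverage=5, read_len=8,
                            insert_mean=500, insert_sd=1, seed=2)

    def test_seed_streams_reproducible_and_independent(self):
        g = build_template(TemplateSpec(unit_length=2000, seed=4))
        sample = inject_variation(g, 0.001, 0.001, seed=5)
        r1 = sample_pe_reads(sample, coverage=3, seed=11)
        r2 = sample_pe_reads(sample, coverage=3, seed=11)
        assert np.array_equal(r1.seqs, r2.seqs)
        assert np.array_equal(r1.quals, r2.quals)
        r3 = sample_pe_reads(sample, coverage=3, seed=12)
        assert not np.array_equal(r1.seqs, r3.seqs)


class TestQualityModel:
    def test_cycle_means_without_clipping(self):
        qm = QualityModel()
        rng = np.random.default_rng(0)
        q = qm.sample(20_000, 36, rng, clip=False)
        se = qm.position_sd / math.sqrt(20_000)
        for c in (0, 17, 35):
            assert abs(q[:, c].mean() - qm.position_means[c]) < 3 * se + 0.5

    def test_clipping_bounds(self):
        qm = QualityModel()
        rng = np.random.default_rng(0)
        q = qm.sample(5000, 36, rng)
        assert q.min() >= 2 and q.max() <= 40

    def test_interpolation_for_other_lengths(self):
        qm = QualityModel()
        m72 = qm.means_for_length(72)
        assert len(m72) == 72
        assert m72[0] == qm.position_means[0]
        assert m72[-1] == qm.position_means[-1]
        assert all(np.diff(m72) < 3)  # smooth profile, no jumps

    @given(st.integers(min_value=2, max_value=200))
    def test_interpolated_means_within_profile_range(self, read_len):
        qm = QualityModel()
        m = qm.means_for_length(read_len)
        assert m.min() >= qm.position_means.min() - 1e-9
        assert m.max() <= qm.position_means.max() + 1e-9


class TestIO:
    def test_fasta_truth_fastq_round_trip(self, tmp_path):
        g = build_template(TemplateSpec(unit_length=500, seed=1))
        g.to_fasta(tmp_path / "ref.fasta")
        g2 = ReferenceGenome.from_fasta(tmp_path / "ref.fasta")
        assert g2.sequences == g.sequences
        sample = inject_variation(g, 0.01, 0.01, seed=2)
        sample.write_truth(tmp_path / "truth.tsv")
        truth = read_truth(tmp_path / "truth.tsv")
        assert [(t.seq_name, t.pos, t.ref, t.genotype, t.zygosity) for t in truth] \
            == [(t.seq_name, t.pos, t.ref, t.genotype, t.zygosity) for t in sample.truth]
        reads = sample_pe_reads(sample, coverage=2, seed=3)
        paths = reads.to_fastq(str(tmp_path / "reads"))
        assert sorted(p.split("reads")[-1] for p in paths) == ["_1.fastq", "_2.fastq"]
        from Bio import SeqIO
        recs = list(SeqIO.parse(str(tmp_path / "reads_1.fastq"), "fastq"))
        assert len(recs) == len(reads) // 2
        assert str(recs[0].seq) == decode(reads.seqs[0])
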