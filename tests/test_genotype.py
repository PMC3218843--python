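import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from multisnp.genotype import (GENOTYPES, ModelParams, call_variants,
                               effective_threshold, genotype_prior,
                               information_diagnostic, locus_posterior, p_bin,
                               p_read, q_score, read_likelihood,
                               read_template_prob)
from multisnp.readmap import OtherContext, PileupColumn, PileupEntry


def _entry(base="A", qual=30, read_len=36, offset=10, mismatch_offsets=(),
           multiplicity=1, others=None, quals=None):
    q = np.full(read_len, qual, dtype=np.int16) if quals is None else np.asarray(quals)
    return PileupEntry(base=base, qual=qual, quals=q, offset=offset,
                       mismatch_offsets=tuple(mismatch_offsets),
                       multiplicity=multiplicity, others=others or [])


class TestPBin:
    def test_printed_value(self):
        assert p_bin(36, 0, 0.0003) == pytest.approx((1 - 0.0003) ** 36, rel=1e-12)
        assert p_bin(36, 0, 0.0003) == pytest.approx(0.98926, abs=1e-5)

    def test_error_free_limit(self):
        assert p_bin(20, 0, 1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_coin(self):
        assert p_bin(2, 1, 0.5) == pytest.approx(0.5)

    def test_invalid(self):
        with pytest.raises(ValueError):
            p_bin(10, 0, 0.0)
        with pytest.raises(ValueError):
            p_bin(10, 11, 0.1)


class TestPRead:
    def test_two_matches(self):
        assert p_read([30, 30], ()) == pytest.approx(0.999 ** 2, rel=1e-12)

    def test_match_and_mismatch(self):
        assert p_read([30, 30], (1,)) == pytest.approx(0.999 * 0.001 / 3, rel=1e-12)

    def test_high_quality_limit(self):
        assert p_read([90] * 10, ()) == pytest.approx(1.0, abs=1e-8)

    def test_negative_quality_rejected(self):
        with pytest.raises(ValueError):
            p_read([-1, 30], ())


class TestMixture:
    def test_lambda_extremes(self):
        quals = [30] * 36
        full_read = ModelParams(lam=1.0)
        assert read_template_prob(quals, (3,), full_read) == \
            pytest.approx(p_read(quals, (3,)), rel=1e-12)
        full_bin = ModelParams(lam=0.0)
        assert read_template_prob(quals, (3,), full_bin) == \
            pytest.approx(p_bin(36, 1, full_bin.e), rel=1e-12)

    def test_mixture_arithmetic(self):
        # lambda=0.67 with component values (0.9, 0.8) -> 0.867
        assert 0.67 * 0.9 + (1 - 0.67) * 0.8 == pytest.approx(0.867)

    def test_orientation_switch(self):
        quals = [20] * 36
        a = read_template_prob(quals, (), ModelParams(lam=0.67, lambda_on_read=True))
        b = read_template_prob(quals, (), ModelParams(lam=0.33, lambda_on_read=False))
        assert a == pytest.approx(b, rel=1e-12)


class TestPrior:
    def test_theta_zero_point_mass(self):
        pri = genotype_prior("C", 0.0)
        assert pri["CC"] == 1.0
        assert sum(pri.values()) == pytest.approx(1.0, abs=1e-15)

    @given(st.floats(min_value=0.0, max_value=0.6))
    def test_sums_to_one(self, theta):
        pri = genotype_prior("G", theta)
        assert sum(pri.values()) == pytest.approx(1.0, abs=1e-12)

    def test_printed_hom_ref_mass(self):
        assert genotype_prior("A", 0.001)["AA"] == pytest.approx(0.998999)

    def test_class_masses(self):
        theta = 0.01
        pri = genotype_prior("A", theta)
        het1 = pri["AC"] + pri["AG"] + pri["AT"]
        hom_alt = pri["CC"] + pri["GG"] + pri["TT"]
        het2 = pri["CG"] + pri["CT"] + pri["GT"]
        assert het1 == pytest.approx(theta / 2)
        assert hom_alt == pytest.approx(theta / 2)
        assert het2 == pytest.approx(theta ** 2)

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            genotype_prior("A", 0.7)


class TestQScore:
    def test_printed_correspondences(self):
        assert q_score(1 - 1e-4) == pytest.approx(40.0, abs=1e-9)
        assert q_score(1 - 1e-9) == pytest.approx(90.0, abs=1e-6)
        assert q_score(0.0) == 0.0

    def test_cap(self):
        assert q_score(1.0) == 255.0
        assert q_score(1 - 1e-40, max_q=100.0) == 100.0

    @given(st.floats(min_value=0.0, max_value=0.999999))
    def test_strictly_monotone(self, p):
        assert q_score(p + 1e-6) > q_score(p)


class TestReadLikelihood:
    def test_unique_read_no_background(self):
        e = _entry(base="T", mismatch_offsets=(10,))
        params = ModelParams()
        # d=0 reduces to the haplotype average
        l_tt = read_likelihood(e, "TT", params)
        l_at = read_likelihood(e, "AT", params)
        l_aa = read_likelihood(e, "AA", params)
        assert l_at == pytest.approx(0.5 * l_tt + 0.5 * l_aa, rel=1e-12)

    def test_hom_genotype_collapses(self):
        e = _entry(base="G")
        params = ModelParams()
        offs_other = ()
        expected = read_template_prob(e.quals, offs_other, params)
        assert read_likelihood(e, "GG", params) == pytest.approx(expected, rel=1e-12)

    def test_likelihood_ratio_washes_out_with_d(self):
        params = ModelParams()
        prev = None
        for d in (0, 1, 10, 1000, 1_000_000):
            # background placements where the read matches the reference
            ctx = OtherContext("g", 500, "T", (), 10)
            e = _entry(base="T", mismatch_offsets=(10,), multiplicity=d + 1,
                       others=[ctx] * d)
            ratio = read_likelihood(e, "TT", params) / read_likelihood(e, "AA", params)
            if prev is not None:
                assert ratio < prev
            prev = ratio
        assert prev == pytest.approx(1.0, abs=1e-4)


class TestLocusPosterior:
    def test_zero_depth_returns_prior(self):
        col = PileupColumn("g", 5, "C", [])
        gp = locus_posterior(col, ModelParams())
        pri = genotype_prior("C", 0.001)
        for g in GENOTYPES:
            assert gp.posterior[g] == pytest.approx(pri[g], abs=1e-15)
        assert gp.map_genotype == "CC"

    def test_deep_unique_alt_column_confident(self):
        # 50 error-free unique reads all carrying T over reference A -> TT, Q > 90
        entries = [_entry(base="T", qual=40, mismatch_offsets=(10,))
                   for _ in range(50)]
        col = PileupColumn("g", 5, "A", entries)
        gp = locus_posterior(col, ModelParams())
        assert gp.map_genotype == "TT"
        assert gp.q > 90

    def test_map_tie_resolves_to_hom_ref(self):
        from multisnp.genotype import _map_genotype
        lp = {g: -1.0 for g in GENOTYPES}
        assert _map_genotype(lp, "G") == "GG"
        lp2 = {g: (-1.0 if g in ("AC", "AG") else -2.0) for g in GENOTYPES}
        assert _map_genotype(lp2, "T") == "AC"  # lexicographic among ties

    def test_posterior_normalized(self, diverged_pipeline):
        from multisnp.readmap import MappingStrategy, apply_strategy, build_pileups
        rm = apply_strategy(diverged_pipeline["alignments"], MappingStrategy("ALL"))
        params = ModelParams()
        for i, col in enumerate(build_pileups(rm, diverged_pipeline["genome"])):
            gp = locus_posterior(col, params)
            assert sum(gp.posterior.values()) == pytest.approx(1.0, abs=1e-9)
            if i > 40:
                break

    def test_entropy_nondecreasing_in_d(self):
        # symmetric reference-concordant backgrounds: more placements dilute
        # the evidence, relaxing a confident hom-ref call back toward the
        # (higher-entropy) prior
        params = ModelParams()

        def entropy(d):
            ctx = OtherContext("g", 500, "A", (), 10)
            entries = [_entry(base="A", mismatch_offsets=(),
                              multiplicity=d + 1, others=[ctx] * d)
                       for _ in range(10)]
            gp = locus_posterior(PileupColumn("g", 5, "A", entries), params)
            return -sum(p * math.log(p) for p in gp.posterior.values() if p > 0)

        ents = [entropy(d) for d in (0, 1, 5, 50, 5000)]
        assert all(b >= a - 1e-12 for a, b in zip(ents, ents[1:]))


class TestCallVariants:
    def _gp(self, map_genotype, q, n_linked=1, ref="A"):
        from multisnp.genotype import GenotypePosterior
        post = {g: 0.0 for g in GENOTYPES}
        post[map_genotype] = 1.0
        return GenotypePosterior("g", 1, ref, post, map_genotype, q, 10, 1.0,
                                 0.0, n_linked, 0.5)

    def test_hom_ref_never_significant(self):
        calls = call_variants([self._gp("AA", 200.0)], ModelParams())
        assert not calls[0].significant

    def test_unique_locus_threshold(self):
        calls = call_variants([self._gp("AT", 45.0)], ModelParams(q_threshold=40))
        assert calls[0].significant
        assert calls[0].effective_threshold == 40.0

    def test_degeneracy_corrected_threshold(self):
        # linked to 9 other loci: threshold 40 -> 50; Q=45 not significant
        gp = self._gp("AT", 45.0, n_linked=10)
        calls = call_variants([gp], ModelParams(q_threshold=40))
        assert calls[0].effective_threshold == pytest.approx(50.0)
        assert not calls[0].significant
        off = call_variants([gp], ModelParams(q_threshold=40,
                                              degeneracy_correction=False))
        assert off[0].significant

    def test_effective_threshold_formula(self):
        assert effective_threshold(40, 1) == 40
        assert effective_threshold(40, 10) == pytest.approx(50.0)
        assert effective_threshold(13, 100) == pytest.approx(33.0)


class TestInformationDiagnostic:
    def test_equal_likelihoods_even_odds(self):
        for n, d in [(1, 0), (10, 5), (100, 1000)]:
            assert information_diagnostic(n, d, 0.3, 0.3) == 0.0

    def test_increasing_in_depth(self):
        vals = [information_diagnostic(n, 2, 0.9, 0.1) for n in (1, 5, 20, 100)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_decreasing_in_d_to_zero(self):
        vals = [information_diagnostic(10, d, 0.9, 0.1, c=0.5)
                for d in (0, 1, 10, 100, 10_000)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(0.0, abs=1e-2)
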