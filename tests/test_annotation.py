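import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiregnet.annotation import (AnnotationConfig, ChromatinTrackSet,
                                  ElementClass, GenicContext, allele_bias,
                                  annotate, annotate_all, classify_element,
                                  genic_context, pwm_delta)
from epiregnet.core import PWM, GeneModel, GenomicInterval, IntervalSet, Variant

from oracles import allele_bias_oracle, pwm_delta_oracle

IV = GenomicInterval


def trackset(**kwargs) -> ChromatinTrackSet:
    ts = ChromatinTrackSet()
    for name, intervals in kwargs.items():
        target = getattr(ts, name)
        for item in intervals:
            if isinstance(item, tuple):
                target.add(*item)
            else:
                target.add(item)
    return ts


class TestClassifyElement:
    def test_k27ac_with_k4me1_is_enhancer(self):
        ts = trackset(h3k27ac=[IV("chr1", 100, 300)],
                      h3k4me1=[IV("chr1", 120, 280)])
        assert classify_element(IV("chr1", 150, 160), ts) \
            is ElementClass.ENHANCER

    def test_k27ac_with_k4me3_is_promoter(self):
        ts = trackset(h3k27ac=[IV("chr1", 100, 300)],
                      h3k4me3=[IV("chr1", 120, 280)])
        assert classify_element(IV("chr1", 150, 160), ts) \
            is ElementClass.PROMOTER

    def test_promoter_wins_when_both_marks_fire(self):
        ts = trackset(h3k27ac=[IV("chr1", 0, 500)],
                      h3k4me1=[IV("chr1", 0, 500)],
                      h3k4me3=[IV("chr1", 0, 500)])
        assert classify_element(IV("chr1", 10, 20), ts) \
            is ElementClass.PROMOTER

    def test_no_overlap_is_unclassified(self):
        assert classify_element(IV("chr1", 0, 10), trackset()) \
            is ElementClass.UNCLASSIFIED
        ts = trackset(h3k4me1=[IV("chr1", 0, 100)])  # no H3K27ac
        assert classify_element(IV("chr1", 0, 10), ts) \
            is ElementClass.UNCLASSIFIED

    def test_min_overlap_enforced(self):
        ts = trackset(h3k27ac=[IV("chr1", 0, 100)],
                      h3k4me1=[IV("chr1", 95, 200)])
        iv = IV("chr1", 90, 100)  # 10 bp of k27ac but 5 bp of k4me1
        assert classify_element(iv, ts, min_overlap_bp=6) \
            is ElementClass.UNCLASSIFIED
        assert classify_element(iv, ts, min_overlap_bp=5) \
            is ElementClass.ENHANCER

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_adding_peaks_never_unclassifies(self, data):
        """Monotonicity: extra peaks can only add evidence."""
        def peaks(n):
            out = []
            for _ in range(n):
                start = data.draw(st.integers(0, 200))
                out.append(IV("chr1", start,
                              start + data.draw(st.integers(1, 100))))
            return out

        base = dict(h3k27ac=peaks(data.draw(st.integers(0, 2))),
                    h3k4me1=peaks(data.draw(st.integers(0, 2))),
                    h3k4me3=peaks(data.draw(st.integers(0, 2))))
        iv = IV("chr1", data.draw(st.integers(0, 250)), 260)
        before = classify_element(iv, trackset(**base))
        extra = data.draw(st.sampled_from(["h3k27ac", "h3k4me1", "h3k4me3"]))
        base[extra] = base[extra] + peaks(1)
        after = classify_element(iv, trackset(**base))
        if before is not ElementClass.UNCLASSIFIED:
            assert after is not ElementClass.UNCLASSIFIED


class TestGenicContext:
    GENES = [
        GeneModel("chr1", 10_000, 20_000, "+", "GENE_A",
                  ((10_000, 11_000), (19_000, 20_000))),
        GeneModel("chr1", 50_000, 55_000, "-", "GENE_B", ((50_000, 55_000),)),
    ]

    def case(self, pos):
        return genic_context(Variant("chr1", pos + 1, "A", "C"), self.GENES)

    def test_intronic(self):
        assert self.case(15_000) is GenicContext.INTRONIC

    def test_exonic_beats_intronic(self):
        assert self.case(10_500) is GenicContext.EXONIC

    def test_five_prime_upstream_plus_strand(self):
        assert self.case(9_000) is GenicContext.FIVE_PRIME

    def test_five_prime_respects_minus_strand(self):
        # 1 kb beyond the right edge of a minus-strand gene is upstream
        assert self.case(56_000) is GenicContext.FIVE_PRIME

    def test_three_prime_downstream(self):
        assert self.case(21_000) is GenicContext.THREE_PRIME

    def test_intergenic_far_away(self):
        assert self.case(900_000) is GenicContext.INTERGENIC

    def test_flank_is_configurable(self):
        v = Variant("chr1", 9_001, "A", "C")
        assert genic_context(v, self.GENES, tss_flank_bp=500) \
            is GenicContext.INTERGENIC


def random_instance(rng, motif_len=None):
    seq_len = int(rng.integers(7, 16))
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, seq_len))
    offset = int(rng.integers(0, seq_len))
    ref = seq[offset]
    alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
    L = motif_len or int(rng.integers(2, 6))
    counts = rng.integers(0, 12, size=(L, 4)).astype(float)
    pwm = PWM.from_counts(f"m{L}", counts)
    v = Variant("chr1", 1000 + offset + 1, ref, alt, "rsT")
    return v, seq, offset, pwm


class TestPwmDelta:
    def test_matches_exhaustive_rescan_on_printed_toy(self):
        """4-bp motif against a 9-bp sequence, checked against the
        brute-force window x strand x allele enumeration."""
        seq = "ACGTAGCTA"
        pwm = PWM.from_counts("toy", np.array(
            [[8, 1, 1, 1], [1, 8, 1, 1], [1, 1, 8, 1], [1, 1, 1, 8]],
            dtype=float))
        v = Variant("chr1", 1005, "A", "G", "rsToy")  # offset 4 in seq
        hit = pwm_delta(v, seq, pwm, var_offset=4)
        expected = pwm_delta_oracle(seq, 4, "A", "G",
                                    pwm.matrix.tolist(),
                                    pwm.background.tolist())
        assert hit.delta == pytest.approx(expected, abs=1e-12)

    def test_agreement_with_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            v, seq, offset, pwm = random_instance(rng)
            hit = pwm_delta(v, seq, pwm, var_offset=offset)
            expected = pwm_delta_oracle(seq, offset, v.ref_allele,
                                        v.alt_allele, pwm.matrix.tolist(),
                                        pwm.background.tolist())
            assert hit.delta == pytest.approx(expected, abs=1e-10)

    def test_antisymmetric_under_allele_swap(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            v, seq, offset, pwm = random_instance(rng)
            swapped = Variant(v.seq_id, v.pos, v.alt_allele, v.ref_allele,
                              v.id)
            d1 = pwm_delta(v, seq, pwm, var_offset=offset).delta
            d2 = pwm_delta(swapped, seq, pwm, var_offset=offset).delta
            assert d1 == pytest.approx(-d2, abs=1e-12)

    def test_motif_longer_than_sequence_gives_zero(self):
        pwm = PWM.from_counts("long", np.ones((10, 4)))
        v = Variant("chr1", 3, "C", "G")
        assert pwm_delta(v, "ACT", pwm, var_offset=2).delta == 0.0

    def test_indel_rejected(self):
        pwm = PWM.from_counts("m", np.ones((2, 4)))
        v = Variant("chr1", 5, "AC", "A")
        with pytest.raises(ValueError, match="SNV"):
            pwm_delta(v, "AAACCC", pwm, var_offset=2)


class TestAlleleBias:
    def test_zero_weights_zero_bias(self):
        v = Variant("chr1", 3, "G", "T")
        assert allele_bias(v, "AAGAA", {}, k=2, var_offset=2) == 0.0

    def test_matches_hand_enumerated_kmer_sum(self):
        """k=2 toy table over a 5-bp sequence."""
        seq = "ACGTA"
        weights = {"AC": 1.0, "CG": 2.0, "GT": 4.0, "CT": 8.0, "CC": 16.0,
                   "TA": 32.0, "CA": 64.0}
        v = Variant("chr1", 1003, "G", "C", "rsK")  # offset 2
        # ref window "CGT" -> CG + GT = 6 ; alt window "CCT" -> CC + CT = 24
        got = allele_bias(v, seq, weights, k=2, var_offset=2)
        assert got == pytest.approx(24.0 - 6.0)
        assert got == pytest.approx(
            allele_bias_oracle(seq, 2, "G", "C", weights, 2))

    def test_agreement_with_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            v, seq, offset, _ = random_instance(rng)
            k = int(rng.integers(1, 5))
            kmers = {"".join("ACGT"[i] for i in rng.integers(0, 4, k)): float(w)
                     for w in rng.normal(0, 1, size=20)}
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = allele_bias(v, seq, kmers, k=k, var_offset=offset)
            assert got == pytest.approx(
                allele_bias_oracle(seq, offset, v.ref_allele, v.alt_allele,
                                   kmers, k), abs=1e-12)

    def test_linear_in_the_weight_table(self):
        rng = np.random.default_rng(11)
        v, seq, offset, _ = random_instance(rng)
        k = 3
        all_kmers = ["".join("ACGT"[i] for i in rng.integers(0, 4, k))
                     for _ in range(30)]
        w1 = {m: float(rng.normal()) for m in all_kmers[:20]}
        w2 = {m: float(rng.normal()) for m in all_kmers[10:]}
        combined = {m: w1.get(m, 0.0) + w2.get(m, 0.0)
                    for m in set(w1) | set(w2)}
        b1 = allele_bias(v, seq, w1, k, var_offset=offset)
        b2 = allele_bias(v, seq, w2, k, var_offset=offset)
        assert allele_bias(v, seq, combined, k, var_offset=offset) \
            == pytest.approx(b1 + b2, abs=1e-12)

    def test_truncation_warns(self):
        v = Variant("chr1", 1, "A", "C")
        with pytest.warns(UserWarning, match="truncated"):
            allele_bias(v, "AAT", {"AA": 1.0}, k=2, var_offset=0)


class TestAnnotate:
    def test_methylated_closed_chromatin_is_never_causal(self):
        ts = trackset(h3k27ac=[IV("chr1", 0, 200)],
                      h3k4me3=[IV("chr1", 0, 200)],
                      methylation=[(IV("chr1", 0, 200), 0.95)])
        v = Variant("chr1", 100, "A", "C", "rsM")
        report = annotate(v, ts, genes=[])
        assert not report.open_chromatin
        assert not report.methylation_ok
        assert not report.causal_call
        assert report.element_class is ElementClass.PROMOTER

    def test_unknown_sequence_reports_empty_evidence(self, caplog):
        ts = trackset(dnase=[IV("chr1", 0, 100)])
        v = Variant("chrZ", 10, "A", "C", "rsZ")
        report = annotate(v, ts, genes=[])
        assert not report.causal_call
        assert report.hic_degree == 0

    def test_closed_loop_on_noise_free_fixture(self, sim_small):
        """Planted causal variants and only those are called."""
        data = sim_small
        reports = annotate_all(data.variants, data.tracks, data.genes,
                               pwms=data.pwms, weights=data.kmer_weights,
                               contacts=data.contacts,
                               config=AnnotationConfig(),
                               sequences=data.genome)
        called = {r.variant.id for r in reports if r.causal_call}
        assert called == set(data.truth.causal_variant_ids)

    def test_annotation_is_deterministic(self, sim_small):
        data = sim_small
        args = (data.tracks, data.genes)
        kwargs = dict(pwms=data.pwms, weights=data.kmer_weights,
                      contacts=data.contacts, config=AnnotationConfig(),
                      sequences=data.genome)
        first = annotate_all(data.variants[:10], *args, **kwargs)
        second = annotate_all(data.variants[:10], *args, **kwargs)
        assert first == second
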