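import math

import numpy as np
import pytest

from epiregnet.core import ExpressionRecord, GeneModel, GenomicInterval, \
    IntervalSet
from epiregnet.network import (adjust_batch, bh_adjust, build_network,
                               classify_tf_direction_bias, direct_tf_closure,
                               fisher_exact_2x2, hot_overlap,
                               identify_master_tfs, node_degree,
                               regulon_coverage, select_differential,
                               tf_overlap_fraction)

from oracles import fisher_two_sided_oracle

ER = ExpressionRecord


class TestSelectDifferential:
    RECORDS = [ER("NR6A1", 1.75, 0.01), ER("FGF7", -3.2, 0.01),
               ER("FLAT", 0.0, 1.0), ER("WEAK", 0.5, 0.001),
               ER("NOISY", 2.5, 0.5)]

    def test_thresholding(self):
        de = select_differential(self.RECORDS, min_abs_log2fc=1.0, max_p=0.05)
        assert de.up == {"NR6A1"}
        assert de.down == {"FGF7"}
        assert de.universe == {"NR6A1", "FGF7", "FLAT", "WEAK", "NOISY"}

    def test_zero_fold_change_in_neither_set(self):
        de = select_differential([ER("G", 1e-300, 0.001)], 0.5, 0.05)
        assert de.de == frozenset()

    def test_duplicate_keeps_smallest_p(self, caplog):
        de = select_differential([ER("X", 2.0, 0.5), ER("X", -2.0, 0.001)],
                                 1.0, 0.05)
        assert de.down == {"X"} and len(de.universe) == 1


class TestFisherExact:
    def test_two_by_two_enumeration_example(self):
        # margins (2,2,2,2): three tables, the diagonal one has p = 1/6;
        # only its mirror ties it, so the two-sided p is 1/3
        _, p = fisher_exact_2x2(2, 0, 0, 2)
        assert p == pytest.approx(1 / 3, rel=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 1, 1, 1)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_odds_ratio_conventions(self):
        odds, _ = fisher_exact_2x2(5, 0, 2, 3)
        assert math.isinf(odds)
        odds, _ = fisher_exact_2x2(1, 4, 2, 4)
        assert odds == pytest.approx(0.5)

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 11, size=4).tolist()
            if a + b + c + d == 0:
                continue
            _, p = fisher_exact_2x2(a, b, c, d)
            expected = fisher_two_sided_oracle(a, b, c, d)
            assert p == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_transposition(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 12, size=4).tolist()
            if a + b + c + d == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d)[1] == pytest.approx(
                fisher_exact_2x2(a, c, b, d)[1], rel=1e-12)
            assert fisher_exact_2x2(a, b, c, d)[1] == pytest.approx(
                fisher_exact_2x2(d, c, b, a)[1], rel=1e-12)


class TestBhAdjustment:
    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, size=200)
        q = bh_adjust(p)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_batch_adjustment_attaches_q(self):
        _, p1 = fisher_exact_2x2(8, 2, 2, 8)
        _, p2 = fisher_exact_2x2(5, 5, 5, 5)
        from epiregnet.network import EnrichmentResult

        batch = adjust_batch([EnrichmentResult("x", 8, 2, 2, 8, 16.0, p1),
                              EnrichmentResult("y", 5, 5, 5, 5, 1.0, p2)])
        assert batch[0].q_bh <= batch[1].q_bh <= 1.0


EDGES = [("TF1", "A", "+"), ("TF1", "B", "-"), ("TF1", "C", "+"),
         ("TF2", "C", "+"), ("TF2", "D", "+")]


def de_set(up, down, universe):
    return select_differential(
        [ER(g, 2.0, 0.001) for g in up]
        + [ER(g, -2.0, 0.001) for g in down]
        + [ER(g, 0.0 + 1e-12, 1.0) for g in universe
           if g not in up and g not in down])


class TestRegulonCoverage:
    def test_full_coverage(self):
        de = de_set({"A"}, {"B"}, {"A", "B", "C", "D", "E"})
        fraction, result = regulon_coverage("TF1", EDGES, de)
        assert fraction == 1.0
        assert result.a == 2

    def test_disjoint_targets_zero_coverage(self):
        de = de_set({"D"}, set(), {"A", "B", "C", "D", "E"})
        fraction, result = regulon_coverage("TF1", EDGES, de)
        assert fraction == 0.0
        assert result.odds_ratio <= 1.0 or math.isnan(result.odds_ratio)

    def test_unknown_tf_rejected(self):
        de = de_set({"A"}, set(), {"A", "B"})
        with pytest.raises(ValueError, match="no targets"):
            regulon_coverage("NOPE", EDGES, de)

    def test_empty_de_set_rejected(self):
        de = de_set(set(), set(), {"A", "B"})
        with pytest.raises(ValueError, match="empty differential"):
            regulon_coverage("TF1", EDGES, de)

    def test_coverage_is_scale_free(self):
        de = de_set({"A", "C"}, set(), {"A", "B", "C", "D", "E"})
        doubled = EDGES + EDGES
        assert regulon_coverage("TF1", EDGES, de)[0] == \
            regulon_coverage("TF1", doubled, de)[0]

    def test_planted_regulon_recovered(self, sim_default):
        data = sim_default
        de = select_differential(data.expression)
        fraction, result = regulon_coverage(data.truth.planted_tf,
                                            data.edges, de)
        assert fraction == pytest.approx(
            data.truth.planted_coverage_fraction, abs=0.02)
        assert result.p_two_sided < 1e-4


class TestDirectionBias:
    def test_perfect_separation(self):
        de = de_set(set("ABC"), set("XYZ"), set("ABCXYZ"))
        results = classify_tf_direction_bias(
            {"glial": set("XYZ"), "neuronal": set("ABC")}, de)
        assert math.isinf(results["glial"].odds_ratio)
        assert results["glial"].p_two_sided == pytest.approx(
            fisher_two_sided_oracle(3, 0, 0, 3), rel=1e-12)

    def test_empty_class_rejected(self):
        de = de_set({"A"}, set(), {"A", "B"})
        with pytest.raises(ValueError, match="empty"):
            classify_tf_direction_bias({"ghost": {"NOT_MEASURED"}}, de)

    def test_planted_bias_detected(self):
        """90% of a 30-TF class down vs 20% background over 300 TFs."""
        rng = np.random.default_rng(17)
        class_tfs = {f"C{i}" for i in range(30)}
        other_tfs = {f"O{i}" for i in range(300)}
        down = {t for t in class_tfs if rng.random() < 0.9}
        down |= {t for t in other_tfs if rng.random() < 0.2}
        up = (class_tfs | other_tfs) - down
        de = de_set(up, down, class_tfs | other_tfs)
        results = classify_tf_direction_bias(
            {"planted": class_tfs, "background": other_tfs}, de)
        assert results["planted"].p_two_sided < 1e-3


class TestMasterTfs:
    MODELS = {
        "TF_IN": GeneModel("chr1", 1000, 3000, "+", "TF_IN", ((1000, 3000),)),
        "TF_OUT": GeneModel("chr1", 50_000, 52_000, "-", "TF_OUT",
                            ((50_000, 52_000),)),
    }

    def test_overlap_with_super_enhancer(self):
        se = IntervalSet([GenomicInterval("chr1", 500, 4000)])
        masters = identify_master_tfs(["TF_IN", "TF_OUT"], se, self.MODELS)
        assert masters == {"TF_IN"}

    def test_no_super_enhancers_no_masters(self):
        assert identify_master_tfs(["TF_IN"], IntervalSet(),
                                   self.MODELS) == set()

    def test_missing_model_excluded_with_warning(self, caplog):
        se = IntervalSet([GenomicInterval("chr1", 0, 10_000_000)])
        masters = identify_master_tfs(["TF_IN", "GHOST"], se, self.MODELS)
        assert masters == {"TF_IN"}

    def test_planted_masters_recovered(self, sim_default):
        data = sim_default
        masters = identify_master_tfs(data.truth.tf_names,
                                      data.tracks.super_enhancers,
                                      data.gene_models)
        assert sorted(masters) == data.truth.master_tfs


class TestOverlapFractions:
    def test_closure_superset_is_100_percent(self):
        assert tf_overlap_fraction({"A", "B", "C"}, {"A", "B"}) == 100.0

    def test_disjoint_is_zero(self):
        assert tf_overlap_fraction({"A"}, {"B", "C"}) == 0.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            tf_overlap_fraction({"A"}, set())

    def test_exact_planted_percentage(self):
        region = {f"R{i}" for i in range(50)}
        closure = {f"R{i}" for i in range(20)} | {"EXTRA"}
        assert tf_overlap_fraction(closure, region) == pytest.approx(40.0)

    def test_direct_closure_one_hop(self):
        edges = [("A", "B", "+"), ("A", "X", "+"), ("B", "C", "+")]
        closure = direct_tf_closure({"A"}, edges, all_tfs={"A", "B", "C"})
        assert closure == {"A", "B"}  # X is not a TF; C is two hops away

    def test_hot_overlap_extremes(self):
        models = {"G1": GeneModel("chr1", 0, 100, "+", "G1", ((0, 100),))}
        whole = IntervalSet([GenomicInterval("chr1", 0, 10_000)])
        assert hot_overlap(["G1"], models, whole) == 1.0
        assert hot_overlap(["G1"], models, IntervalSet()) == 0.0

    def test_hot_background_rate_tracks_coverage(self, sim_default):
        """Random gene sets overlap HOT regions at roughly the planted
        genome fraction (genes are small relative to HOT blocks)."""
        data = sim_default
        rng = np.random.default_rng(8)
        names = [g.name for g in data.genes]
        picks = [names[i] for i in rng.choice(len(names), 400, replace=False)]
        rate = hot_overlap(picks, data.gene_models, data.tracks.hot_regions)
        expected = data.truth.hot_fraction_realized
        # binomial CI at n=400 plus edge effects of gene length
        assert abs(rate - expected) < 4 * math.sqrt(expected * (1 - expected)
                                                    / 400) + 0.03


class TestBuildNetwork:
    def test_isolated_seed_degree_zero(self):
        de = de_set(set(), set(), {"A"})
        net = build_network(de, [], seeds={"LONER"})
        assert node_degree(net, "LONER") == 0

    def test_star_degree(self):
        de = de_set({"HUB"}, set(), {"HUB"})
        edges = [("HUB", f"T{i}", "+") for i in range(23)]
        net = build_network(de, edges)
        assert node_degree(net, "HUB") == 23
        assert net.nodes["HUB"]["direction"] == "up"
        assert net.nodes["T0"]["direction"] == "unmeasured"

    def test_one_hop_expansion_only(self):
        de = de_set({"A"}, set(), {"A"})
        edges = [("A", "B", "+"), ("B", "C", "+"), ("C", "D", "+")]
        net = build_network(de, edges)
        assert set(net.nodes) == {"A", "B"}  # C and D are beyond one hop
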