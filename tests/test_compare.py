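"""FA inter-comparison: Venn partitions, cross-similarity, hPrec/hRec."""

import numpy as np
import pytest

from gofa.annotations import (
    AnnotationError,
    FunctionalAnnotation,
    GeneProductSet,
)
from gofa.compare import (
    coverage_partition,
    cross_similarity,
    flag_outliers,
    gold_comparison,
    hierarchical_precision,
    hierarchical_recall,
    release_series,
)
from gofa.fixture_constants import CANONICAL as K
from gofa.fixtures import FixtureSpec, generate_fa, generate_ontology
from gofa.metrics import UndefinedMetricError
from gofa.similarity import SimilarityError

from _oracles import hierarchical_overlap


def make_fa(fx, name, sets):
    return FunctionalAnnotation(
        name,
        fx.reference,
        {"generic": {g: frozenset(t) for g, t in sets.items()}},
    )


class TestVenn:
    def test_two_fa_partition(self, fx):
        fa1 = make_fa(fx, "one", {"g1": {"C"}, "g2": {"D"}})
        fa2 = make_fa(fx, "two", {"g2": {"E"}, "g3": {"C"}})
        part = coverage_partition([fa1, fa2])
        assert part.count((True, False)) == 1
        assert part.count((True, True)) == 1
        assert part.count((False, True)) == 1
        assert part.count((False, False)) == 2

    def test_identical_fas_all_in_both(self, fx):
        part = coverage_partition([fx.fa, fx.fa])
        assert part.count((True, True)) == 3
        assert part.count((False, False)) == 2

    def test_empty_fa_has_no_exclusive_region(self, fx):
        empty = make_fa(fx, "empty", {})
        part = coverage_partition([fx.fa, fx.gold, empty])
        for pattern, genes in part.regions.items():
            if pattern[2]:
                assert not genes

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_regions_sum_to_reference(self, fx, k):
        fas = [
            make_fa(fx, f"fa{i}", {f"g{i + 1}": {"C"}}) for i in range(k)
        ]
        part = coverage_partition(fas)
        assert sum(len(g) for g in part.regions.values()) == len(fx.reference)
        assert part.to_frame()["count"].sum() == len(fx.reference)

    def test_k_bounds_and_shared_reference(self, fx):
        with pytest.raises(AnnotationError):
            coverage_partition([fx.fa])
        other = FunctionalAnnotation("o", GeneProductSet(("zz",)), {})
        with pytest.raises(AnnotationError):
            coverage_partition([fx.fa, other])


class TestCrossSimilarity:
    def test_self_comparison_all_ones(self, fx):
        cross = cross_similarity(fx.fa, fx.fa, fx.graph)
        assert set(cross.scores.values()) == {1.0}
        assert cross.n_identical == 3

    def test_conflicting_gene_in_low_tail(self, fx):
        fa1 = make_fa(fx, "a", {"g1": {"C"}, "g2": {"C", "D"}})
        fa2 = make_fa(fx, "b", {"g1": {"E"}, "g2": {"C", "D"}})
        cross = cross_similarity(fa1, fa2, fx.graph)
        assert cross.scores["g1"] == pytest.approx(K["gs2_C_vs_E"])
        assert cross.low_tail[0][0] == "g1"

    def test_single_side_genes_absent(self, fx):
        fa1 = make_fa(fx, "a", {"g1": {"C"}, "g4": {"D"}})
        fa2 = make_fa(fx, "b", {"g1": {"C"}})
        cross = cross_similarity(fa1, fa2, fx.graph)
        assert set(cross.scores) == {"g1"}

    def test_empty_intersection_signals(self, fx):
        fa1 = make_fa(fx, "a", {"g1": {"C"}})
        fa2 = make_fa(fx, "b", {"g2": {"C"}})
        with pytest.raises(SimilarityError):
            cross_similarity(fa1, fa2, fx.graph)


class TestHierarchical:
    def test_perfect_agreement(self, fx):
        assert hierarchical_precision("g2", fx.fa, fx.gold, fx.graph,
                                      "generic") == 1.0
        assert hierarchical_recall("g2", fx.fa, fx.gold, fx.graph,
                                   "generic") == 1.0

    def test_sibling_prediction_hand_value(self, fx):
        # fa(g1) = {C}, gold(g1) = {D}
        assert hierarchical_precision(
            "g1", fx.fa, fx.gold, fx.graph, "generic"
        ) == pytest.approx(K["hprec_C_vs_D"])
        assert hierarchical_recall(
            "g1", fx.fa, fx.gold, fx.graph, "generic"
        ) == pytest.approx(K["hrec_C_vs_D"])

    def test_root_prediction_inflates_precision(self, fx):
        fa = make_fa(fx, "shallow", {"g1": {"R"}})
        gold = make_fa(fx, "gold", {"g1": {"C"}})
        assert hierarchical_precision("g1", fa, gold, fx.graph,
                                      "generic") == K["hprec_R_vs_C"]
        assert hierarchical_recall(
            "g1", fa, gold, fx.graph, "generic"
        ) == pytest.approx(K["hrec_R_vs_C"])

    def test_matches_enumeration_oracle(self, fx):
        fa = make_fa(fx, "p", {"g1": {"C", "E"}})
        gold = make_fa(fx, "g", {"g1": {"D", "B"}})
        assert hierarchical_precision(
            "g1", fa, gold, fx.graph, "generic"
        ) == pytest.approx(hierarchical_overlap({"C", "E"}, {"D", "B"}))
        assert hierarchical_recall(
            "g1", fa, gold, fx.graph, "generic"
        ) == pytest.approx(hierarchical_overlap({"D", "B"}, {"C", "E"}))

    def test_duality_on_random_fixture_fas(self, fx):
        rng = np.random.default_rng(7)
        live = sorted(fx.graph.live_terms)
        for _ in range(25):
            s1 = set(rng.choice(live, size=rng.integers(1, 4), replace=False))
            s2 = set(rng.choice(live, size=rng.integers(1, 4), replace=False))
            fa = make_fa(fx, "a", {"g1": s1})
            gold = make_fa(fx, "b", {"g1": s2})
            assert hierarchical_recall(
                "g1", fa, gold, fx.graph, "generic"
            ) == pytest.approx(
                hierarchical_precision("g1", gold, fa, fx.graph, "generic")
            )

    def test_both_one_iff_mutually_covering(self, fx):
        # same closure, different raw sets: {C, A} and {C} close identically
        fa = make_fa(fx, "a", {"g1": {"C", "A"}})
        gold = make_fa(fx, "b", {"g1": {"C"}})
        assert hierarchical_precision("g1", fa, gold, fx.graph,
                                      "generic") == 1.0
        assert hierarchical_recall("g1", fa, gold, fx.graph,
                                   "generic") == 1.0

    def test_unannotated_gene_is_undefined(self, fx):
        with pytest.raises(UndefinedMetricError):
            hierarchical_precision("g4", fx.fa, fx.gold, fx.graph, "generic")


class TestGoldComparison:
    def test_gold_against_itself(self, fx):
        gc = gold_comparison(fx.gold, fx.gold, fx.graph, "generic")
        summary = gc.summary()
        assert summary["hPrecision"] == 1.0 and summary["hRecall"] == 1.0
        assert summary["hPrecision_sem"] == 0.0

    def test_fixture_means(self, fx):
        gc = gold_comparison(fx.fa, fx.gold, fx.graph, "generic")
        summary = gc.summary()
        assert summary["hPrecision"] == pytest.approx(K["gold_mean_hprec"])
        assert summary["hRecall"] == pytest.approx(K["gold_mean_hrec"])
        assert summary["n_common"] == 3

    def test_single_common_gene_sem_undefined(self, fx):
        fa = make_fa(fx, "a", {"g1": {"C"}})
        gold = make_fa(fx, "b", {"g1": {"D"}, "g2": {"E"}})
        gc = gold_comparison(fa, gold, fx.graph, "generic")
        assert gc.summary()["hPrecision_sem"] is None
        assert gc.gold_only == 1


class TestOutliers:
    def test_oversized_set_flagged(self, fx):
        big = make_fa(fx, "big", {"g1": {"R", "A", "B", "C", "D", "E"}})
        report = flag_outliers(big, fx.graph, max_set_size=5)
        assert ("g1", "generic") in report.oversized

    def test_dissimilar_pair_flagged(self, fx):
        fa1 = make_fa(fx, "a", {"g1": {"C"}})
        fa2 = make_fa(fx, "b", {"g1": {"E"}})
        report = flag_outliers(
            fa1, fx.graph, pair=fa2, similarity_floor=0.5
        )
        assert report.dissimilar == {"g1": pytest.approx(1 / 3)}

    def test_no_violations_empty_report(self, fx):
        report = flag_outliers(fx.fa, fx.graph, pair=fx.fa)
        assert not report


class TestReleaseSeries:
    def test_identical_releases_flat(self, fx):
        series = release_series([fx.fa, fx.fa, fx.fa], fx.graph)
        assert series.table["coverage"].nunique() == 1
        for scores in series.change_scores.values():
            assert set(scores.values()) == {1.0}

    def test_added_gene_increases_coverage(self, fx):
        grown = make_fa(
            fx, "r2",
            {"g1": {"C"}, "g2": {"C", "D"}, "g3": {"C", "D", "E"},
             "g4": {"E"}},
        )
        series = release_series([fx.fa, grown], fx.graph)
        cov = series.table["coverage"].tolist()
        assert cov[1] > cov[0]

    def test_disjoint_rewrite_is_minimum_change(self, fx):
        rewritten = make_fa(
            fx, "r2",
            {"g1": {"E"}, "g2": {"C", "D"}, "g3": {"C", "D", "E"}},
        )
        series = release_series([fx.fa, rewritten], fx.graph)
        scores = series.change_scores[("fixtureFA", "r2")]
        assert min(scores, key=scores.get) == "g1"
        low = series.low_change(0.5)
        assert low and low[0][0] == "g1"
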