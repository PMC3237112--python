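"""Inter-comparison of functional annotations.

Coverage Venn partitions, per-gene cross-FA semantic similarity,
hierarchical precision/recall against a gold standard, outlier flagging,
and release time series.

Hierarchical precision credits near misses: a predicted term scores,
against each gold term, the fraction of its *own* ancestor closure that
the gold term's closure covers, and keeps the best match; recall is the
mirror image with gold terms scored against predictions.  Consequently
``hRecall(fa, gold) == hPrecision(gold, fa)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .annotations import AnnotationError, FunctionalAnnotation
from .metrics import GeneKey, coverage, mean_sem, obsolescence, richness
from .metrics import UndefinedMetricError, _live
from .ontology import OntologyGraph
from .similarity import MEASURES, Measure, SimilarityError

__all__ = [
    "VennPartition",
    "coverage_partition",
    "cross_similarity",
    "hierarchical_precision",
    "hierarchical_recall",
    "GoldComparison",
    "gold_comparison",
    "flag_outliers",
    "OutlierReport",
    "release_series",
    "ReleaseSeries",
]


# ---------------------------------------------------------------------------
# coverage Venn partition
# ---------------------------------------------------------------------------


@dataclass
class VennPartition:
    """Counts of reference genes in each membership region of k FAs.

    Regions are keyed by boolean tuples aligned with ``labels``;
    ``(True, False)`` is the region covered by the first FA only.  The
    region counts always sum to the reference size.
    """

    labels: tuple[str, ...]
    regions: dict[tuple[bool, ...], set[str]]
    reference_size: int

    def count(self, pattern: tuple[bool, ...]) -> int:
        return len(self.regions.get(pattern, set()))

    def fractions(self) -> dict[tuple[bool, ...], float]:
        return {
            p: len(g) / self.reference_size for p, g in self.regions.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pattern in sorted(self.regions, reverse=True):
            members = [
                lab for lab, inside in zip(self.labels, pattern) if inside
            ]
            rows.append(
                {
                    "region": "&".join(members) if members else "(none)",
                    "count": len(self.regions[pattern]),
                    "fraction": len(self.regions[pattern])
                    / self.reference_size,
                }
            )
        return pd.DataFrame(rows)


def coverage_partition(
    fas: list[FunctionalAnnotation], aspect: str = "ALL"
) -> VennPartition:
    """Partition the reference by which of 2-4 FAs annotate each gene."""
    if not 2 <= len(fas) <= 4:
        raise AnnotationError("coverage_partition takes 2 to 4 FAs")
    reference = fas[0].reference
    for fa in fas[1:]:
        if fa.reference.ids != reference.ids:
            raise AnnotationError(
                "coverage_partition requires a shared reference"
            )
    covered = [fa.genes(aspect) for fa in fas]
    regions: dict[tuple[bool, ...], set[str]] = {
        pattern: set() for pattern in product([True, False], repeat=len(fas))
    }
    for gene in reference:
        pattern = tuple(gene in cov for cov in covered)
        regions[pattern].add(gene)
    return VennPartition(
        labels=tuple(fa.name for fa in fas),
        regions=regions,
        reference_size=len(reference),
    )


# ---------------------------------------------------------------------------
# cross-FA similarity
# ---------------------------------------------------------------------------


@dataclass
class CrossSimilarity:
    scores: dict[str, float]
    n_identical: int
    low_tail: list[tuple[str, float]]  # sorted ascending

    def histogram(self, bins: int = 10) -> Counter:
        h: Counter = Counter()
        for v in self.scores.values():
            h[min(int(v * bins), bins - 1)] += 1
        return h


def cross_similarity(
    fa1: FunctionalAnnotation,
    fa2: FunctionalAnnotation,
    graph: OntologyGraph,
    measure: Measure = MEASURES["gs2"],
    aspect: str = "ALL",
    low_tail_threshold: float = 0.5,
) -> CrossSimilarity:
    """One similarity score per gene annotated by both FAs.

    For ``ALL``, per-aspect comparisons are averaged per gene (similarity
    across aspects is undefined).
    """
    aspects = (
        sorted(set(fa1.aspects()) & set(fa2.aspects()))
        if aspect == "ALL"
        else [aspect]
    )
    per_gene: dict[str, list[float]] = {}
    for a in aspects:
        common = fa1.genes(a) & fa2.genes(a)
        for gene in common:
            s1 = _live(fa1.annotation_set(gene, a), graph)
            s2 = _live(fa2.annotation_set(gene, a), graph)
            if not s1 or not s2:
                continue
            per_gene.setdefault(gene, []).append(measure(graph, s1, s2))
    if not per_gene:
        raise SimilarityError(
            "no gene is annotated by both FAs for this aspect"
        )
    scores = {g: sum(v) / len(v) for g, v in per_gene.items()}
    low = sorted(
        ((g, v) for g, v in scores.items() if v < low_tail_threshold),
        key=lambda kv: (kv[1], kv[0]),
    )
    return CrossSimilarity(
        scores=scores,
        n_identical=sum(1 for v in scores.values() if v == 1.0),
        low_tail=low,
    )


# ---------------------------------------------------------------------------
# hierarchical precision / recall
# ---------------------------------------------------------------------------


def _directional_overlap(
    graph: OntologyGraph, scored: frozenset[str], against: frozenset[str]
) -> float:
    """Mean over ``scored`` terms of the best fractional coverage of the
    term's own closure by any single ``against`` term's closure."""
    against_closures = [graph.ancestors(t) for t in against]
    total = 0.0
    for s in scored:
        a_s = graph.ancestors(s)
        total += max(len(a_s & a_t) / len(a_s) for a_t in against_closures)
    return total / len(scored)


def hierarchical_precision(
    gene: str,
    fa: FunctionalAnnotation,
    gold: FunctionalAnnotation,
    graph: OntologyGraph,
    aspect: str,
) -> float:
    """Ancestor-weighted fraction of predicted annotations supported by
    the gold standard."""
    predicted = _live(fa.annotation_set(gene, aspect), graph)
    truth = _live(gold.annotation_set(gene, aspect), graph)
    if not predicted or not truth:
        raise UndefinedMetricError(
            f"{gene}: needs annotations in both FA and gold"
        )
    return _directional_overlap(graph, predicted, truth)


def hierarchical_recall(
    gene: str,
    fa: FunctionalAnnotation,
    gold: FunctionalAnnotation,
    graph: OntologyGraph,
    aspect: str,
) -> float:
    """Ancestor-weighted fraction of gold annotations recovered by the FA."""
    predicted = _live(fa.annotation_set(gene, aspect), graph)
    truth = _live(gold.annotation_set(gene, aspect), graph)
    if not predicted or not truth:
        raise UndefinedMetricError(
            f"{gene}: needs annotations in both FA and gold"
        )
    return _directional_overlap(graph, truth, predicted)


@dataclass
class GoldComparison:
    """Per-gene hPrecision/hRecall with mean and SEM, per aspect."""

    fa_name: str
    gold_name: str
    aspect: str
    precision: dict[str, float]
    recall: dict[str, float]
    fa_only: int
    gold_only: int

    @property
    def n_common(self) -> int:
        return len(self.precision)

    def summary(self) -> dict[str, float | None]:
        p_mean, p_sem, n = mean_sem(self.precision.values())
        r_mean, r_sem, _ = mean_sem(self.recall.values())
        return {
            "hPrecision": p_mean,
            "hPrecision_sem": p_sem,
            "hRecall": r_mean,
            "hRecall_sem": r_sem,
            "n_common": n,
        }

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.precision)
        return pd.DataFrame(
            {
                "gene": genes,
                "hPrecision": [self.precision[g] for g in genes],
                "hRecall": [self.recall[g] for g in genes],
            }
        )


def gold_comparison(
    fa: FunctionalAnnotation,
    gold: FunctionalAnnotation,
    graph: OntologyGraph,
    aspect: str,
) -> GoldComparison:
    """Evaluate ``fa`` against a gold standard on their common genes."""
    fa_genes = {
        g for g in fa.genes(aspect)
        if _live(fa.annotation_set(g, aspect), graph)
    }
    gold_genes = {
        g for g in gold.genes(aspect)
        if _live(gold.annotation_set(g, aspect), graph)
    }
    common = fa_genes & gold_genes
    if not common:
        raise UndefinedMetricError(
            "no gene is annotated by both the FA and the gold standard"
        )
    precision = {
        g: hierarchical_precision(g, fa, gold, graph, aspect) for g in common
    }
    recall = {
        g: hierarchical_recall(g, fa, gold, graph, aspect) for g in common
    }
    return GoldComparison(
        fa_name=fa.name,
        gold_name=gold.name,
        aspect=aspect,
        precision=precision,
        recall=recall,
        fa_only=len(fa_genes - gold_genes),
        gold_only=len(gold_genes - fa_genes),
    )


# ---------------------------------------------------------------------------
# outlier flagging
# ---------------------------------------------------------------------------


@dataclass
class OutlierReport:
    oversized: dict[GeneKey, frozenset[str]] = field(default_factory=dict)
    dissimilar: dict[str, float] = field(default_factory=dict)

    def __bool__(self) -> bool:
        return bool(self.oversized or self.dissimilar)


def flag_outliers(
    fa: FunctionalAnnotation,
    graph: OntologyGraph,
    pair: FunctionalAnnotation | None = None,
    max_set_size: int = 30,
    similarity_floor: float = 0.5,
    measure: Measure = MEASURES["gs2"],
    aspect: str = "ALL",
) -> OutlierReport:
    """Flag genes with extreme annotation-set sizes and, when a second FA
    is given, genes whose cross-FA similarity falls below the floor."""
    report = OutlierReport()
    for gene, a, terms in fa.items(aspect):
        if len(terms) > max_set_size:
            report.oversized[(gene, a)] = terms
    if pair is not None:
        try:
            cross = cross_similarity(
                fa, pair, graph, measure, aspect,
                low_tail_threshold=similarity_floor,
            )
        except SimilarityError:
            return report
        report.dissimilar = dict(cross.low_tail)
    return report


# ---------------------------------------------------------------------------
# release time series
# ---------------------------------------------------------------------------


@dataclass
class ReleaseSeries:
    """Metric trajectories across time-ordered FA releases."""

    labels: list[str]
    table: pd.DataFrame  # columns: release, coverage, richness, obsolescence
    stable_genes: set[str]  # annotated in every release
    change_scores: dict[tuple[str, str], dict[str, float]]
    # keyed by (release_i, release_{i+1}) -> per-stable-gene similarity

    def low_change(
        self, threshold: float = 0.5
    ) -> list[tuple[str, str, str, float]]:
        out = []
        for (r1, r2), scores in self.change_scores.items():
            for gene, v in scores.items():
                if v < threshold:
                    out.append((gene, r1, r2, v))
        return sorted(out, key=lambda row: (row[3], row[0]))


def release_series(
    fas: list[FunctionalAnnotation],
    graph: OntologyGraph,
    measure: Measure = MEASURES["gs2"],
    aspect: str = "ALL",
) -> ReleaseSeries:
    """Track coverage/richness/obsolescence across releases and score the
    per-gene similarity between consecutive releases for genes annotated
    in every release."""
    if len(fas) < 2:
        raise AnnotationError("release_series needs at least two releases")
    reference = fas[0].reference
    for fa in fas[1:]:
        if fa.reference.ids != reference.ids:
            raise AnnotationError("releases must share a reference")
    rows = []
    for fa in fas:
        try:
            rich = richness(fa, graph, aspect)
        except UndefinedMetricError:
            rich = None
        try:
            obs = obsolescence(fa, graph, aspect)
        except UndefinedMetricError:
            obs = None
        rows.append(
            {
                "release": fa.name,
                "coverage": coverage(fa, aspect),
                "richness": rich,
                "obsolescence": obs,
            }
        )
    stable = set.intersection(*(fa.genes(aspect) for fa in fas))
    change_scores: dict[tuple[str, str], dict[str, float]] = {}
    for prev, curr in zip(fas, fas[1:]):
        scores: dict[str, float] = {}
        for gene in stable:
            aspects = (
                sorted(set(prev.aspects()) | set(curr.aspects()))
                if aspect == "ALL"
                else [aspect]
            )
            vals = []
            for a in aspects:
                s1 = _live(prev.annotation_set(gene, a), graph)
                s2 = _live(curr.annotation_set(gene, a), graph)
                if s1 and s2:
                    vals.append(measure(graph, s1, s2))
            if vals:
                scores[gene] = sum(vals) / len(vals)
        change_scores[(prev.name, curr.name)] = scores
    return ReleaseSeries(
        labels=[fa.name for fa in fas],
        table=pd.DataFrame(rows),
        stable_genes=stable,
        change_scores=change_scores,
    )
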