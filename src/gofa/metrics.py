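"""The nine single-FA metrics.

Quantity: coverage (fraction of the reference annotated), richness
(fraction of the ontology vocabulary used), per-gene annotation counts.
Diversity: coherence (leave-one-out within-set similarity) and
compactness (mean between-set similarity).  Informativeness: specificity
(mean ancestor count), redundancy (fraction of within-set ancestor
terms), information content, and obsolescence.

Per-gene vectors are keyed by ``(gene, aspect)`` pairs: for a concrete
aspect every key carries that aspect, and the pooled ``ALL`` view simply
concatenates the per-aspect vectors.  Metrics whose domain is empty
raise :class:`UndefinedMetricError` rather than fabricating a zero.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import FunctionalAnnotation
from .ontology import OntologyGraph
from .similarity import MEASURES, Measure, propagate

__all__ = [
    "UndefinedMetricError",
    "coverage",
    "richness",
    "annotation_counts",
    "AnnotationCountSummary",
    "coherence",
    "compactness",
    "specificity",
    "redundancy",
    "term_probabilities",
    "ICTable",
    "mean_ic",
    "obsolescence",
    "summarize",
    "MetricsReport",
    "mean_sem",
]

GeneKey = tuple[str, str]  # (gene id, aspect)


def _live(terms, graph: OntologyGraph) -> frozenset[str]:
    """Restrict a raw annotation set to live (traversable) terms; obsolete
    terms are de facto disconnected and carry no structural signal."""
    return frozenset(t for t in terms if t in graph.live_terms)


class UndefinedMetricError(Exception):
    """The metric's domain is empty (e.g. compactness of a 1-gene FA)."""


def mean_sem(values) -> tuple[float | None, float | None, int]:
    """Mean, standard error of the mean (ddof=1; None for n < 2), n."""
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n == 0:
        return None, None, 0
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else None
    return mean, sem, n


# ---------------------------------------------------------------------------
# A. quantity
# ---------------------------------------------------------------------------


def coverage(fa: FunctionalAnnotation, aspect: str = "ALL") -> float:
    """|GA| / |G_omega|: fraction of reference genes with >= 1 annotation.

    For ``ALL`` a gene counts if any aspect annotates it.
    """
    return len(fa.genes(aspect)) / len(fa.reference)


def richness(
    fa: FunctionalAnnotation, graph: OntologyGraph, aspect: str = "ALL"
) -> float:
    """Fraction of the aspect's live vocabulary used at least once."""
    vocabulary = graph.aspect_terms(aspect)
    if not vocabulary:
        raise UndefinedMetricError(f"no live terms for aspect {aspect}")
    used = {t for t in fa.terms_used(aspect) if t in vocabulary}
    return len(used) / len(vocabulary)


@dataclass
class AnnotationCountSummary:
    """Per-gene annotation-set sizes N(g) with their distribution."""

    counts: dict[GeneKey, int]
    mean: float | None
    max: int | None
    max_gene: GeneKey | None
    histogram: Counter = field(default_factory=Counter)


def annotation_counts(
    fa: FunctionalAnnotation, aspect: str = "ALL"
) -> AnnotationCountSummary:
    counts = {(g, a): len(terms) for g, a, terms in fa.items(aspect)}
    if not counts:
        return AnnotationCountSummary({}, None, None, None, Counter())
    max_gene = max(counts, key=lambda k: (counts[k], k))
    return AnnotationCountSummary(
        counts=counts,
        mean=sum(counts.values()) / len(counts),
        max=counts[max_gene],
        max_gene=max_gene,
        histogram=Counter(counts.values()),
    )


# ---------------------------------------------------------------------------
# B. diversity
# ---------------------------------------------------------------------------


def coherence(
    fa: FunctionalAnnotation,
    graph: OntologyGraph,
    measure: Measure = MEASURES["gs2"],
    aspect: str = "ALL",
) -> dict[GeneKey, float]:
    """Leave-one-out similarity of each term to the rest of its set,
    averaged over the set.  Singleton sets score 1 by convention (there
    is nothing to disagree with)."""
    out: dict[GeneKey, float] = {}
    for gene, a, raw in fa.items(aspect):
        terms = _live(raw, graph)
        if not terms:
            continue
        if len(terms) == 1:
            out[(gene, a)] = 1.0
            continue
        total = sum(
            measure(graph, {t}, terms - {t}) for t in terms
        )
        out[(gene, a)] = total / len(terms)
    return out


def compactness(
    fa: FunctionalAnnotation,
    graph: OntologyGraph,
    measure: Measure = MEASURES["gs2"],
    aspect: str = "ALL",
) -> float:
    """Mean over annotation sets of their mean similarity to every other
    annotation set of the same aspect.

    Similarity across aspects is undefined, so the pooled ``ALL`` value
    averages within-aspect comparisons, weighting each aspect by its
    number of annotation sets.
    """
    sets = list(fa.items(aspect))
    if len(sets) < 2:
        raise UndefinedMetricError(
            "compactness needs at least two annotation sets"
        )
    by_aspect: dict[str, list[tuple[str, frozenset[str]]]] = {}
    for gene, a, raw in sets:
        terms = _live(raw, graph)
        if terms:
            by_aspect.setdefault(a, []).append((gene, terms))
    av_sims: list[float] = []
    for a, members in by_aspect.items():
        if len(members) < 2:
            continue
        # cache closures once per set; pairwise overlap on closures
        for i, (_, terms_i) in enumerate(members):
            sims = [
                measure(graph, terms_i, terms_j)
                for j, (_, terms_j) in enumerate(members)
                if j != i
            ]
            av_sims.append(sum(sims) / len(sims))
    if not av_sims:
        raise UndefinedMetricError(
            "no aspect has two or more annotation sets"
        )
    return sum(av_sims) / len(av_sims)


# ---------------------------------------------------------------------------
# C. informativeness
# ---------------------------------------------------------------------------


def specificity(
    fa: FunctionalAnnotation, graph: OntologyGraph, aspect: str = "ALL"
) -> dict[GeneKey, float]:
    """Mean ancestor-set size over a gene's annotated terms (>= 1)."""
    out: dict[GeneKey, float] = {}
    for g, a, raw in fa.items(aspect):
        terms = _live(raw, graph)
        if terms:
            out[(g, a)] = sum(len(graph.ancestors(t)) for t in terms) / len(terms)
    return out


def redundancy(
    fa: FunctionalAnnotation, graph: OntologyGraph, aspect: str = "ALL"
) -> dict[GeneKey, float]:
    """Fraction of a gene's terms that are ancestors of another term in
    the same set (a term is not counted as its own ancestor here)."""
    out: dict[GeneKey, float] = {}
    for g, a, raw in fa.items(aspect):
        terms = _live(raw, graph)
        if not terms:
            continue
        redundant = sum(
            1
            for i in terms
            if any(i in graph.ancestors(j) for j in terms if j != i)
        )
        out[(g, a)] = redundant / len(terms)
    return out


@dataclass
class ICTable:
    """Per-term corpus probability and information content (bits).

    ``undefined`` lists terms whose probability is zero under the chosen
    variant (their IC is undefined and they are excluded from averages).
    """

    p: dict[str, float]
    ic: dict[str, float]
    undefined: set[str]
    variant: str

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def get(self, term, default=None):
        return self.ic.get(term, default)

    def values(self):
        return self.ic.values()


def term_probabilities(
    corpus_fa: FunctionalAnnotation,
    graph: OntologyGraph,
    aspect: str = "ALL",
    variant: str = "propagated",
) -> ICTable:
    """Corpus usage probability p(i) and IC(i) = -log2 p(i) per term.

    ``propagated`` (default): p(i) is the fraction of annotated genes
    whose ancestor-closed annotation set contains i; gives IC(root) = 0
    and child-to-parent monotonicity.  ``as-printed``: p(i) sums the
    *direct* annotation counts of i and its ancestors over the total
    direct count, so terms never directly annotated (and none of whose
    ancestors are) get p = 0 and an undefined IC.
    """
    aspects = (
        sorted(corpus_fa.aspects()) if aspect == "ALL" else [aspect]
    )
    p: dict[str, float] = {}
    for a in aspects:
        vocabulary = graph.aspect_terms(a)
        if variant == "propagated":
            sets = [
                propagate(graph, terms & vocabulary)
                for _, _, terms in corpus_fa.items(a)
                if terms & vocabulary
            ]
            n_genes = len(sets)
            if n_genes == 0:
                continue
            usage: Counter[str] = Counter()
            for closed in sets:
                usage.update(closed)
            for t in vocabulary:
                p[t] = usage.get(t, 0) / n_genes
        elif variant == "as-printed":
            direct: Counter[str] = Counter()
            for _, _, terms in corpus_fa.items(a):
                direct.update(t for t in terms if t in vocabulary)
            total = sum(direct.values())
            if total == 0:
                continue
            for t in vocabulary:
                p[t] = (
                    sum(direct.get(anc, 0) for anc in graph.ancestors(t))
                    / total
                )
        else:
            raise ValueError(f"unknown IC variant {variant!r}")
    ic = {t: -math.log2(v) for t, v in p.items() if v > 0}
    undefined = {t for t, v in p.items() if v == 0}
    return ICTable(p=p, ic=ic, undefined=undefined, variant=variant)


def mean_ic(
    fa: FunctionalAnnotation,
    graph: OntologyGraph,
    ic_table: ICTable,
    aspect: str = "ALL",
) -> tuple[dict[GeneKey, float], int]:
    """Per-gene mean IC of assigned terms.

    Terms with undefined IC are excluded per term; genes whose terms all
    lack an IC are excluded entirely, and their count is returned.
    """
    out: dict[GeneKey, float] = {}
    excluded = 0
    for g, a, terms in fa.items(aspect):
        ics = [ic_table.ic[t] for t in terms if t in ic_table.ic]
        if ics:
            out[(g, a)] = sum(ics) / len(ics)
        else:
            excluded += 1
    return out, excluded


def obsolescence(
    fa: FunctionalAnnotation, graph: OntologyGraph, aspect: str = "ALL"
) -> float:
    """Fraction of annotation instances pointing at obsolete terms with
    no live alternative, over all annotation instances (gene-term pairs).
    """
    dead = 0
    total = 0
    for _, a, terms in fa.items(aspect):
        for t in terms:
            if t in graph and graph.terms[t].obsolete:
                if aspect != "ALL" and graph.aspect_of(t) not in (aspect, "generic"):
                    continue
                total += 1
                if not graph.resolve_obsolete(t):
                    dead += 1
            else:
                total += 1
    if total == 0:
        raise UndefinedMetricError("FA has no annotation instances")
    return dead / total


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


@dataclass
class AspectReport:
    """One Table-2-style column: scalar metrics plus per-gene vectors."""

    aspect: str
    n_annotated: int
    coverage: float
    richness: float | None
    compactness: float | None
    obsolescence: float | None
    counts: AnnotationCountSummary
    coherence: dict[GeneKey, float]
    specificity: dict[GeneKey, float]
    redundancy: dict[GeneKey, float]
    mean_ic: dict[GeneKey, float]
    ic_excluded: int

    def scalar_rows(self) -> list[tuple[str, float | None, int | None]]:
        rows: list[tuple[str, float | None, int | None]] = [
            ("coverage", self.coverage, self.n_annotated),
            ("richness", self.richness, None),
        ]
        m, _, n = mean_sem(self.counts.counts.values())
        rows.append(("avg_n_annotations", m, n))
        for label, vec in [
            ("avg_coherence", self.coherence),
            ("avg_specificity", self.specificity),
            ("avg_ic", self.mean_ic),
            ("avg_redundancy", self.redundancy),
        ]:
            m, _, n = mean_sem(vec.values())
            rows.append((label, m, n))
        rows.append(("compactness", self.compactness, None))
        rows.append(("obsolescence", self.obsolescence, None))
        return rows


@dataclass
class MetricsReport:
    """All nine metrics for one FA, per aspect plus the pooled ALL view."""

    fa_name: str
    aspects: dict[str, AspectReport]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for aspect, rep in self.aspects.items():
            for metric, value, n in rep.scalar_rows():
                rows.append(
                    {
                        "fa": self.fa_name,
                        "aspect": aspect,
                        "metric": metric,
                        "value": value,
                        "n": n,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        payload = {
            aspect: {
                metric: value
                for metric, value, _ in rep.scalar_rows()
            }
            for aspect, rep in self.aspects.items()
        }
        return json.dumps({"fa": self.fa_name, "metrics": payload}, indent=2)

    def per_gene_frame(self, aspect: str = "ALL") -> pd.DataFrame:
        rep = self.aspects[aspect]
        keys = sorted(rep.counts.counts)
        return pd.DataFrame(
            {
                "gene": [g for g, _ in keys],
                "aspect": [a for _, a in keys],
                "n_annotations": [rep.counts.counts[k] for k in keys],
                "coherence": [rep.coherence.get(k) for k in keys],
                "specificity": [rep.specificity.get(k) for k in keys],
                "redundancy": [rep.redundancy.get(k) for k in keys],
                "mean_ic": [rep.mean_ic.get(k) for k in keys],
            }
        )


def summarize(
    fa: FunctionalAnnotation,
    graph: OntologyGraph,
    measure: Measure = MEASURES["gs2"],
    ic_variant: str = "propagated",
    ic_corpus: FunctionalAnnotation | None = None,
    aspects: list[str] | None = None,
) -> MetricsReport:
    """Compute every metric for each requested aspect plus ``ALL``.

    The IC corpus defaults to the FA itself.  Metrics whose domain is
    empty are reported as ``None`` rather than zero.
    """
    corpus = ic_corpus if ic_corpus is not None else fa
    if aspects is None:
        aspects = fa.aspects()
    blocks: dict[str, AspectReport] = {}
    for aspect in [*aspects, "ALL"]:
        ic_table = term_probabilities(corpus, graph, aspect, ic_variant)
        mic, excluded = mean_ic(fa, graph, ic_table, aspect)
        try:
            rich = richness(fa, graph, aspect)
        except UndefinedMetricError:
            rich = None
        try:
            comp = compactness(fa, graph, measure, aspect)
        except UndefinedMetricError:
            comp = None
        try:
            obs = obsolescence(fa, graph, aspect)
        except UndefinedMetricError:
            obs = None
        blocks[aspect] = AspectReport(
            aspect=aspect,
            n_annotated=len(fa.genes(aspect)),
            coverage=coverage(fa, aspect),
            richness=rich,
            compactness=comp,
            obsolescence=obs,
            counts=annotation_counts(fa, aspect),
            coherence=coherence(fa, graph, measure, aspect),
            specificity=specificity(fa, graph, aspect),
            redundancy=redundancy(fa, graph, aspect),
            mean_ic=mic,
            ic_excluded=excluded,
        )
    return MetricsReport(fa_name=fa.name, aspects=blocks)
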