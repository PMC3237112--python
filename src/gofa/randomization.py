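"""Null models and permutation machinery for annotation metrics.

Two null generators are provided: term randomization of an existing FA
(gene list and per-gene set sizes preserved, terms redrawn uniformly
from the same aspect's live vocabulary) and direct sampling of an FA
from the ontology under a chosen set-size distribution.  Empirical
p-values use the add-one permutation correction, so they are never zero
and never exceed one.

All draws are deterministic under a fixed seed (numpy ``default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .annotations import FunctionalAnnotation, GeneProductSet
from .ontology import OntologyGraph

__all__ = [
    "NullSpec",
    "randomize_terms",
    "sample_fa",
    "empirical_pvalue",
]


@dataclass(frozen=True)
class NullSpec:
    """Configuration of a null model.

    ``mode`` is ``randomize-terms`` (preserve observed gene list and set
    sizes) or ``sample-from-ontology`` (annotate every reference gene
    with sizes drawn from ``size_distribution``, a mapping size ->
    probability).
    """

    mode: str = "randomize-terms"
    seed: int = 0
    size_distribution: Mapping[int, float] | None = None
    aspect: str = "ALL"

    def generate(
        self,
        graph: OntologyGraph,
        fa: FunctionalAnnotation | None = None,
        reference: GeneProductSet | None = None,
        seed: int | None = None,
    ) -> FunctionalAnnotation:
        seed = self.seed if seed is None else seed
        if self.mode == "randomize-terms":
            if fa is None:
                raise ValueError("randomize-terms needs a template FA")
            return randomize_terms(fa, graph, seed)
        if self.mode == "sample-from-ontology":
            if reference is None:
                reference = fa.reference if fa is not None else None
            if reference is None:
                raise ValueError("sample-from-ontology needs a reference")
            if self.size_distribution is None:
                raise ValueError(
                    "sample-from-ontology needs a size distribution"
                )
            aspect = self.aspect if self.aspect != "ALL" else None
            return sample_fa(
                graph, reference, self.size_distribution, seed, aspect=aspect
            )
        raise ValueError(f"unknown null mode {self.mode!r}")


def _draw_set(rng: np.random.Generator, vocab: list[str], size: int) -> frozenset[str]:
    if size > len(vocab):
        raise ValueError(
            f"requested set size {size} exceeds vocabulary of {len(vocab)}"
        )
    idx = rng.choice(len(vocab), size=size, replace=False)
    return frozenset(vocab[i] for i in idx)


def randomize_terms(
    fa: FunctionalAnnotation, graph: OntologyGraph, seed: int
) -> FunctionalAnnotation:
    """Replace every annotation set with a uniform draw (without
    replacement) from the same aspect's live terms, preserving the gene
    list and every set size exactly."""
    rng = np.random.default_rng(seed)
    assignments: dict[str, dict[str, frozenset[str]]] = {}
    for aspect in fa.aspects():
        vocab = sorted(graph.aspect_terms(aspect))
        for gene, terms in sorted(fa.gene_sets(aspect).items()):
            assignments.setdefault(aspect, {})[gene] = _draw_set(
                rng, vocab, len(terms)
            )
    return FunctionalAnnotation(
        f"{fa.name}[randomized:{seed}]", fa.reference, assignments
    )


def sample_fa(
    graph: OntologyGraph,
    reference: GeneProductSet,
    size_distribution: Mapping[int, float],
    seed: int,
    aspect: str | None = None,
    name: str = "sampled",
) -> FunctionalAnnotation:
    """Annotate every reference gene with a term set sampled uniformly
    from the ontology, the set size drawn from ``size_distribution``."""
    sizes = sorted(size_distribution)
    probs = np.array([size_distribution[s] for s in sizes], dtype=float)
    if probs.sum() <= 0 or (probs < 0).any():
        raise ValueError("size distribution must be a non-negative measure")
    probs = probs / probs.sum()
    if min(sizes) < 1:
        raise ValueError("set sizes must be >= 1")
    if aspect is None:
        live_aspects = sorted(a for a, t in graph.aspects.items() if t)
        if len(live_aspects) != 1:
            raise ValueError(
                "specify an aspect for a multi-aspect ontology"
            )
        aspect = live_aspects[0]
    vocab = sorted(graph.aspect_terms(aspect))
    rng = np.random.default_rng(seed)
    assignments: dict[str, frozenset[str]] = {}
    for gene in reference:
        size = int(rng.choice(sizes, p=probs))
        assignments[gene] = _draw_set(rng, vocab, size)
    return FunctionalAnnotation(
        f"{name}:{seed}", reference, {aspect: assignments}
    )


def empirical_pvalue(
    observed: float,
    metric: Callable[[FunctionalAnnotation], float],
    null: NullSpec,
    graph: OntologyGraph,
    n_perm: int,
    seed: int,
    side: str = "upper",
    fa: FunctionalAnnotation | None = None,
    reference: GeneProductSet | None = None,
) -> tuple[float, np.ndarray]:
    """Add-one permutation p-value of ``observed`` against the null.

    ``p = (1 + #{null >= observed}) / (n_perm + 1)`` for the upper side,
    mirrored for the lower; ``two-sided`` doubles the smaller tail
    (capped at 1).  Null draws are seeded ``seed, seed+1, ...`` so the
    whole experiment is reproducible from one integer.

    Returns the p-value and the null metric values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.empty(n_perm)
    for i in range(n_perm):
        null_fa = null.generate(graph, fa=fa, reference=reference, seed=seed + i)
        values[i] = metric(null_fa)
    upper = (1 + int((values >= observed).sum())) / (n_perm + 1)
    lower = (1 + int((values <= observed).sum())) / (n_perm + 1)
    if side == "upper":
        p = upper
    elif side == "lower":
        p = lower
    elif side == "two-sided":
        p = min(1.0, 2 * min(upper, lower))
    else:
        raise ValueError(f"unknown side {side!r}")
    return p, values
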