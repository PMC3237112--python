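"""Set-level semantic similarity over ancestor-closed term sets.

All measures operate on propagated (ancestor-closed) sets, following the
true-path rule: a gene annotated to a term is implicitly annotated to
every ancestor of that term.  Three measures are provided:

``GS2``
    For closures A1, A2: ``½(|A1∩A2|/|A1| + |A1∩A2|/|A2|)``.  Equals 1
    iff the closures are equal; computable for k sets in one pass over a
    shared term-count table (no pairwise loop).
``Czekanowski-Dice``
    ``1 − |A1 Δ A2| / (|A1 ∪ A2| + |A1 ∩ A2|)``.
``Resnik``
    Pairwise term score is the information content of the most
    informative common ancestor (MICA); sets are aggregated by
    best-match-average (default) or max, with an optional [0,1]
    normalisation by the corpus's maximal IC.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .ontology import OntologyGraph

__all__ = [
    "SimilarityScore",
    "SimilarityError",
    "propagate",
    "sim_gs2",
    "gs2_multiset",
    "sim_czekanowski_dice",
    "sim_resnik",
    "get_measure",
    "MEASURES",
]


class SimilarityError(Exception):
    """Undefined similarity (empty set, cross-aspect comparison, ...)."""


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    measure: str
    left: frozenset[str] = frozenset()
    right: frozenset[str] = frozenset()

    def __float__(self) -> float:
        return self.value


def propagate(graph: OntologyGraph, terms: Iterable[str]) -> frozenset[str]:
    """Ancestor closure of a term set (union of per-term closures).

    All terms must be live and belong to a single aspect.
    """
    terms = list(terms)
    aspects = {graph.aspect_of(t) for t in terms}
    if len(aspects) > 1:
        raise SimilarityError(
            f"cannot propagate a mixed-aspect set: {sorted(aspects)}"
        )
    closed: set[str] = set()
    for t in terms:
        closed |= graph.ancestors(t)
    return frozenset(closed)


def _require_nonempty(*sets) -> None:
    for s in sets:
        if not s:
            raise SimilarityError("similarity of an empty set is undefined")


def sim_gs2(graph: OntologyGraph, s1, s2) -> SimilarityScore:
    """GS2 similarity of two term sets (on their ancestor closures)."""
    _require_nonempty(s1, s2)
    a1, a2 = propagate(graph, s1), propagate(graph, s2)
    overlap = len(a1 & a2)
    value = 0.5 * (overlap / len(a1) + overlap / len(a2))
    return SimilarityScore(value, "gs2", frozenset(s1), frozenset(s2))


def gs2_multiset(
    graph: OntologyGraph, sets: Sequence[Iterable[str]]
) -> tuple[list[float], float]:
    """GS2 cohesion of k >= 2 sets in a single pass.

    The per-set score is the mean, over terms of the set's closure, of
    the fraction of the *other* sets whose closures contain that term;
    the overall score is the mean of per-set scores.  For k = 2 the
    overall score equals :func:`sim_gs2` of the pair.  A shared
    term-count table makes the computation linear in the total closure
    size rather than quadratic in k.
    """
    if len(sets) < 2:
        raise SimilarityError("gs2_multiset needs at least two sets")
    closures = [propagate(graph, s) for s in sets]
    _require_nonempty(*closures)
    counts: Counter[str] = Counter()
    for a in closures:
        counts.update(a)
    k = len(closures)
    per_set = [
        sum(counts[t] - 1 for t in a) / (len(a) * (k - 1)) for a in closures
    ]
    return per_set, sum(per_set) / k


def sim_czekanowski_dice(graph: OntologyGraph, s1, s2) -> SimilarityScore:
    """Czekanowski-Dice similarity on ancestor closures."""
    _require_nonempty(s1, s2)
    a1, a2 = propagate(graph, s1), propagate(graph, s2)
    sym_diff = len(a1 ^ a2)
    value = 1.0 - sym_diff / (len(a1 | a2) + len(a1 & a2))
    return SimilarityScore(value, "czekanowski-dice", frozenset(s1), frozenset(s2))


def _mica_ic(
    graph: OntologyGraph, ic: Mapping[str, float], t1: str, t2: str
) -> float:
    common = graph.ancestors(t1) & graph.ancestors(t2)
    if not common:
        raise SimilarityError(f"{t1} and {t2} share no ancestor")
    scored = [(c, ic[c]) for c in common if c in ic]
    if not scored:
        raise SimilarityError(
            f"no IC available for any common ancestor of {t1}, {t2}"
        )
    # ties broken by term id for determinism
    best = max(scored, key=lambda kv: (kv[1], [-ord(ch) for ch in kv[0]]))
    return best[1]


def sim_resnik(
    graph: OntologyGraph,
    ic_table: Mapping[str, float],
    s1,
    s2,
    aggregation: str = "best-match-average",
    normalized: bool = False,
) -> SimilarityScore:
    """Resnik similarity of two term sets via MICA information content.

    ``best-match-average`` averages, over the terms of each set, the best
    pairwise score against the other set, then averages the two
    directions; ``max`` takes the single best pair.
    """
    _require_nonempty(s1, s2)
    s1, s2 = sorted(set(s1)), sorted(set(s2))
    pairwise = {
        (t1, t2): _mica_ic(graph, ic_table, t1, t2) for t1 in s1 for t2 in s2
    }
    if aggregation == "max":
        value = max(pairwise.values())
    elif aggregation == "best-match-average":
        fwd = sum(max(pairwise[(t1, t2)] for t2 in s2) for t1 in s1) / len(s1)
        rev = sum(max(pairwise[(t1, t2)] for t1 in s1) for t2 in s2) / len(s2)
        value = 0.5 * (fwd + rev)
    else:
        raise ValueError(f"unknown Resnik aggregation {aggregation!r}")
    if normalized:
        top = max((v for v in ic_table.values()), default=0.0)
        value = value / top if top > 0 else 0.0
    return SimilarityScore(value, "resnik", frozenset(s1), frozenset(s2))


# ---------------------------------------------------------------------------
# measure registry (strategy contract for coherence/compactness/comparison)
# ---------------------------------------------------------------------------

Measure = Callable[[OntologyGraph, Iterable[str], Iterable[str]], float]


def _gs2(graph, s1, s2):
    return sim_gs2(graph, s1, s2).value


def _cd(graph, s1, s2):
    return sim_czekanowski_dice(graph, s1, s2).value


MEASURES: dict[str, Measure] = {"gs2": _gs2, "cd": _cd}


def get_measure(
    name: str, ic_table: Mapping[str, float] | None = None
) -> Measure:
    """Resolve a measure by name; ``resnik`` needs an IC table and is
    returned in its [0,1]-normalised form so it can stand in wherever a
    bounded similarity is expected."""
    if name in MEASURES:
        return MEASURES[name]
    if name == "resnik":
        if ic_table is None:
            raise ValueError("the Resnik measure requires an IC table")
        return lambda graph, s1, s2: sim_resnik(
            graph, ic_table, s1, s2, normalized=True
        ).value
    raise ValueError(f"unknown similarity measure {name!r}")
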