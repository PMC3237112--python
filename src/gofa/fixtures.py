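"""Deterministic toy ontologies and annotations.

Everything here is synthetic: small DAGs and gene-to-term mappings built
in memory so every analysis path is testable with no download.  The
canonical worked fixture (one root R, branches A/B, leaves C/D under A
and E under B, plus two obsolete terms) is the object on which all the
package's hand-checked reference values are computed; those values are
frozen in :mod:`gofa.fixture_constants`.

Generators emit real OBO flat / GAF 2.0 text and parse it back, so the
readers are exercised on every generated object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .annotations import FunctionalAnnotation, GeneProductSet
from .ontology import OntologyGraph, parse_ontology

__all__ = [
    "CanonicalFixture",
    "canonical_fixture",
    "singleton_corpus",
    "obsolete_augmented_fa",
    "FixtureSpec",
    "render_fasta",
    "render_obo",
    "generate_ontology",
    "generate_fa",
    "CANONICAL_OBO",
]

_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

CANONICAL_OBO = """\
format-version: 1.2
ontology: gofa-canonical-fixture

[Term]
id: R
name: root
namespace: generic

[Term]
id: A
name: branch a
namespace: generic
is_a: R ! root

[Term]
id: B
name: branch b
namespace: generic
is_a: R ! root

[Term]
id: C
name: leaf c
namespace: generic
is_a: A ! branch a

[Term]
id: D
name: leaf d
namespace: generic
is_a: A ! branch a

[Term]
id: E
name: leaf e
namespace: generic
is_a: B ! branch b

[Term]
id: X
name: retired, no alternative
namespace: generic
is_obsolete: true

[Term]
id: Y
name: retired, replaced
namespace: generic
is_obsolete: true
replaced_by: B
"""


@dataclass(frozen=True)
class CanonicalFixture:
    graph: OntologyGraph
    reference: GeneProductSet
    fa: FunctionalAnnotation
    gold: FunctionalAnnotation


def canonical_fixture() -> CanonicalFixture:
    """The fixed worked example: 6 live terms, 2 obsolete, 5 genes.

    FA: g1 -> {C}, g2 -> {C,D}, g3 -> {C,D,E}.
    Gold: g1 -> {D}, g2 -> {C,D}, g3 -> {E}.
    """
    graph = parse_ontology(CANONICAL_OBO, dialect="obo-flat")
    reference = GeneProductSet(("g1", "g2", "g3", "g4", "g5"))
    fa = FunctionalAnnotation(
        "fixtureFA",
        reference,
        {
            "generic": {
                "g1": frozenset({"C"}),
                "g2": frozenset({"C", "D"}),
                "g3": frozenset({"C", "D", "E"}),
            }
        },
    )
    gold = FunctionalAnnotation(
        "fixtureGold",
        reference,
        {
            "generic": {
                "g1": frozenset({"D"}),
                "g2": frozenset({"C", "D"}),
                "g3": frozenset({"E"}),
            }
        },
    )
    return CanonicalFixture(graph, reference, fa, gold)


def singleton_corpus() -> FunctionalAnnotation:
    """Three singleton annotation sets {C},{D},{E}: the corpus on which
    the frozen IC values (e.g. IC(C) = log2 3) are computed."""
    fx = canonical_fixture()
    return FunctionalAnnotation(
        "singletonCorpus",
        fx.reference,
        {
            "generic": {
                "g1": frozenset({"C"}),
                "g2": frozenset({"D"}),
                "g3": frozenset({"E"}),
            }
        },
    )


def obsolete_augmented_fa() -> FunctionalAnnotation:
    """{g1: {C, X}, g2: {C}} with X obsolete and unreplaced: one of three
    annotation instances is dead, so obsolescence = 1/3."""
    fx = canonical_fixture()
    return FunctionalAnnotation(
        "obsoleteAugmented",
        fx.reference,
        {
            "generic": {
                "g1": frozenset({"C", "X"}),
                "g2": frozenset({"C"}),
            }
        },
    )


def render_fasta(reference: GeneProductSet, seed: int = 0) -> str:
    """Dummy-sequence FASTA for a reference gene set (synthetic: the
    sequences carry no signal, only the headers matter)."""
    rng = np.random.default_rng(seed)
    lines = []
    for gene in reference:
        seq = "".join(rng.choice(list("ACGT"), size=60))
        lines.append(f">{gene} synthetic sequence")
        lines.append(seq)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# parametric generators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a generated ontology/FA pair.

    The default set-size distribution is positively skewed (many
    singletons, a thinning tail), emulating the strongly skewed
    annotation-set sizes seen in real microarray FAs.
    """

    aspects: int = 1
    depth: int = 3
    branching: int = 2
    extra_links: int = 0
    n_obsolete_unreplaced: int = 1
    n_obsolete_replaced: int = 1
    n_genes: int = 10
    set_sizes: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.25, 3: 0.15, 4: 0.1}
    )
    planted: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1 or self.branching < 1:
            raise ValueError("depth and branching must be >= 1")
        if not 1 <= self.aspects <= 3:
            raise ValueError("1 to 3 aspects supported")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if not self.set_sizes or min(self.set_sizes) < 1:
            raise ValueError("set sizes must be >= 1")


def _tree_terms(aspect_idx: int, spec: FixtureSpec) -> list[tuple[str, str | None]]:
    """(term id, parent id) pairs of a balanced tree, breadth-first."""
    prefix = f"T{aspect_idx}"
    out: list[tuple[str, str | None]] = [(f"{prefix}:0000", None)]
    level = [f"{prefix}:0000"]
    counter = 1
    for _ in range(spec.depth):
        nxt = []
        for parent in level:
            for _ in range(spec.branching):
                tid = f"{prefix}:{counter:04d}"
                out.append((tid, parent))
                nxt.append(tid)
                counter += 1
        level = nxt
    return out


def render_obo(spec: FixtureSpec) -> str:
    """Emit the generated ontology as OBO flat 1.2 text."""
    rng = np.random.default_rng(spec.seed)
    stanzas = ["format-version: 1.2", "ontology: gofa-generated", ""]
    for a in range(spec.aspects):
        namespace = _NAMESPACES[a] if spec.aspects > 1 else "generic"
        terms = _tree_terms(a, spec)
        by_depth: dict[str, int] = {}
        for tid, parent in terms:
            by_depth[tid] = 0 if parent is None else by_depth[parent] + 1
        extra: dict[str, str] = {}
        candidates = [t for t, p in terms if p is not None and by_depth[t] >= 2]
        for tid in rng.choice(
            candidates,
            size=min(spec.extra_links, len(candidates)),
            replace=False,
        ) if candidates else []:
            # an extra part_of link to a strictly shallower term keeps the
            # graph acyclic
            shallower = [t for t, _ in terms if by_depth[t] < by_depth[tid]]
            extra[tid] = shallower[int(rng.integers(len(shallower)))]
        for tid, parent in terms:
            stanzas.append("[Term]")
            stanzas.append(f"id: {tid}")
            stanzas.append(f"name: synthetic term {tid}")
            stanzas.append(f"namespace: {namespace}")
            if parent is not None:
                stanzas.append(f"is_a: {parent}")
            if tid in extra:
                stanzas.append(f"relationship: part_of {extra[tid]}")
            stanzas.append("")
        live_ids = [t for t, _ in terms]
        for i in range(spec.n_obsolete_unreplaced):
            stanzas += [
                "[Term]",
                f"id: T{a}:OBSX{i:02d}",
                f"name: obsolete unreplaced {i}",
                f"namespace: {namespace}",
                "is_obsolete: true",
                "",
            ]
        for i in range(spec.n_obsolete_replaced):
            target = live_ids[int(rng.integers(len(live_ids)))]
            stanzas += [
                "[Term]",
                f"id: T{a}:OBSY{i:02d}",
                f"name: obsolete replaced {i}",
                f"namespace: {namespace}",
                "is_obsolete: true",
                f"replaced_by: {target}",
                "",
            ]
    return "\n".join(stanzas)


def generate_ontology(spec: FixtureSpec) -> OntologyGraph:
    """Generate, serialise and re-parse a balanced multi-aspect DAG."""
    return parse_ontology(render_obo(spec), dialect="obo-flat")


def generate_fa(
    graph: OntologyGraph,
    spec: FixtureSpec,
    name: str = "generatedFA",
    reference: GeneProductSet | None = None,
) -> FunctionalAnnotation:
    """Generate an FA over a generated (or compatible) ontology.

    With ``planted=True`` each gene's terms are drawn from the
    descendant set of one random internal term, giving functionally
    related (high-coherence) sets; otherwise terms are uniform over the
    aspect's vocabulary.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if reference is None:
        reference = GeneProductSet(
            tuple(f"g{i:04d}" for i in range(1, spec.n_genes + 1))
        )
    sizes = sorted(spec.set_sizes)
    probs = np.array([spec.set_sizes[s] for s in sizes], dtype=float)
    probs /= probs.sum()
    aspect_names = sorted(a for a, t in graph.aspects.items() if t)
    assignments: dict[str, dict[str, frozenset[str]]] = {}
    for gene in reference:
        aspect = aspect_names[int(rng.integers(len(aspect_names)))]
        vocab = sorted(graph.aspect_terms(aspect))
        size = int(rng.choice(sizes, p=probs))
        size = min(size, len(vocab))
        if spec.planted:
            internal = [
                t for t in vocab if len(graph.descendants(t)) >= max(size, 2)
                and t not in graph.roots(aspect)
            ]
            pool = (
                sorted(graph.descendants(
                    internal[int(rng.integers(len(internal)))]
                ))
                if internal
                else vocab
            )
            size = min(size, len(pool))
        else:
            pool = vocab
        idx = rng.choice(len(pool), size=size, replace=False)
        assignments.setdefault(aspect, {})[gene] = frozenset(
            pool[i] for i in idx
        )
    return FunctionalAnnotation(name, reference, assignments)
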