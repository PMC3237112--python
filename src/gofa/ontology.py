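"""Ontology loading and DAG traversal.

The ontology is a directed acyclic graph over terms.  Edges point from a
child term to its parents via a configurable set of traversable relations
(``is_a`` and ``part_of`` by default, the GO-community convention).
Obsolete terms are kept in the term index for obsolescence accounting but
carry no edges: they are de facto disconnected from the graph.

OBO flat-file 1.2 parsing is delegated to :mod:`obonet`; the OBO-XML
dialect is read with a small lxml-based reader behind the same contract.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import networkx as nx
import obonet
from lxml import etree

__all__ = [
    "OntologyTerm",
    "OntologyGraph",
    "OntologyError",
    "ParseError",
    "CycleError",
    "UnknownTermError",
    "parse_ontology",
    "write_obo",
    "DEFAULT_RELATIONS",
    "ASPECTS",
]

DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

#: canonical aspect codes keyed by OBO namespace
_NAMESPACE_TO_ASPECT = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
ASPECTS = ("BP", "MF", "CC")


class OntologyError(Exception):
    """Base class for ontology-layer errors."""


class ParseError(OntologyError):
    """A stanza or element could not be interpreted."""


class CycleError(OntologyError):
    """The traversable relation contains a cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__(
            "ontology relation is cyclic: " + " -> ".join(cycle + cycle[:1])
        )


class UnknownTermError(OntologyError, KeyError):
    """Lookup of an id that is absent (or obsolete where live is required)."""


@dataclass(frozen=True)
class OntologyTerm:
    """One term stanza: accession, label, aspect and parent links.

    ``replacements`` holds the obsolescence alternatives recorded in the
    source file (``replaced_by`` and, optionally, ``consider`` hints);
    it is non-empty only for obsolete terms.  ``parents`` lists
    ``(parent_id, relation)`` pairs restricted to traversable relations.
    """

    id: str
    name: str = ""
    aspect: str = "generic"
    obsolete: bool = False
    replacements: tuple[str, ...] = ()
    parents: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.replacements and not self.obsolete:
            raise ValueError(
                f"{self.id}: replacement hints on a non-obsolete term"
            )
        if self.obsolete and self.parents:
            raise ValueError(f"{self.id}: obsolete term with parents")


class OntologyGraph:
    """Validated term DAG with ancestor/descendant closure.

    Parameters
    ----------
    terms
        Iterable of :class:`OntologyTerm`.  Edge endpoints must exist and
        the child->parent relation must be acyclic.
    """

    def __init__(self, terms: Iterable[OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = {}
        for t in terms:
            if t.id in self.terms:
                raise ParseError(f"duplicate term id {t.id}")
            self.terms[t.id] = t

        # child -> parent digraph over live terms only
        g = nx.DiGraph()
        for t in self.terms.values():
            if t.obsolete:
                continue
            g.add_node(t.id)
            for parent, rel in t.parents:
                if parent not in self.terms:
                    raise ParseError(
                        f"term {t.id}: edge to unknown term {parent}"
                    )
                if self.terms[parent].obsolete:
                    raise ParseError(
                        f"term {t.id}: edge to obsolete term {parent}"
                    )
                g.add_edge(t.id, parent, relation=rel)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise CycleError([u for u, _ in cycle])
        self._graph = g

        self.aspects: dict[str, set[str]] = {}
        for t in self.terms.values():
            if not t.obsolete:
                self.aspects.setdefault(t.aspect, set()).add(t.id)

        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._descendant_cache: dict[str, frozenset[str]] = {}

    # -- basic accessors -------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return sum(1 for t in self.terms.values() if not t.obsolete)

    @property
    def live_terms(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def obsolete_terms(self) -> set[str]:
        return {i for i, t in self.terms.items() if t.obsolete}

    def aspect_of(self, term: str) -> str:
        try:
            return self.terms[term].aspect
        except KeyError:
            raise UnknownTermError(term) from None

    def aspect_terms(self, aspect: str) -> set[str]:
        """Live terms of one aspect, or of all aspects for ``ALL``."""
        if aspect == "ALL":
            return self.live_terms
        return set(self.aspects.get(aspect, set()))

    def roots(self, aspect: str | None = None) -> set[str]:
        nodes = self.live_terms if aspect in (None, "ALL") else self.aspect_terms(aspect)
        return {n for n in nodes if self._graph.out_degree(n) == 0}

    # -- closure ---------------------------------------------------------

    def ancestors(self, term: str) -> frozenset[str]:
        """The set containing ``term`` and all its ancestors."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        self._require_live(term)
        closure = frozenset(nx.descendants(self._graph, term) | {term})
        self._ancestor_cache[term] = closure
        return closure

    def descendants(self, term: str) -> frozenset[str]:
        """The set containing ``term`` and all its descendants."""
        cached = self._descendant_cache.get(term)
        if cached is not None:
            return cached
        self._require_live(term)
        closure = frozenset(nx.ancestors(self._graph, term) | {term})
        self._descendant_cache[term] = closure
        return closure

    def resolve_obsolete(self, term: str) -> frozenset[str]:
        """Live alternatives recorded for an obsolete term (possibly empty)."""
        t = self.terms.get(term)
        if t is None:
            raise UnknownTermError(term)
        if not t.obsolete:
            raise OntologyError(f"{term} is not obsolete")
        return frozenset(
            r
            for r in t.replacements
            if r in self.terms and not self.terms[r].obsolete
        )

    def _require_live(self, term: str) -> None:
        if term not in self.terms:
            raise UnknownTermError(term)
        if self.terms[term].obsolete:
            raise UnknownTermError(f"{term} is obsolete")


def write_obo(graph: OntologyGraph) -> str:
    """Serialise to OBO flat 1.2 (round-trip safe with ``parse_ontology``).

    Obsolescence alternatives are all emitted as ``replaced_by``, so a
    graph parsed with ``consider`` hints round-trips to an equal term
    index even though the hint class is not preserved.
    """
    lines = ["format-version: 1.2", "ontology: gofa-export", ""]
    aspect_to_ns = {v: k for k, v in _NAMESPACE_TO_ASPECT.items()}
    for term_id in sorted(graph.terms):
        t = graph.terms[term_id]
        lines.append("[Term]")
        lines.append(f"id: {t.id}")
        lines.append(f"name: {t.name}")
        lines.append(f"namespace: {aspect_to_ns.get(t.aspect, t.aspect)}")
        for parent, rel in t.parents:
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        if t.obsolete:
            lines.append("is_obsolete: true")
            for r in t.replacements:
                lines.append(f"replaced_by: {r}")
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def parse_ontology(
    source,
    dialect: str = "obo-flat",
    *,
    relations: frozenset[str] = DEFAULT_RELATIONS,
    consider_as_replacement: bool = True,
) -> OntologyGraph:
    """Parse an ontology file into an :class:`OntologyGraph`.

    Parameters
    ----------
    source
        File path, text, or open stream.
    dialect
        ``"obo-flat"`` (OBO flat-file 1.2) or ``"obo-xml"``.
    relations
        Relation labels that are traversable; others are dropped.
    consider_as_replacement
        Whether weaker ``consider`` hints count as alternatives for
        obsolete terms, in addition to ``replaced_by``.
    """
    if dialect == "obo-flat":
        return _parse_obo_flat(source, relations, consider_as_replacement)
    if dialect == "obo-xml":
        return _parse_obo_xml(source, relations, consider_as_replacement)
    raise ValueError(f"unknown ontology dialect: {dialect!r}")


def _as_handle(source):
    if hasattr(source, "read"):
        return source
    text = source
    if isinstance(text, bytes):
        text = text.decode()
    if "\n" in text or text.strip().startswith(("format-version", "<")):
        return io.StringIO(text)
    return open(text)


def _term_from_attrs(
    term_id: str,
    data: Mapping,
    relations: frozenset[str],
    consider_as_replacement: bool,
) -> OntologyTerm:
    obsolete = str(data.get("is_obsolete", "")).lower() == "true"
    replacements: list[str] = []
    if obsolete:
        replacements.extend(data.get("replaced_by", []))
        if consider_as_replacement:
            replacements.extend(data.get("consider", []))
    parents: list[tuple[str, str]] = []
    if not obsolete:
        if "is_a" in relations:
            parents.extend((p, "is_a") for p in data.get("is_a", []))
        for spec in data.get("relationship", []):
            try:
                rel, target = spec.split()[:2]
            except ValueError:
                raise ParseError(
                    f"term {term_id}: malformed relationship {spec!r}"
                ) from None
            if rel in relations:
                parents.append((target, rel))
    return OntologyTerm(
        id=term_id,
        name=data.get("name", ""),
        aspect=_NAMESPACE_TO_ASPECT.get(
            data.get("namespace", ""), data.get("namespace") or "generic"
        ),
        obsolete=obsolete,
        replacements=tuple(dict.fromkeys(replacements)),
        parents=tuple(parents),
    )


def _parse_obo_flat(source, relations, consider_as_replacement) -> OntologyGraph:
    handle = _as_handle(source)
    try:
        g = obonet.read_obo(handle, ignore_obsolete=False)
    except Exception as exc:  # obonet raises bare ValueError on bad stanzas
        raise ParseError(f"malformed OBO flat file: {exc}") from exc
    # obonet materialises edge targets as attribute-less nodes even when
    # no stanza defines them; drop those so edge validation can fire
    terms = [
        _term_from_attrs(node, data, relations, consider_as_replacement)
        for node, data in g.nodes(data=True)
        if data
    ]
    return OntologyGraph(terms)


def _parse_obo_xml(source, relations, consider_as_replacement) -> OntologyGraph:
    handle = _as_handle(source)
    try:
        tree = etree.parse(handle)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed OBO-XML: {exc}") from exc
    terms: list[OntologyTerm] = []
    for elem in tree.iter("term"):
        term_id = elem.findtext("id")
        if not term_id:
            raise ParseError(
                f"term element without <id> (line {elem.sourceline})"
            )
        data: dict[str, object] = {
            "name": elem.findtext("name", default=""),
            "namespace": elem.findtext("namespace", default=""),
            "is_a": [e.text for e in elem.findall("is_a") if e.text],
            "replaced_by": [
                e.text for e in elem.findall("replaced_by") if e.text
            ],
            "consider": [e.text for e in elem.findall("consider") if e.text],
            "relationship": [
                f"{r.findtext('type')} {r.findtext('to')}"
                for r in elem.findall("relationship")
                if r.findtext("type") and r.findtext("to")
            ],
        }
        if (elem.findtext("is_obsolete") or "").strip() in {"1", "true"}:
            data["is_obsolete"] = "true"
        terms.append(
            _term_from_attrs(term_id, data, relations, consider_as_replacement)
        )
    return OntologyGraph(terms)
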