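"""Reference gene sets, functional annotations and FA algebra.

A functional annotation (FA) maps every gene product of a fixed reference
set to a (possibly empty) set of ontology terms per GO aspect.  Readers
exist for GAF 2.0, Affymetrix tabular annotation CSV, generic two-column
mappings, FASTA reference files and plain id lists; the generic TSV
dialect also has a writer so FAs round-trip.

Gene ids are never normalised: probe-set ids are case-sensitive.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

from .ontology import OntologyGraph

__all__ = [
    "GeneProductSet",
    "FunctionalAnnotation",
    "LoadSummary",
    "AnnotationError",
    "EXPERIMENTAL_EVIDENCE_CODES",
    "read_reference",
    "read_gaf",
    "read_affymetrix",
    "read_mapping",
    "write_mapping",
    "write_gaf",
    "strip_obsolete",
    "fa_union",
    "fa_intersection",
]

#: GO experimental evidence codes (the EXP family)
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"}
)

_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}
_ASPECT_GAF = {v: k for k, v in _GAF_ASPECT.items()}


class AnnotationError(Exception):
    pass


@dataclass(frozen=True)
class GeneProductSet:
    """An ordered set of gene-product identifiers for one organism."""

    ids: tuple[str, ...]
    organism: str = ""

    def __post_init__(self):
        if not self.ids:
            raise AnnotationError("empty reference gene set")
        if len(set(self.ids)) != len(self.ids):
            raise AnnotationError("duplicate ids in reference gene set")

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    @property
    def _index(self) -> frozenset[str]:
        return frozenset(self.ids)


@dataclass
class LoadSummary:
    """Per-load bookkeeping so nothing is dropped silently."""

    rows: int = 0
    kept: int = 0
    not_in_reference: int = 0
    not_qualified: int = 0
    unknown_terms: list[tuple[str, str]] = field(default_factory=list)


class FunctionalAnnotation:
    """Mapping from gene products to term sets, per aspect.

    Assignments are stored as ``{aspect: {gene: frozenset(terms)}}``;
    a gene with an empty set for an aspect is simply absent from that
    aspect's mapping.  ``evidence`` records the evidence codes seen for
    each (gene, term) pair.
    """

    def __init__(
        self,
        name: str,
        reference: GeneProductSet,
        assignments: dict[str, dict[str, frozenset[str]]] | None = None,
        evidence: dict[tuple[str, str], frozenset[str]] | None = None,
    ):
        self.name = name
        self.reference = reference
        self.assignments: dict[str, dict[str, frozenset[str]]] = {}
        for aspect, genes in (assignments or {}).items():
            for gene, terms in genes.items():
                if gene not in reference:
                    raise AnnotationError(
                        f"{name}: gene {gene} not in reference"
                    )
                if terms:
                    self.assignments.setdefault(aspect, {})[gene] = frozenset(
                        terms
                    )
        self.evidence: dict[tuple[str, str], frozenset[str]] = {
            k: frozenset(v) for k, v in (evidence or {}).items()
        }

    # -- accessors -------------------------------------------------------

    def aspects(self) -> list[str]:
        return sorted(self.assignments)

    def genes(self, aspect: str = "ALL") -> set[str]:
        """Annotated genes for one aspect (any aspect for ``ALL``)."""
        if aspect == "ALL":
            out: set[str] = set()
            for genes in self.assignments.values():
                out |= genes.keys()
            return out
        return set(self.assignments.get(aspect, {}))

    def annotation_set(self, gene: str, aspect: str = "ALL") -> frozenset[str]:
        if aspect == "ALL":
            out: set[str] = set()
            for genes in self.assignments.values():
                out |= genes.get(gene, frozenset())
            return frozenset(out)
        return self.assignments.get(aspect, {}).get(gene, frozenset())

    def gene_sets(self, aspect: str) -> dict[str, frozenset[str]]:
        """Per-gene annotation sets; for ``ALL``, one pooled set per
        (gene, aspect) pair keyed ``gene#aspect`` is *not* used -- callers
        that need the pooled view iterate :meth:`items`."""
        return dict(self.assignments.get(aspect, {}))

    def items(self, aspect: str = "ALL"):
        """Yield ``(gene, aspect, term_set)`` triples.

        For a concrete aspect this is that aspect's mapping; for ``ALL``
        it yields one triple per (gene, aspect) annotation set, matching
        the pooled per-aspect presentation of the per-gene metrics.
        """
        aspects = self.aspects() if aspect == "ALL" else [aspect]
        for a in aspects:
            for gene, terms in sorted(self.assignments.get(a, {}).items()):
                yield gene, a, terms

    def terms_used(self, aspect: str = "ALL") -> set[str]:
        out: set[str] = set()
        for _, _, terms in self.items(aspect):
            out |= terms
        return out

    def n_assignments(self, aspect: str = "ALL") -> int:
        """Number of gene-term annotation instances."""
        return sum(len(terms) for _, _, terms in self.items(aspect))

    # -- provenance filters ----------------------------------------------

    def filter_evidence(
        self, codes: set[str], name: str | None = None
    ) -> "FunctionalAnnotation":
        """Keep assignments supported by at least one evidence code in
        ``codes``; assignments with no recorded evidence are dropped."""
        keep = {
            pair for pair, ev in self.evidence.items() if ev & set(codes)
        }
        return self._subset_pairs(keep, name or f"{self.name}[evidence]")

    def experimental_consensus(
        self, min_codes: int = 2, name: str | None = None
    ) -> "FunctionalAnnotation":
        """Gold-standard reducer: keep assignments supported by at least
        ``min_codes`` distinct experimental evidence codes."""
        keep = {
            pair
            for pair, ev in self.evidence.items()
            if len(ev & EXPERIMENTAL_EVIDENCE_CODES) >= min_codes
        }
        return self._subset_pairs(keep, name or f"{self.name}[exp{min_codes}]")

    def _subset_pairs(
        self, pairs: set[tuple[str, str]], name: str
    ) -> "FunctionalAnnotation":
        assignments: dict[str, dict[str, frozenset[str]]] = {}
        for aspect, genes in self.assignments.items():
            for gene, terms in genes.items():
                kept = frozenset(t for t in terms if (gene, t) in pairs)
                if kept:
                    assignments.setdefault(aspect, {})[gene] = kept
        evidence = {p: self.evidence[p] for p in pairs if p in self.evidence}
        return FunctionalAnnotation(name, self.reference, assignments, evidence)

    # -- dunders ---------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, FunctionalAnnotation):
            return NotImplemented
        return (
            self.reference.ids == other.reference.ids
            and self.assignments == other.assignments
        )

    def __repr__(self) -> str:
        return (
            f"FunctionalAnnotation({self.name!r}, genes={len(self.genes())}, "
            f"assignments={self.n_assignments()})"
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _text_handle(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            data = data.decode()
        return io.StringIO(data)
    if isinstance(source, bytes):
        return io.StringIO(source.decode())
    if isinstance(source, str) and "\n" in source:
        return io.StringIO(source)
    return open(source)


def read_reference(source, format: str = "id-list", organism: str = "") -> GeneProductSet:
    """Load a reference gene-product set.

    ``fasta``: one id per record, the first whitespace-delimited token of
    the header.  ``id-list``: one id per line, blanks and ``#`` comments
    skipped.  Duplicates are removed with a warning.
    """
    handle = _text_handle(source)
    ids: list[str] = []
    if format == "fasta":
        ids = [rec.id for rec in SeqIO.parse(handle, "fasta")]
    elif format == "id-list":
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    else:
        raise ValueError(f"unknown reference format {format!r}")
    unique = list(dict.fromkeys(ids))
    if len(unique) != len(ids):
        warnings.warn(
            f"reference contains {len(ids) - len(unique)} duplicate ids; "
            "deduplicated",
            stacklevel=2,
        )
    if not unique:
        raise AnnotationError("reference source contains no records")
    return GeneProductSet(tuple(unique), organism=organism)


def read_gaf(
    source,
    reference: GeneProductSet,
    id_column: int = 2,
    name: str = "GAF",
) -> tuple[FunctionalAnnotation, LoadSummary]:
    """Read a GO Annotation File 2.0.

    17 tab-separated columns, ``!`` comment lines.  ``id_column`` is the
    1-based column holding the gene id (2 = DB object id, 11 = synonyms).
    Rows whose id is not in the reference are excluded and counted;
    NOT-qualified rows are dropped.
    """
    handle = _text_handle(source)
    summary = LoadSummary()
    assignments: dict[str, dict[str, set[str]]] = {}
    evidence: dict[tuple[str, str], set[str]] = {}
    for lineno, line in enumerate(handle, start=1):
        if not line.strip() or line.startswith("!"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 17:
            raise AnnotationError(
                f"GAF line {lineno}: expected 17 columns, got {len(fields)}"
            )
        summary.rows += 1
        qualifier, term, ev_code, aspect_code = (
            fields[3],
            fields[4],
            fields[6],
            fields[8],
        )
        if "NOT" in qualifier.split("|"):
            summary.not_qualified += 1
            continue
        gene = fields[id_column - 1]
        if gene not in reference:
            summary.not_in_reference += 1
            continue
        aspect = _GAF_ASPECT.get(aspect_code, aspect_code or "generic")
        assignments.setdefault(aspect, {}).setdefault(gene, set()).add(term)
        if ev_code:
            evidence.setdefault((gene, term), set()).add(ev_code)
        summary.kept += 1
    fa = FunctionalAnnotation(
        name,
        reference,
        {a: {g: frozenset(t) for g, t in genes.items()}
         for a, genes in assignments.items()},
        {k: frozenset(v) for k, v in evidence.items()},
    )
    return fa, summary


_AFFY_GO_COLUMNS = {
    "Gene Ontology Biological Process": "BP",
    "Gene Ontology Molecular Function": "MF",
    "Gene Ontology Cellular Component": "CC",
}
_AFFY_ID_CANDIDATES = ("Probe Set ID", "probe set id", "Probe Set Name")


def read_affymetrix(
    source, reference: GeneProductSet, name: str = "AFFY"
) -> tuple[FunctionalAnnotation, LoadSummary]:
    """Read an Affymetrix tabular annotation file (quoted CSV).

    GO columns are located by header names starting with
    ``Gene Ontology``; cells hold ``///``-delimited values of the form
    ``numeric-id // description // evidence`` and ``---`` means no
    assignment.  Numeric ids are zero-padded to ``GO:XXXXXXX``.
    """
    handle = _text_handle(source)
    reader = csv.reader(handle)
    try:
        header = next(reader)
    except StopIteration:
        raise AnnotationError("empty Affymetrix annotation file") from None
    go_cols = {
        i: aspect
        for i, h in enumerate(header)
        for title, aspect in _AFFY_GO_COLUMNS.items()
        if h.strip() == title
    }
    if not go_cols:
        raise AnnotationError(
            "no 'Gene Ontology *' columns found in Affymetrix header"
        )
    id_col = 0
    for cand in _AFFY_ID_CANDIDATES:
        if cand in header:
            id_col = header.index(cand)
            break
    summary = LoadSummary()
    assignments: dict[str, dict[str, set[str]]] = {}
    evidence: dict[tuple[str, str], set[str]] = {}
    for row in reader:
        if not row:
            continue
        summary.rows += 1
        gene = row[id_col]
        if gene not in reference:
            summary.not_in_reference += 1
            continue
        for col, aspect in go_cols.items():
            cell = row[col].strip() if col < len(row) else "---"
            if cell in ("---", ""):
                continue
            for entry in cell.split("///"):
                parts = [p.strip() for p in entry.split("//")]
                if not parts[0]:
                    continue
                term = f"GO:{int(parts[0]):07d}"
                assignments.setdefault(aspect, {}).setdefault(
                    gene, set()
                ).add(term)
                if len(parts) >= 3 and parts[2]:
                    evidence.setdefault((gene, term), set()).add(parts[2])
                summary.kept += 1
    fa = FunctionalAnnotation(
        name,
        reference,
        {a: {g: frozenset(t) for g, t in genes.items()}
         for a, genes in assignments.items()},
        {k: frozenset(v) for k, v in evidence.items()},
    )
    return fa, summary


def read_mapping(
    source,
    reference: GeneProductSet,
    graph: OntologyGraph,
    name: str = "mapping",
) -> tuple[FunctionalAnnotation, LoadSummary]:
    """Read a generic two-column (gene, term) TSV.

    The second column may be a single term or a ``;``-separated list.
    Aspects are assigned by looking terms up in ``graph``; unknown terms
    are rejected into the load summary, never silently dropped.
    """
    handle = _text_handle(source)
    summary = LoadSummary()
    assignments: dict[str, dict[str, set[str]]] = {}
    for line in handle:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            summary.unknown_terms.append((fields[0], ""))
            continue
        gene = fields[0]
        summary.rows += 1
        if gene not in reference:
            summary.not_in_reference += 1
            continue
        for term in filter(None, (t.strip() for t in fields[1].split(";"))):
            if term not in graph:
                summary.unknown_terms.append((gene, term))
                continue
            aspect = graph.aspect_of(term)
            assignments.setdefault(aspect, {}).setdefault(gene, set()).add(term)
            summary.kept += 1
    fa = FunctionalAnnotation(
        name,
        reference,
        {a: {g: frozenset(t) for g, t in genes.items()}
         for a, genes in assignments.items()},
    )
    return fa, summary


def write_mapping(fa: FunctionalAnnotation) -> str:
    """Serialise to the generic two-column TSV dialect (round-trip safe)."""
    lines = [f"# FA: {fa.name}"]
    for gene, _aspect, terms in fa.items("ALL"):
        lines.append(f"{gene}\t{';'.join(sorted(terms))}")
    return "\n".join(lines) + "\n"


def write_gaf(fa: FunctionalAnnotation, db: str = "gofa") -> str:
    """Serialise to GAF 2.0 (17 columns, one row per gene-term pair)."""
    rows = ["!gaf-version: 2.0"]
    for gene, aspect, terms in fa.items("ALL"):
        for term in sorted(terms):
            ev = sorted(fa.evidence.get((gene, term), {"IEA"}))[0]
            fields = [""] * 17
            fields[0] = db
            fields[1] = gene
            fields[2] = gene
            fields[4] = term
            fields[5] = "GO_REF:0000000"
            fields[6] = ev
            fields[8] = _ASPECT_GAF.get(aspect, aspect)
            fields[11] = "gene_product"
            fields[12] = f"taxon:{fa.reference.organism or '0'}"
            fields[13] = "20100101"
            fields[14] = db
            rows.append("\t".join(fields))
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# FA algebra and cleanup
# ---------------------------------------------------------------------------


@dataclass
class ObsoleteReport:
    dropped: int = 0
    replaced: int = 0

    @property
    def total(self) -> int:
        return self.dropped + self.replaced


def strip_obsolete(
    fa: FunctionalAnnotation, graph: OntologyGraph, mode: str = "drop"
) -> tuple[FunctionalAnnotation, ObsoleteReport]:
    """Remove or rewrite obsolete-term assignments.

    ``drop`` removes every obsolete assignment; ``replace`` rewrites
    assignments whose obsolete term has live alternatives to those
    alternatives and drops the rest.
    """
    if mode not in ("drop", "replace"):
        raise ValueError(f"unknown obsolete-handling mode {mode!r}")
    report = ObsoleteReport()
    assignments: dict[str, dict[str, frozenset[str]]] = {}
    for gene, aspect, terms in fa.items("ALL"):
        kept: set[str] = set()
        for term in terms:
            if term in graph and graph.terms[term].obsolete:
                alternatives = graph.resolve_obsolete(term)
                if mode == "replace" and alternatives:
                    kept |= alternatives
                    report.replaced += 1
                else:
                    report.dropped += 1
            else:
                kept.add(term)
        if kept:
            assignments.setdefault(aspect, {})[gene] = frozenset(kept)
    out = FunctionalAnnotation(fa.name, fa.reference, assignments, fa.evidence)
    return out, report


def _check_references(
    a: FunctionalAnnotation,
    b: FunctionalAnnotation,
    intersect_references: bool,
) -> GeneProductSet:
    if a.reference.ids == b.reference.ids:
        return a.reference
    if not intersect_references:
        raise AnnotationError(
            "FAs have different references; pass intersect_references=True "
            "to operate on the common genes"
        )
    common = [g for g in a.reference.ids if g in b.reference]
    return GeneProductSet(tuple(common), organism=a.reference.organism)


def fa_union(
    a: FunctionalAnnotation,
    b: FunctionalAnnotation,
    intersect_references: bool = False,
) -> FunctionalAnnotation:
    """Per-gene set union of two FAs over a shared reference."""
    reference = _check_references(a, b, intersect_references)
    assignments: dict[str, dict[str, frozenset[str]]] = {}
    for aspect in sorted(set(a.aspects()) | set(b.aspects())):
        for gene in set(a.genes(aspect)) | set(b.genes(aspect)):
            if gene not in reference:
                continue
            merged = a.annotation_set(gene, aspect) | b.annotation_set(
                gene, aspect
            )
            if merged:
                assignments.setdefault(aspect, {})[gene] = merged
    evidence: dict[tuple[str, str], frozenset[str]] = dict(a.evidence)
    for pair, ev in b.evidence.items():
        evidence[pair] = evidence.get(pair, frozenset()) | ev
    return FunctionalAnnotation(
        f"({a.name} | {b.name})", reference, assignments, evidence
    )


def fa_intersection(
    a: FunctionalAnnotation,
    b: FunctionalAnnotation,
    intersect_references: bool = False,
) -> FunctionalAnnotation:
    """Per-gene set intersection; genes left empty are dropped."""
    reference = _check_references(a, b, intersect_references)
    assignments: dict[str, dict[str, frozenset[str]]] = {}
    for aspect in sorted(set(a.aspects()) & set(b.aspects())):
        for gene in set(a.genes(aspect)) & set(b.genes(aspect)):
            if gene not in reference:
                continue
            common = a.annotation_set(gene, aspect) & b.annotation_set(
                gene, aspect
            )
            if common:
                assignments.setdefault(aspect, {})[gene] = common
    return FunctionalAnnotation(
        f"({a.name} & {b.name})", reference, assignments
    )
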