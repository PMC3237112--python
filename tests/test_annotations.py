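"""Reference/FA readers, FA algebra and obsolete-term cleanup."""

import pytest

from gofa.annotations import (
    AnnotationError,
    FunctionalAnnotation,
    GeneProductSet,
    fa_intersection,
    fa_union,
    read_affymetrix,
    read_gaf,
    read_mapping,
    read_reference,
    strip_obsolete,
    write_gaf,
    write_mapping,
)

FASTA = """>g1 some description
ACGT
>g2 another
ACGT
>g3
ACGT
"""

GAF_HEADER = "!gaf-version: 2.0\n"


def gaf_row(gene, term, aspect="P", qualifier="", evidence="IEA"):
    fields = [""] * 17
    fields[0] = "db"
    fields[1] = gene
    fields[2] = gene
    fields[3] = qualifier
    fields[4] = term
    fields[5] = "GO_REF:0"
    fields[6] = evidence
    fields[8] = aspect
    fields[12] = "taxon:0"
    return "\t".join(fields)


@pytest.fixture
def reference():
    return GeneProductSet(("g1", "g2", "g3", "g4", "g5"))


class TestReference:
    def test_fasta_headers(self):
        ref = read_reference(FASTA, format="fasta")
        assert ref.ids == ("g1", "g2", "g3")

    def test_fasta_duplicate_warns_and_dedups(self):
        dup = FASTA + ">g1 again\nACGT\n"
        with pytest.warns(UserWarning):
            ref = read_reference(dup, format="fasta")
        assert ref.ids == ("g1", "g2", "g3")

    def test_id_list_skips_blanks_and_comments(self):
        ref = read_reference("# header\n\ng1\ng2\n\n", format="id-list")
        assert ref.ids == ("g1", "g2")

    def test_empty_source_is_an_error(self):
        with pytest.raises(AnnotationError):
            read_reference("# only comments\n", format="id-list")


class TestGaf:
    def test_rows_merged_per_gene(self, reference):
        text = GAF_HEADER + "\n".join(
            [
                gaf_row("g1", "GO:1"),
                gaf_row("g1", "GO:2"),
                gaf_row("g1", "GO:2"),  # duplicate merges
                gaf_row("g2", "GO:1", aspect="F"),
                gaf_row("g2", "GO:3", aspect="C"),
            ]
        )
        fa, summary = read_gaf(text, reference)
        assert summary.rows == 5
        assert fa.annotation_set("g1", "BP") == {"GO:1", "GO:2"}
        assert fa.annotation_set("g2", "MF") == {"GO:1"}
        assert fa.annotation_set("g2", "CC") == {"GO:3"}

    def test_not_qualifier_dropped(self, reference):
        text = GAF_HEADER + gaf_row("g1", "GO:1", qualifier="NOT")
        fa, summary = read_gaf(text, reference)
        assert summary.not_qualified == 1
        assert fa.genes() == set()

    def test_genes_outside_reference_counted(self, reference):
        text = GAF_HEADER + "\n".join(
            [gaf_row("g1", "GO:1"), gaf_row("ghost", "GO:1")]
        )
        fa, summary = read_gaf(text, reference)
        assert summary.not_in_reference == 1
        assert fa.genes() == {"g1"}

    def test_wrong_column_count_names_line(self, reference):
        text = GAF_HEADER + "too\tfew\tcolumns\n"
        with pytest.raises(AnnotationError, match="line 2"):
            read_gaf(text, reference)

    def test_evidence_recorded(self, reference):
        text = GAF_HEADER + "\n".join(
            [
                gaf_row("g1", "GO:1", evidence="IDA"),
                gaf_row("g1", "GO:1", evidence="IMP"),
                gaf_row("g1", "GO:2", evidence="IEA"),
            ]
        )
        fa, _ = read_gaf(text, reference)
        assert fa.evidence[("g1", "GO:1")] == {"IDA", "IMP"}
        gold = fa.experimental_consensus(min_codes=2)
        assert gold.annotation_set("g1", "BP") == {"GO:1"}
        iea_only = fa.filter_evidence({"IEA"})
        assert iea_only.annotation_set("g1", "BP") == {"GO:2"}


class TestAffymetrix:
    HEADER = (
        '"Probe Set ID","Gene Ontology Biological Process",'
        '"Gene Ontology Molecular Function",'
        '"Gene Ontology Cellular Component"\n'
    )

    def test_cell_parsing(self, reference):
        rows = (
            self.HEADER
            + '"g1","---","123 // kinase // IEA","5634 // nucleus // IEA"\n'
            + '"g2","1 // a // IDA /// 2 // b // IEA /// 3 // c // TAS",'
            '"---","---"\n'
        )
        fa, summary = read_affymetrix(rows, reference)
        assert fa.annotation_set("g1", "CC") == {"GO:0005634"}
        assert fa.annotation_set("g1", "MF") == {"GO:0000123"}
        assert fa.annotation_set("g1", "BP") == frozenset()
        assert len(fa.annotation_set("g2", "BP")) == 3

    def test_missing_go_columns_is_format_error(self, reference):
        with pytest.raises(AnnotationError):
            read_affymetrix('"Probe Set ID","Other"\n"g1","x"\n', reference)


class TestMapping:
    def test_known_terms_loaded(self, fx):
        text = "g1\tC\ng2\tC;D\ng3\tE\n"
        fa, summary = read_mapping(text, fx.reference, fx.graph)
        assert summary.kept == 4
        assert fa.annotation_set("g2", "generic") == {"C", "D"}

    def test_unknown_terms_rejected_into_report(self, fx):
        text = "g1\tC\ng1\tNOPE\n"
        fa, summary = read_mapping(text, fx.reference, fx.graph)
        assert summary.unknown_terms == [("g1", "NOPE")]
        assert fa.annotation_set("g1", "generic") == {"C"}

    def test_duplicate_pairs_collapse(self, fx):
        text = "g1\tC\ng1\tC\n"
        fa, _ = read_mapping(text, fx.reference, fx.graph)
        assert fa.n_assignments() == 1

    def test_round_trip(self, fx):
        again, summary = read_mapping(
            write_mapping(fx.fa), fx.reference, fx.graph, name=fx.fa.name
        )
        assert again == fx.fa
        assert not summary.unknown_terms

    def test_gaf_round_trip(self, fx):
        again, _ = read_gaf(write_gaf(fx.fa), fx.reference, name=fx.fa.name)
        assert again == fx.fa


class TestStripObsolete:
    def make(self, fx, sets):
        return FunctionalAnnotation(
            "t", fx.reference, {"generic": {
                g: frozenset(t) for g, t in sets.items()
            }}
        )

    def test_drop_mode(self, fx):
        fa = self.make(fx, {"g1": {"C", "X"}})
        out, report = strip_obsolete(fa, fx.graph, mode="drop")
        assert out.annotation_set("g1", "generic") == {"C"}
        assert report.dropped == 1

    def test_replace_mode_rewrites(self, fx):
        fa = self.make(fx, {"g1": {"Y"}})
        out, report = strip_obsolete(fa, fx.graph, mode="replace")
        assert out.annotation_set("g1", "generic") == {"B"}
        assert report.replaced == 1

    def test_replace_without_alternative_drops(self, fx):
        fa = self.make(fx, {"g1": {"X", "C"}})
        out, report = strip_obsolete(fa, fx.graph, mode="replace")
        assert out.annotation_set("g1", "generic") == {"C"}
        assert report.dropped == 1 and report.replaced == 0

    def test_clean_fa_unchanged(self, fx):
        out, report = strip_obsolete(fx.fa, fx.graph, mode="drop")
        assert out == fx.fa
        assert report.total == 0


class TestAlgebra:
    def make(self, fx, name, sets):
        return FunctionalAnnotation(
            name, fx.reference, {"generic": {
                g: frozenset(t) for g, t in sets.items()
            }}
        )

    def test_union_and_intersection_examples(self, fx):
        a = self.make(fx, "a", {"g1": {"C"}})
        b = self.make(fx, "b", {"g1": {"D"}})
        assert fa_union(a, b).annotation_set("g1", "generic") == {"C", "D"}
        assert "g1" not in fa_intersection(a, b).genes()

    def test_identical_fas_idempotent(self, fx):
        a = self.make(fx, "a", {"g1": {"C", "A"}})
        assert fa_union(a, a) == a
        assert fa_intersection(a, a) == a

    def test_partial_overlap(self, fx):
        a = self.make(fx, "a", {"g1": {"C", "A"}})
        b = self.make(fx, "b", {"g1": {"A", "E"}})
        assert fa_intersection(a, b).annotation_set("g1", "generic") == {"A"}

    def test_commutative_and_ordered(self, fx):
        a = self.make(fx, "a", {"g1": {"C"}, "g2": {"C", "D"}})
        b = self.make(fx, "b", {"g2": {"D", "E"}, "g3": {"E"}})
        assert fa_union(a, b) == fa_union(b, a)
        assert fa_intersection(a, b) == fa_intersection(b, a)
        inter, union = fa_intersection(a, b), fa_union(a, b)
        for gene in a.genes():
            assert inter.annotation_set(gene, "generic") <= a.annotation_set(
                gene, "generic"
            ) <= union.annotation_set(gene, "generic")

    def test_mismatched_references_need_flag(self, fx):
        other_ref = GeneProductSet(("g1", "zz"))
        a = self.make(fx, "a", {"g1": {"C"}})
        b = FunctionalAnnotation(
            "b", other_ref, {"generic": {"g1": frozenset({"D"})}}
        )
        with pytest.raises(AnnotationError):
            fa_union(a, b)
        merged = fa_union(a, b, intersect_references=True)
        assert merged.reference.ids == ("g1",)
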