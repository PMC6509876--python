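import pytest

from adekb import (
    AdeRecord,
    KnowledgeBase,
    MalformedAxiomError,
    TermRef,
    decode_axiom,
    generate_axiom,
    parse_owl_axioms,
    render_axiom,
    serialize_kb,
)
from adekb.axiom_pattern import (
    FORMS,
    SIDES,
    Intersection,
    Relation,
    Restriction,
    TermLeaf,
    Axiom,
    normalize_expression,
    parse_owl_declarations,
    structural_axioms,
)
from adekb.fixtures import ALOSETRON, CONSTIPATION, LINEZOLID, RASH

from .conftest import small_random_kb


def record_of(kb, drug, ae):
    return next(r for r in kb.records if r.drug == drug and r.ae == ae)


class TestRendering:
    def test_linezolid_drug_side_full(self, paper_kb):
        axiom = generate_axiom(paper_kb, record_of(paper_kb, LINEZOLID, RASH), "drug", "full")
        assert render_axiom(paper_kb, axiom) == (
            "LINEZOLID: ('drug associated with AE' some ('rash AE' and "
            "('occurs in' some Adult and ('has disease' some 'Pneumonia, Bacterial'))))"
        )

    def test_linezolid_drug_side_shortcut(self, paper_kb):
        axiom = generate_axiom(
            paper_kb, record_of(paper_kb, LINEZOLID, RASH), "drug", "shortcut"
        )
        assert render_axiom(paper_kb, axiom) == (
            "LINEZOLID: ('drug associated with AE in adult' some 'rash AE') and "
            "('used to treat disease' some 'Pneumonia, Bacterial')"
        )

    def test_alosetron_ae_side_full(self, paper_kb):
        axiom = generate_axiom(
            paper_kb, record_of(paper_kb, ALOSETRON, CONSTIPATION), "ae", "full"
        )
        rendered = render_axiom(paper_kb, axiom)
        expected = (
            "'constipation AE': 'occurs in' some (Adult and (('has disease' some "
            "'irritable bowel syndrome') and ('treated with drug' some ALOSETRON)))"
        )
        assert normalize_expression(rendered) == normalize_expression(expected)

    def test_context_free_record_prunes_to_bare_association(self):
        kb = KnowledgeBase()
        kb.add_term(TermRef("D", "DRUGX"))
        kb.add_term(TermRef("E", "pain AE"))
        record = AdeRecord("D", "E")
        axiom = generate_axiom(kb, record, "drug", "full")
        assert render_axiom(kb, axiom) == (
            "DRUGX: ('drug associated with AE' some 'pain AE')"
        )
        shortcut = generate_axiom(kb, record, "drug", "shortcut")
        assert render_axiom(kb, shortcut) == (
            "DRUGX: ('drug associated with AE' some 'pain AE')"
        )


class TestDecode:
    @pytest.mark.parametrize("side", SIDES)
    @pytest.mark.parametrize("form", FORMS)
    def test_decode_inverts_generate_on_fixture(self, paper_kb, side, form):
        for record in paper_kb.records:
            axiom = generate_axiom(paper_kb, record, side, form)
            assert decode_axiom(paper_kb, axiom) == record

    def test_forms_are_semantically_equivalent(self, paper_kb):
        """Full and shortcut forms of either side decode to the same record."""
        for record in paper_kb.records:
            decoded = {
                decode_axiom(paper_kb, generate_axiom(paper_kb, record, side, form)).key()
                for side in SIDES
                for form in FORMS
            }
            assert decoded == {record.key()}

    def test_unknown_relation_shape_rejected(self, paper_kb):
        record = record_of(paper_kb, LINEZOLID, RASH)
        bad = Axiom(
            subject=LINEZOLID,
            side="drug",
            form="full",
            tree=Restriction(Relation.HAS_MOA, TermLeaf(RASH)),
            provenance=record,
        )
        with pytest.raises(MalformedAxiomError):
            decode_axiom(paper_kb, bad)

    def test_overfilled_context_rejected(self, paper_kb):
        record = record_of(paper_kb, LINEZOLID, RASH)
        bad = Axiom(
            subject=LINEZOLID,
            side="drug",
            form="full",
            tree=Restriction(
                Relation.DRUG_ASSOCIATED_WITH_AE,
                Intersection((TermLeaf(RASH), TermLeaf(RASH), TermLeaf(RASH))),
            ),
            provenance=record,
        )
        with pytest.raises(MalformedAxiomError):
            decode_axiom(paper_kb, bad)


class TestSerialization:
    def test_empty_kb_serializes_to_header_only_document(self):
        doc = serialize_kb(KnowledgeBase())
        assert "owl:Ontology" in doc
        assert parse_owl_axioms(doc) == {}

    @pytest.mark.parametrize("form", FORMS)
    def test_parse_back_structural_equality(self, paper_kb, form):
        """Reparsing the emitted Turtle yields the same axiom multiset."""
        doc = serialize_kb(paper_kb, form=form)
        assert parse_owl_axioms(doc) == structural_axioms(paper_kb, form)

    def test_declarations_cover_terms_and_relations(self, paper_kb):
        doc = serialize_kb(paper_kb)
        decls = parse_owl_declarations(doc)
        term_iris = {t.iri for t in paper_kb.terms.values()}
        assert term_iris <= decls["classes"]
        # terms + the three domain/range anchor classes
        assert len(decls["classes"]) == len(term_iris) + 3
        assert decls["object_properties"] == {str(r.iri) for r in Relation}

    def test_rendered_axiom_text_embedded_labels(self, paper_kb):
        doc = serialize_kb(paper_kb)
        assert '"Pneumonia, Bacterial"' in doc
        assert '"drug associated with AE"' in doc

    def test_evidence_travels_as_axiom_annotation(self, paper_kb):
        doc = serialize_kb(paper_kb)
        assert "owl:annotatedTarget" in doc
        assert "package insert: linezolid" in doc

    def test_serialization_is_deterministic(self, paper_kb):
        assert serialize_kb(paper_kb) == serialize_kb(paper_kb)
        kb = small_random_kb(seed=13)
        assert serialize_kb(kb, form="shortcut") == serialize_kb(kb, form="shortcut")
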