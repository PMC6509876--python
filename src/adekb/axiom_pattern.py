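"""OWL axiom generation for the drug–AE–age–disease design pattern.

A curated association (drug D, adverse event E, age group G, treated disease
S) is an *n-ary* relation, but OWL object properties are binary. The design
pattern therefore encodes each association as a subclass-of-restriction
axiom in one of four shapes — {full, shortcut} × {drug-side, AE-side}:

* drug-side **full** nests the whole context under one relation::

      D subClassOf 'drug associated with AE' some
          (E and ('occurs in' some (G and ('has disease' some S))))

* drug-side **shortcut** flattens it into binary shortcut relations that
  carry the age in the property itself (efficient to query)::

      D subClassOf ('drug associated with AE in <age>' some E)
                   and ('used to treat disease' some S)

* AE-side **full** states the same fact from the adverse event::

      E subClassOf 'occurs in' some
          (G and ('has disease' some S) and ('treated with drug' some D))

* AE-side **shortcut** lifts the drug link to the top level::

      E subClassOf ('treated with drug' some D)
                   and ('drug AE occurs in' some (G and ('has disease' some S)))

An absent age or disease context prunes the corresponding sub-tree. The two
forms on either side carry the same information: ``decode_axiom`` inverts
``generate_axiom`` exactly for all four shapes.

``serialize_kb`` emits the whole knowledge base as OWL2 in Turtle: class
declarations with labels, subclass axioms for the is_a hierarchy, object
properties (with drug/disease/AE domain–range declarations for the shortcut
relations), one restriction axiom per record and side, profile links
(has_MoA / has_ingredient / used to treat disease) as existential
restrictions, and evidence citations as OWL axiom annotations.
``parse_owl_axioms`` reads such a document back into a structural axiom
multiset, which makes serialization round-trips checkable.
"""

from __future__ import annotations

import enum
import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Counter as CounterT
from typing import Dict, List, Optional, Sequence, Tuple, Union

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.collection import Collection
from rdflib.namespace import DCTERMS, OWL, RDF, RDFS

from .errors import MalformedAxiomError, ValidationError
from .kb_model import (
    AGE_TERM_IDS,
    AGE_TERMS,
    AdeRecord,
    AgeGroup,
    KnowledgeBase,
    curie_to_iri,
)

#: Namespace for the relations (and domain/range anchor classes) this
#: toolkit mints itself; everything else reuses source-ontology IRIs.
ADEKB = Namespace("https://w3id.org/adekb/")


class Relation(enum.Enum):
    """Object properties of the design pattern, with display labels."""

    DRUG_ASSOCIATED_WITH_AE = ("drug_associated_with_AE", "drug associated with AE")
    DRUG_ASSOCIATED_WITH_AE_IN_ADULT = (
        "drug_associated_with_AE_in_adult",
        "drug associated with AE in adult",
    )
    DRUG_ASSOCIATED_WITH_AE_IN_PEDIATRIC = (
        "drug_associated_with_AE_in_pediatric",
        "drug associated with AE in pediatric",
    )
    DRUG_ASSOCIATED_WITH_AE_IN_SENIOR = (
        "drug_associated_with_AE_in_senior",
        "drug associated with AE in senior",
    )
    USED_TO_TREAT_DISEASE = ("used_to_treat_disease", "used to treat disease")
    USED_TO_TREAT_DISEASE_IN_ADULT = (
        "used_to_treat_disease_in_adult",
        "used to treat disease in adult",
    )
    USED_TO_TREAT_DISEASE_IN_PEDIATRIC = (
        "used_to_treat_disease_in_pediatric",
        "used to treat disease in pediatric",
    )
    USED_TO_TREAT_DISEASE_IN_SENIOR = (
        "used_to_treat_disease_in_senior",
        "used to treat disease in senior",
    )
    OCCURS_IN = ("occurs_in", "occurs in")
    HAS_DISEASE = ("has_disease", "has disease")
    TREATED_WITH_DRUG = ("treated_with_drug", "treated with drug")
    DRUG_AE_OCCURS_IN = ("drug_AE_occurs_in", "drug AE occurs in")
    HAS_MOA = ("has_MoA", "has_MoA")
    HAS_INGREDIENT = ("has_ingredient", "has_ingredient")

    def __init__(self, local: str, label: str) -> None:
        self.local = local
        self.label = label

    @property
    def iri(self) -> URIRef:
        return ADEKB[self.local]


_RELATION_BY_IRI: Dict[str, Relation] = {str(r.iri): r for r in Relation}

#: Age-qualified shortcut relation for the drug→AE link.
AE_SHORTCUT: Dict[AgeGroup, Relation] = {
    AgeGroup.ADULT: Relation.DRUG_ASSOCIATED_WITH_AE_IN_ADULT,
    AgeGroup.PEDIATRIC: Relation.DRUG_ASSOCIATED_WITH_AE_IN_PEDIATRIC,
    AgeGroup.SENIOR: Relation.DRUG_ASSOCIATED_WITH_AE_IN_SENIOR,
    AgeGroup.UNSPECIFIED: Relation.DRUG_ASSOCIATED_WITH_AE,
}

#: (domain anchor, range anchor) for the shortcut relations, per the pattern:
#: drug→AE associations have domain drug / range adverse event; treatment
#: shortcuts have domain drug / range disease.
SHORTCUT_DOMAIN_RANGE: Dict[Relation, Tuple[URIRef, URIRef]] = {
    **{
        rel: (ADEKB["Drug"], ADEKB["AdverseEvent"])
        for rel in (
            Relation.DRUG_ASSOCIATED_WITH_AE,
            Relation.DRUG_ASSOCIATED_WITH_AE_IN_ADULT,
            Relation.DRUG_ASSOCIATED_WITH_AE_IN_PEDIATRIC,
            Relation.DRUG_ASSOCIATED_WITH_AE_IN_SENIOR,
        )
    },
    **{
        rel: (ADEKB["Drug"], ADEKB["Disease"])
        for rel in (
            Relation.USED_TO_TREAT_DISEASE,
            Relation.USED_TO_TREAT_DISEASE_IN_ADULT,
            Relation.USED_TO_TREAT_DISEASE_IN_PEDIATRIC,
            Relation.USED_TO_TREAT_DISEASE_IN_SENIOR,
        )
    },
}


# ---------------------------------------------------------------------------
# axiom trees


@dataclass(frozen=True)
class TermLeaf:
    """A named class at a leaf of the restriction tree."""

    id: str


@dataclass(frozen=True)
class Restriction:
    """Existential restriction: ``relation some filler``."""

    relation: Relation
    filler: "Node"


@dataclass(frozen=True)
class Intersection:
    """Boolean intersection of two or more class expressions."""

    parts: Tuple["Node", ...]


Node = Union[TermLeaf, Restriction, Intersection]

Side = str  # "drug" | "ae"
Form = str  # "full" | "shortcut"

SIDES = ("drug", "ae")
FORMS = ("full", "shortcut")


@dataclass(frozen=True)
class Axiom:
    """One subclass-of-restriction axiom encoding a single record."""

    subject: str
    side: Side
    form: Form
    tree: Node
    provenance: AdeRecord


def _age_leaf(age: AgeGroup) -> Optional[TermLeaf]:
    if age is AgeGroup.UNSPECIFIED:
        return None
    return TermLeaf(AGE_TERMS[age].id)


def _intersect(parts: Sequence[Node]) -> Node:
    parts = tuple(parts)
    if len(parts) == 1:
        return parts[0]
    return Intersection(parts)


def generate_axiom(
    kb: KnowledgeBase, record: AdeRecord, side: Side = "drug", form: Form = "full"
) -> Axiom:
    """Encode ``record`` as an axiom of the requested side and form.

    Absent age or disease context prunes the corresponding sub-tree; with no
    context at all the drug-side full form reduces to
    ``'drug associated with AE' some AE``.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    if form not in FORMS:
        raise ValueError(f"form must be one of {FORMS}, got {form!r}")
    kb.term(record.drug)
    kb.term(record.ae)
    if record.disease is not None:
        kb.term(record.disease)

    age = _age_leaf(record.age)
    disease = (
        Restriction(Relation.HAS_DISEASE, TermLeaf(record.disease))
        if record.disease is not None
        else None
    )
    context = [n for n in (age, disease) if n is not None]

    if side == "drug":
        if form == "full":
            inner = [TermLeaf(record.ae)]
            if context:
                inner.append(Restriction(Relation.OCCURS_IN, _intersect(context)))
            tree: Node = Restriction(
                Relation.DRUG_ASSOCIATED_WITH_AE, _intersect(inner)
            )
        else:
            parts: List[Node] = [
                Restriction(AE_SHORTCUT[record.age], TermLeaf(record.ae))
            ]
            if disease is not None:
                parts.append(
                    Restriction(Relation.USED_TO_TREAT_DISEASE, TermLeaf(record.disease))
                )
            tree = _intersect(parts)
        subject = record.drug
    else:
        drug_link = Restriction(Relation.TREATED_WITH_DRUG, TermLeaf(record.drug))
        if form == "full":
            tree = Restriction(Relation.OCCURS_IN, _intersect(context + [drug_link]))
        else:
            parts = [drug_link]
            if context:
                parts.append(
                    Restriction(Relation.DRUG_AE_OCCURS_IN, _intersect(context))
                )
            tree = _intersect(parts)
        subject = record.ae
    return Axiom(subject, side, form, tree, record)


# ---------------------------------------------------------------------------
# decoding


def _as_parts(node: Node) -> Tuple[Node, ...]:
    return node.parts if isinstance(node, Intersection) else (node,)


def _match_context(parts: Sequence[Node]) -> Tuple[AgeGroup, Optional[str]]:
    """Match an (Age, 'has disease' some D) context fragment, either pruned."""
    age = AgeGroup.UNSPECIFIED
    disease: Optional[str] = None
    for part in parts:
        if isinstance(part, TermLeaf) and part.id in AGE_TERM_IDS:
            if age is not AgeGroup.UNSPECIFIED:
                raise MalformedAxiomError("two age leaves in one context")
            age = AGE_TERM_IDS[part.id]
        elif (
            isinstance(part, Restriction)
            and part.relation is Relation.HAS_DISEASE
            and isinstance(part.filler, TermLeaf)
        ):
            if disease is not None:
                raise MalformedAxiomError("two disease fillers in one context")
            disease = part.filler.id
        else:
            raise MalformedAxiomError(f"unexpected context fragment: {part!r}")
    return age, disease


def _decode_tree(subject: str, side: Side, form: Form, tree: Node) -> AdeRecord:
    if side == "drug" and form == "full":
        if (
            not isinstance(tree, Restriction)
            or tree.relation is not Relation.DRUG_ASSOCIATED_WITH_AE
        ):
            raise MalformedAxiomError("drug-side full axiom must start with "
                                      "'drug associated with AE'")
        parts = _as_parts(tree.filler)
        if not parts or not isinstance(parts[0], TermLeaf):
            raise MalformedAxiomError("missing AE leaf")
        ae = parts[0].id
        age, disease = AgeGroup.UNSPECIFIED, None
        if len(parts) == 2:
            occ = parts[1]
            if not isinstance(occ, Restriction) or occ.relation is not Relation.OCCURS_IN:
                raise MalformedAxiomError("context must sit under 'occurs in'")
            age, disease = _match_context(_as_parts(occ.filler))
            if age is AgeGroup.UNSPECIFIED and disease is None:
                raise MalformedAxiomError("empty 'occurs in' context")
        elif len(parts) > 2:
            raise MalformedAxiomError("too many conjuncts under the AE filler")
        return AdeRecord(subject, ae, age, disease)

    if side == "drug" and form == "shortcut":
        parts = _as_parts(tree)
        if not parts or not isinstance(parts[0], Restriction):
            raise MalformedAxiomError("shortcut axiom must start with the AE link")
        head = parts[0]
        ages = [g for g, rel in AE_SHORTCUT.items() if rel is head.relation]
        if not ages or not isinstance(head.filler, TermLeaf):
            raise MalformedAxiomError("unknown AE shortcut relation")
        ae, age = head.filler.id, ages[0]
        disease = None
        if len(parts) == 2:
            tail = parts[1]
            if (
                not isinstance(tail, Restriction)
                or tail.relation is not Relation.USED_TO_TREAT_DISEASE
                or not isinstance(tail.filler, TermLeaf)
            ):
                raise MalformedAxiomError("second conjunct must be "
                                          "'used to treat disease'")
            disease = tail.filler.id
        elif len(parts) > 2:
            raise MalformedAxiomError("too many shortcut conjuncts")
        return AdeRecord(subject, ae, age, disease)

    if side == "ae" and form == "full":
        if not isinstance(tree, Restriction) or tree.relation is not Relation.OCCURS_IN:
            raise MalformedAxiomError("AE-side full axiom must start with 'occurs in'")
        parts = list(_as_parts(tree.filler))
        drugs = [
            p
            for p in parts
            if isinstance(p, Restriction)
            and p.relation is Relation.TREATED_WITH_DRUG
            and isinstance(p.filler, TermLeaf)
        ]
        if len(drugs) != 1:
            raise MalformedAxiomError("exactly one 'treated with drug' link required")
        parts.remove(drugs[0])
        age, disease = _match_context(parts)
        return AdeRecord(drugs[0].filler.id, subject, age, disease)

    # side == "ae", form == "shortcut"
    parts = _as_parts(tree)
    if (
        not parts
        or not isinstance(parts[0], Restriction)
        or parts[0].relation is not Relation.TREATED_WITH_DRUG
        or not isinstance(parts[0].filler, TermLeaf)
    ):
        raise MalformedAxiomError("AE-side shortcut must start with "
                                  "'treated with drug'")
    drug = parts[0].filler.id
    age, disease = AgeGroup.UNSPECIFIED, None
    if len(parts) == 2:
        occ = parts[1]
        if not isinstance(occ, Restriction) or occ.relation is not Relation.DRUG_AE_OCCURS_IN:
            raise MalformedAxiomError("context must sit under 'drug AE occurs in'")
        age, disease = _match_context(_as_parts(occ.filler))
        if age is AgeGroup.UNSPECIFIED and disease is None:
            raise MalformedAxiomError("empty 'drug AE occurs in' context")
    elif len(parts) > 2:
        raise MalformedAxiomError("too many shortcut conjuncts")
    return AdeRecord(drug, subject, age, disease)


def decode_axiom(kb: KnowledgeBase, axiom: Axiom) -> AdeRecord:
    """Recover the record an axiom tree encodes (inverse of generate_axiom).

    The quadruple (drug, AE, age, disease) is read purely from the tree; the
    evidence citation travels as an annotation on the axiom, so it is copied
    from the axiom's provenance. Raises :class:`MalformedAxiomError` when the
    tree matches none of the four pattern shapes, and
    :class:`UnknownTermError` when a leaf id is absent from the store.
    """
    record = _decode_tree(axiom.subject, axiom.side, axiom.form, axiom.tree)
    kb.term(record.drug)
    kb.term(record.ae)
    if record.disease is not None:
        kb.term(record.disease)
    evidence = axiom.provenance.evidence if axiom.provenance is not None else None
    if evidence is not None:
        record = AdeRecord(record.drug, record.ae, record.age, record.disease, evidence)
    return record


# ---------------------------------------------------------------------------
# human-readable rendering


def _token(label: str) -> str:
    return f"'{label}'" if any(ch.isspace() for ch in label) else label


def _label_of(kb: KnowledgeBase, term_id: str) -> str:
    return kb.label(term_id)


def _render(kb: KnowledgeBase, node: Node, depth: int) -> str:
    """Render a class expression in Manchester-like syntax.

    ``depth`` counts enclosing restrictions: an intersection that fills a
    top-level restriction is parenthesized, deeper ones are not, matching
    the conventional printing of these axioms.
    """
    if isinstance(node, TermLeaf):
        return _token(_label_of(kb, node.id))
    if isinstance(node, Restriction):
        filler = node.filler
        if isinstance(filler, TermLeaf):
            body = _render(kb, filler, depth + 1)
        elif isinstance(filler, Restriction):
            body = f"({_render(kb, filler, depth + 1)})"
        else:  # Intersection
            inner = _render(kb, filler, depth + 1)
            body = f"({inner})" if depth == 0 else inner
        return f"{_token(node.relation.label)} some {body}"
    # Intersection: parenthesize restriction conjuncts, leave leaves bare
    rendered = [
        f"({_render(kb, p, depth)})" if isinstance(p, Restriction) else _render(kb, p, depth)
        for p in node.parts
    ]
    return " and ".join(rendered)


def render_axiom(kb: KnowledgeBase, axiom: Axiom) -> str:
    """Render ``SUBJECT: <class expression>`` as human-readable text."""
    subject = _token(_label_of(kb, axiom.subject))
    if isinstance(axiom.tree, Restriction):
        return f"{subject}: ({_render(kb, axiom.tree, 0)})"
    return f"{subject}: {_render(kb, axiom.tree, 0)}"


def normalize_expression(text: str) -> str:
    """Collapse whitespace and strip quotes/parentheses for lenient
    comparison of rendered class expressions (printing conventions vary in
    how they quote multi-word labels and group nested conjunctions)."""
    for ch in "()'‘’“”\"":
        text = text.replace(ch, " ")
    return " ".join(text.split())


# ---------------------------------------------------------------------------
# OWL (Turtle) serialization


def _sorted_records(kb: KnowledgeBase) -> List[AdeRecord]:
    return sorted(
        kb.records, key=lambda r: (r.drug, r.ae, r.age.value, r.disease or "")
    )


class _BNodeSeq:
    """Sequentially numbered blank nodes so serialization is byte-stable."""

    def __init__(self) -> None:
        self._counter = itertools.count()

    def __call__(self) -> BNode:
        return BNode(f"b{next(self._counter)}")


def _rdf_list(graph: Graph, members: Sequence, bnode: _BNodeSeq):
    """Build an rdf:List with sequentially labelled cells (the stock
    Collection helper mints uuid-labelled cells, which both breaks byte
    stability and trips the Turtle pretty-printer into dropping property
    blocks of blank nodes referenced from inside a collection)."""
    if not members:
        return RDF.nil
    head = bnode()
    cell = head
    for i, member in enumerate(members):
        graph.add((cell, RDF.first, member))
        nxt = bnode() if i < len(members) - 1 else RDF.nil
        graph.add((cell, RDF.rest, nxt))
        cell = nxt
    return head


def _tree_to_rdf(graph: Graph, node: Node, bnode: _BNodeSeq) -> Union[URIRef, BNode]:
    if isinstance(node, TermLeaf):
        return URIRef(curie_to_iri(node.id))
    if isinstance(node, Restriction):
        r = bnode()
        graph.add((r, RDF.type, OWL.Restriction))
        graph.add((r, OWL.onProperty, node.relation.iri))
        graph.add((r, OWL.someValuesFrom, _tree_to_rdf(graph, node.filler, bnode)))
        return r
    c = bnode()
    graph.add((c, RDF.type, OWL.Class))
    members = [_tree_to_rdf(graph, p, bnode) for p in node.parts]
    graph.add((c, OWL.intersectionOf, _rdf_list(graph, members, bnode)))
    return c


def serialize_kb(
    kb: KnowledgeBase, form: Form = "full", sides: Sequence[Side] = SIDES
) -> str:
    """Serialize the whole knowledge base as an OWL2 document in Turtle.

    Emits class declarations with label annotations, subclass axioms for the
    is_a hierarchy, object-property declarations (domain/range anchors for
    the shortcut relations), one subclass-of-restriction axiom per record
    and requested side in the requested ``form``, profile links as
    existential restrictions, and evidence strings as axiom annotations.
    Output is deterministic: axioms are ordered by (drug, ae, age, disease)
    and blank nodes are numbered sequentially.
    """
    violations = kb.validate()
    if violations:
        raise ValidationError(
            f"knowledge base invalid: {len(violations)} violation(s), first: "
            f"{violations[0]}"
        )
    graph = Graph()
    graph.bind("owl", OWL)
    graph.bind("rdfs", RDFS)
    graph.bind("dcterms", DCTERMS)
    graph.bind("adekb", ADEKB)
    bnode = _BNodeSeq()

    ontology = ADEKB["ontology"]
    graph.add((ontology, RDF.type, OWL.Ontology))

    for anchor in ("Drug", "AdverseEvent", "Disease"):
        graph.add((ADEKB[anchor], RDF.type, OWL.Class))

    for term_id in sorted(kb.terms):
        term = kb.terms[term_id]
        iri = URIRef(term.iri)
        graph.add((iri, RDF.type, OWL.Class))
        graph.add((iri, RDFS.label, Literal(term.label)))

    for edge in sorted(kb.edges, key=lambda e: (e.child, e.parent)):
        graph.add(
            (
                URIRef(curie_to_iri(edge.child)),
                RDFS.subClassOf,
                URIRef(curie_to_iri(edge.parent)),
            )
        )

    for rel in Relation:
        graph.add((rel.iri, RDF.type, OWL.ObjectProperty))
        graph.add((rel.iri, RDFS.label, Literal(rel.label)))
        if rel in SHORTCUT_DOMAIN_RANGE:
            domain, range_ = SHORTCUT_DOMAIN_RANGE[rel]
            graph.add((rel.iri, RDFS.domain, domain))
            graph.add((rel.iri, RDFS.range, range_))

    for record in _sorted_records(kb):
        for side in sides:
            axiom = generate_axiom(kb, record, side=side, form=form)
            subject = URIRef(curie_to_iri(axiom.subject))
            target = _tree_to_rdf(graph, axiom.tree, bnode)
            graph.add((subject, RDFS.subClassOf, target))
            if record.evidence:
                ann = bnode()
                graph.add((ann, RDF.type, OWL.Axiom))
                graph.add((ann, OWL.annotatedSource, subject))
                graph.add((ann, OWL.annotatedProperty, RDFS.subClassOf))
                graph.add((ann, OWL.annotatedTarget, target))
                graph.add((ann, DCTERMS.source, Literal(record.evidence)))

    for drug_id in sorted(kb.profiles):
        prof = kb.profiles[drug_id]
        subject = URIRef(curie_to_iri(drug_id))
        for rel, targets in (
            (Relation.HAS_INGREDIENT, sorted(prof.ingredients)),
            (Relation.HAS_MOA, sorted(prof.moas)),
            (Relation.USED_TO_TREAT_DISEASE, sorted(prof.diseases_treated)),
        ):
            for target_id in targets:
                target = _tree_to_rdf(graph, Restriction(rel, TermLeaf(target_id)), bnode)
                graph.add((subject, RDFS.subClassOf, target))

    return graph.serialize(format="turtle")


# ---------------------------------------------------------------------------
# structural parse-back (round-trip oracle support)

Canonical = Tuple  # nested tuples; intersections become sorted tuples


def _canonical_tree(node: Node) -> Canonical:
    if isinstance(node, TermLeaf):
        return ("class", curie_to_iri(node.id))
    if isinstance(node, Restriction):
        return ("some", str(node.relation.iri), _canonical_tree(node.filler))
    return ("and", tuple(sorted(_canonical_tree(p) for p in node.parts)))


def structural_axioms(kb: KnowledgeBase, form: Form = "full") -> CounterT[Canonical]:
    """Canonical multiset of all subclass-of-restriction axioms serialize_kb
    would emit (record axioms on both sides plus profile links), computed
    directly from the store without touching RDF."""
    out: CounterT[Canonical] = Counter()
    for record in _sorted_records(kb):
        for side in SIDES:
            axiom = generate_axiom(kb, record, side=side, form=form)
            out[(curie_to_iri(axiom.subject), _canonical_tree(axiom.tree))] += 1
    for drug_id, prof in kb.profiles.items():
        subject = curie_to_iri(drug_id)
        for rel, targets in (
            (Relation.HAS_INGREDIENT, prof.ingredients),
            (Relation.HAS_MOA, prof.moas),
            (Relation.USED_TO_TREAT_DISEASE, prof.diseases_treated),
        ):
            for target_id in targets:
                out[(subject, ("some", str(rel.iri), ("class", curie_to_iri(target_id))))] += 1
    return out


def _rdf_to_canonical(graph: Graph, node) -> Canonical:
    if isinstance(node, URIRef):
        return ("class", str(node))
    if (node, RDF.type, OWL.Restriction) in graph:
        prop = graph.value(node, OWL.onProperty)
        filler = graph.value(node, OWL.someValuesFrom)
        if prop is None or filler is None:
            raise MalformedAxiomError("incomplete restriction in OWL document")
        return ("some", str(prop), _rdf_to_canonical(graph, filler))
    list_head = graph.value(node, OWL.intersectionOf)
    if list_head is not None:
        members = list(Collection(graph, list_head))
        return ("and", tuple(sorted(_rdf_to_canonical(graph, m) for m in members)))
    raise MalformedAxiomError(f"unrecognized class expression node: {node!r}")


def parse_owl_axioms(document: str) -> CounterT[Canonical]:
    """Parse a Turtle OWL document and return the canonical multiset of its
    subclass-of-restriction axioms (named-class subclass edges from the
    hierarchy are excluded). Uses a standard RDF parser, so a document this
    toolkit emits must re-parse without error."""
    graph = Graph()
    graph.parse(data=document, format="turtle")
    out: CounterT[Canonical] = Counter()
    for subject, _, target in graph.triples((None, RDFS.subClassOf, None)):
        if isinstance(target, URIRef):
            continue  # plain is_a edge between named classes
        out[(str(subject), _rdf_to_canonical(graph, target))] += 1
    return out


def parse_owl_declarations(document: str) -> Dict[str, set]:
    """Classes and object properties declared in a Turtle OWL document."""
    graph = Graph()
    graph.parse(data=document, format="turtle")
    return {
        "classes": {
            str(s)
            for s in graph.subjects(RDF.type, OWL.Class)
            if isinstance(s, URIRef)
        },
        "object_properties": {
            str(s) for s in graph.subjects(RDF.type, OWL.ObjectProperty)
        },
    }
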