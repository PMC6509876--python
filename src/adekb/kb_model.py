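"""Core domain model: terms, the is_a hierarchy, drug profiles, and ADE records.

The central object is :class:`KnowledgeBase`, an in-memory store with four
parts:

* ``terms`` — CURIE-identified, labelled nodes (:class:`TermRef`), each
  attributed to a source ontology (OAE for adverse events, NDF-RT for drugs,
  chemical ingredients and mechanisms of action, DOID for diseases, BFO for
  the upper level, ...);
* an ``is_a`` hierarchy over those terms, kept acyclic (a DAG — multiple
  parents are allowed, cycles are hard errors);
* ``profiles`` — per-drug links to chemical ingredients, mechanisms of
  action (MoA) and treatable diseases;
* ``records`` — curated drug–adverse-event associations, each optionally
  contextualised by a patient age group and the disease being treated, with
  a free-text evidence citation (typically a package-insert reference).

Hierarchy reasoning is limited to the transitive closure of ``is_a``
(ancestors/descendants); no description-logic classification is attempted.
All matching is by term id, case-sensitively — labels are display-only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import networkx as nx

from .errors import (
    CycleError,
    DuplicateRecordError,
    DuplicateTermError,
    UnknownTermError,
    ValidationError,
)

#: Registered CURIE prefixes and the IRI namespace each expands to.
#: OTHER is the catch-all for terms outside the registered sources.
PREFIX_REGISTRY: Dict[str, str] = {
    "OAE": "http://purl.obolibrary.org/obo/OAE_",
    "NDFRT": "http://evs.nci.nih.gov/ftp1/NDF-RT/NDF-RT.owl#",
    "DOID": "http://purl.obolibrary.org/obo/DOID_",
    "NCBITaxon": "http://purl.obolibrary.org/obo/NCBITaxon_",
    "BFO": "http://purl.obolibrary.org/obo/BFO_",
    "ODAE": "http://purl.obolibrary.org/obo/ODAE_",
    "OTHER": "https://w3id.org/adekb/term/",
}


class Kind(str, enum.Enum):
    """Role a term plays in the knowledge base."""

    DRUG = "drug"
    DRUG_CLASS = "drug_class"
    MOA = "moa"
    INGREDIENT = "ingredient"
    DISEASE = "disease"
    ADVERSE_EVENT = "adverse_event"
    AGE_GROUP = "age_group"
    UPPER = "upper"


class AgeGroup(str, enum.Enum):
    """Patient age context of an association.

    ``UNSPECIFIED`` marks the *absence* of an age context; it is never a
    fourth population.
    """

    ADULT = "adult"
    PEDIATRIC = "pediatric"
    SENIOR = "senior"
    UNSPECIFIED = "unspecified"


def curie_to_iri(curie: str) -> str:
    """Expand ``PREFIX:local`` to a full IRI using :data:`PREFIX_REGISTRY`."""
    prefix, _, local = curie.partition(":")
    ns = PREFIX_REGISTRY.get(prefix, PREFIX_REGISTRY["OTHER"])
    return ns + local


@dataclass(frozen=True)
class TermRef:
    """A CURIE-identified, labelled node attributed to a source ontology."""

    id: str
    label: str
    source: str = ""
    kind: Kind = Kind.UPPER

    def __post_init__(self) -> None:
        if not self.id or not self.id.strip():
            raise ValidationError("term id must be non-empty")
        if not self.label or not self.label.strip():
            raise ValidationError(f"term {self.id!r}: label must be non-empty")
        if not self.source:
            prefix = self.id.partition(":")[0]
            object.__setattr__(
                self, "source", prefix if prefix in PREFIX_REGISTRY else "OTHER"
            )
        elif self.source not in PREFIX_REGISTRY:
            raise ValidationError(
                f"term {self.id!r}: unknown source {self.source!r}"
            )
        if not isinstance(self.kind, Kind):
            object.__setattr__(self, "kind", Kind(self.kind))

    @property
    def iri(self) -> str:
        return curie_to_iri(self.id)


@dataclass(frozen=True)
class HierarchyEdge:
    """One ``is_a`` assertion: ``child is_a parent``."""

    child: str
    parent: str


@dataclass
class DrugProfile:
    """Links a drug to its chemical ingredients, MoAs and treatable diseases."""

    drug: str
    ingredients: Set[str] = field(default_factory=set)
    moas: Set[str] = field(default_factory=set)
    diseases_treated: Set[str] = field(default_factory=set)


@dataclass(frozen=True)
class AdeRecord:
    """One curated drug–AE association in an (age, disease) context.

    ``disease=None`` means no treated-disease context; ``age=UNSPECIFIED``
    means no age context. ``evidence`` is a free-text citation, typically the
    package-insert document the association was curated from.
    """

    drug: str
    ae: str
    age: AgeGroup = AgeGroup.UNSPECIFIED
    disease: Optional[str] = None
    evidence: Optional[str] = None

    def __post_init__(self) -> None:
        if not isinstance(self.age, AgeGroup):
            object.__setattr__(self, "age", AgeGroup(self.age))

    def key(self) -> Tuple[str, str, str, Optional[str]]:
        """The uniqueness key: (drug, ae, age, disease)."""
        return (self.drug, self.ae, self.age.value, self.disease)


@dataclass(frozen=True)
class Violation:
    """One invariant violation reported by :meth:`KnowledgeBase.validate`."""

    rule: str
    subject: str
    message: str


#: Built-in age-group terms so that axiom trees can reference ages by id.
AGE_TERMS: Dict[AgeGroup, TermRef] = {
    AgeGroup.ADULT: TermRef("ODAE:adult", "Adult", "ODAE", Kind.AGE_GROUP),
    AgeGroup.PEDIATRIC: TermRef(
        "ODAE:pediatric", "Pediatric", "ODAE", Kind.AGE_GROUP
    ),
    AgeGroup.SENIOR: TermRef("ODAE:senior", "Senior", "ODAE", Kind.AGE_GROUP),
}

AGE_TERM_IDS: Dict[str, AgeGroup] = {t.id: g for g, t in AGE_TERMS.items()}


class KnowledgeBase:
    """The single queryable store all other modules build on."""

    def __init__(self) -> None:
        self.terms: Dict[str, TermRef] = {}
        self.profiles: Dict[str, DrugProfile] = {}
        self.records: List[AdeRecord] = []
        self._graph = nx.DiGraph()  # edge child -> parent
        for term in AGE_TERMS.values():
            self.add_term(term)

    # -- terms -------------------------------------------------------------

    def add_term(self, term: TermRef) -> "KnowledgeBase":
        if term.id in self.terms:
            raise DuplicateTermError(f"term id already present: {term.id!r}")
        self.terms[term.id] = term
        self._graph.add_node(term.id)
        return self

    def has_term(self, term_id: str) -> bool:
        return term_id in self.terms

    def term(self, term_id: str) -> TermRef:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term id: {term_id!r}") from None

    def label(self, term_id: str) -> str:
        return self.term(term_id).label

    def terms_of_kind(self, kind: Kind) -> List[TermRef]:
        return [t for t in self.terms.values() if t.kind is kind]

    # -- hierarchy ---------------------------------------------------------

    @property
    def edges(self) -> Set[HierarchyEdge]:
        return {HierarchyEdge(c, p) for c, p in self._graph.edges()}

    def add_is_a(self, child: str, parent: str) -> "KnowledgeBase":
        """Assert ``child is_a parent``; refuses edges that close a cycle."""
        self.term(child)
        self.term(parent)
        if child == parent or nx.has_path(self._graph, parent, child):
            raise CycleError(
                f"edge {child!r} is_a {parent!r} would create a cycle"
            )
        self._graph.add_edge(child, parent)
        return self

    def ancestors(self, term_id: str) -> Set[str]:
        """Transitive closure of parents of ``term_id`` (excludes itself)."""
        self.term(term_id)
        return set(nx.descendants(self._graph, term_id))

    def descendants(self, term_id: str) -> Set[str]:
        """Transitive closure of children of ``term_id`` (excludes itself)."""
        self.term(term_id)
        return set(nx.ancestors(self._graph, term_id))

    # -- profiles ----------------------------------------------------------

    def set_profile(self, profile: DrugProfile) -> "KnowledgeBase":
        """Add a drug profile; repeated calls for one drug merge by union."""
        self.term(profile.drug)
        for ref in (
            profile.ingredients | profile.moas | profile.diseases_treated
        ):
            self.term(ref)
        existing = self.profiles.get(profile.drug)
        if existing is None:
            self.profiles[profile.drug] = DrugProfile(
                profile.drug,
                set(profile.ingredients),
                set(profile.moas),
                set(profile.diseases_treated),
            )
        else:
            existing.ingredients |= profile.ingredients
            existing.moas |= profile.moas
            existing.diseases_treated |= profile.diseases_treated
        return self

    # -- records -----------------------------------------------------------

    def add_record(self, record: AdeRecord) -> "KnowledgeBase":
        self.term(record.drug)
        self.term(record.ae)
        if record.disease is not None:
            self.term(record.disease)
        if any(r.key() == record.key() for r in self.records):
            raise DuplicateRecordError(
                f"duplicate (drug, ae, age, disease) record: {record.key()}"
            )
        self.records.append(record)
        return self

    # -- validation --------------------------------------------------------

    def validate(self) -> List[Violation]:
        """Check every invariant; an empty list means the store is sound.

        Violations are returned, never raised, so a partially built or
        hand-patched store can be diagnosed in one pass.
        """
        out: List[Violation] = []

        def check_ref(ref: str, subject: str, role: str) -> None:
            if ref not in self.terms:
                out.append(
                    Violation(
                        "referential-integrity",
                        subject,
                        f"{role} references unknown term {ref!r}",
                    )
                )

        for edge in self.edges:
            check_ref(edge.child, f"edge {edge.child}->{edge.parent}", "child")
            check_ref(edge.parent, f"edge {edge.child}->{edge.parent}", "parent")
        if not nx.is_directed_acyclic_graph(self._graph):
            out.append(
                Violation("acyclicity", "<hierarchy>", "is_a graph has a cycle")
            )
        for drug, prof in self.profiles.items():
            subject = f"profile {drug}"
            check_ref(drug, subject, "drug")
            for i in sorted(prof.ingredients):
                check_ref(i, subject, "ingredient")
            for m in sorted(prof.moas):
                check_ref(m, subject, "moa")
            for d in sorted(prof.diseases_treated):
                check_ref(d, subject, "disease_treated")
        seen: Set[Tuple[str, str, str, Optional[str]]] = set()
        for rec in self.records:
            subject = f"record {rec.key()}"
            check_ref(rec.drug, subject, "drug")
            check_ref(rec.ae, subject, "ae")
            if rec.disease is not None:
                check_ref(rec.disease, subject, "disease")
            if rec.key() in seen:
                out.append(
                    Violation(
                        "record-uniqueness",
                        subject,
                        "duplicate (drug, ae, age, disease) tuple",
                    )
                )
            seen.add(rec.key())
        return out

    # -- misc --------------------------------------------------------------

    def stats(self) -> Dict[str, int]:
        """Headline counts for the store (terms, edges, profiles, records)."""
        counts = {
            "terms": len(self.terms),
            "is_a_edges": self._graph.number_of_edges(),
            "profiles": len(self.profiles),
            "records": len(self.records),
        }
        for kind in Kind:
            n = len(self.terms_of_kind(kind))
            if n:
                counts[f"terms_{kind.value}"] = n
        return counts


# Functional aliases mirroring the operation-style surface. Each returns the
# (mutated) knowledge base so calls can be chained.

def add_term(kb: KnowledgeBase, term: TermRef) -> KnowledgeBase:
    return kb.add_term(term)


def add_is_a(kb: KnowledgeBase, child: str, parent: str) -> KnowledgeBase:
    return kb.add_is_a(child, parent)


def ancestors(kb: KnowledgeBase, term_id: str) -> Set[str]:
    return kb.ancestors(term_id)


def descendants(kb: KnowledgeBase, term_id: str) -> Set[str]:
    return kb.descendants(term_id)


def validate(kb: KnowledgeBase) -> List[Violation]:
    return kb.validate()
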