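"""Hierarchy-aware queries over a knowledge base.

All class filters are *transitive*: a drug matches a MoA class if any of its
profile MoAs equals the class or lies below it in the is_a hierarchy, and a
disease filter matches a record whose treated disease equals the filter term
or lies below it. Age filters are exact-match — the age axis is a flat
enumeration, and a record without an age context (``unspecified``) matches
only age-unconstrained queries. Adverse events are matched by exact id;
callers wanting AE-subtree aggregation can compose with
``KnowledgeBase.descendants``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

from .kb_model import AdeRecord, AgeGroup, Kind, KnowledgeBase


@dataclass(frozen=True)
class Context:
    """An (age, disease) query context; either element may be absent."""

    age: Optional[AgeGroup] = None
    disease: Optional[str] = None


@dataclass(frozen=True)
class AdeQuadruple:
    """One joined result row: drug, the MoA it matched through (if any),
    the treated-disease context, the adverse event, and the age group."""

    drug: str
    moa: Optional[str]
    disease: Optional[str]
    ae: str
    age: AgeGroup

    def sort_key(self) -> Tuple[str, str, str, str, str]:
        """None-safe deterministic ordering key."""
        return (self.drug, self.moa or "", self.disease or "", self.ae, self.age.value)

    def __lt__(self, other: "AdeQuadruple") -> bool:
        return self.sort_key() < other.sort_key()


def _class_closure(kb: KnowledgeBase, class_id: str) -> Set[str]:
    kb.term(class_id)
    return {class_id} | kb.descendants(class_id)


def drugs_by_class(kb: KnowledgeBase, class_id: str) -> Set[str]:
    """Drugs that belong to a MoA class or drug class, transitively.

    A drug is a member if one of its profile MoAs is the class or a
    descendant of it, or if the drug term itself sits below the class in
    the is_a hierarchy (drug-class membership).
    """
    under = _class_closure(kb, class_id)
    members: Set[str] = set()
    for term in kb.terms.values():
        if term.kind is not Kind.DRUG:
            continue
        prof = kb.profiles.get(term.id)
        if prof is not None and prof.moas & under:
            members.add(term.id)
        elif term.id in under:
            members.add(term.id)
    return members


def _record_matches(
    kb: KnowledgeBase,
    record: AdeRecord,
    age: Optional[AgeGroup],
    disease_closure: Optional[Set[str]],
) -> bool:
    if age is not None and record.age is not age:
        return False
    if disease_closure is not None:
        if record.disease is None or record.disease not in disease_closure:
            return False
    return True


def query_ade(
    kb: KnowledgeBase,
    moa_class: Optional[str] = None,
    age: Optional[AgeGroup] = None,
    disease: Optional[str] = None,
    drug: Optional[str] = None,
) -> List[AdeQuadruple]:
    """Join drug profiles with ADE records under the given filters.

    Returns deduplicated quadruples in a deterministic sort order. When a
    MoA-class filter is given, the quadruple's ``moa`` is each profile MoA
    the drug matched through; otherwise every profile MoA is reported (or
    ``None`` for a drug with no MoA annotation).
    """
    if drug is not None:
        kb.term(drug)
    if age is not None and not isinstance(age, AgeGroup):
        age = AgeGroup(age)
    moa_closure = _class_closure(kb, moa_class) if moa_class is not None else None
    disease_closure = _class_closure(kb, disease) if disease is not None else None
    class_members = drugs_by_class(kb, moa_class) if moa_class is not None else None

    results: Set[AdeQuadruple] = set()
    for record in kb.records:
        if drug is not None and record.drug != drug:
            continue
        if class_members is not None and record.drug not in class_members:
            continue
        if not _record_matches(kb, record, age, disease_closure):
            continue
        prof = kb.profiles.get(record.drug)
        moas: List[Optional[str]]
        if moa_closure is not None:
            moas = sorted((prof.moas & moa_closure) if prof else set())
            if not moas:
                # membership came through the drug hierarchy, not a MoA
                moas = [None]
        else:
            moas = sorted(prof.moas) if prof and prof.moas else [None]
        for moa in moas:
            results.add(
                AdeQuadruple(record.drug, moa, record.disease, record.ae, record.age)
            )
    return sorted(results)


def context_aes(kb: KnowledgeBase, drug: str, context: Context) -> Set[str]:
    """Adverse-event ids recorded for ``drug`` within one (age, disease)
    context."""
    return {
        q.ae
        for q in query_ade(kb, age=context.age, disease=context.disease, drug=drug)
    }


def compare_contexts(
    kb: KnowledgeBase,
    drug: str,
    context_a: Context,
    context_b: Context,
) -> Tuple[Set[str], Set[str], Set[str]]:
    """Set algebra over a drug's AEs in two contexts.

    Returns ``(shared, only_a, only_b)``: the intersection of the two
    context AE sets and each one-sided difference. The three sets are
    pairwise disjoint and their union is the union of the two context sets.
    """
    kb.term(drug)
    aes_a = context_aes(kb, drug, context_a)
    aes_b = context_aes(kb, drug, context_b)
    return aes_a & aes_b, aes_a - aes_b, aes_b - aes_a


def ae_frequency(
    kb: KnowledgeBase,
    age: Optional[AgeGroup] = None,
    top: Optional[int] = None,
) -> List[Tuple[str, int]]:
    """Adverse events ranked by the number of scenarios reporting them.

    The counting unit is the *scenario* — one (drug, age, disease) context —
    so a drug studied under several treated diseases contributes several
    counts for one AE, and a frequency can exceed the number of drugs.
    Sorted by count descending, then AE label ascending.
    """
    if age is not None and not isinstance(age, AgeGroup):
        age = AgeGroup(age)
    scenarios: Dict[str, Set[Tuple[str, str, Optional[str]]]] = {}
    for record in kb.records:
        if age is not None and record.age is not age:
            continue
        scenario = (record.drug, record.age.value, record.disease)
        scenarios.setdefault(record.ae, set()).add(scenario)
    table = sorted(
        ((ae, len(s)) for ae, s in scenarios.items()),
        key=lambda item: (-item[1], kb.label(item[0])),
    )
    return table[:top] if top is not None else table
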