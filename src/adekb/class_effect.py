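"""AE-specific drug class effects via the proportional class-level ratio.

The proportional class-level ratio (PCR) of a drug class C and an adverse
event E is

    PCR(C, E) = (# member drugs of C associated with E) / (# member drugs of C),

optionally restricted to an (age, disease) context. A *class effect* exists
when every member drug carries the association, i.e. PCR = 1. Class
membership uses the same transitive semantics as the query engine: a drug
belongs to a MoA class through any of its profile MoAs at or below the
class, or to a drug class through the is_a hierarchy.

Ratios are exact rationals (``fractions.Fraction``), so threshold
comparisons like ``pcr >= 0.9`` carry no floating-point artifacts. No
statistical significance testing is attached to the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Real
from typing import Iterable, List, Optional, Set, Union

from .errors import EmptyClassError
from .kb_model import AgeGroup, Kind, KnowledgeBase
from .query_engine import Context, _class_closure, _record_matches, drugs_by_class

Threshold = Union[Real, Fraction]


@dataclass(frozen=True)
class PcrResult:
    """PCR of one (class, adverse event) pair under an optional context."""

    class_id: str
    ae_id: str
    n_assoc: int
    n_total: int
    pcr: Fraction
    context: Context = field(default_factory=Context)

    @property
    def is_class_effect(self) -> bool:
        """True when every member drug is associated (PCR = 1)."""
        return self.pcr == 1


def _associated_members(
    kb: KnowledgeBase,
    members: Set[str],
    ae_id: str,
    context: Context,
) -> Set[str]:
    disease_closure = (
        _class_closure(kb, context.disease) if context.disease is not None else None
    )
    age = context.age
    if age is not None and not isinstance(age, AgeGroup):
        age = AgeGroup(age)
    hit: Set[str] = set()
    for record in kb.records:
        if record.ae != ae_id or record.drug not in members:
            continue
        if _record_matches(kb, record, age, disease_closure):
            hit.add(record.drug)
    return hit


def pcr(
    kb: KnowledgeBase,
    class_id: str,
    ae_id: str,
    context: Optional[Context] = None,
) -> PcrResult:
    """Compute the proportional class-level ratio for one class/AE pair.

    Raises :class:`EmptyClassError` when the class has no member drugs and
    :class:`UnknownTermError` for unresolved ids.
    """
    kb.term(ae_id)
    context = context if context is not None else Context()
    members = drugs_by_class(kb, class_id)
    if not members:
        raise EmptyClassError(f"class {class_id!r} has no member drugs")
    associated = _associated_members(kb, members, ae_id, context)
    return PcrResult(
        class_id=class_id,
        ae_id=ae_id,
        n_assoc=len(associated),
        n_total=len(members),
        pcr=Fraction(len(associated), len(members)),
        context=context,
    )


def find_class_effects(
    kb: KnowledgeBase,
    classes: Optional[Iterable[str]] = None,
    threshold: Threshold = 1.0,
    context: Optional[Context] = None,
) -> List[PcrResult]:
    """Scan (class, AE) pairs and return those with PCR at or above
    ``threshold``.

    ``classes`` defaults to every MoA and drug-class term with at least one
    member drug. Only AEs recorded for at least one member are scanned (a
    pair with no association has PCR 0 and cannot reach a positive
    threshold). Results are sorted by PCR descending, then class id, then
    AE id.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold!r}")
    context = context if context is not None else Context()
    if classes is None:
        candidates = sorted(
            t.id
            for t in kb.terms.values()
            if t.kind in (Kind.MOA, Kind.DRUG_CLASS)
        )
    else:
        candidates = sorted(classes)

    results: List[PcrResult] = []
    for class_id in candidates:
        members = drugs_by_class(kb, class_id)
        if not members:
            continue
        aes = {r.ae for r in kb.records if r.drug in members}
        for ae_id in sorted(aes):
            result = pcr(kb, class_id, ae_id, context)
            if result.pcr >= Fraction(threshold).limit_denominator(10**9):
                results.append(result)
    results.sort(key=lambda r: (-r.pcr, r.class_id, r.ae_id))
    return results
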