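"""Read and write the three CSV curation tables and round-trip a KnowledgeBase.

The curation workflow compiles three comma-separated tables (UTF-8,
RFC-4180 quoting, required header row; ``;`` separates values inside a
cell, since labels such as ``"Pneumonia, Bacterial"`` already force commas
to be quoted):

``annotations``
    one row per drug–AE association in a context —
    ``drug_id, drug_label, ae_id, ae_label, age, disease_id, disease_label,
    evidence`` (the last three may be empty; an empty ``age`` means
    unspecified).
``hierarchy``
    one ``is_a`` edge per row —
    ``child_id, child_label, parent_id, parent_label`` plus optional
    ``child_kind``/``parent_kind`` role columns. A row whose parent fields
    are empty declares the child term without asserting an edge, which lets
    a written knowledge base round-trip terms that have no hierarchy or
    annotation attachment.
``profiles``
    one drug per row — ``drug_id, ingredient_ids, moa_ids, disease_ids``
    with ``;``-joined id lists; repeated rows for one drug merge by union.

Terms are auto-registered on first sight with the row's label; when the same
id later reappears with a conflicting label, the first-seen label wins and a
warning is emitted (deterministic, order-stable builds).
"""

from __future__ import annotations

import csv
import io
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

from .errors import FormatError
from .kb_model import AdeRecord, AgeGroup, DrugProfile, Kind, KnowledgeBase, TermRef

ANNOTATION_COLUMNS = [
    "drug_id",
    "drug_label",
    "ae_id",
    "ae_label",
    "age",
    "disease_id",
    "disease_label",
    "evidence",
]
HIERARCHY_COLUMNS = ["child_id", "child_label", "parent_id", "parent_label"]
HIERARCHY_KIND_COLUMNS = ["child_kind", "parent_kind"]
PROFILE_COLUMNS = ["drug_id", "ingredient_ids", "moa_ids", "disease_ids"]

LIST_SEP = ";"

PathLike = Union[str, Path]


def _require_columns(row: Mapping[str, str], required: Sequence[str], table: str) -> None:
    for col in required:
        if col not in row:
            raise FormatError(f"{table} table: missing required column {col!r}")


def _register(
    kb: KnowledgeBase, term_id: str, label: str, kind: Kind
) -> None:
    """Register a term on first sight; keep the first-seen label afterwards."""
    if not kb.has_term(term_id):
        kb.add_term(TermRef(term_id, label or term_id.partition(":")[2] or term_id, kind=kind))
    else:
        existing = kb.terms[term_id]
        if label and existing.label != label:
            warnings.warn(
                f"term {term_id!r}: keeping first-seen label {existing.label!r}, "
                f"ignoring {label!r}",
                stacklevel=3,
            )


# ---------------------------------------------------------------------------
# annotations


def parse_annotation_table(
    rows: Iterable[Mapping[str, str]], kb: Optional[KnowledgeBase] = None
) -> KnowledgeBase:
    """Build (or extend) a knowledge base from annotation-table rows.

    Duplicate (drug, ae, age, disease) rows collapse to one record with a
    warning. Raises :class:`FormatError` on a missing column or an age token
    outside the enumeration.
    """
    kb = kb if kb is not None else KnowledgeBase()
    seen = {r.key() for r in kb.records}
    for i, row in enumerate(rows, start=2):  # row 1 is the header
        _require_columns(row, ANNOTATION_COLUMNS[:5], "annotation")
        drug_id = (row["drug_id"] or "").strip()
        ae_id = (row["ae_id"] or "").strip()
        if not drug_id or not ae_id:
            raise FormatError(f"annotation table row {i}: empty drug_id or ae_id")
        age_token = (row.get("age") or "").strip() or "unspecified"
        try:
            age = AgeGroup(age_token)
        except ValueError:
            raise FormatError(
                f"annotation table row {i}: unknown age token {age_token!r}"
            ) from None
        disease_id = (row.get("disease_id") or "").strip() or None
        evidence = (row.get("evidence") or "").strip() or None
        _register(kb, drug_id, row.get("drug_label", ""), Kind.DRUG)
        _register(kb, ae_id, row.get("ae_label", ""), Kind.ADVERSE_EVENT)
        if disease_id:
            _register(kb, disease_id, row.get("disease_label", ""), Kind.DISEASE)
        record = AdeRecord(drug_id, ae_id, age, disease_id, evidence)
        if record.key() in seen:
            warnings.warn(
                f"annotation table row {i}: duplicate record {record.key()}, collapsed",
                stacklevel=2,
            )
            continue
        seen.add(record.key())
        kb.add_record(record)
    return kb


def write_annotation_table(kb: KnowledgeBase) -> List[Dict[str, str]]:
    """Render the records as annotation-table rows (sorted, deterministic)."""
    rows = []
    for rec in sorted(kb.records, key=lambda r: (r.drug, r.ae, r.age.value, r.disease or "")):
        rows.append(
            {
                "drug_id": rec.drug,
                "drug_label": kb.label(rec.drug),
                "ae_id": rec.ae,
                "ae_label": kb.label(rec.ae),
                "age": rec.age.value,
                "disease_id": rec.disease or "",
                "disease_label": kb.label(rec.disease) if rec.disease else "",
                "evidence": rec.evidence or "",
            }
        )
    return rows


# ---------------------------------------------------------------------------
# hierarchy


def parse_hierarchy_table(
    rows: Iterable[Mapping[str, str]], kb: Optional[KnowledgeBase] = None
) -> KnowledgeBase:
    """Merge is_a edges (and bare term declarations) into a knowledge base.

    Edges go through ``add_is_a`` and so inherit its cycle check.
    """
    kb = kb if kb is not None else KnowledgeBase()
    for i, row in enumerate(rows, start=2):
        _require_columns(row, HIERARCHY_COLUMNS, "hierarchy")
        child_id = (row["child_id"] or "").strip()
        if not child_id:
            raise FormatError(f"hierarchy table row {i}: empty child_id")
        child_kind = (row.get("child_kind") or "").strip() or Kind.UPPER.value
        _register(kb, child_id, row.get("child_label", ""), Kind(child_kind))
        parent_id = (row["parent_id"] or "").strip()
        if not parent_id:
            continue  # declaration-only row
        parent_kind = (row.get("parent_kind") or "").strip() or Kind.UPPER.value
        _register(kb, parent_id, row.get("parent_label", ""), Kind(parent_kind))
        kb.add_is_a(child_id, parent_id)
    return kb


def write_hierarchy_table(kb: KnowledgeBase) -> List[Dict[str, str]]:
    """Render edges plus declaration-only rows for otherwise-unwritten terms.

    Every term of the knowledge base appears in some written table, so that
    parsing the three tables back reconstructs the term set exactly. The
    built-in age-group terms are skipped (a fresh store already has them).
    """
    from .kb_model import AGE_TERM_IDS

    rows = []
    covered = set(AGE_TERM_IDS)
    for edge in sorted(kb.edges, key=lambda e: (e.child, e.parent)):
        child, parent = kb.term(edge.child), kb.term(edge.parent)
        covered.update((child.id, parent.id))
        rows.append(
            {
                "child_id": child.id,
                "child_label": child.label,
                "parent_id": parent.id,
                "parent_label": parent.label,
                "child_kind": child.kind.value,
                "parent_kind": parent.kind.value,
            }
        )
    for term_id in sorted(set(kb.terms) - covered):
        term = kb.terms[term_id]
        rows.append(
            {
                "child_id": term.id,
                "child_label": term.label,
                "parent_id": "",
                "parent_label": "",
                "child_kind": term.kind.value,
                "parent_kind": "",
            }
        )
    return rows


# ---------------------------------------------------------------------------
# profiles


def _split_ids(cell: Optional[str]) -> List[str]:
    return [tok.strip() for tok in (cell or "").split(LIST_SEP) if tok.strip()]


def parse_profile_table(
    rows: Iterable[Mapping[str, str]], kb: Optional[KnowledgeBase] = None
) -> KnowledgeBase:
    """Merge drug profiles into a knowledge base (set union per drug).

    Ids not yet known are auto-registered with their role's kind and a label
    equal to the local part of the CURIE (the hierarchy and annotation tables
    are the authoritative label sources).
    """
    kb = kb if kb is not None else KnowledgeBase()
    for i, row in enumerate(rows, start=2):
        _require_columns(row, PROFILE_COLUMNS, "profile")
        drug_id = (row["drug_id"] or "").strip()
        if not drug_id:
            raise FormatError(f"profile table row {i}: empty drug_id")
        _register(kb, drug_id, "", Kind.DRUG)
        ingredients = _split_ids(row.get("ingredient_ids"))
        moas = _split_ids(row.get("moa_ids"))
        diseases = _split_ids(row.get("disease_ids"))
        for ref, kind in (
            *((x, Kind.INGREDIENT) for x in ingredients),
            *((x, Kind.MOA) for x in moas),
            *((x, Kind.DISEASE) for x in diseases),
        ):
            _register(kb, ref, "", kind)
        kb.set_profile(DrugProfile(drug_id, set(ingredients), set(moas), set(diseases)))
    return kb


def write_profile_table(kb: KnowledgeBase) -> List[Dict[str, str]]:
    rows = []
    for drug_id in sorted(kb.profiles):
        prof = kb.profiles[drug_id]
        rows.append(
            {
                "drug_id": drug_id,
                "ingredient_ids": LIST_SEP.join(sorted(prof.ingredients)),
                "moa_ids": LIST_SEP.join(sorted(prof.moas)),
                "disease_ids": LIST_SEP.join(sorted(prof.diseases_treated)),
            }
        )
    return rows


# ---------------------------------------------------------------------------
# CSV files


def _read_csv(path: PathLike) -> List[Dict[str, str]]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file (header row required)")
        return list(reader)


def _write_csv(path: PathLike, rows: List[Dict[str, str]], columns: Sequence[str]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns))
        writer.writeheader()
        writer.writerows(rows)


def load_kb(
    annotations: Optional[PathLike] = None,
    hierarchy: Optional[PathLike] = None,
    profiles: Optional[PathLike] = None,
) -> KnowledgeBase:
    """Build a knowledge base from up to three CSV files.

    Parse order is annotations, then hierarchy, then profiles, so labelled
    tables take precedence for term registration.
    """
    kb = KnowledgeBase()
    if annotations is not None:
        parse_annotation_table(_read_csv(annotations), kb)
    if hierarchy is not None:
        parse_hierarchy_table(_read_csv(hierarchy), kb)
    if profiles is not None:
        parse_profile_table(_read_csv(profiles), kb)
    return kb


def save_kb(kb: KnowledgeBase, directory: PathLike) -> Dict[str, Path]:
    """Write the three CSV tables into ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": directory / "annotations.csv",
        "hierarchy": directory / "hierarchy.csv",
        "profiles": directory / "profiles.csv",
    }
    _write_csv(paths["annotations"], write_annotation_table(kb), ANNOTATION_COLUMNS)
    _write_csv(
        paths["hierarchy"],
        write_hierarchy_table(kb),
        HIERARCHY_COLUMNS + HIERARCHY_KIND_COLUMNS,
    )
    _write_csv(paths["profiles"], write_profile_table(kb), PROFILE_COLUMNS)
    return paths


def canonical_csv_dump(kb: KnowledgeBase) -> str:
    """One deterministic text blob holding all three tables (for checksums)."""
    buf = io.StringIO()
    for name, rows, cols in (
        ("annotations", write_annotation_table(kb), ANNOTATION_COLUMNS),
        ("hierarchy", write_hierarchy_table(kb), HIERARCHY_COLUMNS + HIERARCHY_KIND_COLUMNS),
        ("profiles", write_profile_table(kb), PROFILE_COLUMNS),
    ):
        buf.write(f"## {name}\n")
        writer = csv.DictWriter(buf, fieldnames=cols, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
    return buf.getvalue()
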