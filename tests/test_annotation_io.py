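import pytest

from adekb import (
    AgeGroup,
    FormatError,
    KnowledgeBase,
    load_kb,
    parse_annotation_table,
    parse_hierarchy_table,
    parse_profile_table,
    save_kb,
    write_annotation_table,
    write_hierarchy_table,
)
from adekb.annotation_io import canonical_csv_dump

from .conftest import small_random_kb

LINEZOLID_ROW = {
    "drug_id": "NDFRT:linezolid",
    "drug_label": "LINEZOLID",
    "ae_id": "OAE:0000425",
    "ae_label": "rash AE",
    "age": "adult",
    "disease_id": "NDFRT:pneumonia_bacterial",
    "disease_label": "Pneumonia, Bacterial",
    "evidence": "package insert: linezolid",
}


class TestAnnotationTable:
    def test_single_row_builds_full_record(self):
        kb = parse_annotation_table([LINEZOLID_ROW])
        assert len(kb.records) == 1
        rec = kb.records[0]
        assert rec.drug == "NDFRT:linezolid"
        assert rec.ae == "OAE:0000425"
        assert rec.age is AgeGroup.ADULT
        assert rec.disease == "NDFRT:pneumonia_bacterial"
        assert kb.label(rec.disease) == "Pneumonia, Bacterial"

    def test_header_only_gives_empty_kb(self):
        kb = parse_annotation_table([])
        assert kb.records == [] and kb.profiles == {}

    def test_empty_age_token_means_unspecified(self):
        row = dict(LINEZOLID_ROW, age="", disease_id="", disease_label="")
        kb = parse_annotation_table([row])
        assert kb.records[0].age is AgeGroup.UNSPECIFIED
        assert kb.records[0].disease is None

    def test_missing_column_names_the_column(self):
        row = {k: v for k, v in LINEZOLID_ROW.items() if k != "ae_id"}
        with pytest.raises(FormatError, match="ae_id"):
            parse_annotation_table([row])

    def test_unknown_age_token_names_the_row(self):
        with pytest.raises(FormatError, match="row 3"):
            parse_annotation_table([LINEZOLID_ROW, dict(LINEZOLID_ROW, age="newborn")])

    def test_duplicate_rows_collapse_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            kb = parse_annotation_table([LINEZOLID_ROW, dict(LINEZOLID_ROW)])
        assert len(kb.records) == 1

    def test_first_seen_label_wins_on_conflict(self):
        other = dict(LINEZOLID_ROW, age="pediatric", drug_label="Linezolid (oral)")
        with pytest.warns(UserWarning, match="first-seen"):
            kb = parse_annotation_table([LINEZOLID_ROW, other])
        assert kb.label("NDFRT:linezolid") == "LINEZOLID"

    def test_roundtrip_identity_on_random_rows(self):
        """write(parse(R)) reproduces R up to row order, >=200 rows."""
        source = small_random_kb(seed=5, assoc_prob=0.5)
        rows = write_annotation_table(source)
        assert len(rows) >= 200
        kb = parse_annotation_table(rows)
        assert write_annotation_table(kb) == rows


class TestHierarchyTable:
    def test_upper_level_chain_parses(self):
        rows = [
            {"child_id": "OAE:0000001", "child_label": "adverse event",
             "parent_id": "BFO:0000015", "parent_label": "process"},
            {"child_id": "BFO:0000015", "child_label": "process",
             "parent_id": "BFO:0000001", "parent_label": "entity"},
        ]
        kb = parse_hierarchy_table(rows)
        assert kb.ancestors("OAE:0000001") == {"BFO:0000015", "BFO:0000001"}

    def test_empty_table_no_edges(self):
        assert parse_hierarchy_table([]).edges == set()

    def test_roundtrip_preserves_edge_set(self):
        source = small_random_kb(seed=7)
        kb = parse_hierarchy_table(write_hierarchy_table(source))
        assert kb.edges == source.edges


class TestProfileTable:
    def test_single_moa_profile(self):
        kb = parse_profile_table(
            [{"drug_id": "NDFRT:imatinib", "ingredient_ids": "",
              "moa_ids": "NDFRT:bcr_abl_tki", "disease_ids": ""}]
        )
        assert kb.profiles["NDFRT:imatinib"].moas == {"NDFRT:bcr_abl_tki"}
        assert kb.profiles["NDFRT:imatinib"].ingredients == set()

    def test_repeated_drug_rows_union_merge(self):
        split = [
            {"drug_id": "D", "ingredient_ids": "I1", "moa_ids": "M1", "disease_ids": ""},
            {"drug_id": "D", "ingredient_ids": "I2", "moa_ids": "M1;M2", "disease_ids": "S1"},
        ]
        combined = [
            {"drug_id": "D", "ingredient_ids": "I1;I2", "moa_ids": "M1;M2",
             "disease_ids": "S1"},
        ]
        kb_split = parse_profile_table(split)
        kb_combined = parse_profile_table(combined)
        ps, pc = kb_split.profiles["D"], kb_combined.profiles["D"]
        assert (ps.ingredients, ps.moas, ps.diseases_treated) == (
            pc.ingredients, pc.moas, pc.diseases_treated
        )

    def test_missing_column_rejected(self):
        with pytest.raises(FormatError, match="moa_ids"):
            parse_profile_table([{"drug_id": "D", "ingredient_ids": "", "disease_ids": ""}])


@pytest.mark.parametrize("kb_source", ["fixture", "random"])
def test_full_roundtrip_reconstructs_kb(tmp_path, paper_kb, kb_source):
    """save_kb/load_kb reproduces terms, edges, profiles and records."""
    source = paper_kb if kb_source == "fixture" else small_random_kb(seed=2)
    paths = save_kb(source, tmp_path)
    rebuilt = load_kb(paths["annotations"], paths["hierarchy"], paths["profiles"])
    assert rebuilt.terms == source.terms
    assert rebuilt.edges == source.edges
    assert {d: (p.ingredients, p.moas, p.diseases_treated) for d, p in rebuilt.profiles.items()} == {
        d: (p.ingredients, p.moas, p.diseases_treated) for d, p in source.profiles.items()
    }
    def norm(records):
        return sorted((r.drug, r.ae, r.age.value, r.disease or "") for r in records)

    assert norm(rebuilt.records) == norm(source.records)
    assert canonical_csv_dump(rebuilt) == canonical_csv_dump(source)
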