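import pytest

from adekb import (
    AdeRecord,
    AgeGroup,
    KnowledgeBase,
    UnknownTermError,
    ae_frequency,
    compare_contexts,
    drugs_by_class,
    query_ade,
)
from adekb.query_engine import Context
from adekb import fixtures as fx

from .conftest import small_random_kb
from . import oracles


def ae_set(rows):
    return {q.ae for q in rows}


class TestDrugsByClass:
    def test_tyrosine_kinase_trio_found_through_sub_moas(self, paper_kb):
        assert drugs_by_class(paper_kb, fx.TKI_CLASS) == {
            fx.IMATINIB, fx.ERLOTINIB, fx.TRASTUZUMAB,
        }

    def test_ion_channel_class_spans_both_blocker_subclasses(self, paper_kb):
        assert drugs_by_class(paper_kb, fx.ION_CHANNEL) == {fx.DILTIAZEM, fx.PHENYTOIN}

    def test_class_with_no_drug_descendants_is_empty(self, paper_kb):
        # the occurrent branch holds processes (AEs), never drugs
        assert drugs_by_class(paper_kb, "BFO:0000003") == set()

    def test_unknown_class_rejected(self, paper_kb):
        with pytest.raises(UnknownTermError):
            drugs_by_class(paper_kb, "NDFRT:nonexistent")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_scan(self, seed):
        kb = small_random_kb(seed)
        for term in kb.terms.values():
            if term.kind.value in ("moa", "drug_class"):
                assert drugs_by_class(kb, term.id) == oracles.drugs_in_class(kb, term.id)


class TestQueryAde:
    def test_diltiazem_hypertension_returns_the_five_aes(self, paper_kb):
        rows = query_ade(
            paper_kb, drug=fx.DILTIAZEM, age=AgeGroup.ADULT, disease=fx.HYPERTENSION
        )
        assert ae_set(rows) == set(fx.DILTIAZEM_HYPERTENSION_AES)
        assert len(ae_set(rows)) == 5

    def test_diltiazem_coronary_syndrome_returns_asthenia_only(self, paper_kb):
        rows = query_ade(paper_kb, drug=fx.DILTIAZEM, disease=fx.ICS)
        assert ae_set(rows) == {fx.ASTHENIA}

    def test_ion_channel_moa_query_reports_matched_moa(self, paper_kb):
        rows = query_ade(paper_kb, moa_class=fx.ION_CHANNEL, age=AgeGroup.ADULT)
        assert {q.drug for q in rows} == {fx.DILTIAZEM, fx.PHENYTOIN}
        moa_of = {q.drug: q.moa for q in rows}
        assert moa_of[fx.DILTIAZEM] == fx.CALCIUM_BLOCKERS
        assert moa_of[fx.PHENYTOIN] == fx.SODIUM_BLOCKERS

    def test_empty_kb_returns_empty_list(self):
        assert query_ade(KnowledgeBase()) == []

    def test_results_deduplicated_and_sorted(self, paper_kb):
        rows = query_ade(paper_kb)
        assert rows == sorted(set(rows))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_nested_loop_filter(self, seed):
        kb = small_random_kb(seed)
        moa = next(t.id for t in kb.terms.values() if t.kind.value == "moa")
        disease = next(t.id for t in kb.terms.values() if t.kind.value == "disease")
        drug = next(t.id for t in kb.terms.values() if t.kind.value == "drug")
        cases = [
            {},
            {"age": AgeGroup.ADULT},
            {"moa_class": moa},
            {"disease": disease},
            {"drug": drug},
            {"moa_class": moa, "age": AgeGroup.PEDIATRIC, "disease": disease},
        ]
        for kwargs in cases:
            got = {
                (q.drug, q.moa, q.disease, q.ae, q.age.value)
                for q in query_ade(kb, **kwargs)
            }
            assert got == oracles.query_quadruples(kb, **kwargs), kwargs

    def test_monotone_under_new_records(self):
        """Adding a record never shrinks a result set."""
        kb = small_random_kb(seed=21)
        before = set(query_ade(kb, age=AgeGroup.ADULT))
        ae = next(t.id for t in kb.terms.values() if t.kind.value == "adverse_event")
        drug = next(t.id for t in kb.terms.values() if t.kind.value == "drug")
        new = AdeRecord(drug, ae, AgeGroup.ADULT, None)
        if any(r.key() == new.key() for r in kb.records):
            kb.records.remove(next(r for r in kb.records if r.key() == new.key()))
            before = set(query_ade(kb, age=AgeGroup.ADULT))
        kb.add_record(new)
        assert before <= set(query_ade(kb, age=AgeGroup.ADULT))

    def test_parent_class_query_superset_of_children(self, paper_kb):
        parent_rows = set(query_ade(paper_kb, moa_class=fx.ION_CHANNEL))
        for child in (fx.CALCIUM_BLOCKERS, fx.SODIUM_BLOCKERS):
            child_aes = ae_set(query_ade(paper_kb, moa_class=child))
            assert child_aes <= ae_set(parent_rows)


class TestCompareContexts:
    def test_sirolimus_shared_aes_across_treated_diseases(self, paper_kb):
        shared, only_lam, only_tx = compare_contexts(
            paper_kb,
            fx.SIROLIMUS,
            Context(disease=fx.LAM),
            Context(disease=fx.RENAL_TX),
        )
        assert set(fx.SIROLIMUS_SHARED_AES) <= shared

    def test_infliximab_context_specific_aes(self, paper_kb):
        shared, only_crohns, only_uc = compare_contexts(
            paper_kb,
            fx.INFLIXIMAB,
            Context(disease=fx.CROHNS),
            Context(disease=fx.ULCERATIVE_COLITIS),
        )
        assert {fx.NEUTROPENIA, fx.LEUKOPENIA} <= only_crohns
        assert {fx.PHARYNGITIS, fx.ABDOMINAL_PAIN} <= only_uc

    def test_identical_contexts_have_empty_differences(self, paper_kb):
        ctx = Context(age=AgeGroup.ADULT, disease=fx.HYPERTENSION)
        shared, only_a, only_b = compare_contexts(paper_kb, fx.DILTIAZEM, ctx, ctx)
        assert only_a == only_b == set()
        assert shared == set(fx.DILTIAZEM_HYPERTENSION_AES)

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_property(self, seed):
        """shared/onlyA/onlyB are disjoint and cover both context AE sets."""
        kb = small_random_kb(seed, assoc_prob=0.15)
        diseases = [t.id for t in kb.terms.values() if t.kind.value == "disease"]
        drugs = [t.id for t in kb.terms.values() if t.kind.value == "drug"]
        ctx_a = Context(age=AgeGroup.ADULT)
        ctx_b = Context(disease=diseases[0])
        for drug in drugs:
            shared, only_a, only_b = compare_contexts(kb, drug, ctx_a, ctx_b)
            assert shared & only_a == shared & only_b == only_a & only_b == set()
            from adekb.query_engine import context_aes

            union = context_aes(kb, drug, ctx_a) | context_aes(kb, drug, ctx_b)
            assert shared | only_a | only_b == union


class TestAeFrequency:
    def test_empty_kb_empty_table(self):
        assert ae_frequency(KnowledgeBase()) == []

    def test_scenario_counting_exceeds_drug_count(self):
        """One drug studied under two diseases contributes two counts."""
        kb = KnowledgeBase()
        from adekb import TermRef

        for tid in ("D", "E", "S1", "S2"):
            kb.add_term(TermRef(tid, tid))
        kb.add_record(AdeRecord("D", "E", AgeGroup.ADULT, "S1"))
        kb.add_record(AdeRecord("D", "E", AgeGroup.ADULT, "S2"))
        assert ae_frequency(kb) == [("E", 2)]

    def test_fixture_top_ae_is_nausea(self, paper_kb):
        table = ae_frequency(paper_kb)
        assert table[0][0] == fx.NAUSEA

    def test_sorted_by_count_then_label(self, paper_kb):
        table = ae_frequency(paper_kb)
        keys = [(-count, paper_kb.label(ae)) for ae, count in table]
        assert keys == sorted(keys)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_scenario_counts(self, seed):
        kb = small_random_kb(seed)
        for age in (None, AgeGroup.SENIOR):
            assert dict(ae_frequency(kb, age=age)) == oracles.ae_counts(kb, age=age)
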