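"""Deterministic test data: a curated mini knowledge base and a seeded
random-KB generator.

``build_paper_fixture`` hand-builds a small knowledge base holding the
classic worked examples of conditional adverse-drug-event curation:

* Linezolid — rash in adults treated for bacterial pneumonia;
* Alosetron — constipation in adult irritable-bowel-syndrome patients;
* Diltiazem (a calcium channel blocker) — asthenia under intermediate
  coronary syndrome vs. five other AEs (pharyngitis, rhinitis, headache,
  constipation, cough increased) under hypertension, all in adults;
* Phenytoin (a sodium channel blocker) — four named AEs under adult EAST
  syndrome;
* Sirolimus — six AEs shared between its two treated diseases
  (lymphangioleiomyomatosis and renal-transplant rejection);
* Infliximab — neutropenia/leukopenia only in Crohn's disease,
  pharyngitis/abdominal pain only in ulcerative colitis;
* the tyrosine-kinase-inhibitor trio (imatinib, erlotinib, trastuzumab),
  each acting through its own sub-MoA, all six class-effect AEs in adults;
* an "Immunologic and Biological Factors [MoA]" class with ten member
  drugs of which nine carry a nausea record (the drug terms themselves are
  synthetic placeholders; only the class label and the 9-of-10 structure
  are curated facts).

A manifest records every term, edge, profile, and record together with a
short note naming the worked example it encodes, so counts can be checked
against the store. The random generator (:func:`random_kb`) draws each
(drug, age, disease-or-none, AE) association independently with a fixed
probability and is byte-reproducible under its seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import List, Tuple

from .kb_model import (
    AdeRecord,
    AgeGroup,
    DrugProfile,
    Kind,
    KnowledgeBase,
    TermRef,
)

# ---------------------------------------------------------------------------
# curated fixture


@dataclass(frozen=True)
class ManifestEntry:
    """One fixture element: its category, key, and provenance note."""

    category: str  # term | edge | profile | record
    key: str
    note: str


class _Builder:
    def __init__(self) -> None:
        self.kb = KnowledgeBase()
        self.manifest: List[ManifestEntry] = []

    def term(self, term_id: str, label: str, kind: Kind, note: str) -> str:
        self.kb.add_term(TermRef(term_id, label, kind=kind))
        self.manifest.append(ManifestEntry("term", term_id, note))
        return term_id

    def is_a(self, child: str, parent: str, note: str) -> None:
        self.kb.add_is_a(child, parent)
        self.manifest.append(ManifestEntry("edge", f"{child} is_a {parent}", note))

    def profile(self, profile: DrugProfile, note: str) -> None:
        self.kb.set_profile(profile)
        self.manifest.append(ManifestEntry("profile", profile.drug, note))

    def record(self, record: AdeRecord, note: str) -> None:
        self.kb.add_record(record)
        self.manifest.append(
            ManifestEntry("record", str(record.key()), note)
        )


# Canonical fixture ids, exported so tests and the CLI can refer to them.

LINEZOLID = "NDFRT:linezolid"
ALOSETRON = "NDFRT:N0000148640"
DILTIAZEM = "NDFRT:diltiazem"
PHENYTOIN = "NDFRT:phenytoin"
SIROLIMUS = "NDFRT:sirolimus"
INFLIXIMAB = "NDFRT:infliximab"
IMATINIB = "NDFRT:imatinib"
ERLOTINIB = "NDFRT:erlotinib"
TRASTUZUMAB = "NDFRT:trastuzumab"

MOA_ROOT = "NDFRT:mechanism_of_action"
ION_CHANNEL = "NDFRT:ion_channel_interactions"
CALCIUM_BLOCKERS = "NDFRT:calcium_channel_blockers"
SODIUM_BLOCKERS = "NDFRT:sodium_channel_blockers"
TKI_CLASS = "NDFRT:tyrosine_kinase_inhibitors"
BCR_ABL = "NDFRT:bcr_abl_tyrosine_kinase_inhibitors"
HER1 = "NDFRT:her1_antagonists"
HER2 = "NDFRT:her2_neu_cerbb2_antagonists"
IMMUNO_CLASS = "NDFRT:immunologic_and_biological_factors"

DRUG_PRODUCT = "NDFRT:drug_product"

PNEUMONIA_BACTERIAL = "NDFRT:pneumonia_bacterial"
IBS = "NDFRT:irritable_bowel_syndrome"
HYPERTENSION = "NDFRT:hypertension"
ICS = "NDFRT:intermediate_coronary_syndrome"
LAM = "NDFRT:lymphangioleiomyomatosis"
RENAL_TX = "NDFRT:renal_transplant_rejection"
CROHNS = "NDFRT:crohns_disease"
ULCERATIVE_COLITIS = "NDFRT:ulcerative_colitis"
EAST_SYNDROME = "NDFRT:east_syndrome"

RASH = "OAE:0000425"
CONSTIPATION = "OAE:constipation"
ASTHENIA = "OAE:asthenia"
PHARYNGITIS = "OAE:pharyngitis"
RHINITIS = "OAE:rhinitis"
HEADACHE = "OAE:headache"
COUGH_INCREASED = "OAE:cough_increased"
ABDOMINAL_PAIN = "OAE:abdominal_pain"
DIARRHEA = "OAE:diarrhea"
HYPERCHOLESTEROLEMIA = "OAE:hypercholesterolemia"
NAUSEA = "OAE:nausea"
PERIPHERAL_EDEMA = "OAE:peripheral_edema"
NEUTROPENIA = "OAE:neutropenia"
LEUKOPENIA = "OAE:leukopenia"
FEVER = "OAE:fever"
EDEMA = "OAE:edema"
DYSPNEA = "OAE:dyspnea"
VOMITING = "OAE:vomiting"
NYSTAGMUS = "OAE:nystagmus"
SOMNOLENCE = "OAE:somnolence"
SPEECH_DISORDER = "OAE:speech_disorder"

ADVERSE_EVENT = "OAE:0000001"

#: Sub-MoA each tyrosine-kinase drug acts through.
TKI_TRIO = {IMATINIB: BCR_ABL, ERLOTINIB: HER1, TRASTUZUMAB: HER2}

#: The six AEs shared class-wide by the tyrosine-kinase inhibitors (adults).
TKI_AES = (RASH, FEVER, NAUSEA, EDEMA, DYSPNEA, VOMITING)

#: The six AEs sirolimus shows under both of its treated diseases.
SIROLIMUS_SHARED_AES = (
    ABDOMINAL_PAIN,
    DIARRHEA,
    HEADACHE,
    HYPERCHOLESTEROLEMIA,
    NAUSEA,
    PERIPHERAL_EDEMA,
)

#: Diltiazem's five AEs under adult hypertension.
DILTIAZEM_HYPERTENSION_AES = (
    PHARYNGITIS,
    RHINITIS,
    HEADACHE,
    CONSTIPATION,
    COUGH_INCREASED,
)

#: Phenytoin's four named AEs under adult EAST syndrome (of seven curated).
PHENYTOIN_EAST_AES = (NYSTAGMUS, RASH, SOMNOLENCE, SPEECH_DISORDER)

#: Ten synthetic member drugs of the immunologic class; the first nine carry
#: a nausea record.
IMMUNO_DRUGS = tuple(f"NDFRT:immunofactor_{i:02d}" for i in range(1, 11))


def _build() -> Tuple[KnowledgeBase, List[ManifestEntry]]:
    b = _Builder()

    # upper-level scaffold
    entity = b.term("BFO:0000001", "entity", Kind.UPPER, "upper-level scaffold")
    continuant = b.term("BFO:0000002", "continuant", Kind.UPPER, "upper-level scaffold")
    occurrent = b.term("BFO:0000003", "occurrent", Kind.UPPER, "upper-level scaffold")
    process = b.term("BFO:0000015", "process", Kind.UPPER, "upper-level scaffold")
    material = b.term("BFO:0000040", "material entity", Kind.UPPER, "upper-level scaffold")
    human = b.term("NCBITaxon:9606", "Homo sapiens", Kind.UPPER, "organism under study")
    b.term(DRUG_PRODUCT, "drug product", Kind.DRUG_CLASS, "upper-level scaffold")
    b.term(ADVERSE_EVENT, "adverse event", Kind.ADVERSE_EVENT, "AE root")
    b.is_a(continuant, entity, "upper-level scaffold")
    b.is_a(occurrent, entity, "upper-level scaffold")
    b.is_a(process, occurrent, "upper-level scaffold")
    b.is_a(material, continuant, "upper-level scaffold")
    b.is_a(human, material, "upper-level scaffold")
    b.is_a(DRUG_PRODUCT, material, "upper-level scaffold")
    b.is_a(ADVERSE_EVENT, process, "AE root under process")

    # MoA hierarchy
    b.term(MOA_ROOT, "mechanism of action", Kind.MOA, "MoA root")
    b.is_a(MOA_ROOT, entity, "MoA root placement")
    for term_id, label, parent, note in (
        (ION_CHANNEL, "Ion Channel Interactions [MoA]", MOA_ROOT, "ion-channel query"),
        (CALCIUM_BLOCKERS, "Calcium Channel Blockers [MoA]", ION_CHANNEL, "Diltiazem MoA"),
        (SODIUM_BLOCKERS, "Sodium Channel Blockers [MoA]", ION_CHANNEL, "Phenytoin MoA"),
        (TKI_CLASS, "Tyrosine Kinase Inhibitors [MoA]", MOA_ROOT, "TKI class effect"),
        (BCR_ABL, "Bcr-Abl Tyrosine Kinase Inhibitors [MoA]", TKI_CLASS, "imatinib sub-MoA"),
        (HER1, "HER1 Antagonists [MoA]", TKI_CLASS, "erlotinib sub-MoA"),
        (HER2, "HER2/Neu/cerbB2 Antagonists [MoA]", TKI_CLASS, "trastuzumab sub-MoA"),
        (IMMUNO_CLASS, "Immunologic and Biological Factors [MoA]", MOA_ROOT,
         "immunologic class, PCR 9/10"),
    ):
        b.term(term_id, label, Kind.MOA, note)
        b.is_a(term_id, parent, note)

    # diseases
    for term_id, label, note in (
        (PNEUMONIA_BACTERIAL, "Pneumonia, Bacterial", "Linezolid context"),
        (IBS, "irritable bowel syndrome", "Alosetron context"),
        (HYPERTENSION, "Hypertension", "Diltiazem context"),
        (ICS, "intermediate coronary syndrome", "Diltiazem context"),
        (LAM, "lymphangioleiomyomatosis", "Sirolimus context"),
        (RENAL_TX, "renal transplant rejection", "Sirolimus context"),
        (CROHNS, "Crohn's disease", "Infliximab context"),
        (ULCERATIVE_COLITIS, "ulcerative colitis", "Infliximab context"),
        (EAST_SYNDROME, "EAST syndrome", "Phenytoin context"),
    ):
        b.term(term_id, label, Kind.DISEASE, note)

    # adverse events
    for term_id, label, note in (
        (RASH, "rash AE", "Linezolid / Phenytoin / TKI"),
        (CONSTIPATION, "constipation AE", "Alosetron / Diltiazem"),
        (ASTHENIA, "asthenia AE", "Diltiazem ICS"),
        (PHARYNGITIS, "pharyngitis AE", "Diltiazem / Infliximab"),
        (RHINITIS, "rhinitis AE", "Diltiazem hypertension"),
        (HEADACHE, "headache AE", "Diltiazem / Sirolimus"),
        (COUGH_INCREASED, "cough increased AE", "Diltiazem hypertension"),
        (ABDOMINAL_PAIN, "abdominal pain AE", "Sirolimus / Infliximab"),
        (DIARRHEA, "diarrhea AE", "Sirolimus shared"),
        (HYPERCHOLESTEROLEMIA, "hypercholesterolemia AE", "Sirolimus shared"),
        (NAUSEA, "nausea AE", "Sirolimus / TKI / immunologic"),
        (PERIPHERAL_EDEMA, "peripheral edema AE", "Sirolimus shared"),
        (NEUTROPENIA, "neutropenia AE", "Infliximab Crohn's-only"),
        (LEUKOPENIA, "leukopenia AE", "Infliximab Crohn's-only"),
        (FEVER, "fever AE", "TKI class effect"),
        (EDEMA, "edema AE", "TKI class effect"),
        (DYSPNEA, "dyspnea AE", "TKI class effect"),
        (VOMITING, "vomiting AE", "TKI class effect"),
        (NYSTAGMUS, "nystagmus AE", "Phenytoin EAST"),
        (SOMNOLENCE, "somnolence AE", "Phenytoin EAST"),
        (SPEECH_DISORDER, "speech disorder AE", "Phenytoin EAST"),
    ):
        b.term(term_id, label, Kind.ADVERSE_EVENT, note)
        b.is_a(term_id, ADVERSE_EVENT, "AE hierarchy")

    # drugs
    for term_id, label, note in (
        (LINEZOLID, "LINEZOLID", "rash in adult bacterial pneumonia"),
        (ALOSETRON, "ALOSETRON", "constipation in adult IBS"),
        (DILTIAZEM, "DILTIAZEM", "hypertension vs ICS contexts"),
        (PHENYTOIN, "PHENYTOIN", "EAST syndrome context"),
        (SIROLIMUS, "SIROLIMUS", "LAM vs renal-transplant contexts"),
        (INFLIXIMAB, "INFLIXIMAB", "Crohn's vs ulcerative colitis"),
        (IMATINIB, "IMATINIB", "TKI trio"),
        (ERLOTINIB, "ERLOTINIB", "TKI trio"),
        (TRASTUZUMAB, "TRASTUZUMAB", "TKI trio"),
    ):
        b.term(term_id, label, Kind.DRUG, note)
        b.is_a(term_id, DRUG_PRODUCT, "drug placement")
    for i, term_id in enumerate(IMMUNO_DRUGS, start=1):
        b.term(
            term_id,
            f"IMMUNOFACTOR-{i:02d}",
            Kind.DRUG,
            "synthetic member of the immunologic class",
        )
        b.is_a(term_id, DRUG_PRODUCT, "drug placement")

    # ingredient example
    alosetron_hcl = b.term(
        "NDFRT:alosetron_hydrochloride",
        "ALOSETRON HYDROCHLORIDE",
        Kind.INGREDIENT,
        "Alosetron active ingredient",
    )

    # profiles
    b.profile(
        DrugProfile(LINEZOLID, diseases_treated={PNEUMONIA_BACTERIAL}),
        "Linezolid treats bacterial pneumonia",
    )
    b.profile(
        DrugProfile(ALOSETRON, ingredients={alosetron_hcl}, diseases_treated={IBS}),
        "Alosetron treats IBS",
    )
    b.profile(
        DrugProfile(
            DILTIAZEM, moas={CALCIUM_BLOCKERS}, diseases_treated={HYPERTENSION, ICS}
        ),
        "Diltiazem: calcium channel blocker",
    )
    b.profile(
        DrugProfile(
            PHENYTOIN, moas={SODIUM_BLOCKERS}, diseases_treated={EAST_SYNDROME}
        ),
        "Phenytoin: sodium channel blocker",
    )
    b.profile(
        DrugProfile(SIROLIMUS, diseases_treated={LAM, RENAL_TX}),
        "Sirolimus treated diseases",
    )
    b.profile(
        DrugProfile(INFLIXIMAB, diseases_treated={CROHNS, ULCERATIVE_COLITIS}),
        "Infliximab treated diseases",
    )
    for drug, sub_moa in TKI_TRIO.items():
        b.profile(DrugProfile(drug, moas={sub_moa}), "TKI trio sub-MoA")
    for term_id in IMMUNO_DRUGS:
        b.profile(
            DrugProfile(term_id, moas={IMMUNO_CLASS}), "immunologic class member"
        )

    # records
    adult = AgeGroup.ADULT
    b.record(
        AdeRecord(LINEZOLID, RASH, adult, PNEUMONIA_BACTERIAL,
                  "package insert: linezolid"),
        "Linezolid worked example",
    )
    b.record(
        AdeRecord(ALOSETRON, CONSTIPATION, adult, IBS,
                  "package insert: alosetron"),
        "Alosetron worked example",
    )
    b.record(
        AdeRecord(DILTIAZEM, ASTHENIA, adult, ICS, "package insert: diltiazem"),
        "Diltiazem under intermediate coronary syndrome",
    )
    for ae in DILTIAZEM_HYPERTENSION_AES:
        b.record(
            AdeRecord(DILTIAZEM, ae, adult, HYPERTENSION,
                      "package insert: diltiazem"),
            "Diltiazem under hypertension",
        )
    for ae in PHENYTOIN_EAST_AES:
        b.record(
            AdeRecord(PHENYTOIN, ae, adult, EAST_SYNDROME,
                      "package insert: phenytoin"),
            "Phenytoin under EAST syndrome",
        )
    for disease in (LAM, RENAL_TX):
        for ae in SIROLIMUS_SHARED_AES:
            b.record(
                AdeRecord(SIROLIMUS, ae, adult, disease,
                          "package insert: sirolimus"),
                "Sirolimus shared AE in both treated diseases",
            )
    for ae in (NEUTROPENIA, LEUKOPENIA):
        b.record(
            AdeRecord(INFLIXIMAB, ae, adult, CROHNS, "package insert: infliximab"),
            "Infliximab Crohn's-only AE",
        )
    for ae in (PHARYNGITIS, ABDOMINAL_PAIN):
        b.record(
            AdeRecord(INFLIXIMAB, ae, adult, ULCERATIVE_COLITIS,
                      "package insert: infliximab"),
            "Infliximab ulcerative-colitis-only AE",
        )
    for drug in TKI_TRIO:
        for ae in TKI_AES:
            b.record(
                AdeRecord(drug, ae, adult, None, "package insert: TKI"),
                "tyrosine-kinase class-effect AE",
            )
    for term_id in IMMUNO_DRUGS[:9]:
        b.record(
            AdeRecord(term_id, NAUSEA, adult, None, "synthetic: immunologic member"),
            "immunologic class nausea (9 of 10 members)",
        )

    return b.kb, b.manifest


def build_paper_fixture() -> KnowledgeBase:
    """Build the curated worked-example knowledge base."""
    return _build()[0]


def fixture_manifest() -> List[ManifestEntry]:
    """The manifest paired with :func:`build_paper_fixture`."""
    return _build()[1]


# ---------------------------------------------------------------------------
# seeded random knowledge bases


@dataclass(frozen=True)
class RandomKbParams:
    """Shape of a randomly generated knowledge base.

    Identical parameters and seed yield a byte-identical store. The
    association space is the full product drugs × age groups × (diseases +
    no-disease) × AEs; each cell is included independently with probability
    ``assoc_prob``.
    """

    n_drugs: int = 12
    n_aes: int = 15
    n_diseases: int = 6
    n_moa_classes: int = 8
    hierarchy_depth: int = 3
    assoc_prob: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_aes", "n_diseases", "n_moa_classes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hierarchy_depth < 1:
            raise ValueError("hierarchy_depth must be >= 1")
        if not 0.0 <= self.assoc_prob <= 1.0:
            raise ValueError("assoc_prob must lie in [0, 1]")


def association_space_size(params: RandomKbParams) -> int:
    """Number of independent association draws :func:`random_kb` makes."""
    return params.n_drugs * len(AgeGroup) * (params.n_diseases + 1) * params.n_aes


def _random_dag(
    kb: KnowledgeBase,
    rng: random.Random,
    prefix: str,
    label_stem: str,
    n: int,
    depth: int,
    kind: Kind,
) -> List[str]:
    """Layered random DAG: nodes are spread over ``depth`` levels and each
    non-root node gets 1–2 parents from strictly lower levels."""
    ids: List[str] = []
    levels: List[int] = []
    per_level = max(1, -(-n // depth))  # ceil
    for i in range(n):
        term_id = f"OTHER:{prefix}_{i:03d}"
        level = min(i // per_level, depth - 1)
        kb.add_term(TermRef(term_id, f"{label_stem} {i:03d}", kind=kind))
        ids.append(term_id)
        levels.append(level)
        if level > 0:
            pool = [ids[j] for j in range(i) if levels[j] < level]
            for parent in rng.sample(pool, k=min(len(pool), rng.randint(1, 2))):
                kb.add_is_a(term_id, parent)
    return ids


def random_kb(params: RandomKbParams) -> KnowledgeBase:
    """Generate a random knowledge base per ``params`` (see the class doc)."""
    rng = random.Random(params.seed)
    kb = KnowledgeBase()

    moas = _random_dag(
        kb, rng, "moa", "MoA class", params.n_moa_classes,
        params.hierarchy_depth, Kind.MOA,
    )
    aes = _random_dag(
        kb, rng, "ae", "adverse event", params.n_aes,
        params.hierarchy_depth, Kind.ADVERSE_EVENT,
    )
    diseases = _random_dag(
        kb, rng, "disease", "disease", params.n_diseases,
        params.hierarchy_depth, Kind.DISEASE,
    )

    # fixed two-level drug-class scaffold
    drug_classes: List[str] = []
    if params.n_drugs:
        root = "OTHER:drugclass_root"
        kb.add_term(TermRef(root, "drug class root", kind=Kind.DRUG_CLASS))
        for i in range(3):
            cls = f"OTHER:drugclass_{i}"
            kb.add_term(TermRef(cls, f"drug class {i}", kind=Kind.DRUG_CLASS))
            kb.add_is_a(cls, root)
            drug_classes.append(cls)

    drugs: List[str] = []
    for i in range(params.n_drugs):
        drug = f"OTHER:drug_{i:03d}"
        kb.add_term(TermRef(drug, f"drug {i:03d}", kind=Kind.DRUG))
        kb.add_is_a(drug, rng.choice(drug_classes))
        drug_moas = (
            set(rng.sample(moas, k=min(len(moas), rng.randint(1, 3)))) if moas else set()
        )
        kb.set_profile(DrugProfile(drug, moas=drug_moas))
        drugs.append(drug)

    for drug in drugs:
        for age in AgeGroup:
            for disease in [None, *diseases]:
                for ae in aes:
                    if rng.random() < params.assoc_prob:
                        kb.add_record(AdeRecord(drug, ae, age, disease))
    return kb
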