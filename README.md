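# adekb — adverse drug event knowledge bases

`adekb` is a toolkit for building, serializing, querying and analyzing
knowledge bases of **conditional adverse drug events (ADEs)**: curated
statements of the form *drug D is associated with adverse event E when used
to treat disease S in patients of age group G*. The same drug often shows
different adverse-event profiles in adults versus children, or under
different treated diseases — sirolimus under lymphangioleiomyomatosis
versus renal-transplant rejection, diltiazem under hypertension versus
intermediate coronary syndrome — and a flat drug→AE list cannot express
that. The toolkit is aimed at pharmacovigilance and biomedical-ontology
practitioners who curate such associations from FDA package inserts (or
similar evidence) into spreadsheets and want a reproducible path from
tables to an OWL2 knowledge base and to class-level statistics.

## What it does

**Knowledge model.** Terms are CURIE-identified classes reused from the
standard source ontologies of the field — OAE for adverse events, NDF-RT
for drugs, chemical ingredients, mechanisms of action (MoA) and
drug-treated diseases, DOID for diseases, BFO for the upper level — linked
by an `is_a` hierarchy (a DAG; cycles are hard errors). Each drug carries a
profile (ingredients, MoAs, treatable diseases) and each curated
association is a record `(drug, AE, age group, treated disease, evidence)`.

**Ontology design pattern.** An association is an *n-ary* relation, while
OWL properties are binary. Each record is therefore emitted as a
subclass-of-restriction axiom, in a *full* (nested) or *shortcut*
(flattened, query-efficient) form, from the drug side or the AE side:

```text
full:      D ⊑ 'drug associated with AE' some
               (E ⊓ ('occurs in' some (G ⊓ ('has disease' some S))))
shortcut:  D ⊑ ('drug associated with AE in <age>' some E)
               ⊓ ('used to treat disease' some S)
```

The two forms encode the same fact: `decode_axiom` inverts
`generate_axiom` exactly for all four shapes. Whole knowledge bases
serialize to OWL2 (Turtle) with labels, hierarchy, property domain/range
declarations, profile links and evidence annotations, and re-parse to a
structurally identical axiom multiset.

**Hierarchy-aware queries.** `drugs_by_class` resolves class membership
transitively (a drug belongs to an MoA class through any sub-MoA in its
profile); `query_ade` joins profiles and records under MoA-class, age,
disease and drug filters; `compare_contexts` splits a drug's AEs into
shared/context-specific sets; `ae_frequency` counts AEs per *scenario*
(one drug–age–disease context, so a drug studied under several diseases
counts several times).

**Class effects.** The proportional class-level ratio for a class C and an
adverse event E is

```text
PCR(C, E) = #{member drugs of C associated with E} / #{member drugs of C}
```

computed as an exact rational; `PCR = 1` flags an AE-specific drug class
effect, and `find_class_effects` scans all classes against a threshold.

## Worked example

The package ships a curated mini knowledge base encoding classic
conditional-ADE examples (`adekb.build_paper_fixture()`, or
`adekb fixture --out dir/` to get it as CSVs + OWL). Querying all drugs
whose MoA falls under ion-channel interactions, in adults:

```console
$ adekb fixture --out kbdemo
$ adekb query -a kbdemo/annotations.csv -H kbdemo/hierarchy.csv \
        -p kbdemo/profiles.csv --moa-class NDFRT:ion_channel_interactions --age adult
drug	moa	disease	ae	age
NDFRT:diltiazem	NDFRT:calcium_channel_blockers	NDFRT:hypertension	OAE:constipation	adult
NDFRT:diltiazem	NDFRT:calcium_channel_blockers	NDFRT:hypertension	OAE:cough_increased	adult
NDFRT:diltiazem	NDFRT:calcium_channel_blockers	NDFRT:hypertension	OAE:headache	adult
NDFRT:diltiazem	NDFRT:calcium_channel_blockers	NDFRT:hypertension	OAE:pharyngitis	adult
NDFRT:diltiazem	NDFRT:calcium_channel_blockers	NDFRT:hypertension	OAE:rhinitis	adult
NDFRT:diltiazem	NDFRT:calcium_channel_blockers	NDFRT:intermediate_coronary_syndrome	OAE:asthenia	adult
NDFRT:phenytoin	NDFRT:sodium_channel_blockers	NDFRT:east_syndrome	OAE:0000425	adult
...
```

Diltiazem (a calcium channel blocker) shows five AEs under adult
hypertension but only asthenia under intermediate coronary syndrome — the
same drug, different context, different AE profile. The class-effect
statistic on the tyrosine-kinase-inhibitor MoA class:

```console
$ adekb pcr -a kbdemo/annotations.csv -H kbdemo/hierarchy.csv -p kbdemo/profiles.csv \
        --class NDFRT:tyrosine_kinase_inhibitors --ae OAE:0000425 --age adult
class=NDFRT:tyrosine_kinase_inhibitors	ae=OAE:0000425	n_assoc=3	n_total=3	pcr=1	class_effect=True
```

All three member drugs (imatinib, erlotinib, trastuzumab — each through
its own sub-MoA) carry a rash record in adults, so PCR = 3/3 = 1: a class
effect. The same call for the immunologic/biological-factors class and
nausea gives `n_assoc=9 n_total=10 pcr=0.9` — a strong but sub-unity
signal. In Python:

```python
from adekb import build_paper_fixture, pcr, Context, AgeGroup

kb = build_paper_fixture()
result = pcr(kb, "NDFRT:tyrosine_kinase_inhibitors", "OAE:0000425",
             Context(age=AgeGroup.ADULT))
print(result.pcr, result.is_class_effect)   # 1 True
```

## Layout

- `src/adekb/kb_model.py` — domain types, the is_a DAG, transitive closure, validation
- `src/adekb/annotation_io.py` — the three CSV curation tables, round-trip I/O
- `src/adekb/axiom_pattern.py` — axiom generation/decoding, rendering, OWL (Turtle) serialization
- `src/adekb/query_engine.py` — hierarchy-aware queries and context comparison
- `src/adekb/class_effect.py` — PCR and class-effect scanning
- `src/adekb/fixtures.py` — the curated mini KB and the seeded random generator
- `src/adekb/cli.py` — the `adekb` command
- `docs/methods.md` — modeling choices, parameters, and limitations
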