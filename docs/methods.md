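# Methods

## The model

A knowledge base holds four kinds of facts:

1. **Terms** — CURIE-identified classes (`PREFIX:local`) with display
   labels, each attributed to a source ontology (OAE, NDF-RT, DOID,
   NCBITaxon, BFO, ODAE, or OTHER) and tagged with a role: drug, drug
   class, mechanism of action (MoA), chemical ingredient, disease, adverse
   event, age group, or upper-level term. Identity is the id, matched
   case-sensitively; labels are display-only, because source-terminology
   labels (e.g. `"Pneumonia, Bacterial"`) are not stable keys. A fixed
   prefix registry maps each prefix to an IRI namespace so emitted OWL
   carries full IRIs without requiring term hosting.
2. **is_a edges** over terms. The hierarchy is a directed acyclic graph,
   not a tree: MoA and adverse-event terminologies routinely give a class
   several parents. An edge that would close a cycle is a hard error at
   insertion time, so the transitive closure is always well defined.
   Reasoning is deliberately limited to this closure
   (ancestors/descendants via reachability, implemented on a `networkx`
   digraph); no OWL-DL classification is attempted.
3. **Drug profiles** — per-drug sets of ingredients, MoAs, and treatable
   diseases. Profiles merge by set union when a drug is declared twice.
4. **ADE records** — `(drug, adverse event, age group, treated disease,
   evidence)`. Age is a closed enumeration {adult, pediatric, senior,
   unspecified}, where *unspecified* is the absence of an age context, not
   a fourth population; the disease slot may likewise be absent. The
   `(drug, AE, age, disease)` tuple is unique per store. Evidence is a
   free-text citation, typically the package-insert document the
   association was curated from.

`validate()` returns (never raises) the full list of invariant violations
— dangling references, duplicate record tuples, cycles — so partially
built stores can be diagnosed in one pass.

## The axiom pattern

OWL object properties are binary; a contextual ADE statement is a
relation among four entities. Each record is encoded as a
subclass-of-existential-restriction axiom in one of four shapes,
{full, shortcut} × {drug-side, AE-side} (see the `axiom_pattern` module
docstring for all four templates). The *shortcut* form carries the age
group inside the property (`'drug associated with AE in adult'`), which
flattens the nesting and makes triple-store queries cheap; the *full*
form keeps one base property and nests the age/disease context under
`'occurs in'`. An absent age or disease prunes the corresponding subtree,
so a context-free record degrades gracefully to
`D ⊑ 'drug associated with AE' some E`.

Design choices that were genuinely open:

- **AE-side shortcut.** Only three of the four shapes have a canonical
  printed form in the literature of this pattern. The AE-side shortcut is
  defined here symmetrically as
  `E ⊑ ('treated with drug' some D) ⊓ ('drug AE occurs in' some (G ⊓ ('has disease' some S)))`,
  reusing the pattern's own `'drug AE occurs in'` property.
- **Decoding.** `decode_axiom` is a structural pattern-matcher over the
  restriction tree; anything outside the four shapes raises
  `MalformedAxiomError`. The evidence string is not part of the class
  expression — it travels as an axiom annotation — so decoding copies it
  from the axiom's provenance.
- **Per-age shortcut properties** are minted for all three age groups,
  although only the adult variant has a printed precedent; the
  unspecified age uses the base property. This keeps generation closed
  and symmetric.
- **Minted IRIs.** The pattern's object properties (and the three
  domain/range anchor classes Drug/AdverseEvent/Disease for the shortcut
  relations) live in the toolkit's own namespace `https://w3id.org/adekb/`,
  with their conventional labels attached as `rdfs:label`, because no
  public id↔label mapping exists to reuse. Age-group terms (Adult,
  Pediatric, Senior) are built-in terms of every store so that axiom-tree
  leaves are always term ids.
- **Serialization** is Turtle carrying OWL2 constructs (restriction and
  intersection blank nodes, `owl:Axiom` annotation for evidence), emitted
  deterministically: axioms ordered by (drug, AE, age, disease), blank
  nodes numbered sequentially, rdf:List cells built by hand rather than
  with the stock collection helper (whose uuid-labelled cells both break
  byte-stability and trip the Turtle pretty-printer into dropping
  property blocks of blank nodes referenced from inside a collection).
  Byte-stable output makes releases diffable. A Manchester-like rendering
  (`render_axiom`) exists for human reading and tests; comparisons of
  rendered text normalize whitespace, quoting and grouping parentheses,
  since printing conventions for nested conjunctions vary.

## Query semantics

- Class filters are transitive: drug d matches MoA class C iff some MoA
  in d's profile is C or a descendant of C, and a drug-class term claims
  every drug below it in the is_a hierarchy. Disease filters are likewise
  transitive over the disease hierarchy.
- Age filters are exact-match — the age axis is flat — and a record with
  unspecified age matches only age-unconstrained queries, because whether
  a context-free association applies to every age group is not decidable
  from the curation.
- Adverse events are matched by exact id; AE-subtree aggregation is left
  to composition with `descendants()`, keeping the query primitive
  orthogonal.
- `ae_frequency` counts *scenarios*: distinct (drug, age, disease)
  contexts whose record set contains the AE. One drug studied under
  several diseases therefore contributes several counts, and a frequency
  may exceed the number of drugs.

## PCR

`PCR(C, E | context) = n_assoc / n_total`, where `n_total` counts the
member drugs of C (same transitive membership as the query engine — the
tyrosine-kinase worked example requires membership to flow through
sub-MoAs) and `n_assoc` counts members with at least one matching record.
Ratios are `fractions.Fraction`, so `pcr == 1` and threshold comparisons
are exact; a float threshold like 0.9 is snapped to its nearest small
rational before comparison to avoid binary-float artifacts (naively,
`9/10 >= float 0.9` is false). A class with no member drugs raises
`EmptyClassError` rather than reporting 0/0. No significance testing is
attached to the ratio; it is a descriptive statistic, and the class-effect
flag is simply `PCR = 1`. Whether sub-unity ratios "count" as effects is
left to the caller's threshold (the scan default is 1.0).

## CSV curation format

Three UTF-8, RFC-4180 CSV tables (annotations, hierarchy, profiles) with
`;` as the intra-cell list separator; exact columns are documented in
`annotation_io`. Terms auto-register on first sight with the row's label;
on a label conflict the first-seen label wins with a warning, which keeps
builds order-stable. The hierarchy table accepts optional role columns
and declaration-only rows (empty parent), which is what lets a written
store round-trip terms that carry no edge or record. Duplicate annotation
rows collapse to one record with a warning.

## The curated fixture and the random generator

The built-in curated store encodes the classic worked examples of
conditional ADE curation exactly as they are stated in running text:
Linezolid (rash/adult/bacterial pneumonia), Alosetron
(constipation/adult/IBS), Diltiazem (asthenia under intermediate coronary
syndrome; pharyngitis, rhinitis, headache, constipation, cough increased
under hypertension), Phenytoin (four named AEs under adult EAST syndrome,
of seven curated in the source data — tests assert inclusion only),
Sirolimus (six AEs shared across its two treated diseases), Infliximab
(neutropenia/leukopenia only in Crohn's disease; pharyngitis/abdominal
pain only in ulcerative colitis), the tyrosine-kinase trio with their
three sub-MoAs and six shared adult AEs, and an immunologic/biological
MoA class with ten member drugs of which nine carry a nausea record. The
ten immunologic drug terms are synthetic placeholders — only the class
label and the 9-of-10 structure are curated facts. Context-comparison
figures in the source material are graphical and not reliably
transcribable, so comparison tests assert set inclusion, not equality.
A manifest pairs every term/edge/profile/record with a note naming its
worked example, and a SHA-256 of the canonical CSV serialization is
pinned in the tests to freeze the fixture.

`random_kb(params)` generates property-test stores: layered random DAGs
for MoA/AE/disease terms (each non-root node takes 1–2 parents from lower
layers), a small fixed drug-class scaffold, 1–3 MoAs per drug, and each
(drug, age, disease-or-none, AE) cell of the full association product
drawn independently with probability `assoc_prob`. Identical params+seed
give byte-identical stores. Defaults (12 drugs, 15 AEs, 6 diseases, 8 MoA
classes, depth 3, p = 0.08) give a few hundred records — the density a
small curation effort would produce; oracle-battery tests use a smaller
shape (5 drugs, 6 AEs, 3 diseases) so that brute-force cross-checks over
hundreds of seeded stores stay fast. What the generator does *not*
emulate: correlated AE profiles within a drug class, age-skewed
prevalence, evidence text, or realistic hierarchy shapes — so passing
property tests demonstrates algebraic correctness (closure, duality,
round-trips, oracle agreement), not epidemiological realism.

## Numerical and degenerate-input choices

- All ratios are exact rationals; no floating-point accumulates anywhere.
- Deterministic orderings throughout: query results sort by (drug, MoA,
  disease, AE, age) with absent fields as empty strings; frequency tables
  by count descending then label; class-effect scans by PCR descending
  then ids.
- Empty stores are valid: queries return empty lists, serialization emits
  a header-only ontology, `find_class_effects` returns nothing.
- A drug with no profile still answers drug-filtered queries (its MoA
  slot reports as absent); a class with members but no matching records
  scores PCR 0.

## Known limitations

- No DL reasoning: equivalence, disjointness and property semantics in
  the emitted OWL are not checked for logical consistency.
- The OWL parse-back (`parse_owl_axioms`) is a structural extractor over
  the RDF graph (restriction/intersection vocabulary), built on rdflib's
  Turtle parser; it is designed as a round-trip oracle, not a general
  OWL2 reader.
- The curated store covers adult (and no senior/pediatric) contexts, as
  the running-text examples do; the age machinery itself is exercised by
  the random generator.
- `Fraction`-based PCR is exact but unsuitable as-is for confidence
  statements; a significance layer (e.g. exact binomial tests per class)
  is out of scope.
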