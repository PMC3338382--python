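# Methods

## Knowledge-base model

The KB is a set of named classes partitioned into pillars — `dysplasia`,
`gene`, `gene_mutation`, `protein`, `phenotypic_composite`,
`anatomical_composite`, `quality_composite` — plus a table of external-term
references. Each pillar has a bootstrapped root class (`Bone_Dysplasia`,
`Gene`, `Gene_Mutation`, `Protein`, `Phenotypic_Composite`,
`Anatomical_Composite`, `Quality_Composite`). Subclass edges form a DAG
(multi-parenthood is allowed; cycles are rejected on every mutation).
Dysplasia depth is the longest subclass path from `Bone_Dysplasia`:
groups at depth 1, diseases at depth 2, subtypes at depth 3. Incremental
identifiers (`G`/`GM`/`P` and `PC_`/`AC_`/`QC_` plus a 7-digit counter)
are normalized from 5–8-digit surface forms, since published listings pad
them inconsistently.

External terms are held MIREOT-style: id, source vocabulary, label, and a
single optional `parent_hint`. Ancestry of an external term is the chain
of parent hints; a chain that ends before reaching a recognized root
(e.g. `HP:HP_0000118`, `PATO:PATO_0001241`) is treated as *unknown
placement*, which degrades to acceptance in range checks rather than a
violation — missing curation is not an inconsistency.

## Axiom grammar

Class restrictions use a restricted Manchester-style grammar:

```
AXIOM  := REL only EXPR | REL some EXPR | AXIOM and AXIOM | (CONJ) or (CONJ) ...
EXPR   := ATOM | EXPR and EXPR | EXPR or EXPR | (EXPR)
```

The frequent paired pattern `R only F and R some F` is normalized into a
single `only_and_some` axiom; serialization expands it back, so
serialize→parse is the identity on axiom values. Top-level composite
definitions additionally need a disjunction of restriction conjunctions
(`(... and ...) or (... and ...)`), represented as a dedicated
disjunctive-axiom value whose branches are plain axioms. Multi-atom
fillers of a restriction must be parenthesized; the serializer
parenthesizes every non-atomic child, which preserves tree shape exactly
and makes round-trips byte-stable.

## Validation semantics

No DL reasoner is used. Published pipelines run open-world reasoners over
such ontologies; at desk scale a closed-world reading is more useful for
record checking, and it is decidable by direct enumeration:

* **TBox** (structural): subclass graph acyclic; every parent resolvable;
  every axiom's relation domain matches the owning class's pillar; every
  filler atom resolves; every filler atom fits the relation's range
  (`characterized_by` accepts gene mutations, phenotypic composites, and
  HP/radiographic abnormality descendants; `has_part` is
  owner-pillar-dependent; etc.).
* **ABox** (closed-world): for each individual and each restriction of its
  asserted classes, `some` requires at least one link of that relation
  whose target satisfies the filler, `only` requires every such link to;
  a disjunctive axiom needs one fully satisfied branch. Filler
  satisfaction is subsumption-aware through both the subclass DAG and
  external parent-hint chains. Universal restrictions over an empty link
  set are vacuously true, which also gives the membership classifier its
  semantics: a dysplasia is *compatible* with a patient when every
  asserted feature falls inside every applicable `characterized_by`
  only-filler (own and inherited).

Violations are returned as sorted, de-duplicated data values, never
exceptions. The validators are differentially tested against brute-force
reference implementations (independent resolver, ancestry walker, and
domain/range tables) on 200 seeded random KBs with injected defects.

## Mutation encoding

`AAA<pos>BBB, <offset> <orig>-<mut>` combines a protein-level
substitution with a nucleotide-level one; either part may stand alone.
`count` always equals the length of the original nucleotide content
(substitutions are the only event type). The offset is an opaque 1-based
coordinate: the dialect does not distinguish cDNA from genomic positions,
so no coordinate conversion is attempted. Parsing is case-insensitive on
amino-acid codes; serialization is canonical, and parse∘serialize is the
identity on records.

## Analytics

* **Phenotype profile** of a disorder: the HP/radiographic externals and
  phenotypic-composite classes in its own `characterized_by` fillers
  (mutations excluded).
* **Ranking**: Jaccard index between patient phenotype set and each
  profile (deterministic, scale-free; ties broken by id), or normalized
  confidence-weighted voting over mined rules.
* **Rule mining**: level-wise Apriori over diagnosed cases, complete for
  antecedents up to 3 items; support is joint count over all cases,
  confidence is joint over antecedent count. The miner is hand-written
  (no mining library is a runtime dependency) and tested against
  exhaustive enumeration on small cohorts. **Refinement** drops rules
  whose antecedent is not contained in every applicable
  `characterized_by` only-filler of the consequent; it never grows the
  rule set and is idempotent.
* **Text annotation**: dictionary matching on whitespace-normalized text,
  word-based, case-insensitive, left-to-right longest match;
  punctuation between words breaks a phrase, punctuation adjacent to a
  word does not. Offsets are 0-based half-open on the normalized text.

## Synthetic-data generator

`generate_nosology(FixtureConfig())` emulates a curated nosology at desk
scale: 40 groups with 2–4 diseases each, 15% of diseases hosting a
depth-3 subtype, 60 genes, 90 mutations (sampled from the encoding
grammar), 50 proteins, a 100-term synthetic phenotype pool arranged in a
shallow random forest under the phenotypic-abnormality root, and
8-phenotype disease profiles. At least 70% of disease leaves carry a
mutation link (a ceiling is used so the fraction is a true lower bound)
and about 80% carry phenotype links (rounded). `reference_scale_config()`
scales to 515 dysplasias, 254 genes, 361 mutations, and 224 proteins.
Output is deterministic per seed and byte-identical across runs; exact
bookkeeping (profiles, mutation links, pool) is attached as
`kb.generator_truth` for oracle-style testing.

`generate_cases(kb, n, dropout, n_spurious, seed)` samples diagnosed
cases: a true disease uniformly among those with non-empty profiles, each
profile phenotype kept with probability `1 − dropout`, `n_spurious`
off-profile phenotypes added, and the disease's mutation links copied.
These defaults (200 cases, 20% dropout, 2 spurious terms) are the study
conditions for the reported ranking accuracy.

Limitations: phenotype terms are synthetic identifiers, not real HPO
terms; profiles are sampled independently per disease, so inter-disease
phenotype correlation is limited to chance overlap; mutation/disease
linkage is one-way (`characterized_by` fillers) with no population
frequencies; and the generator emits only substitution-type mutations.

## Numerical choices

All scores are exact ratios of small integers computed in double
precision; no iterative numerics are involved. Sorting keys
(score descending, then id) make every ranking and violation report
deterministic. Random processes use `random.Random` with explicit seeds;
derived seeds stay below 2³¹.
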