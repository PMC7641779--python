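# Methods

## The knowledge model

The schema treats pharmacogenomics knowledge as a closed, typed vocabulary.
Entities are `{EID*, TERM*, Source, SemanticType*}` (starred fields required);
relations are `{RID*, Relationship*, Domain*, Range*, Definition, TreeNumber*}`.
Validation is purely structural — membership, non-emptiness, attribute
inventories, and domain/range typing of triples. There is deliberately no
description-logic reasoning: the model is a curated registry, not an ontology,
and violations are reported as messages rather than raised mid-pipeline so
curation tooling can collect them.

**Six core types vs a five-type presentation.** The model is sometimes
presented with population folded into a broader "precise medication" grouping,
giving five types. We model six concrete core types (Population and DrugUse
separate) because their attribute inventories are disjoint and the annotation
label set distinguishes them; the five-type view is a presentation grouping
only.

**The auxiliary Mutation type.** The melanoma case study contains
gene–mutation triples, which requires mutations to be addressable as objects,
not only as a Gene attribute. The default registry therefore ships a seventh,
auxiliary semantic type `Mutation` flagged `auxiliary: true`; counts of "core
semantic types" exclude it. This is an explicit schema extension, kept visible
in the registry config.

**Tree numbers.** The relation taxonomy has exactly two levels. We encode
level as dotted codes (`R01` first-level, `R01.01` second-level; level = dot
count + 1), defined in a versioned YAML config so curators can re-key without
code changes. The registry invariant `count(level 1) + count(level 2) = total`
holds for any registry, and the default ships 14 + 12 = 26.

**Reconstructed relations.** Nine relations are fixed by name and typing
(treats, synergized_by, antagonized_by, have_dosage, have_mutation,
is_biomarker_efficacy_of, is_biomarker_prognosis_of, has_dose_form,
dose_form_of). The full 26-relation inventory with definitions lives in
curation material that is not redistributed here, so the remaining 17 are
completed from the nine melanoma relationship groups with placeholder
definitions and are flagged `reconstructed: true` in the config. Inverse
pairs (has_dose_form / dose_form_of) are declared and checked to mirror each
other's domain/range.

## Corpus layer

Documents are ordered lists of named sections; the annotation workflow targets
five (Indications and Usage, Dosage and Administration, Use in Specific
Populations, Warnings and Precautions, Adverse Reactions). Annotations are
0-based half-open character spans *per section* — sections are annotated
independently, so section-local offsets survive section-level edits.

Tokenization splits `\w+` runs and individual punctuation marks; whitespace is
the only separator, so every non-whitespace character lands in exactly one
token and each token equals its source slice. This makes numeric–unit pairs
("2 mg") two tokens and keeps span/token alignment checkable.

BIO conversion is strict: a span that cuts a token raises an alignment error
rather than snapping, because silent snapping hides annotation bugs. The
inverse conversion repairs invalid `I-` openings to `B-` (the conventional
repair) and logs them. Plain BIO (not BIOES) is used: the tagging interface
only needs per-token tags, and BIO is the minimal faithful scheme.

Train/test splitting rounds half-up on the train side (190 documents at 0.9
split exactly 171/19) and is a deterministic function of the seed. Corpus
statistics report both mention counts and unique-term counts per label, since
"number of entities" is ambiguous between the two readings; pinned tests use
mention counts.

Inter-annotator agreement is the exact-match F score
`F = 2·|matches| / (|a| + |b|)` with a match requiring identical
(section, start, end, label). Two empty sets agree at 1.0 (logged). Double
annotation and third-annotator adjudication are modelled as data (the
`annotator` field), not workflow code.

## The CRF tagger

The tagger is a linear-chain CRF with binary emission features and a learned
transition matrix; the weight vector has length
`|features|·|labels| + |labels|²`. Inference is exact: the forward recursion
gives log Z, forward–backward gives node/edge marginals, and the gradient of
the negative log-likelihood is expected-minus-empirical feature counts plus
the Gaussian-prior term `w/σ²`. All recursions run in log space with an
open-coded log-sum-exp (the generic library routine dominated runtime in the
training loop).

**Features.** Per position: a bias, the lowercased token, a character-shape
pattern (case/digit classes), prefixes/suffixes to length 3, and an is-digit
flag, plus lowercase/shape/digit features of neighbours within a window
(default radius 2), each tagged with its relative offset; boundary positions
contribute sentinel features. These templates are standard for feature CRFs
on biomedical text and are deliberately modest — the discrete feature layer is
one implementation of the emission interface, not the point of the design.

**Encoder interface.** `Encoder.emissions(seq, labels)` returns a dense
(N × L) score matrix, and `viterbi_decode_dense` runs on it directly. This is
the slot a pretrained contextual encoder (e.g. a fine-tuned transformer)
plugs into; training such an encoder requires external weights and is out of
scope, so the shipped reference implementation is a lookup encoder used to
exercise the dense path.

**Training.** Deterministic full-batch L-BFGS from zero initialization on the
L2-penalized objective (`σ = 10` by default, max 200 iterations, relative
objective tolerance 1e-6). Full-batch quasi-Newton was chosen over mini-batch
schedules because bit-reproducibility given a seed is worth more here than
fidelity to stochastic training regimes that belong to the encoder stage.
A corpus with a single distinct tag is rejected as degenerate.

**Decoding.** Viterbi with ties broken toward the lexicographically smallest
label-index sequence: the recursion runs back-to-front on suffix maxima, then
the path is reconstructed front-to-back taking the smallest label index
achieving the maximum at each step. With all-zero weights this yields the
first label repeated — a fixed, documented outcome rather than an arbitrary
one.

**Evaluation.** Entity-level exact (section, start, end, label) matching,
one-to-one; micro-averaging pools TP/FP/FN over labels before computing
P/R/F1; per-label metrics use that label's counts. Percentages are rounded
half-up to two decimals. The report header declares the granularity. Note the
arithmetic identity: when pooled precision equals pooled recall, F1 equals
both (e.g. 85.12/85.12 → 85.12).

## Expression normalization

Relation surface expressions are matched as case-insensitive,
whitespace-normalized literals with a single wildcard operator `***` that
captures a maximal non-empty token run, bounded at 6 tokens by default
(configurable) to prevent pathological captures. Free regex is deliberately
excluded so curator rules remain auditable. Scanning is left-to-right; at
each position the longest match wins, an accepted match consumes its tokens,
and scanning resumes after it. The shipped rule file covers the documented
expression inventory (treats, synergized_by, antagonized_by, have_dosage,
have_mutation families) and is extensible at runtime; additions are rejected
if the surface duplicates an existing rule or the target relation is not
registered. Statistical relation extraction from free text is explicitly not
attempted — the normalizer handles already-extracted expressions.

## Triple store and queries

Every triple is validated on insertion (domain/range typing, known entities,
no reflexive assertions); exact duplicates are dropped with a log entry, so a
store can never hold an invalid or duplicated triple. Group counts key on the
(domain, range) pair of each triple's relation.

`query_drugs` implements Dr = F(C, G): candidates must hold a Drug→Disease
link to C (when given) and a drug–gene link to G in either direction (when
given); results are eid-sorted for determinism. `query_dosage` implements
Ds = F(Dr, G, A, P): defaults are the drug's routine-dosage links; each
supplied context factor is applied independently (the factors are treated as
independent), and a contextual DrugUse must be reachable both from the factor
entity (e.g. AdverseReaction → adjusts_dosage) and from the drug's own
adjusted-dosage links — context is encoded as triples joined through the
drug, keeping the query pure traversal. Contextual results precede defaults
because they override the routine instruction.

Export: N-Triples with IRIs minted deterministically from eids/rids under a
configurable base (lines sorted for reproducibility), TSV that round-trips
byte-identically through import, and JSON grouped by relationship group.

## The melanoma case-study store

The curated melanoma data set is not redistributed; `pgxkit.melanoma`
reconstructs a synthetic store with the documented structure: the seven drugs
(binimetinib, cobimetinib, dabrafenib, encorafenib, nivolumab, trametinib,
vemurafenib), their target genes (three BRAF inhibitors, three MEK-pathway
inhibitors, one PD-1 blocker), BRAF V600E/V600K mutation entities, and
trametinib's dosage narrative (2 mg orally once daily by default; permanent
discontinuation on fever or interstitial lung disease). The nine group sizes
(4713 drug–drug, 41 drug–adverse reaction, 30 drug–dosage, 24 adverse
reaction–dosage, 22 drug–disease, 7 drug–gene, 4 drug–population, 2
gene–mutation, 3 gene–disease; total 4846) are realized exactly, with the
bulk of the drug–drug group filled by deterministic synthetic interactant
drugs labelled as such. The store is a structural reconstruction: its group
arithmetic and query behaviour are faithful, its bulk content is not curated
knowledge.

## Ingest

The SPL reader identifies the five target sections by normalized
(case-insensitive) title match — section names, not LOINC codes, are the
primary key, with code matching an additive fallback behind the same
interface. The DrugBank-dialect reader extracts only the attribute subset
the schema consumes (name, description, formula, molecular weight in daltons,
approval status, CAS, UNII, indication text) and ignores unknown elements,
since upstream schemas drift; CAS numbers are checksum-validated and flagged,
not dropped. Mapping the record's indication text to the
PharmacologyIndication attribute is an assumption, documented here. The RRF
reader parses RXNCONSO/RXNREL pipe-delimited lines with the standard column
layout, filters relations to has_dose_form/dose_form_of, and never aborts on
a malformed line (line-level error, parse continues). UTF-8 is mandated.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes: five
label sections per document, one to three sentences per section drawn from
section-specific templates, entity slots filled from per-label vocabularies,
relation expressions embedded verbatim from the shipped synonym inventory,
and entity-free distractor sentences at a configurable rate (default 0.2).
Defaults are the study conditions: 190 documents, the melanoma cast in the
vocabulary (the seven drugs, BRAF V600E/V600K, "2 mg orally once daily"),
invented synthetic fillers beyond it. Every emitted mention and relation
instance is recorded in a gold ledger with exact offsets, so corpus
statistics, training, evaluation and normalization are all checkable against
the generator's own bookkeeping.

What the generator does **not** emulate: real-label vocabulary breadth and
long-tail spelling, boundary ambiguity, discontinuous or overlapping
mentions, OCR/conversion noise, or annotator disagreement. Templated labels
are near-separable, so a converged feature CRF scores near 100% on held-out
synthetic labels; passing that bar demonstrates the pipeline is correct
end-to-end, not that comparable accuracy transfers to real drug labels,
where feature CRFs and encoder-based taggers score far lower.

The `corrupt` operation perturbs gold spans (drop / shift-by-one / relabel)
deterministically and returns the expected exact-match agreement computed
from its own edit ledger, providing an independent check of the agreement
implementation.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale sizes chosen to exercise every
code path while keeping the suite fast: exhaustive-enumeration oracles at
N ≤ 4 tokens and L ≤ 3 labels (81 paths maximum) with agreement to 1e-8;
central finite differences at 1e-6 step with relative gradient agreement to
1e-5; learning checks at 10/25/50 training documents with 10 held out over
three seeds; 1000 random span layouts for round-trip checks. Floating-point
ties in Viterbi are resolved by the lexicographic rule above; percentage
rounding is half-up; the agreement of two empty annotation sets is defined
as 1.0.

## Known limitations

- The registry's reconstructed relations carry placeholder definitions.
- Contextual dosage joins require explicit adjusted-dosage triples; free-text
  dosage-adjustment narratives are not parsed into triples automatically.
- The normalizer matches literal token runs; it will not bridge inflection
  ("in combination" vs "in combinations") or discontinuous expressions.
- No transformer encoder ships with the package; the encoder interface is the
  integration point, and the feature CRF is the reference tagger.
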