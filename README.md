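# pgxkit

A pharmacogenomics (PGx) knowledge-model toolkit for mining precision-medication
knowledge out of drug labels. It is aimed at biomedical NLP practitioners and
knowledge-base curators who need, in one place: a typed entity/relation schema
with structural validation, a drug-label annotation corpus layer, a
fully-implemented linear-chain CRF entity tagger with exact inference,
normalization of free-text relation expressions, and a validated triple store
with risk-factor queries and export — all testable offline on synthetic labels.

## The model

Entities are typed records `{EID*, TERM*, Source, SemanticType*}` over six core
semantic types — Drug, Gene, Disease, AdverseReaction, Population, DrugUse —
each with a fixed attribute inventory (e.g. Drug carries DrugName, CAS, UNII,
…; Gene carries GeneName and Mutation). Relations are records
`{RID*, Relationship*, Domain*, Range*, Definition, TreeNumber*}` in a
two-level taxonomy of 26 relations (14 first-level + 12 second-level), with
domain/range constraints enforced on every triple.

The knowledge model casts precision medication as risk-factor lookups: with
disease *C*, gene (mutation) *G*, adverse reaction *A* and population *P*,

    Dr = F(C, G)              candidate drugs from disease and causal gene
    Ds = F(Dr, G, A, P)       dosage / dose form, adjusted per factor
    Dr, Ds = F(C, G, A, P)

Entity tagging uses a linear-chain conditional random field over BIO tags of
the eight annotation labels (Drug, Gene, Disease, Body_Part, Daily_Dose,
Dose_Form, Frequency, Adverse_Reaction):

    score(y | x) = Σ_t w·φ(x, t, y_t) + Σ_t T[y_{t-1}, y_t]
    p(y | x) = exp(score) / Z(x)

with the partition function computed exactly by the forward recursion,
gradients by forward–backward marginals, decoding by Viterbi, and training by
deterministic full-batch L-BFGS on the L2-penalized conditional likelihood.
Evaluation is entity-level (exact span + label) micro-averaged P/R/F1. A
pluggable encoder interface accepts dense per-token emissions from any
representation model (e.g. a fine-tuned transformer) in place of the discrete
feature layer.

## Worked example

Build the melanoma case-study store and run the risk-factor queries
(`examples/05_melanoma_queries.py`):

```text
4846 triples in 9 groups:
  Drug-Drug: 4713
  Drug-AdverseReaction: 41
  Drug-DrugUse: 30
  AdverseReaction-DrugUse: 24
  Drug-Disease: 22
  Drug-Gene: 7
  Drug-Population: 4
  Gene-Disease: 3
  Gene-Mutation: 2
BRAF-targeted melanoma drugs: ['dabrafenib', 'encorafenib', 'vemurafenib']
trametinib dosage (no context): '2 mg orally once daily' [default]
trametinib dosage (fever): 'stop permanently' [adverse_reaction]
```

The first block is the store's relationship-group breakdown; the drug query is
`Dr = F(C=melanoma, G=BRAF)` — the three BRAF inhibitors among the seven
melanoma drugs; the dosage queries show the routine instruction and how an
adverse-reaction context overrides it.

Train and score the tagger on synthetic labels
(`examples/03_train_tagger.py`):

```text
held-out micro P/R/F1: 100.00 / 100.00 / 100.00  (entity-level (exact span + label match))
```

Templated synthetic labels are near-separable, so a converged feature CRF
tags them essentially perfectly; the number is a pipeline health check, not a
claim about real labels. The other `examples/*.py` scripts cover schema
validation, BIO annotation and agreement, expression normalization, and the
source-dialect parsers; each prints what it computes and is runnable as
`python examples/<name>.py`.

A thin CLI wraps the same functions: `pgxkit gen-synth`, `pgxkit train-ner`,
`pgxkit eval-ner`, `pgxkit tag`, `pgxkit build-kg`, `pgxkit query`.

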