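"""The melanoma case study: group counts and the risk-factor queries.

Builds the synthetic case-study store (4846 triples in nine relationship
groups) and runs the two lookups the model defines: candidate drugs from
disease and gene, Dr = F(C, G), and dosage for a drug under an adverse
reaction, Ds = F(Dr, A).
"""

from pgxkit.kgraph import QueryContext, group_counts, query_dosage, query_drugs
from pgxkit.melanoma import build_melanoma_store

store = build_melanoma_store()
report = group_counts(store)
print(f"{report.total} triples in {len(report.counts)} groups:")
for (subj, obj), n in sorted(report.counts.items(), key=lambda kv: -kv[1]):
    print(f"  {subj}-{obj}: {n}")

# Dr = F(C, G): drugs that treat melanoma AND target BRAF
drugs = query_drugs(store, QueryContext(disease="syn:dis-melanoma", gene="syn:gene-BRAF"))
print("BRAF-targeted melanoma drugs:", [e.term for e in drugs])

# Ds = F(Dr, A): trametinib dosage, default vs in case of fever
for ctx, label in [
    (QueryContext(drug="db:trametinib"), "no context"),
    (QueryContext(drug="db:trametinib", adverse_reaction="syn:adr-fever"), "fever"),
]:
    top = query_dosage(store, ctx)[0]
    print(f"trametinib dosage ({label}): {top.entity.term!r} [{top.kind}]")
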