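"""Triple store: validated insertion, group counts, risk-factor queries, export."""

import random

import pytest
import rdflib

from pgxkit.kgraph import (
    QueryContext,
    Triple,
    TripleStore,
    TripleValidationError,
    add_triple,
    export,
    group_counts,
    import_tsv,
    query_dosage,
    query_drugs,
)
from pgxkit.melanoma import MELANOMA_GROUP_SIZES
from pgxkit.schema import Entity


@pytest.fixture
def small_store(registry):
    store = TripleStore(registry=registry)
    store.add_entity(Entity(eid="d:tram", term="trametinib", semantic_type="Drug"))
    store.add_entity(Entity(eid="d:dab", term="dabrafenib", semantic_type="Drug"))
    store.add_entity(Entity(eid="c:mel", term="melanoma", semantic_type="Disease"))
    store.add_entity(Entity(eid="g:braf", term="BRAF", semantic_type="Gene"))
    return store


def rel(registry, name):
    return registry.relation_by_name(name).rid


class TestAddTriple:
    def test_valid_triple_grows_store(self, small_store, registry):
        add_triple(small_store, Triple("d:tram", rel(registry, "treats"), "c:mel"))
        assert len(small_store) == 1

    def test_duplicate_ignored(self, small_store, registry):
        t = Triple("d:tram", rel(registry, "treats"), "c:mel")
        add_triple(small_store, t)
        add_triple(small_store, t)
        assert len(small_store) == 1

    def test_domain_violation_raises(self, small_store, registry):
        with pytest.raises(TripleValidationError, match="domain"):
            add_triple(small_store, Triple("g:braf", rel(registry, "treats"), "c:mel"))

    def test_reflexive_rejected(self, small_store, registry):
        with pytest.raises(TripleValidationError, match="reflexive"):
            add_triple(small_store, Triple("d:tram", rel(registry, "synergized_by"), "d:tram"))

    def test_unknown_entity_rejected(self, small_store, registry):
        with pytest.raises(KeyError):
            add_triple(small_store, Triple("d:nope", rel(registry, "treats"), "c:mel"))

    def test_store_revalidates_after_adds(self, small_store, registry):
        from pgxkit.schema import validate_triple

        add_triple(small_store, Triple("d:tram", rel(registry, "treats"), "c:mel"))
        add_triple(small_store, Triple("d:tram", rel(registry, "targets"), "g:braf"))
        for t in small_store.triples:
            assert validate_triple(
                small_store.entity(t.subject), t.rid, small_store.entity(t.object), registry
            ) == []


class TestGroupCounts:
    def test_empty_store(self, registry):
        report = group_counts(TripleStore(registry=registry))
        assert report.counts == {} and report.total == 0

    def test_single_group(self, small_store, registry):
        add_triple(small_store, Triple("d:tram", rel(registry, "treats"), "c:mel"))
        add_triple(small_store, Triple("d:dab", rel(registry, "treats"), "c:mel"))
        report = group_counts(small_store)
        assert report.counts == {("Drug", "Disease"): 2} and report.total == 2

    def test_melanoma_breakdown(self, melanoma_store):
        report = group_counts(melanoma_store)
        assert report.counts == MELANOMA_GROUP_SIZES
        assert report.total == 4846

    def test_total_equals_store_size_on_random_stores(self, registry):
        rng = random.Random(4)
        store = TripleStore(registry=registry)
        drugs, diseases = [], []
        for i in range(6):
            e = Entity(eid=f"d{i}", term=f"drug{i}", semantic_type="Drug")
            store.add_entity(e)
            drugs.append(e.eid)
        for i in range(4):
            e = Entity(eid=f"c{i}", term=f"dis{i}", semantic_type="Disease")
            store.add_entity(e)
            diseases.append(e.eid)
        for _ in range(40):
            t = Triple(rng.choice(drugs), rel(registry, rng.choice(["treats", "prevents"])),
                       rng.choice(diseases))
            add_triple(store, t)
        report = group_counts(store)
        assert report.total == len(store) == sum(report.counts.values())


class TestQueryDrugs:
    def test_disease_and_gene_matches_full_scan(self, melanoma_store, registry):
        ctx = QueryContext(disease="syn:dis-melanoma", gene="syn:gene-BRAF")
        got = {e.eid for e in query_drugs(melanoma_store, ctx)}
        # independent brute-force scan over the triple list
        treats_rels = {r.rid for r in registry.relations.values()
                       if (r.domain, r.range) == ("Drug", "Disease")}
        gene_rels = {r.rid for r in registry.relations.values()
                     if (r.domain, r.range) == ("Drug", "Gene")}
        treaters = {t.subject for t in melanoma_store.triples
                    if t.rid in treats_rels and t.object == "syn:dis-melanoma"}
        gene_linked = {t.subject for t in melanoma_store.triples
                       if t.rid in gene_rels and t.object == "syn:gene-BRAF"}
        assert got == treaters & gene_linked
        assert got == {"db:dabrafenib", "db:encorafenib", "db:vemurafenib"}

    def test_disease_only_returns_all_treaters(self, melanoma_store):
        got = [e.term for e in query_drugs(melanoma_store, QueryContext(disease="syn:dis-melanoma"))]
        assert len(got) == 7 and got == sorted(got)

    def test_untreated_disease_empty(self, small_store):
        assert query_drugs(small_store, QueryContext(disease="c:mel")) == []

    def test_no_context_rejected(self):
        with pytest.raises(ValueError):
            QueryContext()

    def test_drug_only_context_rejected_for_drug_query(self, melanoma_store):
        with pytest.raises(ValueError, match="disease .* gene|requires"):
            query_drugs(melanoma_store, QueryContext(drug="db:trametinib"))


class TestQueryDosage:
    def test_default_dosage(self, melanoma_store):
        res = query_dosage(melanoma_store, QueryContext(drug="db:trametinib"))
        defaults = [r for r in res if r.kind == "default"]
        assert defaults and defaults[0].entity.term == "2 mg orally once daily"

    def test_adverse_reaction_overrides_default(self, melanoma_store):
        ctx = QueryContext(drug="db:trametinib", adverse_reaction="syn:adr-fever")
        res = query_dosage(melanoma_store, ctx)
        assert res[0].kind == "adverse_reaction"
        assert res[0].entity.term == "stop permanently"
        kinds = [r.kind for r in res]
        assert kinds.index("adverse_reaction") < kinds.index("default")

    def test_drug_without_dosage_triples(self, small_store):
        assert query_dosage(small_store, QueryContext(drug="d:tram")) == []

    def test_missing_drug_rejected(self, melanoma_store):
        with pytest.raises(ValueError, match="requires the drug"):
            query_dosage(melanoma_store, QueryContext(disease="syn:dis-melanoma"))


class TestExport:
    def test_empty_store_tsv_header_only(self, registry):
        text = export(TripleStore(registry=registry), "tsv")
        assert text == "subject\trelationship\tobject\tdoc_id\tsection\n"

    def test_ntriples_grammar(self, small_store, registry):
        add_triple(small_store, Triple("d:tram", rel(registry, "treats"), "c:mel"))
        add_triple(small_store, Triple("d:dab", rel(registry, "treats"), "c:mel"))
        add_triple(small_store, Triple("d:tram", rel(registry, "targets"), "g:braf"))
        nt = export(small_store, "ntriples")
        lines = nt.strip().splitlines()
        assert len(lines) == 3
        assert all(line.endswith(" .") for line in lines)
        parsed = rdflib.Graph()
        parsed.parse(data=nt, format="nt")
        assert len(parsed) == 3

    def test_tsv_round_trip_byte_identical(self, small_store, registry):
        add_triple(small_store, Triple("d:tram", rel(registry, "treats"), "c:mel",
                                       provenance=("doc-1", "Indications and Usage")))
        add_triple(small_store, Triple("d:tram", rel(registry, "targets"), "g:braf"))
        text = export(small_store, "tsv")
        rebuilt = import_tsv(text, registry, small_store.entities.values())
        assert export(rebuilt, "tsv") == text

    def test_json_groups(self, small_store, registry):
        import json

        add_triple(small_store, Triple("d:tram", rel(registry, "treats"), "c:mel"))
        payload = json.loads(export(small_store, "json"))
        assert payload["total"] == 1
        assert payload["groups"][0]["group"] == "Drug-Disease"

    def test_unknown_format_rejected(self, small_store):
        with pytest.raises(ValueError, match="unknown export format"):
            export(small_store, "xml")
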