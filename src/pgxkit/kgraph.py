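"""Triple store over the knowledge model: construction, counting, queries, export.

The model casts precision medication as risk-factor lookups over directed
triples. With disease C, gene (mutation) G, adverse reaction A and
population P:

    Dr = F(C, G)          candidate drugs from disease and gene
    Ds = F(Dr, G, A, P)   dosage/dose form for a drug, adjusted per factor
    Dr, Ds = F(C, G, A, P)

Every triple is validated against the registry's domain/range typing on
insertion, duplicates are dropped, and context-adjusted dosage is encoded
as triples (AdverseReaction → adjusts_dosage → DrugUse, Population →
population_adjusts_dosage → DrugUse) joined through the drug's own
has_adjusted_dosage links, so the queries are pure triple traversal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import rdflib

from pgxkit.schema import (
    Entity,
    KnowledgeModelRegistry,
    RelationDef,
    validate_entity,
    validate_triple,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Triple",
    "TripleStore",
    "QueryContext",
    "GroupCountReport",
    "DosageResult",
    "TripleValidationError",
    "add_triple",
    "group_counts",
    "query_drugs",
    "query_dosage",
    "export",
    "import_tsv",
]

#: Base IRI prefix for N-Triples minting; configurable per export.
DEFAULT_BASE_IRI = "http://pgxkit.local/"


class TripleValidationError(ValueError):
    """Raised when a triple fails schema validation; carries the report."""

    def __init__(self, report: list[str]):
        super().__init__("; ".join(report))
        self.report = report


@dataclass(frozen=True, order=True)
class Triple:
    """A directed (subject, relation, object) assertion with provenance."""

    subject: str  # Entity eid
    rid: str  # RelationDef id
    object: str  # Entity eid
    provenance: tuple[str, str] | None = None  # (doc_id, section_name)

    def key(self) -> tuple[str, str, str]:
        return (self.subject, self.rid, self.object)


@dataclass
class TripleStore:
    """Entities plus validated triples under one registry."""

    registry: KnowledgeModelRegistry
    entities: dict[str, Entity] = field(default_factory=dict)
    triples: list[Triple] = field(default_factory=list)
    _keys: set[tuple[str, str, str]] = field(default_factory=set, repr=False)

    def add_entity(self, e: Entity) -> None:
        report = validate_entity(e, self.registry)
        if report:
            raise TripleValidationError(report)
        if e.eid in self.entities and self.entities[e.eid] != e:
            raise ValueError(f"entity id {e.eid!r} already registered with different content")
        self.entities[e.eid] = e

    def entity(self, eid: str) -> Entity:
        try:
            return self.entities[eid]
        except KeyError:
            raise KeyError(f"unknown entity {eid!r}") from None

    def __len__(self) -> int:
        return len(self.triples)


@dataclass
class QueryContext:
    """Risk factors for a query; at least one field must be set."""

    disease: str | None = None  # C
    gene: str | None = None  # G
    adverse_reaction: str | None = None  # A
    population: str | None = None  # P
    drug: str | None = None  # Dr

    def __post_init__(self) -> None:
        if not any(
            v is not None
            for v in (self.disease, self.gene, self.adverse_reaction, self.population, self.drug)
        ):
            raise ValueError("query context must set at least one field")


@dataclass
class GroupCountReport:
    """Triple counts per (subject semantic type, object semantic type) group."""

    counts: dict[tuple[str, str], int]
    total: int


@dataclass(frozen=True)
class DosageResult:
    """A DrugUse entity selected for a drug, labelled default vs contextual."""

    entity: Entity
    kind: str  # "default" | "adverse_reaction" | "population" | "gene"
    context_eid: str | None = None


def add_triple(store: TripleStore, t: Triple) -> TripleStore:
    """Validate and insert a triple; exact duplicates are ignored (logged)."""
    subj = store.entity(t.subject)
    obj = store.entity(t.object)
    report = validate_triple(subj, t.rid, obj, store.registry)
    rel = store.registry.relation(t.rid) or store.registry.relation_by_name(t.rid)
    if not report and t.subject == t.object and rel is not None:
        report = [f"reflexive triple {t.subject!r} -{rel.relationship}-> itself is not permitted"]
    if report:
        raise TripleValidationError(report)
    if t.key() in store._keys:
        logger.info("duplicate triple ignored: %s", t.key())
        return store
    store._keys.add(t.key())
    store.triples.append(t)
    return store


def group_counts(store: TripleStore) -> GroupCountReport:
    """Count triples per ordered (domain, range) pair of their relation."""
    counts: dict[tuple[str, str], int] = {}
    for t in store.triples:
        rel = store.registry.relation(t.rid)
        key = (rel.domain, rel.range)
        counts[key] = counts.get(key, 0) + 1
    return GroupCountReport(counts=counts, total=len(store.triples))


def _relations_with_signature(
    reg: KnowledgeModelRegistry, domain: str, range_: str
) -> set[str]:
    return {r.rid for r in reg.relations.values() if (r.domain, r.range) == (domain, range_)}


def query_drugs(store: TripleStore, ctx: QueryContext) -> list[Entity]:
    """Dr = F(C, G): drugs treating the disease and/or linked to the gene.

    With C set, a drug must hold a treats-family link (any Drug→Disease
    relation) to C; with G set, it must hold a drug–gene link in either
    direction (Drug→Gene, or Gene→Drug such as efficacy-biomarker).
    Both constraints apply when both are set. Results are sorted by eid.
    """
    if ctx.disease is None and ctx.gene is None:
        raise ValueError("query_drugs requires disease (C) and/or gene (G)")
    for eid in (ctx.disease, ctx.gene):
        if eid is not None:
            store.entity(eid)
    reg = store.registry
    candidates: set[str] | None = None
    if ctx.disease is not None:
        treat_rels = _relations_with_signature(reg, "Drug", "Disease")
        hits = {t.subject for t in store.triples if t.rid in treat_rels and t.object == ctx.disease}
        candidates = hits
    if ctx.gene is not None:
        d2g = _relations_with_signature(reg, "Drug", "Gene")
        g2d = _relations_with_signature(reg, "Gene", "Drug")
        hits = {t.subject for t in store.triples if t.rid in d2g and t.object == ctx.gene}
        hits |= {t.object for t in store.triples if t.rid in g2d and t.subject == ctx.gene}
        candidates = hits if candidates is None else candidates & hits
    return [store.entity(eid) for eid in sorted(candidates or ())]


def query_dosage(store: TripleStore, ctx: QueryContext) -> list[DosageResult]:
    """Ds = F(Dr, G, A, P): dosage instructions for a drug, per risk factor.

    Default results are the drug's routine dosage links (have_dosage /
    has_routine_dosage). Each supplied context factor is applied
    independently: a contextual DrugUse must be reachable both from the
    factor entity (e.g. AdverseReaction → adjusts_dosage) and from the
    drug (has_adjusted_dosage family). Contextual results are listed
    before defaults — they override the routine instruction.
    """
    if ctx.drug is None:
        raise ValueError("query_dosage requires the drug (Dr)")
    store.entity(ctx.drug)
    reg = store.registry
    drug_dosage_rels = _relations_with_signature(reg, "Drug", "DrugUse")
    from_drug = {
        t.object for t in store.triples if t.rid in drug_dosage_rels and t.subject == ctx.drug
    }

    results: list[DosageResult] = []
    seen: set[tuple[str, str]] = set()

    def factor(eid: str | None, semantic_type: str, kind: str) -> None:
        if eid is None:
            return
        ent = store.entity(eid)
        if ent.semantic_type != semantic_type:
            raise ValueError(
                f"context entity {eid!r} has type {ent.semantic_type!r}, expected {semantic_type!r}"
            )
        ctx_rels = _relations_with_signature(reg, semantic_type, "DrugUse")
        hits = {
            t.object
            for t in store.triples
            if t.rid in ctx_rels and t.subject == eid and t.object in from_drug
        }
        for du in sorted(hits):
            if (du, kind) not in seen:
                seen.add((du, kind))
                results.append(DosageResult(store.entity(du), kind=kind, context_eid=eid))

    factor(ctx.adverse_reaction, "AdverseReaction", "adverse_reaction")
    factor(ctx.population, "Population", "population")
    factor(ctx.gene, "Gene", "gene")

    default_rels = {
        r.rid
        for r in reg.relations.values()
        if r.relationship in ("have_dosage", "has_routine_dosage", "has_dose_form")
    }
    for t in sorted(store.triples):
        if t.subject == ctx.drug and t.rid in default_rels:
            if (t.object, "default") not in seen:
                seen.add((t.object, "default"))
                results.append(DosageResult(store.entity(t.object), kind="default"))
    return results


# -- export / import -------------------------------------------------------

_TSV_HEADER = "subject\trelationship\tobject\tdoc_id\tsection"


def _sorted_triples(store: TripleStore) -> list[Triple]:
    return sorted(store.triples)


def export(store: TripleStore, format: str, base_iri: str = DEFAULT_BASE_IRI) -> str:
    """Serialize the store as N-Triples, TSV, or grouped JSON.

    IRIs are minted deterministically from eids/rids under ``base_iri``;
    TSV round-trips through :func:`import_tsv` byte-identically; JSON
    groups triples by relationship group (domain–range pair).
    """
    if format == "tsv":
        lines = [_TSV_HEADER]
        for t in _sorted_triples(store):
            doc_id, section = t.provenance or ("", "")
            rel = store.registry.relation(t.rid)
            lines.append(f"{t.subject}\t{rel.relationship}\t{t.object}\t{doc_id}\t{section}")
        return "\n".join(lines) + "\n"
    if format == "ntriples":
        g = rdflib.Graph()
        for t in _sorted_triples(store):
            rel = store.registry.relation(t.rid)
            g.add(
                (
                    rdflib.URIRef(base_iri + "entity/" + t.subject),
                    rdflib.URIRef(base_iri + "relation/" + rel.relationship),
                    rdflib.URIRef(base_iri + "entity/" + t.object),
                )
            )
        lines = [ln for ln in g.serialize(format="nt").splitlines() if ln.strip()]
        return "\n".join(sorted(lines)) + ("\n" if lines else "")
    if format == "json":
        groups: dict[str, list[dict]] = {}
        for t in _sorted_triples(store):
            rel = store.registry.relation(t.rid)
            key = f"{rel.domain}-{rel.range}"
            groups.setdefault(key, []).append(
                {
                    "subject": t.subject,
                    "subject_term": store.entity(t.subject).term,
                    "relationship": rel.relationship,
                    "object": t.object,
                    "object_term": store.entity(t.object).term,
                    "provenance": list(t.provenance) if t.provenance else None,
                }
            )
        payload = {
            "groups": [
                {"group": key, "n_triples": len(items), "triples": items}
                for key, items in sorted(groups.items())
            ],
            "total": len(store.triples),
        }
        return json.dumps(payload, indent=2, sort_keys=False) + "\n"
    raise ValueError(f"unknown export format {format!r}; expected ntriples, tsv or json")


def import_tsv(
    text: str,
    registry: KnowledgeModelRegistry,
    entities: Iterable[Entity],
) -> TripleStore:
    """Rebuild a store from TSV export plus the entity inventory."""
    store = TripleStore(registry=registry)
    for e in entities:
        store.add_entity(e)
    lines = text.splitlines()
    if lines and lines[0] == _TSV_HEADER:
        lines = lines[1:]
    for lineno, line in enumerate(lines, start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"TSV line {lineno}: expected 5 fields, got {len(parts)}")
        subject, relationship, obj, doc_id, section = parts
        rel = registry.relation_by_name(relationship)
        if rel is None:
            raise ValueError(f"TSV line {lineno}: unknown relationship {relationship!r}")
        provenance = (doc_id, section) if doc_id or section else None
        add_triple(store, Triple(subject=subject, rid=rel.rid, object=obj, provenance=provenance))
    return store
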