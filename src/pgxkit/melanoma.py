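"""The melanoma case study as a reproducible, synthetic triple store.

Melanoma driven by BRAF mutations (V600E/V600K) is the model's worked
example: seven drugs — binimetinib, cobimetinib, dabrafenib, encorafenib,
nivolumab, trametinib, and vemurafenib — of which dabrafenib, encorafenib
and vemurafenib target BRAF directly. The case-study store groups its
triples into nine relationship groups (drug–drug, drug–adverse reaction,
drug–dosage, adverse reaction–dosage, drug–disease, drug–gene,
drug–population, gene–mutation, gene–disease).

The curated source data set is not redistributed here; this module
reconstructs a synthetic store with the documented group sizes. The seven
drugs, their targets, and trametinib's dosage narrative (2 mg orally once
daily by default; permanent discontinuation on fever or interstitial lung
disease) are encoded faithfully; the bulk of the drug–drug interaction
group is filled with synthetic partner drugs, clearly labelled as such.
"""

from __future__ import annotations

from pgxkit.kgraph import Triple, TripleStore, add_triple
from pgxkit.schema import Entity, KnowledgeModelRegistry, build_default_registry

__all__ = ["MELANOMA_DRUGS", "MELANOMA_GROUP_SIZES", "build_melanoma_store"]

#: The seven drugs of the case study.
MELANOMA_DRUGS = (
    "binimetinib",
    "cobimetinib",
    "dabrafenib",
    "encorafenib",
    "nivolumab",
    "trametinib",
    "vemurafenib",
)

#: Target gene per drug (BRAF inhibitors, MEK inhibitors, PD-1 blockade).
_DRUG_TARGETS = {
    "binimetinib": "MAP2K1",
    "cobimetinib": "MAP2K1",
    "trametinib": "MAP2K1",
    "dabrafenib": "BRAF",
    "encorafenib": "BRAF",
    "vemurafenib": "BRAF",
    "nivolumab": "PDCD1",
}

#: Documented group sizes, keyed by (subject type, object type); total 4846.
MELANOMA_GROUP_SIZES = {
    ("Drug", "Drug"): 4713,
    ("Drug", "AdverseReaction"): 41,
    ("Drug", "DrugUse"): 30,
    ("AdverseReaction", "DrugUse"): 24,
    ("Drug", "Disease"): 22,
    ("Drug", "Gene"): 7,
    ("Drug", "Population"): 4,
    ("Gene", "Mutation"): 2,
    ("Gene", "Disease"): 3,
}

_ADVERSE_REACTIONS = (
    "fever",
    "interstitial lung disease",
    "rash",
    "nausea",
    "diarrhea",
    "fatigue",
)

_POPULATIONS = ("pediatric", "geriatric", "pregnancy", "lactation")

_DISEASES = (
    ("melanoma", "unresectable or metastatic melanoma"),
    ("metastatic-melanoma", "metastatic melanoma"),
    ("thyroid-cancer", "metastatic thyroid cancer"),
    ("nsclc", "non-small cell lung cancer"),
)


def build_melanoma_store(
    registry: KnowledgeModelRegistry | None = None,
) -> TripleStore:
    """Build the synthetic melanoma case-study store.

    Deterministic; the resulting store has exactly the nine documented
    group sizes (4846 triples in total).
    """
    reg = registry or build_default_registry()
    store = TripleStore(registry=reg)
    sizes = dict(MELANOMA_GROUP_SIZES)

    # -- entities ----------------------------------------------------------
    for name in MELANOMA_DRUGS:
        store.add_entity(
            Entity(
                eid=f"db:{name}",
                term=name,
                semantic_type="Drug",
                source="DrugBank",
                attributes={"DrugName": name, "DrugApprovalStatus": "approved"},
            )
        )
    # synthetic interaction partners fill out the drug-drug group
    n_pairs_needed = -(-sizes[("Drug", "Drug")] // 4)  # 4 drug-drug relations
    n_drugs = 7
    while n_drugs * (n_drugs - 1) < n_pairs_needed:
        n_drugs += 1
    partners = [f"interactant-{i:02d}" for i in range(n_drugs - 7)]
    for name in partners:
        store.add_entity(
            Entity(
                eid=f"syn:{name}",
                term=f"{name} (synthetic)",
                semantic_type="Drug",
                source="synthetic",
                attributes={"DrugName": name},
            )
        )
    drug_eids = [f"db:{n}" for n in MELANOMA_DRUGS] + [f"syn:{n}" for n in partners]

    for gene in ("BRAF", "MAP2K1", "PDCD1", "NRAS"):
        store.add_entity(
            Entity(
                eid=f"syn:gene-{gene}",
                term=gene,
                semantic_type="Gene",
                source="corpus",
                attributes={"GeneName": gene},
            )
        )
    for variant in ("V600E", "V600K"):
        store.add_entity(
            Entity(
                eid=f"syn:mut-{variant}",
                term=f"BRAF {variant}",
                semantic_type="Mutation",
                source="corpus",
                attributes={"MutationName": variant},
            )
        )
    for slug, term in _DISEASES:
        store.add_entity(
            Entity(
                eid=f"syn:dis-{slug}",
                term=term,
                semantic_type="Disease",
                source="corpus",
                attributes={"DiseaseName": term},
            )
        )
    for adr in _ADVERSE_REACTIONS:
        store.add_entity(
            Entity(
                eid=f"syn:adr-{adr.replace(' ', '-')}",
                term=adr,
                semantic_type="AdverseReaction",
                source="corpus",
            )
        )
    for pop in _POPULATIONS:
        store.add_entity(
            Entity(
                eid=f"syn:pop-{pop}",
                term=pop,
                semantic_type="Population",
                source="corpus",
                attributes={"ApplicablePopulation": pop},
            )
        )

    # DrugUse entities: routine dosage, dose form, frequency, adjusted dosage
    def add_druguse(eid: str, term: str, **attrs: str) -> str:
        store.add_entity(
            Entity(eid=eid, term=term, semantic_type="DrugUse", source="RxNorm", attributes=attrs)
        )
        return eid

    routine = {}
    form = {}
    freq = {}
    adjusted = {}
    for name in MELANOMA_DRUGS:
        if name == "trametinib":
            routine[name] = add_druguse(
                f"rx:{name}-routine", "2 mg orally once daily",
                DailyDose="2 mg", Frequency="once daily",
            )
        else:
            routine[name] = add_druguse(
                f"rx:{name}-routine", f"{name} routine dosage (synthetic)", DailyDose="n/a"
            )
        form[name] = add_druguse(f"rx:{name}-form", "tablet", DoseForm="tablet")
        freq[name] = add_druguse(f"rx:{name}-freq", "once daily", Frequency="once daily")
        if name == "trametinib":
            adjusted[name] = add_druguse(
                f"rx:{name}-adjusted", "stop permanently",
                TakeWithMeal="no",
            )
        else:
            adjusted[name] = add_druguse(
                f"rx:{name}-adjusted", f"{name} adjusted dosage (synthetic)"
            )
    tram_meal = add_druguse(
        "rx:trametinib-meal", "take 1-2 hours before meals", TakeTimeFor="1-2 hours before meals"
    )
    tram_liver = add_druguse("rx:trametinib-liver", "once a day", Frequency="once a day")
    adjusted_dus = [adjusted["trametinib"], tram_meal, tram_liver] + [
        adjusted[n] for n in MELANOMA_DRUGS if n != "trametinib"
    ]

    # -- triples, group by group ------------------------------------------
    def rel(name: str) -> str:
        return reg.relation_by_name(name).rid

    def emit(n: int, triples: list[Triple]) -> None:
        for t in triples[:n]:
            add_triple(store, t)
        if len(triples) < n:
            raise ValueError(f"cannot realize group of size {n}: only {len(triples)} available")

    # drug-gene (7): each drug targets its kinase / receptor gene
    emit(
        sizes[("Drug", "Gene")],
        [
            Triple(f"db:{d}", rel("targets"), f"syn:gene-{g}")
            for d, g in sorted(_DRUG_TARGETS.items())
        ],
    )
    # gene-mutation (2)
    emit(
        sizes[("Gene", "Mutation")],
        [
            Triple("syn:gene-BRAF", rel("have_mutation"), "syn:mut-V600E"),
            Triple("syn:gene-BRAF", rel("have_mutation"), "syn:mut-V600K"),
        ],
    )
    # gene-disease (3)
    emit(
        sizes[("Gene", "Disease")],
        [
            Triple("syn:gene-BRAF", rel("causes"), "syn:dis-melanoma"),
            Triple("syn:gene-BRAF", rel("causes"), "syn:dis-metastatic-melanoma"),
            Triple("syn:gene-NRAS", rel("causes"), "syn:dis-melanoma"),
        ],
    )
    # drug-disease (22): every drug treats melanoma, plus further indications
    ddis = [Triple(f"db:{d}", rel("treats"), "syn:dis-melanoma") for d in MELANOMA_DRUGS]
    for slug, _ in _DISEASES[1:]:
        ddis.extend(
            Triple(f"db:{d}", rel("treats"), f"syn:dis-{slug}") for d in MELANOMA_DRUGS
        )
    emit(sizes[("Drug", "Disease")], ddis)
    # drug-adverse reaction (41)
    dar = [
        Triple(f"db:{d}", rel("has_adverse_reaction"), f"syn:adr-{a.replace(' ', '-')}")
        for d in MELANOMA_DRUGS
        for a in _ADVERSE_REACTIONS
    ]
    emit(sizes[("Drug", "AdverseReaction")], dar)
    # drug-dosage (30): routine + dose form + frequency + adjusted
    ddos = []
    for name in MELANOMA_DRUGS:
        ddos.append(Triple(f"db:{name}", rel("have_dosage"), routine[name]))
    for name in MELANOMA_DRUGS:
        ddos.append(Triple(f"db:{name}", rel("has_dose_form"), form[name]))
    for name in MELANOMA_DRUGS:
        ddos.append(Triple(f"db:{name}", rel("has_frequency"), freq[name]))
    for name in MELANOMA_DRUGS:
        ddos.append(Triple(f"db:{name}", rel("has_adjusted_dosage"), adjusted[name]))
    ddos.append(Triple("db:trametinib", rel("has_adjusted_dosage"), tram_meal))
    ddos.append(Triple("db:trametinib", rel("has_adjusted_dosage"), tram_liver))
    emit(sizes[("Drug", "DrugUse")], ddos)
    # adverse reaction-dosage (24): fever and interstitial lung disease force
    # trametinib's permanent stop; the rest fill deterministically
    ardos = [
        Triple("syn:adr-fever", rel("adjusts_dosage"), adjusted["trametinib"]),
        Triple(
            "syn:adr-interstitial-lung-disease", rel("adjusts_dosage"), adjusted["trametinib"]
        ),
    ]
    for a in _ADVERSE_REACTIONS:
        a_eid = f"syn:adr-{a.replace(' ', '-')}"
        for du in adjusted_dus:
            t = Triple(a_eid, rel("adjusts_dosage"), du)
            if t.key() not in {x.key() for x in ardos}:
                ardos.append(t)
    emit(sizes[("AdverseReaction", "DrugUse")], ardos)
    # drug-population (4)
    emit(
        sizes[("Drug", "Population")],
        [Triple("db:trametinib", rel("used_in_population"), f"syn:pop-{p}") for p in _POPULATIONS],
    )
    # drug-drug (4713): interaction pairs across the four drug-drug relations
    dd = []
    need = sizes[("Drug", "Drug")]
    for rname in ("synergized_by", "antagonized_by", "coadministered_with", "avoid_concurrent_use_with"):
        r = rel(rname)
        for s in drug_eids:
            for o in drug_eids:
                if s != o:
                    dd.append(Triple(s, r, o))
        if len(dd) >= need:
            break
    emit(need, dd)
    return store
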