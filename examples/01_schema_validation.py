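"""Build the default knowledge-model registry and validate entities and triples.

The registry holds the six core semantic types with their attribute
inventories and 26 typed relations (14 first-level, 12 second-level).
Validation is structural: it returns a list of violations, empty when valid.
"""

from pgxkit.schema import Entity, build_default_registry, validate_entity, validate_triple

registry = build_default_registry()
first, second = registry.level_counts()
print(f"semantic types: {len(registry.core_semantic_types())} core")
print(f"relations: {len(registry.relations)} total = {first} first-level + {second} second-level")

trametinib = Entity(eid="db:trametinib", term="trametinib", semantic_type="Drug",
                    attributes={"DrugName": "trametinib"})
melanoma = Entity(eid="syn:melanoma", term="melanoma", semantic_type="Disease")
braf = Entity(eid="syn:BRAF", term="BRAF", semantic_type="Gene")

print("valid drug entity:", validate_entity(trametinib, registry) == [])
# (drug, treats, disease) respects the relation's domain/range typing:
print("drug treats disease:", validate_triple(trametinib, "treats", melanoma, registry))
# a gene cannot be the subject of `treats` (domain is Drug):
print("gene treats disease:", validate_triple(braf, "treats", melanoma, registry))
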