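"""Knowledge-model type system: semantic types, entities, relations, validation.

The model describes pharmacogenomics (PGx) knowledge as typed entities
(drugs, genes, diseases, adverse reactions, populations, drug-use
instructions) connected by a closed registry of directed relations. An
entity record is ``{EID*, TERM*, Source, SemanticType*}`` (starred fields
required); a relation record is ``{RID*, Relationship*, Domain*, Range*,
Definition, TreeNumber*}``. Relations live in a two-level taxonomy encoded
by dotted tree numbers ("R01" is first-level, "R01.01" second-level).

Validation is structural only: reports are lists of human-readable
violation messages, and an empty report means valid.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "SemanticTypeDef",
    "Entity",
    "RelationDef",
    "KnowledgeModelRegistry",
    "ValidationReport",
    "build_default_registry",
    "load_registry",
    "save_registry",
    "validate_entity",
    "validate_triple",
    "relation_level",
    "CORE_SEMANTIC_TYPES",
]

#: The six core semantic types of the knowledge model.
CORE_SEMANTIC_TYPES = (
    "Drug",
    "Gene",
    "Disease",
    "AdverseReaction",
    "Population",
    "DrugUse",
)

ValidationReport = list  # list[str]; empty report == valid


@dataclass(frozen=True)
class SemanticTypeDef:
    """A semantic type and its ordered attribute inventory.

    ``auxiliary`` marks extension types (e.g. Mutation) that supplement the
    six core types without being counted among them.
    """

    name: str
    attribute_names: tuple[str, ...] = ()
    auxiliary: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("semantic type name must be non-empty")
        if len(set(self.attribute_names)) != len(self.attribute_names):
            raise ValueError(
                f"duplicate attribute names in semantic type {self.name!r}"
            )


@dataclass(frozen=True)
class Entity:
    """A typed PGx entity: identifier, preferred term, provenance, type, attributes."""

    eid: str
    term: str
    semantic_type: str
    source: str = ""
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", dict(self.attributes))


@dataclass(frozen=True)
class RelationDef:
    """A relation-registry record with domain/range typing and a tree number."""

    rid: str
    relationship: str
    domain: str
    range: str
    tree_number: str
    definition: str = ""
    reconstructed: bool = False
    inverse_of: str | None = None

    @property
    def level(self) -> int:
        return relation_level(self.tree_number)


def relation_level(tree_number: str) -> int:
    """Return the taxonomy level (1 or 2) encoded by a dotted tree number.

    A separator-free code ("R03") is first-level; one dot ("R03.01") is
    second-level. Anything else is malformed — the taxonomy has exactly
    two levels.
    """
    if not tree_number:
        raise ValueError("tree number must be non-empty")
    parts = tree_number.split(".")
    if any(not p.isalnum() for p in parts):
        raise ValueError(f"malformed tree number {tree_number!r}")
    if len(parts) > 2:
        raise ValueError(
            f"tree number {tree_number!r} has {len(parts)} levels; only two are defined"
        )
    return len(parts)


@dataclass
class KnowledgeModelRegistry:
    """The knowledge model itself: semantic types plus the relation registry."""

    semantic_types: dict[str, SemanticTypeDef] = field(default_factory=dict)
    relations: dict[str, RelationDef] = field(default_factory=dict)
    version: int = 1

    # -- registration ------------------------------------------------------

    def register_semantic_type(self, st: SemanticTypeDef) -> None:
        if st.name in self.semantic_types:
            raise ValueError(f"semantic type {st.name!r} already registered")
        self.semantic_types[st.name] = st

    def register_relation(self, rel: RelationDef) -> None:
        for label, value in (
            ("rid", rel.rid),
            ("relationship", rel.relationship),
            ("domain", rel.domain),
            ("range", rel.range),
            ("tree_number", rel.tree_number),
        ):
            if not value:
                raise ValueError(f"relation {rel.rid!r}: {label} must be non-empty")
        if rel.rid in self.relations:
            raise ValueError(f"relation {rel.rid!r} already registered")
        for st_name in (rel.domain, rel.range):
            if st_name not in self.semantic_types:
                raise ValueError(
                    f"relation {rel.rid!r}: {st_name!r} is not a registered semantic type"
                )
        relation_level(rel.tree_number)  # validates the code grammar
        self.relations[rel.rid] = rel

    # -- lookup ------------------------------------------------------------

    def relation(self, rid: str) -> RelationDef | None:
        return self.relations.get(rid)

    def relation_by_name(self, relationship: str) -> RelationDef | None:
        for rel in self.relations.values():
            if rel.relationship == relationship:
                return rel
        return None

    def core_semantic_types(self) -> list[SemanticTypeDef]:
        return [st for st in self.semantic_types.values() if not st.auxiliary]

    def level_counts(self) -> tuple[int, int]:
        """(first-level count, second-level count) over all relations."""
        first = sum(1 for r in self.relations.values() if r.level == 1)
        second = sum(1 for r in self.relations.values() if r.level == 2)
        return first, second

    def check_inverse_pairs(self) -> ValidationReport:
        """Verify that declared inverse relations mirror each other's typing."""
        report: list[str] = []
        for rel in self.relations.values():
            if rel.inverse_of is None:
                continue
            inv = self.relations.get(rel.inverse_of)
            if inv is None:
                report.append(f"{rel.rid}: inverse {rel.inverse_of!r} not registered")
            elif (inv.domain, inv.range) != (rel.range, rel.domain):
                report.append(
                    f"{rel.rid}/{inv.rid}: inverse pair does not mirror domain/range"
                )
        return report


# -- config file I/O -------------------------------------------------------


def _registry_from_mapping(data: Mapping) -> KnowledgeModelRegistry:
    reg = KnowledgeModelRegistry(version=int(data.get("version", 1)))
    for st in data["semantic_types"]:
        reg.register_semantic_type(
            SemanticTypeDef(
                name=st["name"],
                attribute_names=tuple(st.get("attributes", ())),
                auxiliary=bool(st.get("auxiliary", False)),
            )
        )
    for rel in data.get("relations", ()):
        reg.register_relation(
            RelationDef(
                rid=rel["rid"],
                relationship=rel["relationship"],
                domain=rel["domain"],
                range=rel["range"],
                tree_number=rel["tree_number"],
                definition=rel.get("definition", ""),
                reconstructed=bool(rel.get("reconstructed", False)),
                inverse_of=rel.get("inverse_of"),
            )
        )
    return reg


def load_registry(text: str) -> KnowledgeModelRegistry:
    """Load a registry from its YAML config text."""
    return _registry_from_mapping(yaml.safe_load(text))


def save_registry(reg: KnowledgeModelRegistry) -> str:
    """Serialize a registry to YAML config text (round-trips with load_registry)."""
    data = {
        "version": reg.version,
        "semantic_types": [
            {
                "name": st.name,
                "attributes": list(st.attribute_names),
                **({"auxiliary": True} if st.auxiliary else {}),
            }
            for st in reg.semantic_types.values()
        ],
        "relations": [
            {
                "rid": r.rid,
                "relationship": r.relationship,
                "domain": r.domain,
                "range": r.range,
                "tree_number": r.tree_number,
                "definition": r.definition,
                **({"reconstructed": True} if r.reconstructed else {}),
                **({"inverse_of": r.inverse_of} if r.inverse_of else {}),
            }
            for r in reg.relations.values()
        ],
    }
    return yaml.safe_dump(data, sort_keys=False, allow_unicode=True)


def build_default_registry() -> KnowledgeModelRegistry:
    """Build the default registry shipped with the package.

    Six core semantic types (plus the auxiliary Mutation type) and 26
    relations — 14 first-level and 12 second-level. The core named
    relations are fixed; the rest complete the inventory from the melanoma
    relationship groups and are flagged ``reconstructed``.
    """
    text = (
        importlib.resources.files("pgxkit.data")
        .joinpath("registry.yaml")
        .read_text(encoding="utf-8")
    )
    return load_registry(text)


# -- validation ------------------------------------------------------------


def validate_entity(e: Entity, reg: KnowledgeModelRegistry) -> ValidationReport:
    """Check an entity against the registry; return violation messages."""
    report: list[str] = []
    if not e.eid:
        report.append("EID must be non-empty")
    if not e.term:
        report.append("TERM must be non-empty (required field)")
    st = reg.semantic_types.get(e.semantic_type)
    if st is None:
        report.append(f"semantic type {e.semantic_type!r} is not registered")
    else:
        for key in e.attributes:
            if key not in st.attribute_names:
                report.append(
                    f"attribute {key!r} is not defined for semantic type {st.name!r}"
                )
    return report


def validate_triple(
    subject: Entity,
    rid: str,
    obj: Entity,
    reg: KnowledgeModelRegistry,
) -> ValidationReport:
    """Check a (subject, relation, object) assertion against domain/range typing."""
    rel = reg.relations.get(rid)
    if rel is None:
        # also try by relationship name for convenience
        rel = reg.relation_by_name(rid)
    if rel is None:
        return [f"unregistered relation {rid!r}"]
    report: list[str] = []
    if subject.semantic_type != rel.domain:
        report.append(
            f"domain violation: relation {rel.relationship!r} expects subject type "
            f"{rel.domain!r}, got {subject.semantic_type!r}"
        )
    if obj.semantic_type != rel.range:
        report.append(
            f"range violation: relation {rel.relationship!r} expects object type "
            f"{rel.range!r}, got {obj.semantic_type!r}"
        )
    return report
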