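"""Readers for the three source dialects: SPL drug labels, DrugBank records, RxNorm RRF.

Each parser targets only the minimal field subset the knowledge model
consumes and ignores unknown elements by design, since the upstream
schemas evolve. Input must be UTF-8; anything else is rejected loudly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from lxml import etree

from pgxkit.corpus import SECTION_NAMES, Document
from pgxkit.schema import Entity, KnowledgeModelRegistry

logger = logging.getLogger(__name__)

__all__ = [
    "DrugRecord",
    "DoseFormRelation",
    "parse_spl",
    "parse_drugbank",
    "parse_rxnorm_rrf",
    "records_to_entities",
    "cas_checksum_ok",
]

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")

#: Dose-form relation names retained from RxNorm relationship files.
DOSE_FORM_RELATIONS = ("has_dose_form", "dose_form_of")


@dataclass
class DrugRecord:
    """Drug attributes extracted from a DrugBank-dialect record."""

    name: str
    description: str = ""
    chemical_formula: str = ""
    molecular_weight: float | None = None  # daltons
    approval_status: str = ""
    cas: str = ""
    unii: str = ""
    pharmacology_indication: str = ""
    cas_valid: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("drug record name must be non-empty")


@dataclass(frozen=True)
class DoseFormRelation:
    """A has_dose_form / dose_form_of link between two concept ids."""

    source_concept_id: str
    target_concept_id: str
    relation_name: str

    def __post_init__(self) -> None:
        if self.relation_name not in DOSE_FORM_RELATIONS:
            raise ValueError(f"unexpected relation {self.relation_name!r}")
        if not self.source_concept_id or not self.target_concept_id:
            raise ValueError("concept ids must be non-empty")


def cas_checksum_ok(cas: str) -> bool:
    """Validate a Chemical Abstracts Service number (pattern + check digit).

    The check digit is the weighted digit sum of the body taken mod 10,
    weights increasing right to left.
    """
    m = _CAS_RE.match(cas)
    if not m:
        return False
    digits = (m.group(1) + m.group(2))[::-1]
    total = sum((i + 1) * int(d) for i, d in enumerate(digits))
    return total % 10 == int(m.group(3))


def _norm_ws(text: str) -> str:
    return " ".join(text.split())


def _norm_title(title: str) -> str:
    return _norm_ws(title).casefold().rstrip(".")


_SECTION_BY_TITLE = {_norm_title(name): name for name in SECTION_NAMES}


def parse_spl(xml_text: str | bytes) -> Document:
    """Extract the document id and the five target sections from SPL XML.

    Sections are identified by normalized (case-insensitive) title match;
    missing target sections are omitted with a log entry. Section text is
    whitespace-normalized.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed SPL XML: {exc}") from exc
    doc_id = ""
    id_el = root.find(".//id")
    if id_el is not None:
        doc_id = id_el.get("root", "")
    sections: list[tuple[str, str]] = []
    found = set()
    for sec in root.iter("section"):
        title_el = sec.find("title")
        text_el = sec.find("text")
        if title_el is None:
            continue
        canonical = _SECTION_BY_TITLE.get(_norm_title(title_el.text or ""))
        if canonical is None:
            continue
        body = _norm_ws("".join(text_el.itertext())) if text_el is not None else ""
        sections.append((canonical, body))
        found.add(canonical)
    for name in SECTION_NAMES:
        if name not in found:
            logger.warning("SPL document %s: section %r missing", doc_id or "<no id>", name)
    return Document(doc_id=doc_id, sections=sections)


def parse_drugbank(xml_text: str | bytes) -> list[DrugRecord]:
    """Parse DrugBank-dialect XML into drug-attribute records.

    Absent fields are left empty; a malformed CAS number is flagged on the
    record (``cas_valid``) but the record is kept.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed DrugBank XML: {exc}") from exc

    def text_of(el: etree._Element, tag: str) -> str:
        child = el.find(tag)
        return _norm_ws(child.text or "") if child is not None and child.text else ""

    records: list[DrugRecord] = []
    for drug in root.iter("drug"):
        name = text_of(drug, "name")
        if not name:
            logger.warning("skipping drug record without a name")
            continue
        weight_text = text_of(drug, "molecular-weight") or text_of(drug, "average-mass")
        weight = None
        if weight_text:
            try:
                weight = float(weight_text)
            except ValueError:
                logger.warning("drug %s: unparseable molecular weight %r", name, weight_text)
        cas = text_of(drug, "cas-number")
        record = DrugRecord(
            name=name,
            description=text_of(drug, "description"),
            chemical_formula=text_of(drug, "chemical-formula"),
            molecular_weight=weight,
            approval_status=text_of(drug, "groups/group") or text_of(drug, "approval-status"),
            cas=cas,
            unii=text_of(drug, "unii"),
            pharmacology_indication=text_of(drug, "indication"),
            cas_valid=(not cas) or cas_checksum_ok(cas),
        )
        if not record.cas_valid:
            logger.warning("drug %s: CAS number %r fails checksum", name, cas)
        records.append(record)
    return records


# RRF column positions (pipe-delimited). RXNCONSO: concept id, language, ...,
# term type at 12, string at 14 (18 columns). RXNREL: concept ids at 0 and 4,
# relation attribute at 7 (16 columns).
_CONSO_COLS = 18
_REL_COLS = 16


def parse_rxnorm_rrf(
    conso_lines: Iterable[str],
    rel_lines: Iterable[str],
) -> tuple[dict[str, dict[str, str]], list[DoseFormRelation]]:
    """Parse RXNCONSO/RXNREL pipe-delimited lines.

    Returns concepts keyed by concept id (name, term type) and the
    relations filtered to the dose-form pair. A malformed line is reported
    with its line number and skipped; parsing continues.
    """
    concepts: dict[str, dict[str, str]] = {}
    for lineno, line in enumerate(conso_lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("|")
        if len(parts) < _CONSO_COLS:
            logger.error("RXNCONSO line %d: expected %d columns, got %d", lineno, _CONSO_COLS, len(parts))
            continue
        rxcui, tty, name = parts[0], parts[12], parts[14]
        if rxcui and rxcui not in concepts:
            concepts[rxcui] = {"name": name, "tty": tty}
    relations: list[DoseFormRelation] = []
    for lineno, line in enumerate(rel_lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("|")
        if len(parts) < _REL_COLS:
            logger.error("RXNREL line %d: expected %d columns, got %d", lineno, _REL_COLS, len(parts))
            continue
        cui1, cui2, rela = parts[0], parts[4], parts[7]
        if rela in DOSE_FORM_RELATIONS:
            try:
                relations.append(
                    DoseFormRelation(source_concept_id=cui1, target_concept_id=cui2, relation_name=rela)
                )
            except ValueError as exc:
                logger.error("RXNREL line %d: %s", lineno, exc)
    return concepts, relations


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", name.casefold()).strip("-")


def records_to_entities(
    records: Sequence[DrugRecord],
    registry: KnowledgeModelRegistry,
    dose_form_concepts: dict[str, dict[str, str]] | None = None,
) -> list[Entity]:
    """Convert parsed records to schema-valid entities.

    Drug records become Drug entities (source "DrugBank") carrying the
    knowledge-model attribute set; dose-form concepts become DrugUse
    entities (source "RxNorm").
    """
    entities: list[Entity] = []
    for rec in records:
        attrs = {"DrugName": rec.name}
        if rec.description:
            attrs["Description"] = rec.description
        if rec.chemical_formula:
            attrs["ChemicalFormula"] = rec.chemical_formula
        if rec.molecular_weight is not None:
            attrs["MolecularWeight"] = repr(rec.molecular_weight)
        if rec.approval_status:
            attrs["DrugApprovalStatus"] = rec.approval_status
        if rec.cas:
            attrs["CAS"] = rec.cas
        if rec.unii:
            attrs["UNII"] = rec.unii
        if rec.pharmacology_indication:
            attrs["PharmacologyIndication"] = rec.pharmacology_indication
        entities.append(
            Entity(
                eid=f"db:{_slug(rec.name)}",
                term=rec.name,
                semantic_type="Drug",
                source="DrugBank",
                attributes=attrs,
            )
        )
    for rxcui, concept in (dose_form_concepts or {}).items():
        entities.append(
            Entity(
                eid=f"rx:{rxcui}",
                term=concept["name"],
                semantic_type="DrugUse",
                source="RxNorm",
                attributes={"DoseForm": concept["name"]} if concept.get("tty") == "DF" else {},
            )
        )
    return entities
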