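"""Seeded generator of synthetic drug labels with gold entities and relations.

Generated documents mimic the structure the pipeline assumes: the five
target label sections, sentences drawn from section-specific templates
whose slots are filled from per-label vocabularies, relation expressions
embedded verbatim from the documented synonym inventory, and distractor
sentences carrying no entities. Every emitted entity mention and relation
instance is recorded in a gold ledger with exact character offsets, so
corpus statistics, NER training/evaluation and normalization can all be
cross-checked against the generator's own bookkeeping.

The default vocabulary is seeded with the melanoma case-study cast
(binimetinib … vemurafenib, BRAF V600E/V600K, "2 mg orally once daily");
filler terms beyond that cast are invented and synthetic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from lxml import etree

from pgxkit.corpus import ENTITY_LABELS, SECTION_NAMES, Document, SpanAnnotation

__all__ = [
    "GeneratorConfig",
    "GoldLedger",
    "RelationInstance",
    "DEFAULT_VOCAB",
    "generate_corpus",
    "emit_spl",
    "corrupt",
]

#: Default per-label vocabularies. The first seven drugs, the BRAF variants
#: and the trametinib dosage are the melanoma case-study cast; remaining
#: fillers are invented synthetic terms.
DEFAULT_VOCAB: dict[str, tuple[str, ...]] = {
    "Drug": (
        "binimetinib",
        "cobimetinib",
        "dabrafenib",
        "encorafenib",
        "nivolumab",
        "trametinib",
        "vemurafenib",
        "lumetinib",
        "vorextinib",
    ),
    "Gene": ("BRAF V600E", "BRAF V600K", "NRAS Q61K", "KIT D816V", "BRAF"),
    "Disease": ("melanoma", "metastatic melanoma", "thyroid cancer", "colorectal cancer"),
    "Body_Part": ("skin", "liver", "lung", "lymph nodes", "brain"),
    "Daily_Dose": ("2 mg", "40 mg", "150 mg", "100 mg", "0.5 mg"),
    "Dose_Form": ("tablet", "capsule", "oral solution", "injection"),
    "Frequency": ("once daily", "twice daily", "once a day", "every 12 hours"),
    "Adverse_Reaction": (
        "fever",
        "rash",
        "nausea",
        "interstitial lung disease",
        "diarrhea",
        "fatigue",
        "hemorrhage",
    ),
}

#: Entity-free sentences mixed in at the distractor rate.
DISTRACTOR_SENTENCES = (
    "Store at controlled room temperature .",
    "See full prescribing information for details .",
    "Advise patients to read the approved patient labeling .",
    "Keep out of reach of children .",
    "Refer to the dosing tables above .",
)

# Template pieces: ("lit", text) literal words; ("ent", label) vocabulary
# slot; ("rel", surface, normalized) relation expression embedded verbatim;
# ("relwild", head, tail, normalized) a wildcard expression — head words,
# then the entity slot that follows in the template, then the tail word.
_TEMPLATES: dict[str, list[list[tuple]]] = {
    "Indications and Usage": [
        [("ent", "Drug"), ("lit", "is indicated"), ("rel", "for the treatment of", "treats"),
         ("ent", "Disease"), ("lit", "in patients"),
         ("relwild", "with", "mutation", "have_mutation"), ("ent", "Gene")],
        [("ent", "Drug"), ("lit", "is indicated"), ("rel", "in combination with", "synergized_by"),
         ("ent", "Drug"), ("rel", "for the treatment of", "treats"), ("ent", "Disease")],
        [("ent", "Drug"), ("lit", "is indicated"), ("rel", "as monotherapy of", "treats"),
         ("ent", "Disease")],
        [("ent", "Drug"), ("lit", "is indicated"), ("rel", "for the prevention of", "treats"),
         ("ent", "Disease"), ("lit", "of the"), ("ent", "Body_Part")],
        [("ent", "Drug"), ("lit", "is indicated"),
         ("rel", "for relief of the signs and symptoms", "treats"), ("lit", "of"),
         ("ent", "Disease")],
    ],
    "Dosage and Administration": [
        [("lit", "The"), ("rel", "recommended dosage", "have_dosage"), ("lit", "is"),
         ("ent", "Daily_Dose"), ("lit", "orally"), ("ent", "Frequency")],
        [("lit", "Administer"), ("ent", "Drug"), ("ent", "Daily_Dose"), ("lit", "as a"),
         ("ent", "Dose_Form"), ("ent", "Frequency")],
        [("lit", "Do not exceed"), ("rel", "total daily doses", "have_dosage"), ("lit", "of"),
         ("ent", "Daily_Dose")],
    ],
    "Use in Specific Populations": [
        [("lit", "Safety in pediatric patients with"), ("ent", "Disease"),
         ("lit", "has not been established")],
        [("lit", "Patients must"), ("rel", "be homozygous for", "have_mutation"),
         ("ent", "Gene"), ("lit", "before treatment with"), ("ent", "Drug")],
    ],
    "Warnings and Precautions": [
        [("rel", "avoid concomitant use of", "antagonized_by"), ("ent", "Drug"),
         ("lit", "and"), ("ent", "Drug")],
        [("rel", "avoid concurrent administration of", "antagonized_by"), ("ent", "Drug"),
         ("lit", "with strong inhibitors")],
        [("lit", "Interrupt"), ("ent", "Drug"), ("lit", "in patients with"),
         ("ent", "Adverse_Reaction")],
        [("lit", "Confirm"), ("relwild", "the presence of", "mutation", "have_mutation"),
         ("ent", "Gene"), ("lit", "before initiating treatment")],
        [("ent", "Drug"), ("lit", "may be"), ("rel", "coadministered with", "synergized_by"),
         ("ent", "Drug")],
    ],
    "Adverse Reactions": [
        [("lit", "The most common adverse reactions were"), ("ent", "Adverse_Reaction"),
         ("lit", "and"), ("ent", "Adverse_Reaction")],
        [("ent", "Adverse_Reaction"), ("lit", "occurred in patients receiving"),
         ("ent", "Drug")],
        [("lit", "Monitor for"), ("ent", "Adverse_Reaction"), ("lit", "involving the"),
         ("ent", "Body_Part")],
    ],
}


@dataclass
class GeneratorConfig:
    """Synthetic corpus parameters.

    Defaults emulate the study conditions: 190 documents (the annotated
    drug-label corpus size), the full label-section inventory, and a
    moderate distractor rate so sections are not wall-to-wall entities.
    """

    n_documents: int = 190
    seed: int = 0
    vocab: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_VOCAB))
    templates: dict[str, list[list[tuple]]] = field(default_factory=lambda: {k: list(v) for k, v in _TEMPLATES.items()})
    noise: float = 0.2  # distractor-sentence rate
    max_sentences_per_section: int = 3

    def __post_init__(self) -> None:
        if self.n_documents < 0:
            raise ValueError("n_documents must be non-negative")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError("noise rate must lie in [0, 1]")
        for label in ENTITY_LABELS:
            if not self.vocab.get(label):
                raise ValueError(f"vocabulary for label {label!r} must be non-empty")


@dataclass(frozen=True)
class RelationInstance:
    """A relation expression emitted into a section, with its argument spans."""

    section_index: int
    normalized: str
    start: int  # character span of the expression (incl. wildcard fill)
    end: int
    surface: str
    args: tuple[SpanAnnotation, ...] = ()


@dataclass
class GoldLedger:
    """The generator's own record of what it emitted."""

    spans: dict[str, list[SpanAnnotation]] = field(default_factory=dict)
    relations: dict[str, list[RelationInstance]] = field(default_factory=dict)
    emission_counts: dict[str, int] = field(default_factory=lambda: {l: 0 for l in ENTITY_LABELS})


class _SectionBuilder:
    def __init__(self, section_index: int, annotator: str):
        self.section_index = section_index
        self.annotator = annotator
        self.words: list[str] = []
        self.pos = 0
        self.spans: list[SpanAnnotation] = []
        self.relations: list[RelationInstance] = []

    def add_words(self, text: str) -> tuple[int, int]:
        """Append space-separated words; return their character span."""
        words = text.split()
        if not words:
            return self.pos, self.pos
        if self.words:
            self.pos += 1  # joining space
        start = self.pos
        for k, word in enumerate(words):
            if k > 0:
                self.pos += 1
            self.words.append(word)
            self.pos += len(word)
        return start, self.pos

    def text(self) -> str:
        return " ".join(self.words)


def _realize_sentence(
    builder: _SectionBuilder, template: list[tuple], rng: random.Random, vocab: dict
) -> None:
    pending_rel: tuple[str, str, int] | None = None  # (tail words, normalized, start)
    sentence_spans: list[SpanAnnotation] = []
    sentence_rels: list[tuple[str, int, int]] = []  # (normalized, start, end)
    for piece in template:
        kind = piece[0]
        if kind == "lit":
            builder.add_words(piece[1])
        elif kind == "rel":
            start, end = builder.add_words(piece[1])
            sentence_rels.append((piece[2], start, end))
        elif kind == "relwild":
            head, tail, normalized = piece[1], piece[2], piece[3]
            start, _ = builder.add_words(head)
            pending_rel = (tail, normalized, start)
        elif kind == "ent":
            label = piece[1]
            term = rng.choice(vocab[label])
            start, end = builder.add_words(term)
            span = SpanAnnotation(builder.section_index, start, end, label, builder.annotator)
            builder.spans.append(span)
            sentence_spans.append(span)
            if pending_rel is not None:
                tail, normalized, rel_start = pending_rel
                _, rel_end = builder.add_words(tail)
                sentence_rels.append((normalized, rel_start, rel_end))
                pending_rel = None
        else:  # pragma: no cover - template author error
            raise ValueError(f"unknown template piece {piece!r}")
    builder.add_words(".")
    text = builder.text()
    for normalized, start, end in sentence_rels:
        builder.relations.append(
            RelationInstance(
                section_index=builder.section_index,
                normalized=normalized,
                start=start,
                end=end,
                surface=text[start:end],
                args=tuple(sentence_spans),
            )
        )


def generate_corpus(cfg: GeneratorConfig) -> tuple[list[Document], GoldLedger]:
    """Generate a seeded synthetic corpus with its gold ledger.

    Deterministic in the seed; every document carries the five label
    sections; ledger spans slice out of the generated text exactly.
    """
    rng = random.Random(cfg.seed)
    docs: list[Document] = []
    ledger = GoldLedger()
    for d in range(cfg.n_documents):
        doc_id = f"synth-{d:04d}"
        sections: list[tuple[str, str]] = []
        doc_spans: list[SpanAnnotation] = []
        doc_rels: list[RelationInstance] = []
        for si, name in enumerate(SECTION_NAMES):
            builder = _SectionBuilder(section_index=si, annotator="gold")
            n_sent = rng.randint(1, cfg.max_sentences_per_section)
            for _ in range(n_sent):
                if rng.random() < cfg.noise:
                    builder.add_words(rng.choice(DISTRACTOR_SENTENCES))
                else:
                    template = rng.choice(cfg.templates[name])
                    _realize_sentence(builder, template, rng, cfg.vocab)
            sections.append((name, builder.text()))
            doc_spans.extend(builder.spans)
            doc_rels.extend(builder.relations)
        docs.append(Document(doc_id=doc_id, sections=sections))
        ledger.spans[doc_id] = doc_spans
        ledger.relations[doc_id] = doc_rels
        for s in doc_spans:
            ledger.emission_counts[s.label] += 1
    return docs, ledger


def emit_spl(doc: Document) -> str:
    """Serialize a document to the SPL XML dialect the ingest reader accepts."""
    root = etree.Element("document")
    etree.SubElement(root, "id", root=doc.doc_id)
    body = etree.SubElement(root, "structuredBody")
    for name, text in doc.sections:
        comp = etree.SubElement(body, "component")
        sec = etree.SubElement(comp, "section")
        title = etree.SubElement(sec, "title")
        title.text = name
        text_el = etree.SubElement(sec, "text")
        text_el.text = text
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def corrupt(
    doc: Document,
    spans: Sequence[SpanAnnotation],
    rate: float,
    seed: int,
    annotator: str = "B",
    ops: tuple[str, ...] = ("drop", "shift", "relabel"),
) -> tuple[list[SpanAnnotation], float]:
    """Deterministically perturb a fraction of spans; return the expected F.

    Edits are drawn from ``ops`` (drop / shift-by-one / relabel) per span. The
    expected exact-match agreement against the original set is computed
    from the edit ledger: every edit destroys one exact match, drops also
    shrink the perturbed set.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    rng = random.Random(seed)
    n = len(spans)
    n_edit = round(rate * n)
    to_edit = set(rng.sample(range(n), n_edit)) if n_edit else set()
    original_keys = {s.key() for s in spans}
    perturbed: list[SpanAnnotation] = []
    n_matches = n - n_edit
    for i, s in enumerate(spans):
        if i not in to_edit:
            perturbed.append(SpanAnnotation(s.section_index, s.start, s.end, s.label, annotator))
            continue
        op = rng.choice(ops)
        if op == "shift":
            sec_len = len(doc.section_text(s.section_index))
            if s.end + 1 <= sec_len:
                cand = SpanAnnotation(s.section_index, s.start + 1, s.end + 1, s.label, annotator)
            elif s.start >= 1:
                cand = SpanAnnotation(s.section_index, s.start - 1, s.end - 1, s.label, annotator)
            else:
                cand = None
            if cand is not None and cand.key() not in original_keys:
                perturbed.append(cand)
            # otherwise fall through to a drop
        elif op == "relabel":
            others = [l for l in ENTITY_LABELS if l != s.label]
            new_label = others[rng.randrange(len(others))]
            cand = SpanAnnotation(s.section_index, s.start, s.end, new_label, annotator)
            if cand.key() not in original_keys:
                perturbed.append(cand)
        # "drop": emit nothing
    denominator = n + len(perturbed)
    expected_f = 1.0 if denominator == 0 else 2.0 * n_matches / denominator
    return perturbed, expected_f
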