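"""Drug-label corpora: documents, span annotations, BIO tags, splits, statistics.

A drug label is modelled as an ordered list of named sections (the five the
annotation workflow targets: Indications and Usage, Dosage and
Administration, Use in Specific Populations, Warnings and Precautions,
Adverse Reactions). Annotations are character-offset spans *per section*
(0-based, half-open) carrying one of the eight entity labels and an
annotator id. BIO conversion, corpus statistics, deterministic train/test
splitting and exact-match inter-annotator agreement live here, together
with CoNLL and standoff file I/O.
"""

from __future__ import annotations

import logging
import math
import random
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "ENTITY_LABELS",
    "SECTION_NAMES",
    "Document",
    "SpanAnnotation",
    "TokenSequence",
    "CorpusStats",
    "AlignmentError",
    "tokenize",
    "spans_to_bio",
    "bio_to_spans",
    "split_corpus",
    "corpus_stats",
    "agreement_f",
    "read_conll",
    "write_conll",
    "read_standoff",
    "write_standoff",
]

#: The eight entity labels of the annotation scheme.
ENTITY_LABELS = (
    "Drug",
    "Gene",
    "Disease",
    "Body_Part",
    "Daily_Dose",
    "Dose_Form",
    "Frequency",
    "Adverse_Reaction",
)

#: The five drug-label sections the annotation workflow targets.
SECTION_NAMES = (
    "Indications and Usage",
    "Dosage and Administration",
    "Use in Specific Populations",
    "Warnings and Precautions",
    "Adverse Reactions",
)


class AlignmentError(ValueError):
    """A span does not align to token boundaries."""


@dataclass
class Document:
    """A sectioned drug-label document."""

    doc_id: str
    sections: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, _ in self.sections:
            if not name:
                raise ValueError(f"document {self.doc_id!r}: empty section name")

    def section_text(self, index: int) -> str:
        return self.sections[index][1]


@dataclass(frozen=True, order=True)
class SpanAnnotation:
    """A labelled character span inside one section of a document."""

    section_index: int
    start: int
    end: int
    label: str
    annotator: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span offsets ({self.start}, {self.end}); need 0 <= start < end"
            )

    def key(self) -> tuple[int, int, int, str]:
        """Identity for exact matching: (section, start, end, label)."""
        return (self.section_index, self.start, self.end, self.label)


@dataclass(frozen=True)
class TokenSequence:
    """Tokens with per-token (start, end) offsets into the source text."""

    tokens: tuple[str, ...]
    offsets: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


@dataclass
class CorpusStats:
    """Mention counts per label plus vocabulary statistics."""

    entity_counts: dict[str, int]
    unique_term_counts: dict[str, int]
    n_unique_unigrams: int
    n_unique_bigrams: int
    n_docs: int


_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def tokenize(text: str) -> TokenSequence:
    """Split text into word/punctuation tokens with exact source offsets.

    Words (``\\w+`` runs) and individual punctuation marks are separate
    tokens; whitespace is the only separator, so every non-whitespace
    character lands in exactly one token and each token equals its source
    slice.
    """
    tokens: list[str] = []
    offsets: list[tuple[int, int]] = []
    for m in _TOKEN_RE.finditer(text):
        tokens.append(m.group())
        offsets.append((m.start(), m.end()))
    return TokenSequence(tuple(tokens), tuple(offsets))


def spans_to_bio(seq: TokenSequence, spans: Iterable[SpanAnnotation]) -> list[str]:
    """Convert character spans over one section to per-token BIO tags.

    The first token of each span is tagged ``B-<label>``, later tokens
    ``I-<label>``, everything else ``O``. Spans must start and end exactly
    on token boundaries; a span that cuts a token raises
    :class:`AlignmentError` — annotation bugs must surface, not be snapped.
    """
    tags = ["O"] * len(seq)
    starts = {s: i for i, (s, _) in enumerate(seq.offsets)}
    ends = {e: i for i, (_, e) in enumerate(seq.offsets)}
    for span in sorted(spans, key=lambda s: (s.start, s.end)):
        first = starts.get(span.start)
        last = ends.get(span.end)
        if first is None or last is None or last < first:
            raise AlignmentError(
                f"span ({span.start}, {span.end}, {span.label}) does not align "
                f"to token boundaries"
            )
        for i in range(first, last + 1):
            if tags[i] != "O":
                raise AlignmentError(
                    f"span ({span.start}, {span.end}, {span.label}) overlaps an "
                    f"already-tagged token"
                )
            tags[i] = ("B-" if i == first else "I-") + span.label
    return tags


def bio_to_spans(
    seq: TokenSequence,
    tags: Sequence[str],
    section_index: int = 0,
    annotator: str = "",
) -> list[SpanAnnotation]:
    """Convert BIO tags back to character spans (inverse of spans_to_bio).

    Invalid openings (``I-`` after ``O`` or after a different label) are
    repaired to ``B-`` and logged, the conventional repair.
    """
    if len(tags) != len(seq):
        raise ValueError(f"{len(tags)} tags for {len(seq)} tokens")
    spans: list[SpanAnnotation] = []
    open_label: str | None = None
    open_start = 0
    open_end = 0

    def close() -> None:
        nonlocal open_label
        if open_label is not None:
            spans.append(
                SpanAnnotation(section_index, open_start, open_end, open_label, annotator)
            )
            open_label = None

    for i, tag in enumerate(tags):
        tok_start, tok_end = seq.offsets[i]
        if tag == "O":
            close()
            continue
        prefix, _, label = tag.partition("-")
        if prefix not in ("B", "I") or not label:
            raise ValueError(f"invalid tag {tag!r} at position {i}")
        if prefix == "I" and open_label == label:
            open_end = tok_end
            continue
        if prefix == "I":
            logger.debug("repairing invalid I-%s opening at token %d to B-%s", label, i, label)
        close()
        open_label = label
        open_start, open_end = tok_start, tok_end
    close()
    return spans


def split_corpus(
    docs: Sequence[Document], train_fraction: float, seed: int
) -> tuple[list[Document], list[Document]]:
    """Randomly partition documents into train and test sets.

    The train side gets ``round-half-up(train_fraction * n)`` documents
    (190 documents at 0.9 split exactly 171/19); assignment is a
    deterministic function of the seed.
    """
    if not docs:
        raise ValueError("cannot split an empty corpus")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be strictly between 0 and 1")
    n_train = int(math.floor(train_fraction * len(docs) + 0.5))
    order = list(range(len(docs)))
    random.Random(seed).shuffle(order)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    return [docs[i] for i in train_idx], [docs[i] for i in test_idx]


def corpus_stats(
    docs: Sequence[Document],
    annotations: Sequence[Sequence[SpanAnnotation]] | None = None,
) -> CorpusStats:
    """Tally entity mentions per label and case-folded n-gram vocabularies.

    ``entity_counts`` counts mentions; ``unique_term_counts`` counts
    distinct case-folded surface strings per label (both readings of
    "number of entities" are reported).
    """
    entity_counts: Counter[str] = Counter({label: 0 for label in ENTITY_LABELS})
    unique_terms: dict[str, set[str]] = {label: set() for label in ENTITY_LABELS}
    unigrams: set[str] = set()
    bigrams: set[tuple[str, str]] = set()
    if annotations is None:
        annotations = [[] for _ in docs]
    for doc, spans in zip(docs, annotations):
        for _, text in doc.sections:
            toks = [t.casefold() for t in tokenize(text).tokens]
            unigrams.update(toks)
            bigrams.update(zip(toks, toks[1:]))
        for span in spans:
            entity_counts[span.label] += 1
            surface = doc.section_text(span.section_index)[span.start : span.end]
            unique_terms.setdefault(span.label, set()).add(surface.casefold())
    return CorpusStats(
        entity_counts=dict(entity_counts),
        unique_term_counts={k: len(v) for k, v in unique_terms.items()},
        n_unique_unigrams=len(unigrams),
        n_unique_bigrams=len(bigrams),
        n_docs=len(docs),
    )


def agreement_f(
    a: Iterable[SpanAnnotation],
    b: Iterable[SpanAnnotation],
) -> float:
    """Exact-match F score between two annotators' span sets.

    A match requires identical (section, start, end, label);
    ``F = 2·|matches| / (|a| + |b|)``, symmetric in the two sets. Two empty
    sets agree perfectly (F = 1.0, logged).
    """
    keys_a = Counter(s.key() for s in a)
    keys_b = Counter(s.key() for s in b)
    n_a, n_b = sum(keys_a.values()), sum(keys_b.values())
    if n_a == 0 and n_b == 0:
        logger.info("agreement_f: both annotation sets empty; F defined as 1.0")
        return 1.0
    matches = sum((keys_a & keys_b).values())
    return 2.0 * matches / (n_a + n_b)


# -- CoNLL-style file I/O ---------------------------------------------------


def write_conll(docs_tokens: Iterable[tuple[str, list[tuple[TokenSequence, list[str]]]]]) -> str:
    """Serialize tokenized, BIO-tagged documents to CoNLL text.

    One ``token<TAB>tag`` pair per line, blank line between sentences,
    ``-DOCSTART- <doc_id>`` delimiting documents.
    """
    lines: list[str] = []
    for doc_id, sentences in docs_tokens:
        lines.append(f"-DOCSTART- {doc_id}")
        lines.append("")
        for seq, tags in sentences:
            for tok, tag in zip(seq.tokens, tags):
                lines.append(f"{tok}\t{tag}")
            lines.append("")
    return "\n".join(lines) + ("\n" if lines else "")


def read_conll(text: str) -> list[tuple[str, list[tuple[list[str], list[str]]]]]:
    """Parse CoNLL text into (doc_id, [(tokens, tags), ...]) groups."""
    docs: list[tuple[str, list[tuple[list[str], list[str]]]]] = []
    cur_tokens: list[str] = []
    cur_tags: list[str] = []

    def flush_sentence() -> None:
        nonlocal cur_tokens, cur_tags
        if cur_tokens:
            if not docs:
                docs.append(("", []))
            docs[-1][1].append((cur_tokens, cur_tags))
            cur_tokens, cur_tags = [], []

    for line in text.splitlines():
        if line.startswith("-DOCSTART-"):
            flush_sentence()
            doc_id = line[len("-DOCSTART-") :].strip()
            docs.append((doc_id, []))
        elif not line.strip():
            flush_sentence()
        else:
            tok, _, tag = line.partition("\t")
            cur_tokens.append(tok)
            cur_tags.append(tag or "O")
    flush_sentence()
    return docs


# -- standoff span file I/O -------------------------------------------------

_STANDOFF_HEADER = "doc_id\tsection_index\tstart\tend\tlabel\tannotator\tsurface"


def write_standoff(records: Iterable[tuple[str, SpanAnnotation, str]]) -> str:
    """Serialize (doc_id, span, surface) records to the tab-separated standoff format."""
    lines = [_STANDOFF_HEADER]
    for doc_id, s, surface in records:
        lines.append(
            f"{doc_id}\t{s.section_index}\t{s.start}\t{s.end}\t{s.label}"
            f"\t{s.annotator}\t{surface}"
        )
    return "\n".join(lines) + "\n"


def read_standoff(text: str) -> list[tuple[str, SpanAnnotation, str]]:
    """Parse the standoff span format back into (doc_id, span, surface) records."""
    records: list[tuple[str, SpanAnnotation, str]] = []
    lines = text.splitlines()
    if lines and lines[0] == _STANDOFF_HEADER:
        lines = lines[1:]
    for lineno, line in enumerate(lines, start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError(f"standoff line {lineno}: expected 7 fields, got {len(parts)}")
        doc_id, sec, start, end, label, annotator, surface = parts
        records.append(
            (doc_id, SpanAnnotation(int(sec), int(start), int(end), label, annotator), surface)
        )
    return records
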