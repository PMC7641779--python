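"""Normalization of free-text relation expressions from drug labels.

Drug labels phrase the same relation many ways ("in combination with",
"coadministered with" → synergized_by). This module maintains the synonym
table mapping surface expressions to normalized relation names and scans
text for them. Matching is literal (case-insensitive, whitespace-
normalized) with a single wildcard operator ``***`` that captures a
maximal non-empty token run — deliberately not regex, so curator rules
stay auditable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable

from pgxkit.corpus import tokenize
from pgxkit.schema import KnowledgeModelRegistry

__all__ = [
    "NormalizationRule",
    "SynonymTable",
    "ExpressionMatch",
    "load_rules",
    "load_default_rules",
    "save_rules",
    "normalize_expression",
    "add_synonym",
]

WILDCARD = "***"

#: Default cap on the number of tokens a wildcard may capture.
DEFAULT_MAX_WILDCARD_TOKENS = 6


@dataclass(frozen=True)
class NormalizationRule:
    """One surface expression pattern and the relation name it normalizes to."""

    surface: str
    normalized: str

    def __post_init__(self) -> None:
        if not self.surface.strip():
            raise ValueError("rule surface must be non-empty")
        if not self.normalized:
            raise ValueError("rule normalized name must be non-empty")

    @property
    def pattern_tokens(self) -> tuple[str, ...]:
        """Case-folded, whitespace-normalized pattern tokens (wildcard kept)."""
        return tuple(
            tok if tok == WILDCARD else tok.casefold()
            for tok in self.surface.split()
        )


@dataclass
class SynonymTable:
    """Ordered rule list; surfaces unique, every normalized name resolvable."""

    rules: list[NormalizationRule] = field(default_factory=list)
    max_wildcard_tokens: int = DEFAULT_MAX_WILDCARD_TOKENS

    def __post_init__(self) -> None:
        surfaces = [r.surface.casefold() for r in self.rules]
        if len(set(surfaces)) != len(surfaces):
            raise ValueError("duplicate surface forms in synonym table")

    def lookup(self, surface: str) -> str | None:
        """Exact (case-insensitive) surface lookup."""
        key = " ".join(surface.casefold().split())
        for rule in self.rules:
            if " ".join(rule.surface.casefold().split()) == key:
                return rule.normalized
        return None


@dataclass(frozen=True)
class ExpressionMatch:
    """A normalized expression found in text."""

    start: int
    end: int
    surface: str
    normalized: str
    capture: str | None = None


def load_rules(text: str, registry: KnowledgeModelRegistry | None = None) -> SynonymTable:
    """Parse a tab-separated rule file ("surface<TAB>normalized", "#" comments)."""
    rules: list[NormalizationRule] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"rule file line {lineno}: expected 2 tab-separated fields")
        rules.append(NormalizationRule(surface=parts[0].strip(), normalized=parts[1].strip()))
    table = SynonymTable(rules=rules)
    if registry is not None:
        _check_resolvable(table, registry)
    return table


def save_rules(table: SynonymTable) -> str:
    return "\n".join(f"{r.surface}\t{r.normalized}" for r in table.rules) + "\n"


def load_default_rules(registry: KnowledgeModelRegistry | None = None) -> SynonymTable:
    """The shipped rule table (the documented expression inventory)."""
    text = (
        importlib.resources.files("pgxkit.data")
        .joinpath("relation_expressions.tsv")
        .read_text(encoding="utf-8")
    )
    return load_rules(text, registry)


def _check_resolvable(table: SynonymTable, registry: KnowledgeModelRegistry) -> None:
    for rule in table.rules:
        if registry.relation_by_name(rule.normalized) is None:
            raise ValueError(
                f"rule {rule.surface!r}: {rule.normalized!r} is not a registered relation"
            )


def add_synonym(
    table: SynonymTable,
    surface: str,
    normalized: str,
    registry: KnowledgeModelRegistry,
) -> SynonymTable:
    """Return a new table with one rule appended.

    Rejects duplicate surfaces and normalized names not in the registry.
    """
    if registry.relation_by_name(normalized) is None:
        raise ValueError(f"{normalized!r} is not a registered relation")
    if table.lookup(surface) is not None:
        raise ValueError(f"surface {surface!r} already present in the table")
    return SynonymTable(
        rules=[*table.rules, NormalizationRule(surface=surface, normalized=normalized)],
        max_wildcard_tokens=table.max_wildcard_tokens,
    )


def _match_at(
    tokens: list[str],
    folded: list[str],
    i: int,
    pattern: tuple[str, ...],
    max_wild: int,
) -> tuple[int, tuple[int, int] | None] | None:
    """Try to match a pattern starting at token i.

    Returns (end token index, wildcard token range) or None. The wildcard
    consumes a maximal run of 1..max_wild tokens such that the remainder
    of the pattern still matches.
    """
    j = i
    capture: tuple[int, int] | None = None
    for p, pat in enumerate(pattern):
        if pat != WILDCARD:
            if j >= len(folded) or folded[j] != pat:
                return None
            j += 1
            continue
        rest = pattern[p + 1 :]
        # maximal capture first
        for k in range(min(max_wild, len(folded) - j), 0, -1):
            sub = _match_at(tokens, folded, j + k, rest, max_wild)
            if sub is not None:
                end, _ = sub
                return end, (j, j + k)
        return None
    return j, capture


def normalize_expression(text: str, table: SynonymTable) -> list[ExpressionMatch]:
    """Scan text for synonym-table expressions, left to right.

    Longest match wins at each position; an accepted match consumes its
    tokens, and scanning resumes after it (earlier-starting matches win on
    overlap). Wildcards capture the original-text slice they consumed.
    """
    seq = tokenize(text)
    tokens = list(seq.tokens)
    folded = [t.casefold() for t in tokens]
    patterns = [(r.pattern_tokens, r) for r in table.rules]
    matches: list[ExpressionMatch] = []
    i = 0
    while i < len(tokens):
        best: tuple[int, tuple[int, int] | None, NormalizationRule] | None = None
        for pattern, rule in patterns:
            res = _match_at(tokens, folded, i, pattern, table.max_wildcard_tokens)
            if res is None:
                continue
            end, cap = res
            if best is None or end > best[0]:
                best = (end, cap, rule)
        if best is None:
            i += 1
            continue
        end, cap, rule = best
        start_char = seq.offsets[i][0]
        end_char = seq.offsets[end - 1][1]
        capture = None
        if cap is not None:
            capture = text[seq.offsets[cap[0]][0] : seq.offsets[cap[1] - 1][1]]
        matches.append(
            ExpressionMatch(
                start=start_char,
                end=end_char,
                surface=text[start_char:end_char],
                normalized=rule.normalized,
                capture=capture,
            )
        )
        i = end
    return matches
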