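"""Discrete feature templates for the linear-chain CRF.

Each template maps a token (or a neighbour within the context window) to a
string feature; the CRF learns one emission weight per (feature, label)
pair. Features are tagged with their relative offset so "braf at the focus
position" and "braf one token to the left" are distinct.
"""

from __future__ import annotations

from dataclasses import dataclass

from pgxkit.corpus import TokenSequence

__all__ = ["FeatureExtractor", "extract_features", "TEMPLATE_NAMES"]

#: The documented template set.
TEMPLATE_NAMES = ("bias", "lower", "shape", "prefix", "suffix", "isdigit")

_BOS = "<s>"
_EOS = "</s>"


def _shape(token: str) -> str:
    out = []
    for ch in token:
        if ch.isupper():
            out.append("A")
        elif ch.islower():
            out.append("a")
        elif ch.isdigit():
            out.append("d")
        else:
            out.append("x")
    return "".join(out)


def _token_features(token: str, offset: int, templates: tuple[str, ...]) -> list[str]:
    feats: list[str] = []
    if "lower" in templates:
        feats.append(f"{offset}:lower={token.casefold()}")
    if "shape" in templates:
        feats.append(f"{offset}:shape={_shape(token)}")
    if offset == 0 and "prefix" in templates:
        for k in range(1, min(3, len(token)) + 1):
            feats.append(f"0:pre{k}={token[:k].casefold()}")
    if offset == 0 and "suffix" in templates:
        for k in range(1, min(3, len(token)) + 1):
            feats.append(f"0:suf{k}={token[-k:].casefold()}")
    if "isdigit" in templates and token.isdigit():
        feats.append(f"{offset}:isdigit")
    return feats


@dataclass(frozen=True)
class FeatureExtractor:
    """Feature template configuration: context radius and enabled templates."""

    window: int = 2
    template_names: tuple[str, ...] = TEMPLATE_NAMES

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        unknown = set(self.template_names) - set(TEMPLATE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature templates: {sorted(unknown)}")

    def extract(self, seq: TokenSequence, position: int) -> list[str]:
        return extract_features(seq, position, self.window, self.template_names)


def extract_features(
    seq: TokenSequence,
    position: int,
    window: int = 2,
    templates: tuple[str, ...] = TEMPLATE_NAMES,
) -> list[str]:
    """Feature strings for one token position, deterministically ordered.

    Positions beyond the sequence boundary contribute boundary-marker
    features so edge tokens still see a full window.
    """
    if not (0 <= position < len(seq)):
        raise IndexError(f"position {position} out of range for {len(seq)} tokens")
    feats: list[str] = []
    if "bias" in templates:
        feats.append("bias")
    for offset in range(-window, window + 1):
        j = position + offset
        if j < 0:
            feats.append(f"{offset}:lower={_BOS}")
        elif j >= len(seq):
            feats.append(f"{offset}:lower={_EOS}")
        else:
            feats.extend(_token_features(seq.tokens[j], offset, tuple(templates)))
    return feats
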