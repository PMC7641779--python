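"""Pluggable token encoders producing dense per-token emission scores.

The discrete feature layer is one way to fill the CRF's emission matrix;
an encoder is any object mapping a token sequence to an (N × L) real
matrix of per-label scores. Contextual representation models (e.g. a
fine-tuned transformer) slot in behind this interface without touching
the CRF inference code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, runtime_checkable

import numpy as np

from pgxkit.corpus import TokenSequence

__all__ = ["Encoder", "LookupEncoder"]


@runtime_checkable
class Encoder(Protocol):
    def emissions(self, seq: TokenSequence, labels: tuple[str, ...]) -> np.ndarray:
        """Return an (len(seq), len(labels)) matrix of emission scores."""
        ...


@dataclass
class LookupEncoder:
    """Trivial encoder: a fixed per-token score vector over labels.

    Unknown tokens score zero everywhere. Exists to exercise the dense
    inference path and as the minimal reference implementation of the
    encoder contract.
    """

    table: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    case_sensitive: bool = False

    def emissions(self, seq: TokenSequence, labels: tuple[str, ...]) -> np.ndarray:
        E = np.zeros((len(seq), len(labels)))
        for t, tok in enumerate(seq.tokens):
            key = tok if self.case_sensitive else tok.casefold()
            row = self.table.get(key)
            if row:
                for j, lab in enumerate(labels):
                    E[t, j] = row.get(lab, 0.0)
        return E
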