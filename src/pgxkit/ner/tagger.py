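"""Training and end-to-end tagging built on the CRF core.

Training is deterministic full-batch optimization of the L2-penalized
conditional log-likelihood with L-BFGS: given the same corpus, config and
seed, the learned weights are bit-identical. Each annotated section is one
training sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from pgxkit.corpus import Document, SpanAnnotation, TokenSequence, bio_to_spans, spans_to_bio, tokenize
from pgxkit.ner.crf import CRFModel, TrainConfig, objective_and_gradient
from pgxkit.ner.crf import viterbi_decode
from pgxkit.ner.features import FeatureExtractor

logger = logging.getLogger(__name__)

__all__ = ["CRFTagger", "train_crf", "sentences_from_docs", "token_sequence_from_tokens"]


def token_sequence_from_tokens(tokens: Sequence[str]) -> TokenSequence:
    """Wrap pre-tokenized input (e.g. CoNLL) with synthetic offsets."""
    offsets = []
    pos = 0
    for tok in tokens:
        offsets.append((pos, pos + len(tok)))
        pos += len(tok) + 1
    return TokenSequence(tuple(tokens), tuple(offsets))


def sentences_from_docs(
    docs: Sequence[Document],
    annotations: Sequence[Sequence[SpanAnnotation]],
) -> list[tuple[TokenSequence, list[str]]]:
    """Tokenize each section and convert its spans to BIO tags."""
    sentences: list[tuple[TokenSequence, list[str]]] = []
    for doc, spans in zip(docs, annotations):
        by_section: dict[int, list[SpanAnnotation]] = {}
        for s in spans:
            by_section.setdefault(s.section_index, []).append(s)
        for i, (_, text) in enumerate(doc.sections):
            seq = tokenize(text)
            if len(seq) == 0:
                continue
            sentences.append((seq, spans_to_bio(seq, by_section.get(i, []))))
    return sentences


@dataclass
class CRFTagger:
    """A trained CRF model plus the feature extractor it was trained with."""

    model: CRFModel
    extractor: FeatureExtractor

    def _featurize(self, seq: TokenSequence) -> list[np.ndarray]:
        return self.model.featurize(
            [self.extractor.extract(seq, i) for i in range(len(seq))]
        )

    def tag(self, seq: TokenSequence) -> list[str]:
        """BIO tags for one token sequence (Viterbi decoding)."""
        tags, _ = viterbi_decode(self.model, self._featurize(seq))
        return tags

    def tag_document(self, doc: Document) -> list[SpanAnnotation]:
        """Predict entity spans for every section of a document."""
        spans: list[SpanAnnotation] = []
        for i, (_, text) in enumerate(doc.sections):
            seq = tokenize(text)
            if len(seq) == 0:
                continue
            spans.extend(bio_to_spans(seq, self.tag(seq), section_index=i))
        return spans

    def predict(self, docs: Sequence[Document]) -> dict[str, list[SpanAnnotation]]:
        return {doc.doc_id: self.tag_document(doc) for doc in docs}


def train_crf(
    corpus: Sequence[tuple[TokenSequence, Sequence[str]]],
    cfg: TrainConfig | None = None,
    extractor: FeatureExtractor | None = None,
) -> CRFTagger:
    """Train a feature CRF on BIO-tagged sequences.

    The penalized objective is minimized by full-batch L-BFGS from a zero
    initialization, so training is deterministic; it stops when the
    relative objective change falls below the tolerance or at the
    iteration cap.
    """
    cfg = cfg or TrainConfig()
    extractor = extractor or FeatureExtractor()
    if not corpus:
        raise ValueError("training corpus must be non-empty")
    tagset = sorted({t for _, tags in corpus for t in tags})
    if len(tagset) < 2:
        raise ValueError(
            "degenerate task: the corpus contains a single tag everywhere"
        )
    labels = tuple(tagset)

    feature_lists = [
        [extractor.extract(seq, i) for i in range(len(seq))] for seq, _ in corpus
    ]
    feature_index = {
        f: i
        for i, f in enumerate(sorted({f for doc in feature_lists for pos in doc for f in pos}))
    }
    L, F = len(labels), len(feature_index)
    model = CRFModel(labels=labels, feature_index=feature_index, weights=np.zeros(F * L + L * L))
    batch = [
        (model.featurize(feats), list(tags))
        for feats, (_, tags) in zip(feature_lists, corpus)
    ]

    def fun(w: np.ndarray) -> tuple[float, np.ndarray]:
        model.weights = w
        return objective_and_gradient(model, batch, cfg)

    w0 = np.zeros(F * L + L * L)
    f0, _ = fun(w0)
    res = minimize(
        fun,
        w0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": cfg.max_iterations, "ftol": cfg.tolerance, "gtol": 1e-8},
    )
    if res.fun > f0:  # pragma: no cover - L-BFGS never accepts an ascent step
        raise RuntimeError("optimizer ended above the initial objective")
    logger.info(
        "trained CRF: %d labels, %d features, objective %.4f -> %.4f (%d iterations)",
        L, F, f0, res.fun, res.nit,
    )
    model.weights = res.x
    return CRFTagger(model=model, extractor=extractor)
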