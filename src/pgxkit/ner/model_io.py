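"""Versioned plain-text model files (diffable; no binary payload).

Layout: a header line with format name and version, the label list, the
feature-extractor configuration, the feature→column table, then one
decimal weight per line.
"""

from __future__ import annotations

import numpy as np

from pgxkit.ner.crf import CRFModel
from pgxkit.ner.features import FeatureExtractor
from pgxkit.ner.tagger import CRFTagger

__all__ = ["save_model", "load_model"]

_MAGIC = "pgxkit-crf"
_VERSION = 1


def save_model(tagger: CRFTagger) -> str:
    """Serialize a trained tagger to the versioned text format."""
    m = tagger.model
    lines = [f"{_MAGIC} {_VERSION}"]
    lines.append("labels\t" + "\t".join(m.labels))
    lines.append(f"window\t{tagger.extractor.window}")
    lines.append("templates\t" + ",".join(tagger.extractor.template_names))
    lines.append(f"features\t{m.n_features}")
    for feat, idx in sorted(m.feature_index.items(), key=lambda kv: kv[1]):
        lines.append(f"{feat}\t{idx}")
    lines.append(f"weights\t{len(m.weights)}")
    lines.extend(repr(float(w)) for w in m.weights)
    return "\n".join(lines) + "\n"


def load_model(text: str) -> CRFTagger:
    """Parse the text format back into a tagger (inverse of save_model)."""
    lines = text.splitlines()
    header = lines[0].split()
    if header[0] != _MAGIC:
        raise ValueError(f"not a {_MAGIC} model file")
    if int(header[1]) != _VERSION:
        raise ValueError(f"unsupported model format version {header[1]}")
    labels = tuple(lines[1].split("\t")[1:])
    window = int(lines[2].split("\t")[1])
    templates = tuple(lines[3].split("\t")[1].split(","))
    n_features = int(lines[4].split("\t")[1])
    feature_index: dict[str, int] = {}
    for line in lines[5 : 5 + n_features]:
        feat, idx = line.rsplit("\t", 1)
        feature_index[feat] = int(idx)
    w_header = lines[5 + n_features].split("\t")
    n_weights = int(w_header[1])
    weights = np.asarray(
        [float(x) for x in lines[6 + n_features : 6 + n_features + n_weights]]
    )
    model = CRFModel(labels=labels, feature_index=feature_index, weights=weights)
    return CRFTagger(model=model, extractor=FeatureExtractor(window=window, template_names=templates))
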