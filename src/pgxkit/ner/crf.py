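"""Linear-chain CRF: exact inference, likelihood, gradient.

The model scores a tag sequence y for an N-token input as

    score(y) = sum_t  E[t, y_t]  +  sum_{t>0}  T[y_{t-1}, y_t]

where the emission matrix E comes from binary token features (E[t, y] =
sum of emission weights of the features active at position t, for label y)
and T is the learned transition matrix. The conditional probability is
p(y|x) = exp(score(y)) / Z with Z summing over all |labels|^N sequences;
the forward recursion computes log Z exactly, forward-backward gives the
node and edge marginals needed for the gradient, and Viterbi gives the
argmax sequence with lexicographic tie-breaking on label indices.

All recursions run in log space; weights are a single flat vector of
length |features|·|labels| + |labels|² (emissions first, then transitions
row-major).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CRFModel",
    "TrainConfig",
    "log_partition",
    "sequence_log_likelihood",
    "gradient",
    "viterbi_decode",
    "viterbi_decode_dense",
    "emission_matrix",
]

# A featurized sequence: one integer array of active feature columns per token.
FeaturizedSeq = Sequence[np.ndarray]


@dataclass
class CRFModel:
    """Label set, feature index, and the flat weight vector."""

    labels: tuple[str, ...]
    feature_index: dict[str, int]
    weights: np.ndarray

    def __post_init__(self) -> None:
        L, F = len(self.labels), len(self.feature_index)
        expected = F * L + L * L
        if self.weights.shape != (expected,):
            raise ValueError(
                f"weight vector has shape {self.weights.shape}, expected ({expected},)"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return len(self.feature_index)

    @property
    def emission_weights(self) -> np.ndarray:
        """View of shape (n_features, n_labels)."""
        L, F = self.n_labels, self.n_features
        return self.weights[: F * L].reshape(F, L)

    @property
    def transition_weights(self) -> np.ndarray:
        """View of shape (n_labels, n_labels); [i, j] scores i → j."""
        L, F = self.n_labels, self.n_features
        return self.weights[F * L :].reshape(L, L)

    def label_index(self, tag: str) -> int:
        try:
            return self.labels.index(tag)
        except ValueError:
            raise ValueError(f"tag {tag!r} is not in the model's label set") from None

    def featurize(self, feature_lists: Sequence[Sequence[str]]) -> list[np.ndarray]:
        """Map per-position feature strings to column indices, dropping unknowns."""
        out = []
        for feats in feature_lists:
            idx = [self.feature_index[f] for f in feats if f in self.feature_index]
            out.append(np.asarray(sorted(idx), dtype=np.int64))
        return out


@dataclass
class TrainConfig:
    """Deterministic full-batch training configuration.

    ``l2_sigma`` is the Gaussian prior scale: the objective is the negative
    log-likelihood plus ``||w||² / (2·l2_sigma²)``, so larger sigma means
    weaker regularization.
    """

    l2_sigma: float = 10.0
    max_iterations: int = 200
    tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l2_sigma <= 0:
            raise ValueError("l2_sigma must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _lse(a: np.ndarray, axis: int | None = None):
    """Log-sum-exp, open-coded: the recursions call this in a tight loop."""
    mx = a.max(axis=axis, keepdims=axis is not None)
    out = np.log(np.exp(a - mx).sum(axis=axis)) + np.squeeze(mx, axis=axis) if axis is not None \
        else float(np.log(np.exp(a - mx).sum()) + mx)
    return out


def emission_matrix(m: CRFModel, seq: FeaturizedSeq) -> np.ndarray:
    """E[t, y]: summed emission weights of the features active at position t."""
    W = m.emission_weights
    E = np.zeros((len(seq), m.n_labels))
    for t, feats in enumerate(seq):
        if len(feats):
            E[t] = W[feats].sum(axis=0)
    return E


def _forward(E: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Forward log-messages alpha[t, y] = log sum over prefixes ending in y at t."""
    N, L = E.shape
    alpha = np.empty((N, L))
    alpha[0] = E[0]
    for t in range(1, N):
        alpha[t] = E[t] + _lse(alpha[t - 1][:, None] + T, axis=0)
    return alpha


def _backward(E: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Backward log-messages beta[t, y] = log sum over suffixes from t given y."""
    N, L = E.shape
    beta = np.zeros((N, L))
    for t in range(N - 2, -1, -1):
        beta[t] = _lse(T + E[t + 1] + beta[t + 1], axis=1)
    return beta


def log_partition(m: CRFModel, seq: FeaturizedSeq) -> float:
    """log Z: log of the summed exponentiated scores of all tag sequences."""
    if len(seq) == 0:
        raise ValueError("cannot compute the partition function of an empty sequence")
    E = emission_matrix(m, seq)
    alpha = _forward(E, m.transition_weights)
    return _lse(alpha[-1])


def _path_score(E: np.ndarray, T: np.ndarray, y: np.ndarray) -> float:
    s = float(E[np.arange(len(y)), y].sum())
    if len(y) > 1:
        s += float(T[y[:-1], y[1:]].sum())
    return s


def sequence_log_likelihood(m: CRFModel, seq: FeaturizedSeq, tags: Sequence[str]) -> float:
    """log p(tags | seq) = score(tags) − log Z; always ≤ 0."""
    if len(tags) != len(seq):
        raise ValueError(f"{len(tags)} tags for {len(seq)} positions")
    y = np.asarray([m.label_index(t) for t in tags], dtype=np.int64)
    E = emission_matrix(m, seq)
    T = m.transition_weights
    alpha = _forward(E, T)
    return _path_score(E, T, y) - _lse(alpha[-1])


def _nll_and_grad_one(
    m: CRFModel, seq: FeaturizedSeq, y: np.ndarray,
    grad_E_feat: np.ndarray, grad_T: np.ndarray,
) -> float:
    """Accumulate the NLL gradient of one sequence; return its NLL."""
    E = emission_matrix(m, seq)
    T = m.transition_weights
    N, L = E.shape
    alpha = _forward(E, T)
    beta = _backward(E, T)
    logZ = _lse(alpha[-1])

    # node marginals q[t, y] and their NLL contribution (model − empirical)
    q = np.exp(alpha + beta - logZ)
    dE = q.copy()
    dE[np.arange(N), y] -= 1.0
    for t, feats in enumerate(seq):
        if len(feats):
            grad_E_feat[feats] += dE[t]

    # edge marginals between t−1 and t
    for t in range(1, N):
        M = np.exp(alpha[t - 1][:, None] + T + (E[t] + beta[t])[None, :] - logZ)
        grad_T += M
    if N > 1:
        np.add.at(grad_T, (y[:-1], y[1:]), -1.0)

    return logZ - _path_score(E, T, y)


def gradient(
    m: CRFModel,
    batch: Sequence[tuple[FeaturizedSeq, Sequence[str]]],
    cfg: TrainConfig,
) -> np.ndarray:
    """Gradient of the L2-penalized negative log-likelihood over a batch.

    Equals expected feature counts under the model minus empirical counts,
    plus the prior term ``w / l2_sigma²``.
    """
    _, g = objective_and_gradient(m, batch, cfg)
    return g


def objective_and_gradient(
    m: CRFModel,
    batch: Sequence[tuple[FeaturizedSeq, Sequence[str]]],
    cfg: TrainConfig,
) -> tuple[float, np.ndarray]:
    """Penalized NLL and its gradient, for the batch optimizer."""
    if not batch:
        raise ValueError("batch must be non-empty")
    L, F = m.n_labels, m.n_features
    grad_E = np.zeros((F, L))
    grad_T = np.zeros((L, L))
    nll = 0.0
    for seq, tags in batch:
        y = np.asarray([m.label_index(t) for t in tags], dtype=np.int64)
        nll += _nll_and_grad_one(m, seq, y, grad_E, grad_T)
    grad = np.concatenate([grad_E.ravel(), grad_T.ravel()])
    # Gaussian prior
    sigma2 = cfg.l2_sigma**2
    nll += float(m.weights @ m.weights) / (2.0 * sigma2)
    grad += m.weights / sigma2
    return nll, grad


def viterbi_decode(m: CRFModel, seq: FeaturizedSeq) -> tuple[list[str], float]:
    """Best-scoring tag sequence and its path score.

    Ties are broken toward the lexicographically smallest label-index
    sequence: the recursion runs back-to-front on suffix maxima, then the
    path is built front-to-back taking the smallest label index achieving
    the maximum at each step.
    """
    if len(seq) == 0:
        raise ValueError("cannot decode an empty sequence")
    E = emission_matrix(m, seq)
    idx, score = viterbi_decode_dense(E, m.transition_weights)
    return [m.labels[i] for i in idx], score


def viterbi_decode_dense(E: np.ndarray, T: np.ndarray) -> tuple[list[int], float]:
    """Viterbi on a dense emission matrix (the encoder-facing inference path).

    Accepts per-token emission scores from any encoder; returns label
    indices and the best path score, with the same lexicographic
    tie-breaking as :func:`viterbi_decode`.
    """
    N, L = E.shape
    # delta[t, y]: best score of the suffix t..N−1 given label y at t
    delta = np.empty((N, L))
    delta[N - 1] = E[N - 1]
    for t in range(N - 2, -1, -1):
        delta[t] = E[t] + np.max(T + delta[t + 1][None, :], axis=1)
    path = [int(np.argmax(delta[0]))]
    for t in range(1, N):
        prev = path[-1]
        path.append(int(np.argmax(T[prev] + delta[t])))
    return path, float(delta[0][path[0]])
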