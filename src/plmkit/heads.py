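"""Task heads for downstream prediction on frozen or adapted embeddings.

A protein-level representation h is pooled from the per-residue embeddings —
either the arithmetic mean or attention pooling with learnable class-token
queries (``h = softmax(C (E Wk)^T / sqrt(d_k)) E``, normalized within each
sequence only, so the operation is packing-compatible). A two-layer ReLU
head maps h to a scalar (regression) or through a sigmoid to a probability
(binary classification, e.g. transcription-factor identification). Class
imbalance in binary tasks is handled by resampling the positive class with
replacement to match the negative count each epoch.

Pooling excludes the cls/eos embeddings so h does not depend on sequence
length through the special tokens.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, segment_mean, segment_softmax
from .packing import PackedBatch

__all__ = ["RegressionHead", "AttentionPooling", "mean_pool", "regression_forward",
           "attention_pool", "classify_forward", "upsample_positive",
           "strip_special_tokens"]


def strip_special_tokens(values, batch: PackedBatch):
    """Drop the first (cls) and last (eos) row of every sequence in a packed
    per-token array; returns (residue rows, residue boundaries)."""
    b = batch.boundaries
    lengths = np.diff(b) - 2
    if np.any(lengths <= 0):
        raise ValueError("a sequence has no residue tokens")
    idx = np.concatenate([np.arange(b[i] + 1, b[i + 1] - 1)
                          for i in range(batch.n_sequences)])
    new_b = np.concatenate([[0], np.cumsum(lengths)])
    stripped = values[idx]
    return stripped, new_b


def mean_pool(embeddings, boundaries=None):
    """Arithmetic mean over residue embeddings, per sequence.

    With ``boundaries`` the input is a packed [tokens, d] array and one mean
    per segment is returned; without, the whole array is one sequence.
    """
    is_tensor = isinstance(embeddings, Tensor)
    e = embeddings if is_tensor else Tensor(np.asarray(embeddings, dtype=np.float64))
    if e.shape[0] == 0:
        raise ValueError("cannot pool an empty sequence")
    if boundaries is None:
        boundaries = np.array([0, e.shape[0]])
    out = segment_mean(e, np.asarray(boundaries))
    return out if is_tensor else out.numpy()


class RegressionHead:
    """Two feed-forward layers with ReLU: y = W2 relu(W1 h + b1) + b2."""

    def __init__(self, in_dim: int, hidden: int = 256, seed: int = 0):
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(in_dim)
        self.params = {
            "W1": Tensor(rng.uniform(-s, s, size=(hidden, in_dim)).astype(np.float32),
                         requires_grad=True),
            "b1": Tensor(np.zeros(hidden, dtype=np.float32), requires_grad=True),
            "W2": Tensor(rng.uniform(-1 / np.sqrt(hidden), 1 / np.sqrt(hidden),
                                     size=(1, hidden)).astype(np.float32),
                         requires_grad=True),
            "b2": Tensor(np.zeros(1, dtype=np.float32), requires_grad=True),
        }

    def forward_t(self, h: Tensor) -> Tensor:
        p = self.params
        if h.shape[-1] != p["W1"].shape[1]:
            raise ValueError(
                f"input width {h.shape[-1]} does not match head width {p['W1'].shape[1]}")
        hidden = (h @ p["W1"].T + p["b1"]).relu()
        return hidden @ p["W2"].T + p["b2"]

    def __call__(self, h) -> np.ndarray:
        ht = h if isinstance(h, Tensor) else Tensor(np.asarray(h, dtype=np.float32))
        return self.forward_t(ht).numpy()


def regression_forward(h, head: RegressionHead) -> np.ndarray:
    """Scalar prediction(s) for pooled representation(s) h."""
    out = head(np.atleast_2d(np.asarray(h, dtype=np.float32)))
    return out[..., 0]


class AttentionPooling:
    """Learnable class-token attention pooling, packing-compatible.

    ``C`` holds ``n_class_tokens`` query rows of width d_k; ``Wk`` projects
    embeddings to keys. Attention weights are softmax-normalized within each
    sequence segment, never across, and each class token's output row is a
    convex combination of that sequence's residue embeddings. Rows are
    concatenated into one [n_class_tokens * d] vector per sequence.
    """

    def __init__(self, embed_dim: int, d_k: int | None = None,
                 n_class_tokens: int = 1, seed: int = 0):
        d_k = d_k or embed_dim
        rng = np.random.default_rng(seed)
        self.d_k = d_k
        self.n_class_tokens = n_class_tokens
        self.params = {
            "C": Tensor(rng.normal(0, 0.02, size=(n_class_tokens, d_k)).astype(np.float32),
                        requires_grad=True),
            "Wk": Tensor(rng.normal(0, 0.02, size=(d_k, embed_dim)).astype(np.float32),
                         requires_grad=True),
        }

    def weights(self, embeddings, boundaries=None) -> np.ndarray:
        """Per-token attention weights [tokens, n_class_tokens] (numpy)."""
        return self._weights_t(_as_t(embeddings), _default_bounds(embeddings, boundaries)).numpy()

    def _weights_t(self, e: Tensor, boundaries: np.ndarray) -> Tensor:
        keys = e @ self.params["Wk"].T              # [T, d_k]
        scores = keys @ self.params["C"].T          # [T, n_class]
        scores = scores * (1.0 / np.sqrt(self.d_k))
        return segment_softmax(scores, boundaries)

    def forward_t(self, e: Tensor, boundaries: np.ndarray) -> Tensor:
        T, d = e.shape
        probs = self._weights_t(e, boundaries)      # [T, n_class]
        weighted = probs.reshape(T, self.n_class_tokens, 1) * e.reshape(T, 1, d)
        flat = weighted.reshape(T, self.n_class_tokens * d)
        lengths = np.diff(boundaries).astype(np.float32)
        return segment_mean(flat, boundaries) * lengths[:, None]   # segment sums

    def __call__(self, embeddings, boundaries=None) -> np.ndarray:
        e = _as_t(embeddings)
        return self.forward_t(e, _default_bounds(embeddings, boundaries)).numpy()


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _default_bounds(x, boundaries) -> np.ndarray:
    if boundaries is not None:
        return np.asarray(boundaries)
    n = x.shape[0] if not isinstance(x, Tensor) else x.shape[0]
    if n == 0:
        raise ValueError("cannot pool an empty sequence")
    return np.array([0, n])


def attention_pool(embeddings, pooling: AttentionPooling, boundaries=None) -> np.ndarray:
    """Pooled representation(s): [n_sequences, n_class_tokens * embed_dim]."""
    return pooling(embeddings, boundaries)


def classify_forward(h, head: RegressionHead) -> np.ndarray:
    """Probability in (0, 1): sigmoid of the regression head's logit."""
    logit = regression_forward(h, head)
    return 1.0 / (1.0 + np.exp(-logit))


def upsample_positive(labels, seed: int = 0) -> np.ndarray:
    """Index multiset balancing the positive class against the negatives.

    Negatives keep their indices; positives are resampled with replacement to
    match the negative count. Balanced input returns the identity multiset.
    Deterministic for a given seed (use seed + epoch for fresh draws).
    """
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("upsampling requires both classes present")
    if len(pos) == len(neg):
        return np.arange(len(labels))
    rng = np.random.default_rng(seed)
    drawn = rng.choice(pos, size=len(neg), replace=True)
    return np.concatenate([neg, drawn])
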