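"""ESM-style masked-language-model transformer.

The model maps a packed stream of amino-acid tokens to per-token logits over
the vocabulary. Architecture follows the ESM family: token embeddings plus
either a learned positional table (ESM-1b/1v style, with the two reserved
pad rows so table rows = max_positions + 2) or rotary position embeddings
(ESM2/ESM-C style); a stack of transformer blocks (GeLU feed-forward with
post-layer-norm by default, or SwiGLU with pre-layer-norm); and a language
model head producing logits.

All computation runs on packed batches with a dense block-diagonal attention
mask, which is mathematically equivalent to running each sequence alone —
that equivalence is the central correctness contract of the packing
mechanism. Positions restart at 0 for every sequence inside a packed batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .autograd import Tensor, concat, take_rows
from .alphabet import TokenAlphabet, esm_alphabet
from .packing import PackedBatch, block_diagonal_mask, pack, packed_positions

__all__ = ["ModelConfig", "ProteinLM", "self_attention", "apply_rotary",
           "transformer_block", "forward_logits", "POSITION_OFFSET"]

# Learned positional tables reserve two leading rows (pad convention), so a
# model advertising max_positions N stores a table with N + 2 rows and a
# tokenized sequence may be at most N tokens long.
POSITION_OFFSET = 2

_LN_EPS = 1e-5


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters for one model variant."""

    num_layers: int
    embed_dim: int
    num_heads: int
    ffn_dim: int
    vocab_size: int = 33
    max_positions: int = 1024
    positional_mode: str = "learned"   # "learned" | "rotary"
    activation: str = "gelu"           # "gelu" | "swiglu"
    norm_style: str = "post"           # "post" | "pre"
    tie_lm_head: bool = False

    def __post_init__(self):
        if self.embed_dim % self.num_heads != 0:
            raise ValueError("embed_dim must be divisible by num_heads")
        if self.positional_mode not in ("learned", "rotary"):
            raise ValueError(f"unknown positional_mode {self.positional_mode!r}")
        if self.positional_mode == "learned" and self.max_positions < 2:
            raise ValueError("learned positional mode requires max_positions >= 2")
        if self.activation not in ("gelu", "swiglu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.norm_style not in ("post", "pre"):
            raise ValueError(f"unknown norm_style {self.norm_style!r}")
        for name in ("num_layers", "embed_dim", "num_heads", "ffn_dim", "vocab_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.num_heads

    def to_dict(self) -> dict:
        return {
            "num_layers": self.num_layers, "embed_dim": self.embed_dim,
            "num_heads": self.num_heads, "ffn_dim": self.ffn_dim,
            "vocab_size": self.vocab_size, "max_positions": self.max_positions,
            "positional_mode": self.positional_mode, "activation": self.activation,
            "norm_style": self.norm_style, "tie_lm_head": self.tie_lm_head,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        return cls(**dict(d))


# ---------------------------------------------------------------------------
# Primitive operations (also exposed standalone for direct use and testing)
# ---------------------------------------------------------------------------

def _rotary_angles(positions: np.ndarray, head_dim: int, dtype=np.float32):
    half = head_dim // 2
    inv_freq = 1.0 / (10000.0 ** (np.arange(half, dtype=np.float64) * 2.0 / head_dim))
    angles = np.asarray(positions, dtype=np.float64)[:, None] * inv_freq[None, :]
    cos = np.cos(angles).astype(dtype)
    sin = np.sin(angles).astype(dtype)
    # duplicate for the two halves: rotation acts on pairs (i, i + half)
    return np.concatenate([cos, cos], axis=-1), np.concatenate([sin, sin], axis=-1)


def _rotate_half(x: Tensor) -> Tensor:
    half = x.shape[-1] // 2
    x1 = x[..., :half]
    x2 = x[..., half:]
    return concat([-x2, x1], axis=-1)


def apply_rotary(x, positions) -> np.ndarray | Tensor:
    """Rotate per-head vectors by position-dependent angles.

    ``x`` has shape [..., T, head_dim] with an even head dimension; entry
    ``i`` of the leading token axis is rotated by the angle set for
    ``positions[i]``. Rotations are isometries, so vector norms are
    preserved, and the induced query-key dot products depend only on relative
    position.
    """
    is_tensor = isinstance(x, Tensor)
    xt = x if is_tensor else Tensor(np.asarray(x, dtype=np.float32))
    head_dim = xt.shape[-1]
    if head_dim % 2 != 0:
        raise ValueError("rotary embedding requires an even head dimension")
    cos, sin = _rotary_angles(positions, head_dim, dtype=xt.dtype)
    out = xt * cos + _rotate_half(xt) * sin
    return out if is_tensor else out.numpy()


def _masked_softmax(scores: Tensor, allowed: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to allowed key positions."""
    if not np.all(allowed.any(axis=-1)):
        raise ValueError("a query row has no allowed keys; cannot normalize softmax")
    neg = np.where(allowed, 0.0, -np.inf).astype(scores.dtype)
    shifted = scores + neg
    rowmax = np.max(shifted.data, axis=-1, keepdims=True)  # detached shift
    e = (shifted - rowmax).exp()
    return e / e.sum(axis=-1, keepdims=True)


def self_attention(q, k, v, mask, d: float | None = None):
    """Scaled dot-product attention restricted to an allowed-pairs mask.

    ``q``, ``k``, ``v``: [..., T, d_head]; ``mask``: boolean [T, T] with True
    marking allowed (query, key) pairs; ``d`` defaults to the head dimension.
    Each output row is a convex combination of value rows.
    """
    is_tensor = isinstance(q, Tensor)
    qt = q if is_tensor else Tensor(np.asarray(q, dtype=np.float32))
    kt = k if isinstance(k, Tensor) else Tensor(np.asarray(k, dtype=qt.dtype))
    vt = v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=qt.dtype))
    if d is None:
        d = qt.shape[-1]
    mask = np.asarray(mask, dtype=bool)
    if not (qt.requires_grad or kt.requires_grad or vt.requires_grad):
        # inference fast path: same arithmetic, fused in-place (no graph)
        out = Tensor(_attention_numpy(qt.data, kt.data, vt.data, mask, d))
        return out if is_tensor else out.numpy()
    scores = (qt @ kt.swapaxes(-1, -2)) * (1.0 / math.sqrt(d))
    attn = _masked_softmax(scores, mask)
    out = attn @ vt
    return out if is_tensor else out.numpy()


def _attention_numpy(q: np.ndarray, k: np.ndarray, v: np.ndarray,
                     allowed: np.ndarray, d: float) -> np.ndarray:
    if not np.all(allowed.any(axis=-1)):
        raise ValueError("a query row has no allowed keys; cannot normalize softmax")
    s = q @ np.swapaxes(k, -1, -2)
    s *= 1.0 / math.sqrt(d)
    np.copyto(s, -np.inf, where=~allowed)
    m = s.max(axis=-1, keepdims=True)
    np.subtract(s, m, out=s)
    np.exp(s, out=s)
    s /= s.sum(axis=-1, keepdims=True)
    return s @ v


def _layer_norm(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + _LN_EPS).sqrt() * weight + bias


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class ProteinLM:
    """A protein language model: config + named parameter tensors.

    Parameters live in a flat dict keyed by archive names
    (``layers.{i}.attn.q.weight`` ...), matching the on-disk named-tensor
    layout, so serialization is a direct dump of this dict. LoRA adapters,
    when attached, live in ``self.adapters`` keyed by the projection name
    and are consulted transparently during the forward pass.
    """

    def __init__(self, config: ModelConfig, params: Mapping[str, Tensor],
                 alphabet: TokenAlphabet | None = None):
        self.config = config
        self.params: dict[str, Tensor] = dict(params)
        self.alphabet = alphabet or esm_alphabet()
        self.adapters: dict[str, tuple[Tensor, Tensor, float]] = {}
        self._validate_shapes()

    # -- bookkeeping ---------------------------------------------------------

    def _validate_shapes(self):
        c = self.config
        d = c.embed_dim
        expect: dict[str, tuple[int, ...]] = {"embed_tokens.weight": (c.vocab_size, d)}
        if c.positional_mode == "learned":
            expect["embed_positions.weight"] = (c.max_positions + POSITION_OFFSET, d)
        fc1_out = 2 * c.ffn_dim if c.activation == "swiglu" else c.ffn_dim
        for i in range(c.num_layers):
            p = f"layers.{i}."
            for proj in ("q", "k", "v", "out"):
                expect[p + f"attn.{proj}.weight"] = (d, d)
                expect[p + f"attn.{proj}.bias"] = (d,)
            expect[p + "ffn.fc1.weight"] = (fc1_out, d)
            expect[p + "ffn.fc1.bias"] = (fc1_out,)
            expect[p + "ffn.fc2.weight"] = (d, c.ffn_dim)
            expect[p + "ffn.fc2.bias"] = (d,)
            for norm in ("norm1", "norm2"):
                expect[p + norm + ".weight"] = (d,)
                expect[p + norm + ".bias"] = (d,)
        expect["final_norm.weight"] = (d,)
        expect["final_norm.bias"] = (d,)
        if not c.tie_lm_head:
            expect["lm_head.weight"] = (c.vocab_size, d)
        expect["lm_head.bias"] = (c.vocab_size,)
        for name, shape in expect.items():
            if name not in self.params:
                raise ValueError(f"missing parameter {name}")
            got = self.params[name].shape
            if tuple(got) != shape:
                raise ValueError(f"parameter {name} has shape {got}, expected {shape}")
            if not np.all(np.isfinite(self.params[name].data)):
                raise ValueError(f"parameter {name} contains non-finite values")

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def trainable_parameters(self) -> dict[str, Tensor]:
        out = {name: p for name, p in self.params.items() if p.requires_grad}
        for name, (a, b, _) in self.adapters.items():
            if a.requires_grad:
                out[f"adapters.{name}.A"] = a
            if b.requires_grad:
                out[f"adapters.{name}.B"] = b
        return out

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def set_trainable(self, names=None) -> None:
        """Mark the given parameter names trainable (all if None), rest frozen."""
        for name, p in self.params.items():
            p.requires_grad = names is None or name in names
            p.grad = None

    def freeze(self) -> None:
        for p in self.params.values():
            p.requires_grad = False
            p.grad = None

    # -- forward -------------------------------------------------------------

    def _as_batch(self, tokens) -> PackedBatch:
        if isinstance(tokens, PackedBatch):
            return tokens
        tokens = np.asarray(tokens)
        if tokens.ndim != 1:
            raise ValueError("expected a 1-D token-id array or a PackedBatch")
        return pack([tokens])

    def _linear(self, name: str, x: Tensor, params: Mapping[str, Tensor]) -> Tensor:
        w = params[name + ".weight"]
        h = x @ w.T + params[name + ".bias"]
        if name in self.adapters:
            a, b, scaling = self.adapters[name]
            h = h + ((x @ a.T) @ b.T) * scaling
        return h

    def _ffn(self, i: int, x: Tensor, params: Mapping[str, Tensor]) -> Tensor:
        c = self.config
        h = self._linear(f"layers.{i}.ffn.fc1", x, params)
        if c.activation == "swiglu":
            gate = h[..., :c.ffn_dim]
            up = h[..., c.ffn_dim:]
            h = gate.silu() * up
        else:
            h = h.gelu()
        return self._linear(f"layers.{i}.ffn.fc2", h, params)

    def _attn(self, i: int, x: Tensor, allowed: np.ndarray,
              positions: np.ndarray, params: Mapping[str, Tensor]) -> Tensor:
        c = self.config
        T = x.shape[0]
        p = f"layers.{i}.attn."

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(T, c.num_heads, c.head_dim).swapaxes(0, 1)

        q = split_heads(self._linear(p + "q", x, params))
        k = split_heads(self._linear(p + "k", x, params))
        v = split_heads(self._linear(p + "v", x, params))
        if c.positional_mode == "rotary":
            q = apply_rotary(q, positions)
            k = apply_rotary(k, positions)
        ctx = self_attention(q, k, v, allowed, d=c.head_dim)
        ctx = ctx.swapaxes(0, 1).reshape(T, c.embed_dim)
        return self._linear(p + "out", ctx, params)

    def _block(self, i: int, x: Tensor, allowed: np.ndarray,
               positions: np.ndarray, params: Mapping[str, Tensor]) -> Tensor:
        p = f"layers.{i}."
        n1w, n1b = params[p + "norm1.weight"], params[p + "norm1.bias"]
        n2w, n2b = params[p + "norm2.weight"], params[p + "norm2.bias"]
        if self.config.norm_style == "pre":
            x = x + self._attn(i, _layer_norm(x, n1w, n1b), allowed, positions, params)
            x = x + self._ffn(i, _layer_norm(x, n2w, n2b), params)
        else:
            x = _layer_norm(x + self._attn(i, x, allowed, positions, params), n1w, n1b)
            x = _layer_norm(x + self._ffn(i, x, params), n2w, n2b)
        return x

    def forward_t(self, tokens, return_hidden: bool = False,
                  dtype=None) -> Tensor:
        """Differentiable forward pass; returns per-token logits (Tensor).

        ``dtype`` casts parameters and activations (half-precision inference
        mode); the default computes in the parameters' native float32.
        """
        c = self.config
        batch = self._as_batch(tokens)
        ids = batch.tokens
        if np.any(ids < 0) or np.any(ids >= c.vocab_size):
            raise ValueError("token id out of vocabulary range")
        if c.positional_mode == "learned":
            too_long = batch.lengths > c.max_positions
            if np.any(too_long):
                worst = int(batch.lengths.max())
                raise ValueError(
                    f"sequence of {worst} tokens exceeds max_positions="
                    f"{c.max_positions} in learned positional mode; truncate "
                    "explicitly (e.g. variant-centered truncation) before inference")

        params = self.params
        if dtype is not None:
            params = {name: Tensor(p.data.astype(dtype), requires_grad=False)
                      for name, p in params.items()}

        positions = packed_positions(batch.boundaries)
        allowed = block_diagonal_mask(batch.boundaries)

        x = take_rows(params["embed_tokens.weight"], ids)
        if c.positional_mode == "learned":
            x = x + take_rows(params["embed_positions.weight"], positions + POSITION_OFFSET)
        for i in range(c.num_layers):
            x = self._block(i, x, allowed, positions, params)
        x = _layer_norm(x, params["final_norm.weight"], params["final_norm.bias"])
        if return_hidden:
            return x
        head_w = params["embed_tokens.weight"] if c.tie_lm_head else params["lm_head.weight"]
        return x @ head_w.T + params["lm_head.bias"]

    def forward(self, tokens, return_hidden: bool = False, dtype=None) -> np.ndarray:
        """Inference forward pass; returns a numpy array."""
        return self.forward_t(tokens, return_hidden=return_hidden, dtype=dtype).numpy()

    def embed(self, tokens, dtype=None) -> np.ndarray:
        """Final-layer hidden states (after the last norm), [tokens, embed_dim]."""
        return self.forward(tokens, return_hidden=True, dtype=dtype)


def transformer_block(model: ProteinLM, layer: int, x, allowed=None,
                      positions=None):
    """Run one transformer block standalone on embeddings ``x`` [T, d]."""
    xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    if xt.ndim != 2 or xt.shape[1] != model.config.embed_dim:
        raise ValueError("x must be [tokens, embed_dim]")
    T = xt.shape[0]
    if allowed is None:
        allowed = np.ones((T, T), dtype=bool)
    if positions is None:
        positions = np.arange(T)
    out = model._block(layer, xt, np.asarray(allowed, dtype=bool),
                       np.asarray(positions), model.params)
    return out if isinstance(x, Tensor) else out.numpy()


def forward_logits(model: ProteinLM, tokens, dtype=None) -> np.ndarray:
    """Per-token logits over the vocabulary for a token list or PackedBatch."""
    return model.forward(tokens, dtype=dtype)
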