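"""Synthetic protein corpora and tiny randomly initialized models.

The generator emulates the length statistics of a real proteome: log-normal
lengths with median 414 residues and a heavy right tail placing roughly 12%
of proteins past 1000 residues, clipped to [20, 5000]. Residues are i.i.d.
uniform over the 20 canonical amino acids — no homology, composition bias,
or positional structure, which is exactly what makes these corpora useful as
*mechanical* fixtures (packing, batching, scoring plumbing) rather than as
stand-ins for evolutionary sequence data.

Optional per-protein labels come from a known generative model so that
fine-tuning tests can verify parameter recovery: a seeded effect vector is
projected onto amino-acid composition (or onto frozen model embeddings via
:func:`embedding_labels`), standardized to unit variance, and perturbed with
Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import CANONICAL_AA, esm_alphabet
from .autograd import Tensor
from .io import ProteinRecord
from .model import ModelConfig, ProteinLM, POSITION_OFFSET

__all__ = ["FixtureSpec", "synth_proteins", "synth_tiny_model", "init_params",
           "tiny_config", "embedding_labels"]

# Log-normal sigma chosen so P(length > 1000) ≈ 0.12 at median 414:
# ln(1000/414) / Phi^{-1}(0.88) ≈ 0.75.
_DEFAULT_SIGMA = 0.75


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible synthetic corpus."""

    n_proteins: int = 500
    median_length: float = 414.0
    sigma_log: float = _DEFAULT_SIGMA
    min_length: int = 20
    max_length: int = 5000
    seed: int = 0
    label_model: str = "none"        # "none" | "linear-regression" | "logistic"
    noise_sigma: float = 0.1

    def __post_init__(self):
        if self.n_proteins <= 0 or self.median_length <= 0:
            raise ValueError("counts and lengths must be positive")
        if self.label_model not in ("none", "linear-regression", "logistic"):
            raise ValueError(f"unknown label model {self.label_model!r}")


def _composition(records: list[ProteinRecord]) -> np.ndarray:
    aa_index = {aa: i for i, aa in enumerate(CANONICAL_AA)}
    out = np.zeros((len(records), 20))
    for r, rec in enumerate(records):
        for ch in rec.sequence:
            out[r, aa_index[ch]] += 1
        out[r] /= len(rec.sequence)
    return out


def synth_proteins(spec: FixtureSpec):
    """Generate a corpus; returns (records, labels-or-None, meta dict).

    Labels: the seeded effect vector w is projected onto amino-acid
    composition, the projection standardized to unit variance across the
    corpus, then noise N(0, noise_sigma²) is added (linear-regression) or the
    standardized score is passed through a sigmoid to draw Bernoulli labels
    (logistic). ``meta`` records w and the noiseless scores.
    """
    rng = np.random.default_rng(spec.seed)
    mu = np.log(spec.median_length)
    lengths = np.clip(
        np.rint(rng.lognormal(mu, spec.sigma_log, size=spec.n_proteins)).astype(int),
        spec.min_length, spec.max_length)
    aa = np.array(list(CANONICAL_AA))
    records = [
        ProteinRecord(id=f"prot{i:05d}", sequence="".join(rng.choice(aa, size=n)))
        for i, n in enumerate(lengths)
    ]
    meta: dict = {"lengths": lengths}
    labels = None
    if spec.label_model != "none":
        w = rng.normal(size=20)
        score = _composition(records) @ w
        z = (score - score.mean()) / score.std()
        meta["effect_vector"] = w
        meta["signal"] = z
        if spec.label_model == "linear-regression":
            labels = z + rng.normal(0.0, spec.noise_sigma, size=len(z))
        else:
            p = 1.0 / (1.0 + np.exp(-2.0 * z))
            labels = (rng.random(len(z)) < p).astype(int)
    return records, labels, meta


def embedding_labels(model: ProteinLM, records, seed: int = 0,
                     sigma: float = 0.1, max_tokens: int = 1024):
    """Labels y = w · mean-pooled-embedding, standardized, plus N(0, sigma²).

    The generating projection lives in the frozen model's embedding space, so
    a head trained on those embeddings can recover it; returns (y, w, z)."""
    from .heads import mean_pool, strip_special_tokens
    from .packing import pack, plan_token_batches

    rng = np.random.default_rng(seed)
    token_lists = [model.alphabet.encode(r.sequence) for r in records]
    plan = plan_token_batches([len(t) for t in token_lists], max_tokens, seed=0)
    feats = np.empty((len(records), model.config.embed_dim), dtype=np.float64)
    for batch_idx in plan.batches:
        packed = pack([token_lists[i] for i in batch_idx])
        hidden = model.embed(packed)
        res, bounds = strip_special_tokens(hidden, packed)
        feats[list(batch_idx)] = mean_pool(res, bounds)
    w = rng.normal(size=model.config.embed_dim)
    score = feats @ w
    z = (score - score.mean()) / score.std()
    y = z + rng.normal(0.0, sigma, size=len(z))
    return y.astype(np.float64), w, z


def tiny_config(positional_mode: str = "rotary", **overrides) -> ModelConfig:
    """The default 2-layer, 64-dim, 4-head fixture architecture."""
    base = dict(num_layers=2, embed_dim=64, num_heads=4, ffn_dim=128,
                vocab_size=33, max_positions=1024,
                positional_mode=positional_mode,
                activation="gelu", norm_style="post")
    base.update(overrides)
    # the SwiGLU variant conventionally pairs with pre-layer-norm
    if base["activation"] == "swiglu" and "norm_style" not in overrides:
        base["norm_style"] = "pre"
    return ModelConfig(**base)


def init_params(config: ModelConfig, seed: int = 0) -> dict[str, Tensor]:
    """Seeded random initialization: N(0, 0.02) weights, zero biases, unit norms."""
    rng = np.random.default_rng(seed)

    def w(*shape):
        return Tensor(rng.normal(0.0, 0.02, size=shape).astype(np.float32))

    def zeros(*shape):
        return Tensor(np.zeros(shape, dtype=np.float32))

    def ones(*shape):
        return Tensor(np.ones(shape, dtype=np.float32))

    d = config.embed_dim
    params: dict[str, Tensor] = {"embed_tokens.weight": w(config.vocab_size, d)}
    if config.positional_mode == "learned":
        params["embed_positions.weight"] = w(config.max_positions + POSITION_OFFSET, d)
    fc1_out = 2 * config.ffn_dim if config.activation == "swiglu" else config.ffn_dim
    for i in range(config.num_layers):
        p = f"layers.{i}."
        for proj in ("q", "k", "v", "out"):
            params[p + f"attn.{proj}.weight"] = w(d, d)
            params[p + f"attn.{proj}.bias"] = zeros(d)
        params[p + "ffn.fc1.weight"] = w(fc1_out, d)
        params[p + "ffn.fc1.bias"] = zeros(fc1_out)
        params[p + "ffn.fc2.weight"] = w(d, config.ffn_dim)
        params[p + "ffn.fc2.bias"] = zeros(d)
        for norm in ("norm1", "norm2"):
            params[p + norm + ".weight"] = ones(d)
            params[p + norm + ".bias"] = zeros(d)
    params["final_norm.weight"] = ones(d)
    params["final_norm.bias"] = zeros(d)
    if not config.tie_lm_head:
        params["lm_head.weight"] = w(config.vocab_size, d)
    params["lm_head.bias"] = zeros(config.vocab_size)
    return params


def synth_tiny_model(config: ModelConfig | None = None, seed: int = 0) -> ProteinLM:
    """A seeded, randomly initialized fixture model (2 layers / 64 dim / 4 heads
    by default)."""
    config = config or tiny_config()
    return ProteinLM(config, init_params(config, seed), esm_alphabet())
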