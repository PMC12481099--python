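"""Optimization loops: masked-LM training, positional-embedding extension,
and head/LoRA fine-tuning.

Defaults follow the reference training protocol: Adam with learning rate
1e-4 and momentum parameters (0.9, 0.999), the learning rate reduced by 10%
every 10 epochs over 100 epochs, minibatches of 50,000 tokens with 16 steps
of gradient accumulation, and 15% of input tokens masked for the
masked-language-model objective. Masking replaces selected residues with the
mask token outright; the BERT-style 80/10/10 split is available behind a
flag. All loops are deterministic for a given seed, and in head-only or
LoRA mode every base weight is bitwise invariant across the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Tensor, segment_mean
from .heads import (AttentionPooling, RegressionHead, mean_pool,
                    strip_special_tokens, upsample_positive)
from .model import ProteinLM
from .packing import PackedBatch, pack, plan_token_batches
from .metrics import spearman, auroc, auprc

__all__ = ["TrainConfig", "Adam", "masked_lm_loss", "train_masked_lm",
           "extend_positional", "finetune", "FinetuneResult",
           "training_time_budget", "lr_at_epoch"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; serializable to/from YAML.

    ``activation_checkpointing`` and ``cpu_offload`` are accepted for config
    compatibility: the numpy engine already computes and updates on the CPU,
    so both are no-ops here and training output is identical either way.
    """

    lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    lr_decay: float = 0.9          # multiplicative, applied every `decay_every` epochs
    decay_every: int = 10
    epochs: int = 100
    minibatch_tokens: int = 50_000
    grad_accum_steps: int = 16
    mask_rate: float = 0.15
    seed: int = 0
    loss: str = "mse"              # "mse" | "bce" | "mlm_ce"
    bert_style: bool = False
    val_fraction: float = 0.01
    activation_checkpointing: bool = False
    cpu_offload: bool = False

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "betas" in raw:
            raw["betas"] = tuple(raw["betas"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict
        d = asdict(self)
        d["betas"] = list(d["betas"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def __post_init__(self):
        if not 0 < self.mask_rate < 1:
            raise ValueError("mask_rate must be in (0, 1)")
        for name in ("epochs", "minibatch_tokens", "grad_accum_steps", "decay_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.loss not in ("mse", "bce", "mlm_ce"):
            raise ValueError(f"unknown loss {self.loss!r}")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Learning rate in force during 1-based ``epoch``: decayed ×0.9 at
    epochs 10, 20, ... (so epoch 25 runs at lr·0.9²)."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    return config.lr * config.lr_decay ** (epoch // config.decay_every)


class Adam:
    """Adam over a named dict of Tensors, with bias correction."""

    def __init__(self, params: dict[str, Tensor], betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self, lr: float):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            mhat = self._m[k] / (1 - self.b1 ** self.t)
            vhat = self._v[k] / (1 - self.b2 ** self.t)
            p.data = (p.data - lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)


# ---------------------------------------------------------------------------
# Masked-LM objective
# ---------------------------------------------------------------------------

def _log_softmax_t(z: Tensor) -> Tensor:
    m = z.data.max(axis=-1, keepdims=True)   # detached shift
    return (z - m) - (z - m).exp().sum(axis=-1, keepdims=True).log()


def masked_lm_loss(model: ProteinLM, batch: PackedBatch, mask_rate: float = 0.15,
                   seed: int = 0, bert_style: bool = False,
                   rng: np.random.Generator | None = None):
    """Cross-entropy over independently masked residue positions.

    Each residue token is masked with probability ``mask_rate`` (at least one
    forced); cls/eos (and any pad) are never masked, and the loss sums only
    over masked positions. Returns (loss Tensor, masked token indices).
    """
    alpha = model.alphabet
    rng = rng or np.random.default_rng(seed)
    tokens = batch.tokens
    special = {alpha.cls_id, alpha.eos_id, alpha.pad_id, alpha.mask_id}
    candidates = np.flatnonzero(~np.isin(tokens, list(special)))
    picked = candidates[rng.random(len(candidates)) < mask_rate]
    if len(picked) == 0:
        picked = rng.choice(candidates, size=1)

    corrupted = tokens.copy()
    if bert_style:
        u = rng.random(len(picked))
        residues = np.array(alpha.residue_ids)
        corrupted[picked[u < 0.8]] = alpha.mask_id
        rand_sel = picked[(u >= 0.8) & (u < 0.9)]
        corrupted[rand_sel] = rng.choice(residues, size=len(rand_sel))
        # remaining 10%: left unchanged
    else:
        corrupted[picked] = alpha.mask_id

    logits = model.forward_t(PackedBatch(corrupted, batch.boundaries))
    logp = _log_softmax_t(logits[picked])
    true = logp[np.arange(len(picked)), tokens[picked]]
    loss = -true.mean()
    return loss, picked


def train_masked_lm(model: ProteinLM, sequences, steps: int,
                    config: TrainConfig | None = None,
                    trainable: set[str] | None = None) -> list[float]:
    """Run ``steps`` masked-LM optimization steps on a fixed corpus.

    ``sequences`` are amino-acid strings; ``trainable`` restricts which base
    parameters receive updates (None trains everything). Returns the loss
    history. Sized for tiny fixture models: each step evaluates one packed
    batch drawn round-robin from the token-budget plan.
    """
    config = config or TrainConfig()
    token_lists = [model.alphabet.encode(s) for s in sequences]
    lengths = [len(t) for t in token_lists]
    plan = plan_token_batches(lengths, config.minibatch_tokens, seed=config.seed)
    model.set_trainable(trainable)
    opt = Adam(model.trainable_parameters(), betas=config.betas)
    rng = np.random.default_rng(config.seed)
    history = []
    for step in range(steps):
        batch_idx = plan.batches[step % plan.n_batches]
        packed = pack([token_lists[i] for i in batch_idx])
        loss, _ = masked_lm_loss(model, packed, config.mask_rate,
                                 bert_style=config.bert_style, rng=rng)
        opt.zero_grad()
        loss.backward()
        opt.step(config.lr)
        history.append(float(loss.data))
    return history


# ---------------------------------------------------------------------------
# Positional-embedding extension
# ---------------------------------------------------------------------------

def extend_positional(model: ProteinLM, new_max: int, corpus=None,
                      config: TrainConfig | None = None, steps: int = 0,
                      seed: int = 0):
    """Extend a learned positional table to ``new_max`` positions and retrain
    only that table.

    Rows up to the old maximum are copied; new rows are seeded N(0, 0.02).
    Every other weight is frozen, so the report's trainable-parameter count
    is exactly the new table's size ((new_max + 2) rows × embed_dim). With a
    ``corpus`` of sequences and ``steps`` > 0, the table is trained with the
    masked-LM objective, holding out ``val_fraction`` of the corpus.
    """
    from .model import POSITION_OFFSET

    c = model.config
    if c.positional_mode != "learned":
        raise ValueError("positional extension applies to learned positions only")
    if new_max <= c.max_positions:
        raise ValueError(f"new_max ({new_max}) must exceed current max ({c.max_positions})")

    rng = np.random.default_rng(seed)
    old = model.params["embed_positions.weight"].data
    table = rng.normal(0.0, 0.02, size=(new_max + POSITION_OFFSET, c.embed_dim)).astype(old.dtype)
    table[: old.shape[0]] = old

    new_config = replace_config(c, max_positions=new_max)
    new_params = {k: Tensor(p.data.copy()) for k, p in model.params.items()}
    new_params["embed_positions.weight"] = Tensor(table, requires_grad=True)
    extended = ProteinLM(new_config, new_params, model.alphabet)
    extended.set_trainable({"embed_positions.weight"})

    report = {
        "trainable_parameters": int(table.size),
        "frozen_parameters": int(extended.num_parameters() - table.size),
        "old_max_positions": int(c.max_positions),
        "new_max_positions": int(new_max),
        "val_loss": [],
        "train_loss": [],
    }
    if corpus and steps > 0:
        config = config or TrainConfig()
        n_val = max(1, int(round(config.val_fraction * len(corpus))))
        val, train = list(corpus[:n_val]), list(corpus[n_val:])
        report["train_loss"] = train_masked_lm(
            extended, train, steps, config, trainable={"embed_positions.weight"})
        val_tokens = pack([extended.alphabet.encode(s) for s in val])
        vloss, _ = masked_lm_loss(extended, val_tokens, config.mask_rate,
                                  seed=config.seed + 1)
        report["val_loss"] = [float(vloss.data)]
    return extended, report


def replace_config(config, **kw):
    return replace(config, **kw)


# ---------------------------------------------------------------------------
# Head / LoRA fine-tuning
# ---------------------------------------------------------------------------

@dataclass
class FinetuneResult:
    head: RegressionHead
    pooling: AttentionPooling | None
    model: ProteinLM
    log: list[dict] = field(default_factory=list)

    def predict(self, sequences) -> np.ndarray:
        feats = _pooled_features(self.model, sequences, self.pooling)
        return self.head(feats)[:, 0]

    def log_frame(self):
        import pandas as pd
        return pd.DataFrame(self.log)


def _pooled_features(model: ProteinLM, sequences, pooling, max_tokens: int = 1024,
                     as_tensor: bool = False):
    """Pooled per-protein representations, computed over packed batches."""
    token_lists = [model.alphabet.encode(s) for s in sequences]
    plan = plan_token_batches([len(t) for t in token_lists], max_tokens, seed=0)
    dim = model.config.embed_dim * (pooling.n_class_tokens if pooling else 1)
    feats = np.empty((len(sequences), dim), dtype=np.float32)
    for batch_idx in plan.batches:
        packed = pack([token_lists[i] for i in batch_idx])
        hidden = model.embed(packed)
        res, bounds = strip_special_tokens(hidden, packed)
        pooled = pooling(res, bounds) if pooling else mean_pool(res, bounds)
        feats[list(batch_idx)] = pooled
    return feats


def _softplus_neg(z: Tensor) -> Tensor:
    """Numerically stable log(1 + exp(-z)) via log-sum-exp with 0."""
    m = np.maximum(0.0, -z.data)                     # detached pivot
    return (((-z) - m).exp() + (-Tensor(m)).exp()).log() + m


def finetune(model: ProteinLM, dataset, config: TrainConfig | None = None,
             task: str = "regression", pooling: str = "mean",
             mode: str = "head-only", lora_rank: int = 16,
             lora_targets=("q", "v", "out"), head_hidden: int = 256,
             max_tokens: int | None = None, checkpoint_dir=None,
             checkpoint_every: int = 0) -> FinetuneResult:
    """Fine-tune a task head (and optionally LoRA adapters) on labeled proteins.

    ``dataset`` is (train_sequences, train_labels, val_sequences, val_labels).
    The schedule applies the configured decay (×lr_decay every
    ``decay_every`` epochs); minibatches are planned to ``minibatch_tokens``
    tokens and parameters update every ``grad_accum_steps`` minibatches.
    Head-only mode freezes the base model and precomputes embeddings once;
    LoRA mode backpropagates through the adapted transformer each step.
    Per-epoch losses and validation metrics are returned in ``result.log``.
    """
    from . import peft

    config = config or TrainConfig(loss="mse" if task == "regression" else "bce")
    if task not in ("regression", "binary"):
        raise ValueError(f"unknown task {task!r}")
    train_seqs, train_y, val_seqs, val_y = dataset
    if len(train_seqs) == 0 or len(val_seqs) == 0:
        raise ValueError("empty train or validation split")
    train_y = np.asarray(train_y, dtype=np.float32)
    val_y = np.asarray(val_y, dtype=np.float32)

    pool_obj = None
    if pooling == "attention":
        pool_obj = AttentionPooling(model.config.embed_dim, seed=config.seed)
    elif pooling != "mean":
        raise ValueError(f"unknown pooling {pooling!r}")

    head = RegressionHead(model.config.embed_dim * (pool_obj.n_class_tokens if pool_obj else 1),
                          hidden=head_hidden, seed=config.seed)

    use_lora = mode == "lora"
    if mode not in ("head-only", "lora"):
        raise ValueError(f"unknown mode {mode!r}")
    if use_lora:
        peft.attach(model, rank=lora_rank, targets=lora_targets, seed=config.seed)
    else:
        model.freeze()

    trainables: dict[str, Tensor] = dict(head.params)
    if pool_obj is not None:
        trainables.update({f"pool.{k}": v for k, v in pool_obj.params.items()})
    if use_lora:
        trainables.update({k: v for k, v in model.trainable_parameters().items()
                           if k.startswith("adapters.")})
    opt = Adam(trainables, betas=config.betas)

    token_budget = max_tokens or min(config.minibatch_tokens, 1024)
    token_lists = [model.alphabet.encode(s) for s in train_seqs]
    lengths = np.array([len(t) for t in token_lists])

    # Head-only with a frozen base: per-token hidden states never change, so
    # compute them once instead of re-running the transformer every epoch.
    cached_hidden: list[np.ndarray] | None = None
    if not use_lora:
        cached_hidden = []
        plan0 = plan_token_batches(lengths, token_budget, seed=0)
        store: dict[int, np.ndarray] = {}
        for batch_idx in plan0.batches:
            packed = pack([token_lists[i] for i in batch_idx])
            hidden = model.embed(packed)
            for i, h in zip(batch_idx, (hidden[packed.boundaries[j]:packed.boundaries[j + 1]]
                                        for j in range(packed.n_sequences))):
                store[i] = h
        cached_hidden = [store[i] for i in range(len(train_seqs))]

    # With a frozen base the validation hidden states are constant too.
    cached_val: tuple[np.ndarray, np.ndarray] | None = None
    if not use_lora:
        val_tokens = [model.alphabet.encode(s) for s in val_seqs]
        vplan = plan_token_batches([len(t) for t in val_tokens], token_budget, seed=0)
        vstore: dict[int, np.ndarray] = {}
        for batch_idx in vplan.batches:
            packed = pack([val_tokens[i] for i in batch_idx])
            hidden = model.embed(packed)
            for j, i in enumerate(batch_idx):
                vstore[i] = hidden[packed.boundaries[j]:packed.boundaries[j + 1]]
        rows = [vstore[i] for i in range(len(val_seqs))]
        vbounds = np.concatenate([[0], np.cumsum([len(r) for r in rows])])
        cached_val = (np.concatenate(rows, axis=0), vbounds)

    log: list[dict] = []
    for epoch in range(1, config.epochs + 1):
        lr = lr_at_epoch(config, epoch)
        if task == "binary":
            idx_pool = upsample_positive(train_y, seed=config.seed + epoch)
        else:
            idx_pool = np.arange(len(train_seqs))
        plan = plan_token_batches(lengths[idx_pool], token_budget,
                                  seed=config.seed + epoch)
        epoch_losses = []
        accum = 0
        opt.zero_grad()
        for batch_pos in plan.batches:
            batch_idx = idx_pool[list(batch_pos)]
            y = train_y[batch_idx]
            if use_lora:
                packed = pack([token_lists[i] for i in batch_idx])
                hidden_t = model.forward_t(packed, return_hidden=True)
                res, bounds = _strip_t(hidden_t, packed)
            else:
                rows = [cached_hidden[i] for i in batch_idx]
                packed = pack([token_lists[i] for i in batch_idx])
                hidden_t = Tensor(np.concatenate(rows, axis=0))
                res, bounds = _strip_t(hidden_t, packed)
            pooled = (pool_obj.forward_t(res, bounds) if pool_obj
                      else segment_mean(res, bounds))
            pred = head.forward_t(pooled)[:, 0]
            if task == "regression":
                diff = pred - y
                loss = (diff * diff).mean()
            else:
                loss = _softplus_neg(_signed(pred, y)).mean()
            loss.backward(np.full((), 1.0 / config.grad_accum_steps, dtype=np.float32))
            epoch_losses.append(float(loss.data))
            accum += 1
            if accum == config.grad_accum_steps:
                opt.step(lr)
                opt.zero_grad()
                accum = 0
        if accum:
            opt.step(lr)
            opt.zero_grad()

        if cached_val is not None:
            vh, vb = cached_val
            res_v, bounds_v = _strip_rows(vh, vb)
            feats = pool_obj(res_v, bounds_v) if pool_obj else mean_pool(res_v, bounds_v)
            val_pred = head(np.asarray(feats, dtype=np.float32))[:, 0]
        else:
            val_pred = _predict(model, head, pool_obj, val_seqs, token_budget)
        row = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(epoch_losses))}
        if task == "regression":
            row["val_spearman"] = spearman(val_y, val_pred)
        else:
            probs = 1.0 / (1.0 + np.exp(-val_pred))
            row["val_auroc"] = auroc(val_y, probs)
            row["val_auprc"] = auprc(val_y, probs)
        log.append(row)
        if checkpoint_dir is not None and checkpoint_every \
                and epoch % checkpoint_every == 0:
            _save_checkpoint(checkpoint_dir, epoch, head, pool_obj, model)

    return FinetuneResult(head=head, pooling=pool_obj, model=model, log=log)


def _signed(pred: Tensor, y: np.ndarray) -> Tensor:
    return pred * np.where(y > 0.5, 1.0, -1.0).astype(np.float32)


def _strip_t(hidden: Tensor, packed: PackedBatch):
    b = packed.boundaries
    idx = np.concatenate([np.arange(b[i] + 1, b[i + 1] - 1)
                          for i in range(packed.n_sequences)])
    lengths = np.diff(b) - 2
    new_b = np.concatenate([[0], np.cumsum(lengths)])
    return hidden[idx], new_b


def _strip_rows(hidden: np.ndarray, boundaries: np.ndarray):
    idx = np.concatenate([np.arange(boundaries[i] + 1, boundaries[i + 1] - 1)
                          for i in range(len(boundaries) - 1)])
    lengths = np.diff(boundaries) - 2
    return hidden[idx], np.concatenate([[0], np.cumsum(lengths)])


def _save_checkpoint(directory, epoch, head, pool_obj, model) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {f"head.{k}": t.data for k, t in head.params.items()}
    if pool_obj is not None:
        arrays.update({f"pool.{k}": t.data for k, t in pool_obj.params.items()})
    for name, (a, b, _) in model.adapters.items():
        arrays[f"adapters.{name}.A"] = a.data
        arrays[f"adapters.{name}.B"] = b.data
    np.savez(str(directory / f"checkpoint_epoch{epoch:04d}.npz"), **arrays)


def _predict(model, head, pool_obj, sequences, token_budget) -> np.ndarray:
    feats = _pooled_features(model, sequences, pool_obj, max_tokens=token_budget)
    return head(feats)[:, 0]


# ---------------------------------------------------------------------------
# Epoch-budget arithmetic
# ---------------------------------------------------------------------------

def training_time_budget(steps: int, tokens_per_step: int,
                         corpus_tokens: int) -> tuple[float, int]:
    """Epoch count implied by a step budget: steps × tokens/step ÷ corpus
    tokens, returned as (raw value, nearest integer)."""
    if steps <= 0 or tokens_per_step <= 0:
        raise ValueError("steps and tokens_per_step must be positive")
    if corpus_tokens <= 0:
        raise ValueError("corpus token count must be positive")
    raw = steps * tokens_per_step / corpus_tokens
    return raw, int(round(raw))
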