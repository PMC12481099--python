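"""LoRA: low-rank adaptation of frozen projection layers.

A LoRA adapter augments a frozen projection ``h = W x`` with a trainable
low-rank update ``h = W x + scaling * B (A x)`` where ``A`` is r×m and ``B``
is n×r with rank r much smaller than n and m. ``B`` starts at zero, so a
freshly attached adapter leaves the forward pass bitwise unchanged; training
touches only A and B while every base weight stays frozen. Adapters can be
merged into the base weight (``W + scaling * B A``) or detached and
serialized separately, which makes task-specific adapters shareable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .model import ProteinLM

__all__ = ["LoRAAdapter", "lora_forward", "attach", "merge", "detach",
           "trainable_parameter_count", "DEFAULT_TARGETS"]

DEFAULT_TARGETS = ("q", "v", "out")
_VALID_TARGETS = ("q", "k", "v", "out")


@dataclass
class LoRAAdapter:
    """One low-rank update attached to a named projection layer."""

    A: Tensor            # [r, m] — seeded small random init
    B: Tensor            # [n, r] — zero init
    rank: int
    scaling: float
    target: str          # e.g. "layers.0.attn.q"

    def __post_init__(self):
        n, r_b = self.B.shape
        r_a, m = self.A.shape
        if r_a != self.rank or r_b != self.rank:
            raise ValueError("adapter matrices do not match the declared rank")
        if self.rank > min(n, m):
            raise ValueError(f"rank {self.rank} exceeds min(n, m) = {min(n, m)}")
        if self.scaling <= 0:
            raise ValueError("scaling must be positive")

    @property
    def delta(self) -> np.ndarray:
        """The dense update scaling * B @ A (materialized only on request)."""
        return self.scaling * (self.B.data @ self.A.data)


def lora_forward(W: np.ndarray, adapter: LoRAAdapter, x: np.ndarray) -> np.ndarray:
    """h = W x + scaling * B (A x), computed without materializing B A.

    ``x`` may be a vector [m] or a matrix of row vectors [batch, m]; the
    projection uses the row-vector convention ``x @ W.T``.
    """
    W = np.asarray(W)
    x = np.asarray(x)
    if x.shape[-1] != W.shape[1]:
        raise ValueError(f"input width {x.shape[-1]} does not match W columns {W.shape[1]}")
    base = x @ W.T
    return base + adapter.scaling * ((x @ adapter.A.data.T) @ adapter.B.data.T)


def _target_names(model: ProteinLM, targets) -> list[str]:
    for t in targets:
        if t not in _VALID_TARGETS:
            raise ValueError(f"unknown LoRA target {t!r}; expected subset of {_VALID_TARGETS}")
    return [f"layers.{i}.attn.{t}"
            for i in range(model.config.num_layers) for t in targets]


def attach(model: ProteinLM, rank: int = 16, targets=DEFAULT_TARGETS,
           seed: int = 0, scaling: float = 1.0) -> ProteinLM:
    """Attach fresh LoRA adapters; freezes the base model in place.

    A is drawn N(0, 0.02) from ``seed``; B is zero, so the forward pass is
    unchanged until training moves B. Raises if the model is already adapted.
    """
    if model.adapters:
        raise ValueError("model already has adapters attached; detach or merge first")
    rng = np.random.default_rng(seed)
    model.freeze()
    for name in _target_names(model, targets):
        w = model.params[name + ".weight"].data
        n, m = w.shape
        if rank > min(n, m):
            raise ValueError(f"rank {rank} exceeds projection size {min(n, m)}")
        a = Tensor(rng.normal(0.0, 0.02, size=(rank, m)).astype(w.dtype),
                   requires_grad=True)
        b = Tensor(np.zeros((n, rank), dtype=w.dtype), requires_grad=True)
        model.adapters[name] = (a, b, float(scaling))
    return model


def merge(model: ProteinLM) -> ProteinLM:
    """Fold every adapter into its base weight and drop the adapters."""
    if not model.adapters:
        raise ValueError("merge called on a model with no adapters")
    for name, (a, b, scaling) in model.adapters.items():
        w = model.params[name + ".weight"]
        w.data = (w.data + scaling * (b.data @ a.data)).astype(w.data.dtype)
    model.adapters = {}
    return model


def detach(model: ProteinLM) -> tuple[ProteinLM, dict[str, LoRAAdapter]]:
    """Remove adapters, restoring the base forward pass bitwise."""
    if not model.adapters:
        raise ValueError("detach called on a model with no adapters")
    adapters = {
        name: LoRAAdapter(A=a, B=b, rank=a.shape[0], scaling=scaling, target=name)
        for name, (a, b, scaling) in model.adapters.items()
    }
    model.adapters = {}
    return model, adapters


def reattach(model: ProteinLM, adapters: dict[str, LoRAAdapter]) -> ProteinLM:
    if model.adapters:
        raise ValueError("model already has adapters attached")
    for name, ad in adapters.items():
        model.adapters[name] = (ad.A, ad.B, ad.scaling)
    return model


def trainable_parameter_count(model: ProteinLM) -> int:
    return int(sum(a.data.size + b.data.size for a, b, _ in model.adapters.values()))


def adapter_state(model: ProteinLM) -> dict[str, np.ndarray]:
    """Flat named-tensor view of the adapters (``adapters.{layer}.{A,B}``)."""
    out = {}
    for name, (a, b, scaling) in model.adapters.items():
        out[f"adapters.{name}.A"] = a.data
        out[f"adapters.{name}.B"] = b.data
    return out
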