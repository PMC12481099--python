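"""Model-quality and variant-effect scoring.

Two quantities drive everything here:

* **Pseudo-perplexity** of a sequence x with T residues:
  ``exp((1/T) * sum_t -log p(x_t | x_without_t))``, where each term comes
  from a forward pass with position t replaced by the mask token and all
  other residues intact. Lower is better; a uniform model scores exactly the
  vocabulary size and a perfect model scores 1.

* **Masked-marginal variant score** ``v = log p(alt) - log p(ref)`` read
  from the log-softmax at the masked variant position (natural log, nats).
  Negative v means the model disfavors the substitution.

The T masked copies needed for pseudo-perplexity (and arbitrary variant
tables) are evaluated through sequence packing with token-count batching, so
scoring exercises the exact packed-attention path used everywhere else.
Long proteins in learned-positional mode are truncated by centering the
variant in a fixed-size window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ProteinLM
from .packing import pack, plan_token_batches, unpack

__all__ = ["VariantSpec", "ScoreRecord", "pseudo_perplexity", "masked_margin",
           "truncate_center", "score_variant_table", "masked_log_probs"]


@dataclass(frozen=True)
class VariantSpec:
    """One missense substitution in protein coordinates (1-based)."""

    protein_id: str
    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive, got {self.position}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("ref and alt must be single amino-acid codes")

    def check_against(self, sequence: str) -> None:
        if self.position > len(sequence):
            raise ValueError(
                f"{self.protein_id}: position {self.position} beyond sequence "
                f"length {len(sequence)}")
        observed = sequence[self.position - 1].upper()
        if observed != self.ref.upper():
            raise ValueError(
                f"{self.protein_id}: ref mismatch at position {self.position}: "
                f"expected {self.ref!r}, sequence has {observed!r}")


@dataclass(frozen=True)
class ScoreRecord:
    protein_id: str
    position: int
    ref: str
    alt: str
    score: float    # log p(alt) - log p(ref), nats

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValueError("variant score must be finite")


def _log_softmax64(logits: np.ndarray) -> np.ndarray:
    """Row-wise log-softmax accumulated in float64 (log-sum-exp form)."""
    z = np.asarray(logits, dtype=np.float64)
    m = z.max(axis=-1, keepdims=True)
    return z - (m + np.log(np.exp(z - m).sum(axis=-1, keepdims=True)))


def _masked_copies(model: ProteinLM, sequence: str):
    """Token lists for T copies of `sequence`, copy t masked at residue t."""
    alpha = model.alphabet
    base = np.asarray(alpha.encode(sequence), dtype=np.int64)
    T = len(sequence)
    copies = np.tile(base, (T, 1))
    residue_axis = np.arange(T)
    copies[residue_axis, residue_axis + 1] = alpha.mask_id   # +1 skips cls
    return base, copies


def pseudo_perplexity(model: ProteinLM, sequence: str,
                      max_tokens: int = 2048, dtype=None) -> float:
    """Pseudo-perplexity of one sequence under the model.

    Each residue position is masked separately; the masked copies are packed
    into token-budgeted batches and evaluated together. Only residue
    positions enter the average (cls/eos are never masked or scored).
    """
    if not sequence:
        raise ValueError("cannot score an empty sequence")
    base, copies = _masked_copies(model, sequence)
    T = len(sequence)
    lengths = np.full(T, len(base))
    plan = plan_token_batches(lengths, max_tokens, seed=0)
    nll = np.empty(T, dtype=np.float64)
    for batch_idx in plan.batches:
        packed = pack([copies[i] for i in batch_idx])
        logits = model.forward(packed, dtype=dtype)
        per_seq = unpack(packed, logits)
        for i, seq_logits in zip(batch_idx, per_seq):
            logp = _log_softmax64(seq_logits[i + 1])
            nll[i] = -logp[base[i + 1]]
    return float(np.exp(nll.mean()))


def masked_log_probs(model: ProteinLM, sequence: str, position: int,
                     dtype=None) -> np.ndarray:
    """Log-softmax over the vocabulary at a masked 1-based residue position."""
    alpha = model.alphabet
    tokens = np.asarray(alpha.encode(sequence), dtype=np.int64)
    tokens[position] = alpha.mask_id   # token index = residue position (cls at 0)
    logits = model.forward(tokens, dtype=dtype)
    return _log_softmax64(logits[position])


def masked_margin(model: ProteinLM, sequence: str, variant: VariantSpec,
                  dtype=None) -> ScoreRecord:
    """Score one substitution: mask the site, run forward once, take
    ``log p(alt) - log p(ref)`` from the masked position's log-softmax."""
    variant.check_against(sequence)
    alpha = model.alphabet
    logp = masked_log_probs(model, sequence, variant.position, dtype=dtype)
    v = logp[alpha.id_of(variant.alt.upper())] - logp[alpha.id_of(variant.ref.upper())]
    return ScoreRecord(variant.protein_id, variant.position, variant.ref,
                       variant.alt, float(v))


def truncate_center(sequence: str, position: int, window: int) -> tuple[str, int]:
    """Contiguous window of at most ``window`` residues centered on ``position``.

    Returns (subsequence, new 1-based position). When both flanks overflow,
    the variant lands at position ``window // 2`` (ties toward the left
    flank); window-clipping at either end shifts it accordingly. Sequences
    already within the window are returned unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    n = len(sequence)
    if n <= window:
        return sequence, position
    pos0 = position - 1
    start = min(max(pos0 - (window // 2 - 1), 0), n - window)
    return sequence[start:start + window], position - start


def score_variant_table(model: ProteinLM, sequences: dict[str, str],
                        variants: list[VariantSpec], max_tokens: int = 2048,
                        window: int | None = None, dtype=None) -> list[ScoreRecord]:
    """Score a table of variants in packed, token-budgeted batches.

    Output preserves input order and is independent of the batch plan. A
    ``window`` (or a learned-positional length limit) triggers
    variant-centered truncation per variant. Missing proteins are reported
    together in one error.
    """
    missing = sorted({v.protein_id for v in variants} - set(sequences))
    if missing:
        raise KeyError(f"variants reference proteins absent from FASTA: {', '.join(missing)}")

    alpha = model.alphabet
    if window is None and model.config.positional_mode == "learned":
        window = model.config.max_positions - 2   # room for cls/eos

    # One forward per unique masked (sequence, site): duplicate variant rows
    # reuse the same masked log-softmax, so they score exactly identically.
    prepared: list[tuple[np.ndarray, int]] = []   # (masked token array, site index)
    unique: dict[tuple, int] = {}
    row_to_forward: list[int] = []
    row_ids: list[tuple[int, int]] = []           # (ref id, alt id) per row
    for v in variants:
        seq = sequences[v.protein_id]
        v.check_against(seq)
        pos = v.position
        if window is not None and len(seq) > window:
            seq, pos = truncate_center(seq, pos, window)
        key = (v.protein_id, seq, pos)
        if key not in unique:
            tokens = np.asarray(alpha.encode(seq), dtype=np.int64)
            tokens[pos] = alpha.mask_id
            unique[key] = len(prepared)
            prepared.append((tokens, pos))
        row_to_forward.append(unique[key])
        row_ids.append((alpha.id_of(v.ref.upper()), alpha.id_of(v.alt.upper())))

    site_logp = [None] * len(prepared)
    if prepared:
        lengths = [len(t) for t, _ in prepared]
        plan = plan_token_batches(lengths, max_tokens, seed=0)
        for batch_idx in plan.batches:
            packed = pack([prepared[i][0] for i in batch_idx])
            logits = model.forward(packed, dtype=dtype)
            per_seq = unpack(packed, logits)
            for i, seq_logits in zip(batch_idx, per_seq):
                site_logp[i] = _log_softmax64(seq_logits[prepared[i][1]])

    records = []
    for v, fwd, (ref_id, alt_id) in zip(variants, row_to_forward, row_ids):
        logp = site_logp[fwd]
        records.append(ScoreRecord(v.protein_id, v.position, v.ref, v.alt,
                                   float(logp[alt_id] - logp[ref_id])))
    return records
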