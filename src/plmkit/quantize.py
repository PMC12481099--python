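"""Blockwise weight quantization for inference.

Three techniques, applied independently per weight tensor:

* 8-bit absmax quantization: each block of ``block_size`` values is scaled by
  its absolute maximum and rounded to the signed-int8 grid (±127).
* 4-bit NormalFloat (NF4): values are snapped to a 16-level codebook built
  from evenly spaced quantiles of the standard normal (normalized to [-1, 1]
  and containing 0), which matches the near-normal distribution of trained
  network weights better than a uniform grid. Per-block absmax constants can
  themselves be quantized to 8 bits ("double quantization").
* Outlier decomposition: rare large-magnitude *columns* are held out of
  quantization entirely and stored sparsely at full precision, so they do not
  inflate the block scales.

Quantization here is inference-only: quantized tensors are dequantized before
matmul (there are no fused low-bit kernels), so the value of the technique is
the storage accounting, which ``QuantizedTensor.stored_bytes`` makes exact —
4-bit codes really are packed two to a byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm

__all__ = ["QuantizedTensor", "DoubleQuantizedConstants", "nf4_codebook",
           "quantize_absmax8", "quantize_nf4", "double_quantize_constants",
           "dequantize_constants", "decompose_outliers", "dequantize",
           "quantize_model_weights"]


@lru_cache(maxsize=1)
def nf4_codebook() -> np.ndarray:
    """The 16-level NormalFloat codebook: sorted, in [-1, 1], containing 0.

    Levels are evenly spaced quantiles of N(0, 1) (8 negative, zero, 7
    positive), normalized so the endpoints are exactly ±1.
    """
    offset = 0.5 * (1 / 32 + 1 / 30)
    neg = norm.ppf(np.linspace(offset, 0.5, 9))[:-1]
    pos = -norm.ppf(np.linspace(offset, 0.5, 8))[:-1][::-1]
    levels = np.concatenate([neg, [0.0], pos])
    levels = levels / np.abs(levels).max()
    return np.ascontiguousarray(levels, dtype=np.float64)


@dataclass(frozen=True)
class DoubleQuantizedConstants:
    """Per-block absmax constants, themselves 8-bit absmax-quantized.

    The constants are mean-shifted (they are all positive) before the
    second-level quantization so the int8 grid is centered.
    """

    codes: np.ndarray        # int8, one per first-level block
    absmax2: np.ndarray      # float32, one per second-level block
    mean: float
    block_size2: int

    def stored_bytes(self) -> int:
        return int(self.codes.size + self.absmax2.size * 4 + 4)


@dataclass(frozen=True)
class QuantizedTensor:
    """A blockwise-quantized weight tensor plus everything needed to invert it."""

    codes: np.ndarray                 # int8 (8-bit) or nibble-packed uint8 (4-bit)
    absmax: np.ndarray | DoubleQuantizedConstants
    block_size: int
    bits: int                         # 8 or 4
    shape: tuple[int, ...]
    dtype: np.dtype
    codebook: np.ndarray | None = None
    outlier_indices: np.ndarray | None = None   # held-out column indices
    outlier_values: np.ndarray | None = None    # [rows, n_outlier_cols], original dtype

    def __post_init__(self):
        if self.bits not in (8, 4):
            raise ValueError("bits must be 8 or 4")
        n = int(np.prod(self.shape))
        n_inlier = n if self.outlier_indices is None else (
            n - self.shape[0] * len(self.outlier_indices))
        expect_codes = n_inlier if self.bits == 8 else (n_inlier + 1) // 2
        if self.codes.size != expect_codes:
            raise ValueError(
                f"corrupted code array: {self.codes.size} codes for {n_inlier} values")
        n_blocks = -(-n_inlier // self.block_size) if n_inlier else 0
        stored_blocks = (self.absmax.codes.size
                         if isinstance(self.absmax, DoubleQuantizedConstants)
                         else self.absmax.size)
        if stored_blocks != n_blocks:
            raise ValueError(f"corrupted block count: {stored_blocks} != {n_blocks}")

    def stored_bytes(self) -> int:
        """Exact bytes of the quantized representation (codes + constants)."""
        total = int(self.codes.size * self.codes.itemsize)
        if isinstance(self.absmax, DoubleQuantizedConstants):
            total += self.absmax.stored_bytes()
        else:
            total += int(self.absmax.size * 4)
        if self.codebook is not None:
            total += int(self.codebook.size * 4)
        if self.outlier_values is not None:
            total += int(self.outlier_values.nbytes + self.outlier_indices.nbytes)
        return total


def _blockwise_absmax(flat: np.ndarray, block_size: int) -> np.ndarray:
    n = flat.size
    n_blocks = -(-n // block_size)
    padded = np.zeros(n_blocks * block_size, dtype=np.float64)
    padded[:n] = np.abs(flat)
    return padded.reshape(n_blocks, block_size).max(axis=1)


def _expand_constants(absmax: np.ndarray, n: int, block_size: int) -> np.ndarray:
    return np.repeat(absmax, block_size)[:n]


def quantize_absmax8(W: np.ndarray, block_size: int = 2048) -> QuantizedTensor:
    """Blockwise signed-int8 absmax quantization."""
    W = np.asarray(W)
    if not np.all(np.isfinite(W)):
        raise ValueError("cannot quantize non-finite weights")
    flat = W.reshape(-1).astype(np.float64)
    absmax = _blockwise_absmax(flat, block_size)
    scale = _expand_constants(absmax, flat.size, block_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = np.where(scale > 0, flat / np.where(scale > 0, scale, 1.0), 0.0)
    codes = np.rint(normed * 127.0).astype(np.int8)
    return QuantizedTensor(codes=codes, absmax=absmax.astype(np.float32),
                           block_size=block_size, bits=8, shape=W.shape, dtype=W.dtype)


def _pack_nibbles(idx: np.ndarray) -> np.ndarray:
    if idx.size % 2:
        idx = np.concatenate([idx, [0]])
    return ((idx[0::2] << 4) | idx[1::2]).astype(np.uint8)


def _unpack_nibbles(packed: np.ndarray, n: int) -> np.ndarray:
    out = np.empty(packed.size * 2, dtype=np.uint8)
    out[0::2] = packed >> 4
    out[1::2] = packed & 0x0F
    return out[:n]


def quantize_nf4(W: np.ndarray, block_size: int = 64,
                 double_quant: bool = False,
                 dq_block_size: int = 256) -> QuantizedTensor:
    """Blockwise 4-bit NormalFloat quantization, optionally double-quantized."""
    W = np.asarray(W)
    if not np.all(np.isfinite(W)):
        raise ValueError("cannot quantize non-finite weights")
    book = nf4_codebook()
    mids = (book[:-1] + book[1:]) / 2.0
    flat = W.reshape(-1).astype(np.float64)
    absmax = _blockwise_absmax(flat, block_size)
    scale = _expand_constants(absmax, flat.size, block_size)
    normed = np.where(scale > 0, flat / np.where(scale > 0, scale, 1.0), 0.0)
    idx = np.searchsorted(mids, normed).astype(np.uint8)
    constants: np.ndarray | DoubleQuantizedConstants = absmax.astype(np.float32)
    if double_quant:
        constants = double_quantize_constants(absmax.astype(np.float32), dq_block_size)
    return QuantizedTensor(codes=_pack_nibbles(idx), absmax=constants,
                           block_size=block_size, bits=4, shape=W.shape,
                           dtype=W.dtype, codebook=book.astype(np.float32))


def double_quantize_constants(absmax: np.ndarray,
                              block_size2: int = 256) -> DoubleQuantizedConstants:
    """8-bit absmax quantization of the (mean-shifted) block constants."""
    absmax = np.asarray(absmax, dtype=np.float64).reshape(-1)
    if absmax.size == 0:
        raise ValueError("empty constant array")
    mean = float(absmax.mean())
    shifted = absmax - mean
    absmax2 = _blockwise_absmax(shifted, block_size2)
    scale = _expand_constants(absmax2, shifted.size, block_size2)
    codes = np.rint(np.where(scale > 0, shifted / np.where(scale > 0, scale, 1.0), 0.0)
                    * 127.0).astype(np.int8)
    return DoubleQuantizedConstants(codes=codes, absmax2=absmax2.astype(np.float32),
                                    mean=mean, block_size2=block_size2)


def dequantize_constants(dq: DoubleQuantizedConstants) -> np.ndarray:
    scale = _expand_constants(dq.absmax2.astype(np.float64), dq.codes.size, dq.block_size2)
    return (dq.codes.astype(np.float64) / 127.0) * scale + dq.mean


def decompose_outliers(W: np.ndarray, threshold: float = 6.0):
    """Split a 2-D weight matrix into an inlier part and sparse outlier columns.

    Any column containing an entry with ``|w| > threshold`` is moved, at the
    input's own precision, to the sparse part; the inlier matrix has those
    columns zeroed. ``inlier + scatter(outliers)`` reproduces ``W`` exactly.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    W = np.asarray(W)
    if W.ndim != 2:
        raise ValueError("outlier decomposition operates on 2-D matrices")
    col_mask = (np.abs(W) > threshold).any(axis=0)
    cols = np.flatnonzero(col_mask)
    inlier = W.copy()
    inlier[:, cols] = 0
    return inlier, cols, W[:, cols].copy()


def reassemble(inlier: np.ndarray, outlier_indices: np.ndarray,
               outlier_values: np.ndarray) -> np.ndarray:
    out = inlier.copy()
    out[:, outlier_indices] = outlier_values
    return out


def quantize_with_outliers(W: np.ndarray, threshold: float = 6.0,
                           block_size: int = 2048) -> QuantizedTensor:
    """LLM.int8-style mixed precision: quantize inliers, hold out outlier columns."""
    inlier, cols, vals = decompose_outliers(W, threshold)
    kept = np.delete(np.asarray(inlier), cols, axis=1)
    qt = quantize_absmax8(kept, block_size)
    return QuantizedTensor(codes=qt.codes, absmax=qt.absmax, block_size=block_size,
                           bits=8, shape=W.shape, dtype=np.asarray(W).dtype,
                           outlier_indices=cols, outlier_values=vals)


def dequantize(qt: QuantizedTensor) -> np.ndarray:
    """Invert quantization back to a dense array of the original shape/dtype."""
    if qt.outlier_indices is not None and len(qt.outlier_indices):
        inner_cols = qt.shape[1] - len(qt.outlier_indices)
        inner_shape: tuple[int, ...] = (qt.shape[0], inner_cols)
    else:
        inner_shape = qt.shape
    n = int(np.prod(inner_shape))
    if isinstance(qt.absmax, DoubleQuantizedConstants):
        absmax = dequantize_constants(qt.absmax)
    else:
        absmax = qt.absmax.astype(np.float64)
    scale = _expand_constants(absmax, n, qt.block_size)
    if qt.bits == 8:
        flat = qt.codes.astype(np.float64) / 127.0 * scale
    else:
        idx = _unpack_nibbles(qt.codes, n)
        flat = qt.codebook.astype(np.float64)[idx] * scale
    dense = flat.reshape(inner_shape)
    if qt.outlier_indices is not None and len(qt.outlier_indices):
        out = np.empty(qt.shape, dtype=np.float64)
        keep = np.setdiff1d(np.arange(qt.shape[1]), qt.outlier_indices)
        out[:, keep] = dense
        out[:, qt.outlier_indices] = qt.outlier_values.astype(np.float64)
        dense = out
    return dense.astype(qt.dtype)


_QUANTIZABLE_SUFFIXES = ("attn.q.weight", "attn.k.weight", "attn.v.weight",
                         "attn.out.weight", "ffn.fc1.weight", "ffn.fc2.weight",
                         "lm_head.weight")


def quantize_model_weights(model, mode: str, block_size: int | None = None,
                           double_quant: bool = True, outlier_threshold: float = 6.0):
    """Return a copy of ``model`` whose projection weights went through a
    quantize→dequantize round trip (simulated low-bit inference), plus the
    quantized archive entries.

    ``mode``: ``"int8"`` (absmax + outlier decomposition) or ``"nf4"``
    (NormalFloat-4 with double quantization). Embeddings, norms, and biases
    stay at full precision, as in the cited recipes.
    """
    from .autograd import Tensor
    from .model import ProteinLM

    if mode not in ("int8", "nf4"):
        raise ValueError(f"unknown quantization mode {mode!r}")
    archive: dict[str, QuantizedTensor] = {}
    new_params = {}
    for name, p in model.params.items():
        if name.endswith(_QUANTIZABLE_SUFFIXES) and p.data.ndim == 2:
            if mode == "int8":
                qt = quantize_with_outliers(p.data, threshold=outlier_threshold,
                                            block_size=block_size or 2048)
            else:
                qt = quantize_nf4(p.data, block_size=block_size or 64,
                                  double_quant=double_quant)
            archive[name] = qt
            new_params[name] = Tensor(dequantize(qt))
        else:
            new_params[name] = Tensor(p.data.copy())
    return ProteinLM(model.config, new_params, model.alphabet), archive
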