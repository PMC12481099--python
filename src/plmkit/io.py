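"""Standard-format I/O: FASTA sequences, TSV variant/score tables, and
named-tensor weight archives.

Conventions, stated once and used everywhere: variant positions in files are
1-based (biology convention; internal indices are 0-based, converted only at
this boundary); scores are natural-log probabilities (nats); every output
TSV starts with '#'-prefixed header lines naming units. Weight archives are
flat named-tensor containers (numpy ``.npz``) with the architecture config
embedded as JSON under ``__config__``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .autograd import Tensor
from .model import ModelConfig, ProteinLM

__all__ = ["ProteinRecord", "read_fasta", "write_fasta", "read_variants",
           "write_scores", "save_model", "load_model", "save_adapters",
           "load_adapters", "save_quantized", "load_quantized"]

VARIANT_COLUMNS = ["protein_id", "position", "ref", "alt"]


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein record must have a non-empty id")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")


def read_fasta(path) -> list[ProteinRecord]:
    """Order-preserving FASTA parse; id = header token before first whitespace.

    Lowercase residues are uppercased. Duplicate ids, empty sequences, and
    non-letter characters raise errors naming the offending record.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        seq = str(rec.seq).upper()
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r}")
        if not seq:
            raise ValueError(f"record {rid!r} has an empty sequence")
        bad = [ch for ch in seq if not ch.isalpha()]
        if bad:
            raise ValueError(f"record {rid!r} contains non-letter characters: {bad[:5]}")
        seen.add(rid)
        records.append(ProteinRecord(rid, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_variants(path) -> pd.DataFrame:
    """Read a variant TSV with columns protein_id, position (1-based), ref, alt."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=VARIANT_COLUMNS, header=None,
                     dtype={"protein_id": str, "ref": str, "alt": str})
    # tolerate a literal header row
    if len(df) and df.iloc[0]["protein_id"] == "protein_id":
        df = df.iloc[1:].reset_index(drop=True)
    df["position"] = df["position"].astype(int)
    return df


def write_scores(records, path, extra_header: str | None = None) -> None:
    """Write ScoreRecords as TSV with a header documenting the conventions."""
    with open(path, "w") as fh:
        fh.write("# masked-marginal variant scores: score = log p(alt) - log p(ref), "
                 "natural log (nats); positions are 1-based\n")
        if extra_header:
            fh.write(f"# {extra_header}\n")
        fh.write("protein_id\tposition\tref\talt\tscore\n")
        for r in records:
            fh.write(f"{r.protein_id}\t{r.position}\t{r.ref}\t{r.alt}\t{r.score:.6f}\n")


def save_model(model: ProteinLM, path) -> None:
    """Serialize config + parameters to a flat named-tensor ``.npz`` archive."""
    arrays = {name: p.data for name, p in model.params.items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_model(path, alphabet=None) -> ProteinLM:
    with np.load(str(path)) as archive:
        config = ModelConfig.from_dict(
            json.loads(archive["__config__"].tobytes().decode()))
        params = {name: Tensor(archive[name]) for name in archive.files
                  if name != "__config__"}
    return ProteinLM(config, params, alphabet)


def save_quantized(archive: dict, config: ModelConfig, path) -> None:
    """Serialize quantized tensors with a format tag and per-tensor metadata
    (bits, block_size) so a reader can dequantize without guessing."""
    from .quantize import DoubleQuantizedConstants

    arrays: dict = {}
    meta: dict = {"format": "plmkit-quantized-v1",
                  "config": None, "tensors": {}}
    meta["config"] = config.to_dict()
    for name, qt in archive.items():
        arrays[f"{name}.codes"] = qt.codes
        entry = {"bits": qt.bits, "block_size": qt.block_size,
                 "shape": list(qt.shape), "dtype": str(np.dtype(qt.dtype)),
                 "double_quant": isinstance(qt.absmax, DoubleQuantizedConstants)}
        if entry["double_quant"]:
            arrays[f"{name}.dq.codes"] = qt.absmax.codes
            arrays[f"{name}.dq.absmax2"] = qt.absmax.absmax2
            entry["dq_mean"] = qt.absmax.mean
            entry["dq_block_size2"] = qt.absmax.block_size2
        else:
            arrays[f"{name}.absmax"] = qt.absmax
        if qt.codebook is not None:
            arrays[f"{name}.codebook"] = qt.codebook
        if qt.outlier_indices is not None:
            arrays[f"{name}.outlier_indices"] = qt.outlier_indices
            arrays[f"{name}.outlier_values"] = qt.outlier_values
        meta["tensors"][name] = entry
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_quantized(path):
    """Load a quantized archive; returns ({name: QuantizedTensor}, ModelConfig)."""
    from .quantize import DoubleQuantizedConstants, QuantizedTensor

    with np.load(str(path)) as z:
        meta = json.loads(z["__meta__"].tobytes().decode())
        if meta.get("format") != "plmkit-quantized-v1":
            raise ValueError("not a plmkit quantized archive")
        out = {}
        for name, entry in meta["tensors"].items():
            if entry["double_quant"]:
                absmax = DoubleQuantizedConstants(
                    codes=z[f"{name}.dq.codes"], absmax2=z[f"{name}.dq.absmax2"],
                    mean=entry["dq_mean"], block_size2=entry["dq_block_size2"])
            else:
                absmax = z[f"{name}.absmax"]
            out[name] = QuantizedTensor(
                codes=z[f"{name}.codes"], absmax=absmax,
                block_size=entry["block_size"], bits=entry["bits"],
                shape=tuple(entry["shape"]), dtype=np.dtype(entry["dtype"]),
                codebook=z[f"{name}.codebook"] if f"{name}.codebook" in z.files else None,
                outlier_indices=(z[f"{name}.outlier_indices"]
                                 if f"{name}.outlier_indices" in z.files else None),
                outlier_values=(z[f"{name}.outlier_values"]
                                if f"{name}.outlier_values" in z.files else None))
        config = ModelConfig.from_dict(meta["config"])
    return out, config


def save_adapters(model: ProteinLM, path) -> None:
    """Serialize attached LoRA adapters as ``adapters.{layer}.{A,B}`` tensors."""
    from .peft import adapter_state

    state = adapter_state(model)
    if not state:
        raise ValueError("model has no adapters to save")
    scalings = {name: s for name, (_, _, s) in model.adapters.items()}
    state["__scaling__"] = np.frombuffer(json.dumps(scalings).encode(), dtype=np.uint8)
    np.savez(str(path), **state)


def load_adapters(path) -> dict[str, tuple[Tensor, Tensor, float]]:
    with np.load(str(path)) as archive:
        scalings = json.loads(archive["__scaling__"].tobytes().decode())
        out: dict[str, tuple[Tensor, Tensor, float]] = {}
        for target, s in scalings.items():
            a = Tensor(archive[f"adapters.{target}.A"], requires_grad=True)
            b = Tensor(archive[f"adapters.{target}.B"], requires_grad=True)
            out[target] = (a, b, float(s))
    return out
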