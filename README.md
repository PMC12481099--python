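# plmkit

Efficient protein language model (PLM) inference, scoring, and fine-tuning,
built around **sequence packing**: instead of padding a batch of proteins to
the longest member, all sequences are concatenated into one flat token stream
and a block-diagonal attention mask preserves the batch structure, so no
compute is spent on padding. Batches are assembled to a fixed *token* budget
rather than a fixed protein count, which matters because protein lengths are
heavy-tailed (median ~400 residues, a substantial fraction past 1000).

The package is aimed at computational biologists who want to run ESM-style
masked-language models — for sequence scoring, missense variant effect
prediction, and protein property/function prediction — on modest hardware,
and at developers who need a transparent, fully testable reference
implementation of the efficiency machinery: every component runs on CPU with
tiny randomly initialized models, no downloads required.

## What it implements

* **ESM-style transformer** (`plmkit.model`): the 33-token amino-acid
  vocabulary, learned or rotary positional embeddings, GeLU (post-layer-norm)
  or SwiGLU (pre-layer-norm) blocks, and a language-model head. Forward and
  backward passes run on a small in-package reverse-mode autodiff engine
  (`plmkit.autograd`) over numpy.
* **Sequence packing & token-count batching** (`plmkit.packing`):
  `pack`/`unpack`, the block-diagonal mask, and a deterministic
  length-sorted first-fit batch planner. The central contract — packed
  forward equals per-sequence forward — is enforced by tests to 1e-4.
* **Scoring** (`plmkit.scoring`): pseudo-perplexity
  `PPL(x) = exp((1/T) Σ_t −log p(x_t | x_\t))` (each residue masked in turn)
  and the masked-marginal variant score `v = log p(alt) − log p(ref)` in
  nats, with variant-centered truncation for proteins longer than the
  model's context.
* **LoRA** (`plmkit.peft`): low-rank adapters `h = Wx + s·B(Ax)` on the
  attention projections; attach/merge/detach with frozen-base guarantees.
* **Blockwise quantization** (`plmkit.quantize`): 8-bit absmax, 4-bit
  NormalFloat with double-quantized constants, and mixed-precision outlier
  decomposition — inference-side, with exact storage accounting.
* **Task heads & training** (`plmkit.heads`, `plmkit.training`): mean and
  packing-compatible attention pooling, two-layer regression/classification
  heads, positive-class upsampling, masked-LM training, learned-positional
  table extension, and head-only / LoRA fine-tuning loops with token-budget
  minibatches and gradient accumulation.
* **I/O, fixtures, CLI** (`plmkit.io`, `plmkit.fixtures`, `plmkit.cli`):
  FASTA and TSV readers/writers, `.npz` named-tensor weight archives, and a
  seeded synthetic-corpus generator with known label models for recovery
  tests.

## Worked example

Generate a tiny corpus and a seeded random 2-layer model, inspect the batch
plan, and score sequences and variants:

```sh
plmkit make-fixtures --n-proteins 4 --median-length 60 --seed 42 \
    --out-fasta demo.fa --out-weights tiny.npz
plmkit pack-stats --fasta demo.fa --max-tokens 128
plmkit ppl --fasta demo.fa --weights tiny.npz --max-tokens 512 --out ppl.tsv
plmkit variants --fasta demo.fa --variants vars.tsv --weights tiny.npz --out scores.tsv
```

`pack-stats` reports how well token-budget batching fills each batch:

```
metric  value
n_sequences     4
n_batches       3
max_tokens_per_batch    128
mean_tokens_per_batch   112.3
utilization     0.8776
n_oversized     0
```

`ppl.tsv` holds per-protein pseudo-perplexities. A random untrained model
knows nothing about protein sequences, so values sit at the vocabulary size
(33 — the uniform-prediction baseline); a trained model scores lower:

```
id      length  pseudo_perplexity
prot00000       75      33.5932
prot00001       28      33.3588
prot00002       105     32.4910
prot00003       121     32.8338
```

`scores.tsv` holds masked-marginal scores, `log p(alt) − log p(ref)` in
nats; under a trained model, negative values flag substitutions the model
disfavors (potentially deleterious), while a random model scores near 0:

```
protein_id      position        ref     alt     score
prot00000       5       F       A       0.124262
prot00000       12      D       W       0.207519
```

The same operations are available as library calls (`pseudo_perplexity`,
`score_variant_table`, `finetune`, ...); see the module docstrings and
`docs/methods.md`.

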