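# Methods

This note records the models, conventions, and numerical choices behind
plmkit, and what the synthetic fixtures do and do not demonstrate.

## Model

The transformer is a masked-language model over amino-acid tokens. The
vocabulary is the 33-token layout used by the ESM family: cls, pad, eos,
unk, the 20 canonical amino acids, the rare codes X/B/U/Z/O, "." and "-", a
null placeholder, and mask. Tokenization wraps a sequence as
`[cls] + residues + [eos]`; unknown letters map to unk, non-letters are
errors.

Each block computes multi-head scaled dot-product attention
`softmax(QKᵀ/√d)V` with `d` the per-head dimension (not the embedding
width), followed by a feed-forward sub-layer. Two variants are supported:
GeLU feed-forward with post-layer-norm (the ESM-1/ESM2 convention used
here as default) and SwiGLU with pre-layer-norm (the ESM-C convention;
`fc1` then produces the gate and up projections stacked, keeping the flat
archive naming). A final layer norm precedes the LM head; head weights may
optionally be tied to the token embedding (untied by default, so an archive
is self-contained — whether tying is used in practice varies by model
family, so it is a config flag rather than a fixed choice).

Positions are either rotary (half-split pairing, base 10000, applied to Q
and K per head) or a learned table. Learned tables reserve two leading rows
(pad convention), so a model with `max_positions = N` stores `N + 2` rows
and accepts tokenized sequences of at most `N` tokens; this bookkeeping is
what makes the extension parameter count below exact. Exceeding the limit
is an explicit error, never silent truncation.

## Autodiff and precision

Training needs gradients, so the package carries a small reverse-mode
engine over numpy arrays (`plmkit.autograd`) implementing exactly the ops
the model uses, each verified against central finite differences in the
test suite. All model computation is float32; a float16 inference mode is a
flag on `forward`. Scalar log-probabilities (log-softmax for scoring) are
accumulated in float64 from the float32 logits so that reductions over long
sequences do not lose precision. Adam keeps its moments in float64 and
casts updates back to the parameter dtype.

Masked softmax sets disallowed scores to −inf before the (detached)
max-shift; a row with no allowed keys is an error rather than a NaN. When
no input requires gradients, attention runs a fused in-place numpy path
that performs the identical arithmetic without building a graph; the two
paths produce bitwise-identical results.

## Packing

`pack` concatenates token lists into one stream with cumulative boundary
offsets; attention uses the dense boolean block-diagonal mask built from
those boundaries, which is the reference semantics for variable-length
attention (a fused kernel would implement the same contract, and the dense
path is what all tests exercise). Positions restart at 0 for every sequence
inside a packed batch, in both positional modes, so a sequence's output is
independent of where it sits in the stream up to float reassociation
(~1e-7; the packed-vs-single contract is tested at 1e-4 in float32).

The batch planner sorts sequences by length descending and places them
greedy first-fit into the token budget, then shuffles batch order with the
seed. This is deterministic and keeps utilization high (≥ 0.5 is asserted
on a log-normal corpus at a 16,384-token budget; typical values are far
higher). A sequence longer than the budget becomes a singleton batch and is
reported, not rejected. Whether to reshuffle within length bins per epoch
is an open design point; the seeded shuffle of batch order was chosen for
reproducibility.

## Scoring conventions

Pseudo-perplexity masks each residue position separately (cls/eos are never
masked and never enter the T-average) and evaluates the T masked copies
through the packing machinery — deliberately, so scoring exercises the same
code path as everything else. Masked-marginal scores are differences of the
masked position's log-softmax in natural log. `score_variant_table` runs
one forward per *unique* masked (sequence, site) pair, so duplicate variant
rows are exactly identical and ref/alt pairs at one site share a forward.

Variant-centered truncation returns a contiguous window of `window`
residues; when both flanks overflow, the variant lands at 1-based position
`window // 2` (ties toward the left flank), and window-clipping at either
sequence end shifts it accordingly. In learned-positional mode a window of
`max_positions − 2` is applied automatically (room for cls/eos).

## LoRA

Adapters implement `h = Wx + s·B(Ax)` without materializing `BA`. `A` is
seeded N(0, 0.02), `B` starts at zero, so attaching is exactly forward-
neutral; the default scaling is 1 (no independent α was adopted). Default
targets are the query, value, and output projections; query/key/value is
reachable via config — both placements appear in practice and neither is
asserted as canonical. Attaching freezes the base model; merge folds
`s·BA` into `W`; detach restores the base bitwise and yields serializable
adapters (`adapters.{layer}.{target}.{A,B}`).

## Quantization

8-bit: per block of 2048 values, `codes = round(w/absmax·127)` stored as
int8 with a float32 absmax per block; the worst-case reconstruction error
is `absmax/254`. 4-bit: per block of 64 values, each normalized value
snaps to the nearest of 16 NormalFloat levels. The codebook is built from
evenly spaced standard-normal quantiles — 8 negative levels, zero, 7
positive levels, normalized so the endpoints are ±1. A 16-level set cannot
be simultaneously exactly symmetric and contain zero, so the codebook
follows the standard NormalFloat construction (asymmetric by one level,
zero included); the enforced invariants are sorted order, zero membership,
and ±1 endpoints. Double quantization mean-shifts the (positive) absmax
constants and absmax-quantizes them to int8 in blocks of 256.

Outlier decomposition moves any column containing an entry with
`|w| > 6.0` out of the quantization path. Outlier values are stored in the
*input tensor's* dtype (float16 when the model is half-precision) rather
than force-cast, so inlier + outlier reassembly reproduces the original
tensor exactly.

Quantization here is inference-only (fine-tuning on quantized bases is out
of scope); quantized tensors are dequantized before matmuls, so the
deliverable claims are about reconstruction error and storage. Storage
accounting is honest: 4-bit codes are packed two per byte, and
`stored_bytes()` counts codes, constants, codebook, and outliers.

## Training protocol

Defaults: Adam, learning rate 1e-4 with momentum parameters (0.9, 0.999),
learning rate multiplied by 0.9 every 10 epochs across 100 epochs (epoch
`e`, 1-based, runs at `lr·0.9^(e div 10)`; "reduced by 10%" is read as
multiplicative), minibatches of 50,000 tokens with 16 steps of gradient
accumulation, and a 15% masking rate. Masking replaces selected residues
with the mask token outright; the BERT-style 80/10/10 split is available
behind `bert_style` but is not the default, since plain replacement is the
simpler faithful reading of a "mask 15% of tokens" protocol. At least one
position is always masked, and cross-entropy is computed only over masked
positions.

Positional extension copies the old learned table into a larger one
(`new_max + 2` rows), seeds the new rows N(0, 0.02), and marks only that
table trainable — for a 1280-wide table extended to 4096 positions that is
(4096 + 2)·1280 = 5,245,440 trainable parameters. Extension training holds
out 1% of the corpus for validation. Fine-tuning supports head-only mode
(base frozen; per-token hidden states are computed once and cached, since
they cannot change) and LoRA mode (backprop through the adapted
transformer each step). In both, base-weight invariance is bitwise and
tested.

Epoch-budget arithmetic: `steps × tokens_per_step / corpus_tokens`,
reported raw and rounded — e.g. 500,000 steps × 2M tokens over an
18.7-billion-token corpus ≈ 53 epochs.

## Synthetic data

`synth_proteins` draws lengths log-normal with median 414 and σ_log 0.75,
clipped to [20, 5000]; σ_log was set once so that roughly 12% of proteins
exceed 1000 residues, matching the heavy right tail of a real proteome.
Residues are i.i.d. uniform over the 20 canonical amino acids.

Label models generate a seeded effect vector `w`, project it onto a
feature (amino-acid composition, or mean-pooled embeddings of a frozen
model via `embedding_labels`), **standardize the projection to unit
variance across the corpus**, then add N(0, 0.1²) noise (linear) or draw
Bernoulli through a sigmoid (logistic). The standardization is part of the
generator's definition: composition features have variance ~1/L, so an
unstandardized projection would drown in any fixed noise level and no
recovery statement would be meaningful.

What these fixtures demonstrate: the mechanical contracts (packing
equivalence, batching invariance, freeze conservation, oracle agreement)
and trainability (loss decreases, a linear signal in embedding space is
recovered to held-out Spearman ≥ 0.9). What they do not demonstrate:
biological performance. Uniform-residue corpora carry no homology,
composition bias, or evolutionary constraint, and tiny random models carry
no learned sequence knowledge, so passing tests say nothing about variant
effect prediction accuracy or property-prediction quality on real
proteins — those require pretrained weights and experimental datasets,
which are intentionally outside this package.

## Problem sizes

The test suite and the acceptance script run on 2-layer/64-dim/4-head
fixture models. Packed-equivalence checks use 50 random batches of 2–7
sequences (3–44 residues); scoring oracles use sequences of 5–40 residues
and 60–100 variants; the recovery experiment uses 600 proteins at the
generator's default length distribution (500 train, 100 held out, 30
epochs, token budget 2048); masked-LM sanity runs 50 steps on a fixed
20-sequence corpus. These sizes were chosen as the smallest that exercise
every code path with stable statistics; all scale up linearly through
function arguments.

## Known limitations

Attention is dense O(T²) in the packed length — the package provides the
mathematics of variable-length attention, not an IO-aware kernel, and a
full attention matrix is materialized per batch (which is also why very
long proteins are costly). Structure-prediction uses of attention maps are
out of scope. Quantized fine-tuning is excluded by design. The numpy
engine targets clarity over speed and holds one process's graph in memory;
it is sized for fixture-scale models, not for billion-parameter training.

Checkpointing during fine-tuning (head, pooling, and adapter tensors every
N epochs) and YAML round-tripping of the training config are available for
longer runs; the `activation_checkpointing` and `cpu_offload` config flags
are accepted for compatibility and are documented no-ops in this engine.
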