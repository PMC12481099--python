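import numpy as np
import pytest

from plmkit.fixtures import (FixtureSpec, embedding_labels, synth_proteins,
                             synth_tiny_model, tiny_config)
from plmkit.packing import pack
from plmkit.training import (Adam, TrainConfig, extend_positional, finetune,
                             lr_at_epoch, masked_lm_loss, train_masked_lm,
                             training_time_budget)

from conftest import random_protein


class TestTrainConfig:
    def test_defaults_match_reference_protocol(self):
        cfg = TrainConfig()
        assert cfg.lr == 1e-4
        assert cfg.betas == (0.9, 0.999)
        assert cfg.minibatch_tokens == 50_000
        assert cfg.grad_accum_steps == 16
        assert cfg.mask_rate == 0.15
        assert cfg.epochs == 100

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(mask_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(loss="hinge")

    def test_lr_schedule_arithmetic(self):
        cfg = TrainConfig()
        assert lr_at_epoch(cfg, 1) == 1e-4
        assert lr_at_epoch(cfg, 25) == pytest.approx(1e-4 * 0.9 ** 2)
        assert lr_at_epoch(cfg, 100) == pytest.approx(1e-4 * 0.9 ** 10)

    def test_schedule_audit_reproduces_decay_sequence(self):
        cfg = TrainConfig()
        lrs = sorted({lr_at_epoch(cfg, e) for e in range(1, 101)}, reverse=True)
        assert np.allclose(lrs, [1e-4 * 0.9 ** k for k in range(11)])


class TestMaskedLmLoss:
    def test_masked_fraction_matches_binomial_expectation(self, rotary_model):
        rng = np.random.default_rng(0)
        seqs = [rotary_model.alphabet.encode(random_protein(rng, 500)) for _ in range(20)]
        batch = pack(seqs)
        n_residues = 20 * 500
        _, picked = masked_lm_loss(rotary_model, batch, mask_rate=0.15, seed=1)
        rate = len(picked) / n_residues
        ci = 3 * np.sqrt(0.15 * 0.85 / n_residues)
        assert abs(rate - 0.15) < ci

    def test_uniform_logit_model_loss_is_log_vocab(self, rng):
        model = synth_tiny_model(tiny_config("rotary"), seed=0)
        for name in ("lm_head.weight", "lm_head.bias"):
            model.params[name].data[:] = 0
        seqs = [model.alphabet.encode(random_protein(rng, 30))]
        loss, picked = masked_lm_loss(model, pack(seqs), 0.15, seed=0)
        assert float(loss.data) == pytest.approx(np.log(33), rel=1e-6)

    def test_loss_restricted_to_masked_positions(self, rotary_model, rng):
        seqs = [rotary_model.alphabet.encode(random_protein(rng, 40))]
        batch = pack(seqs)
        loss, picked = masked_lm_loss(rotary_model, batch, 0.2, seed=5)
        corrupted = batch.tokens.copy()
        corrupted[picked] = rotary_model.alphabet.mask_id
        logits = rotary_model.forward(pack([corrupted]))
        z = logits[picked].astype(np.float64)
        logp = z - (z.max(1, keepdims=True)
                    + np.log(np.exp(z - z.max(1, keepdims=True)).sum(1, keepdims=True)))
        manual = -logp[np.arange(len(picked)), batch.tokens[picked]].mean()
        assert float(loss.data) == pytest.approx(manual, rel=1e-5)

    def test_special_tokens_never_masked(self, rotary_model, rng):
        seqs = [rotary_model.alphabet.encode(random_protein(rng, 30)) for _ in range(5)]
        batch = pack(seqs)
        for seed in range(10):
            _, picked = masked_lm_loss(rotary_model, batch, 0.5, seed=seed)
            toks = batch.tokens[picked]
            assert rotary_model.alphabet.cls_id not in toks
            assert rotary_model.alphabet.eos_id not in toks

    def test_at_least_one_position_masked(self, rotary_model):
        seqs = [rotary_model.alphabet.encode("MK")]
        _, picked = masked_lm_loss(rotary_model, pack(seqs), 0.01, seed=0)
        assert len(picked) >= 1


class TestExtendPositional:
    def test_reference_width_table_parameter_count(self):
        cfg = tiny_config("learned", num_layers=1, embed_dim=1280, num_heads=16,
                          ffn_dim=64, max_positions=1024)
        model = synth_tiny_model(cfg, seed=0)
        extended, report = extend_positional(model, new_max=4096)
        assert report["trainable_parameters"] == 5_245_440
        assert extended.params["embed_positions.weight"].shape == (4098, 1280)

    def test_old_rows_copied_and_only_table_trainable(self):
        model = synth_tiny_model(tiny_config("learned", max_positions=32), seed=1)
        old = model.params["embed_positions.weight"].data.copy()
        extended, _ = extend_positional(model, new_max=64)
        assert np.array_equal(extended.params["embed_positions.weight"].data[:34], old)
        trainable = extended.trainable_parameters()
        assert set(trainable) == {"embed_positions.weight"}

    def test_non_positional_tensors_bitwise_unchanged_after_step(self, rng):
        model = synth_tiny_model(
            tiny_config("learned", embed_dim=32, num_heads=4, ffn_dim=64,
                        max_positions=32), seed=2)
        corpus = [random_protein(rng, int(n)) for n in rng.integers(20, 30, size=12)]
        before = {k: p.data.copy() for k, p in model.params.items()}
        cfg = TrainConfig(lr=1e-3, minibatch_tokens=1024, seed=0)
        extended, report = extend_positional(model, 64, corpus=corpus,
                                             config=cfg, steps=1)
        for k, p in extended.params.items():
            if k != "embed_positions.weight":
                assert np.array_equal(before[k], p.data), k
        assert not np.array_equal(
            before["embed_positions.weight"],
            extended.params["embed_positions.weight"].data[:34])

    def test_masked_lm_loss_improves_on_long_fixtures(self, rng):
        model = synth_tiny_model(
            tiny_config("learned", embed_dim=32, num_heads=4, ffn_dim=64,
                        max_positions=32), seed=3)
        corpus = [random_protein(rng, int(n)) for n in rng.integers(48, 60, size=10)]
        cfg = TrainConfig(lr=5e-3, minibatch_tokens=1024, seed=0)
        extended, report = extend_positional(model, 64, corpus=corpus,
                                             config=cfg, steps=200)
        losses = report["train_loss"]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_rotary_model_rejected(self):
        model = synth_tiny_model(tiny_config("rotary"), seed=0)
        with pytest.raises(ValueError, match="learned positions"):
            extend_positional(model, 2048)

    def test_shrinking_rejected(self):
        model = synth_tiny_model(tiny_config("learned", max_positions=64), seed=0)
        with pytest.raises(ValueError, match="exceed"):
            extend_positional(model, 64)


@pytest.fixture(scope="module")
def tiny_dataset():
    model = synth_tiny_model(tiny_config("rotary"), seed=5)
    spec = FixtureSpec(n_proteins=40, median_length=40, sigma_log=0.3, seed=3)
    records, _, _ = synth_proteins(spec)
    y, _, _ = embedding_labels(model, records, seed=3, sigma=0.1)
    seqs = [r.sequence for r in records]
    return model, (seqs[:30], y[:30], seqs[30:], y[30:])


class TestFinetuneLoop:
    def test_deterministic_given_seed(self, tiny_dataset):
        model, dataset = tiny_dataset
        cfg = TrainConfig(lr=1e-3, epochs=3, minibatch_tokens=512, seed=9)
        runs = []
        for _ in range(2):
            res = finetune(model, dataset, config=cfg, task="regression",
                           pooling="mean", mode="head-only")
            runs.append({k: t.data.copy() for k, t in res.head.params.items()})
        for k in runs[0]:
            assert np.array_equal(runs[0][k], runs[1][k])

    def test_base_checksum_invariant_in_head_only_mode(self, tiny_dataset):
        model, dataset = tiny_dataset
        before = {k: p.data.copy() for k, p in model.params.items()}
        cfg = TrainConfig(lr=1e-3, epochs=2, minibatch_tokens=512, seed=0)
        finetune(model, dataset, config=cfg, task="regression", mode="head-only")
        for k, p in model.params.items():
            assert np.array_equal(before[k], p.data)

    def test_gradient_accumulation_updates_every_nth_minibatch(self, tiny_dataset,
                                                               monkeypatch):
        model, dataset = tiny_dataset
        cfg = TrainConfig(lr=1e-3, epochs=1, minibatch_tokens=128,
                          grad_accum_steps=4, seed=0)
        steps = []
        orig = Adam.step

        def spy(self, lr):
            steps.append(self.t)
            return orig(self, lr)

        monkeypatch.setattr(Adam, "step", spy)
        res = finetune(model, dataset, config=cfg, task="regression", mode="head-only")
        from plmkit.packing import plan_token_batches
        lengths = [len(s) + 2 for s in dataset[0]]
        n_batches = plan_token_batches(lengths, 128, seed=cfg.seed + 1).n_batches
        assert len(steps) == int(np.ceil(n_batches / 4))

    def test_binary_task_logs_auroc_and_learns(self):
        model = synth_tiny_model(tiny_config("rotary"), seed=6)
        spec = FixtureSpec(n_proteins=60, median_length=40, sigma_log=0.3, seed=4)
        records, _, _ = synth_proteins(spec)
        y, _, z = embedding_labels(model, records, seed=4, sigma=0.1)
        labels = (z > 0).astype(int)
        seqs = [r.sequence for r in records]
        dataset = (seqs[:45], labels[:45], seqs[45:], labels[45:])
        cfg = TrainConfig(lr=1e-3, epochs=10, minibatch_tokens=512, seed=0, loss="bce")
        res = finetune(model, dataset, config=cfg, task="binary", mode="head-only")
        assert "val_auroc" in res.log[-1]
        assert res.log[-1]["val_auroc"] > 0.7

    def test_lora_mode_trains_adapters_only(self):
        model = synth_tiny_model(tiny_config("rotary"), seed=7)
        spec = FixtureSpec(n_proteins=16, median_length=25, sigma_log=0.2, seed=5)
        records, _, _ = synth_proteins(spec)
        y, _, _ = embedding_labels(model, records, seed=5, sigma=0.1)
        seqs = [r.sequence for r in records]
        dataset = (seqs[:12], y[:12], seqs[12:], y[12:])
        before = {k: p.data.copy() for k, p in model.params.items()}
        cfg = TrainConfig(lr=1e-3, epochs=2, minibatch_tokens=256, seed=0)
        res = finetune(model, dataset, config=cfg, task="regression", mode="lora",
                       lora_rank=2)
        for k, p in model.params.items():
            assert np.array_equal(before[k], p.data)
        assert any(np.abs(b.data).max() > 0 for _, b, _ in model.adapters.values())

    def test_empty_split_rejected(self, tiny_dataset):
        model, dataset = tiny_dataset
        with pytest.raises(ValueError, match="empty"):
            finetune(model, ([], [], dataset[2], dataset[3]))

    def test_attention_pooling_mode_runs(self, tiny_dataset):
        model, dataset = tiny_dataset
        cfg = TrainConfig(lr=1e-3, epochs=2, minibatch_tokens=512, seed=0)
        res = finetune(model, dataset, config=cfg, task="regression",
                       pooling="attention", mode="head-only")
        assert len(res.log) == 2


class TestTrainingTimeBudget:
    def test_reference_pretraining_budget_rounds_to_53(self):
        raw, epochs = training_time_budget(500_000, 2_000_000, 18_700_000_000)
        assert epochs == 53
        assert raw == pytest.approx(53.48, abs=0.01)

    def test_exact_single_epoch(self):
        raw, epochs = training_time_budget(10, 100, 1000)
        assert raw == 1.0 and epochs == 1

    def test_doubling_corpus_halves_raw_epochs(self):
        raw1, _ = training_time_budget(100, 1000, 10_000)
        raw2, _ = training_time_budget(100, 1000, 20_000)
        assert raw1 == pytest.approx(2 * raw2)

    def test_zero_corpus_rejected(self):
        with pytest.raises(ValueError):
            training_time_budget(1, 1, 0)


def test_full_training_determinism_same_seed_same_parameters(small_corpus):
    params = []
    for _ in range(2):
        model = synth_tiny_model(tiny_config("rotary"), seed=8)
        cfg = TrainConfig(lr=1e-3, minibatch_tokens=512, seed=17)
        train_masked_lm(model, small_corpus[:8], steps=10, config=cfg)
        params.append({k: p.data.copy() for k, p in model.params.items()})
    for k in params[0]:
        assert np.array_equal(params[0][k], params[1][k])


def test_finetune_checkpoints_written_every_n_epochs(tiny_dataset, tmp_path):
    model, dataset = tiny_dataset
    cfg = TrainConfig(lr=1e-3, epochs=4, minibatch_tokens=512, seed=0)
    finetune(model, dataset, config=cfg, task="regression", mode="head-only",
             checkpoint_dir=tmp_path, checkpoint_every=2)
    names = sorted(p.name for p in tmp_path.glob("checkpoint_epoch*.npz"))
    assert names == ["checkpoint_epoch0002.npz", "checkpoint_epoch0004.npz"]
    with np.load(tmp_path / names[0]) as z:
        assert any(k.startswith("head.") for k in z.files)
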