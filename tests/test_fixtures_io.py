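import numpy as np
import pytest
from click.testing import CliRunner

from plmkit.cli import main as cli_main
from plmkit.fixtures import (FixtureSpec, embedding_labels, synth_proteins,
                             synth_tiny_model, tiny_config)
from plmkit.io import (ProteinRecord, load_model, read_fasta, read_variants,
                       save_adapters, save_model, write_fasta, write_scores)
from plmkit.metrics import spearman


class TestFasta:
    def test_round_trip_bitwise(self, tmp_path):
        records = [ProteinRecord("a", "ACDEF"), ProteinRecord("b", "MKWL")]
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(records, p1)
        write_fasta(read_fasta(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">p desc here\nacd\nef\n")
        recs = read_fasta(p)
        assert recs[0].id == "p" and recs[0].sequence == "ACDEF"

    def test_duplicate_id_named_in_error(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">dup\nACD\n>dup\nEFG\n")
        with pytest.raises(ValueError, match="dup"):
            read_fasta(p)

    def test_illegal_characters_named(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">bad\nAC*D\n")
        with pytest.raises(ValueError, match="bad"):
            read_fasta(p)

    def test_thousand_records_preserved(self, tmp_path):
        records, _, _ = synth_proteins(FixtureSpec(n_proteins=1000, seed=0))
        p = tmp_path / "big.fa"
        write_fasta(records, p)
        back = read_fasta(p)
        assert len(back) == 1000
        assert all(a.id == b.id and len(a.sequence) == len(b.sequence)
                   for a, b in zip(records, back))


class TestSynthProteins:
    def test_same_seed_identical_corpus(self):
        a, _, _ = synth_proteins(FixtureSpec(n_proteins=50, seed=5))
        b, _, _ = synth_proteins(FixtureSpec(n_proteins=50, seed=5))
        assert all(x.sequence == y.sequence for x, y in zip(a, b))

    def test_median_length_near_configured_value(self):
        records, _, _ = synth_proteins(FixtureSpec(n_proteins=2000, seed=1))
        med = np.median([len(r.sequence) for r in records])
        assert abs(med - 414) / 414 < 0.10

    def test_heavy_tail_fraction_past_1000(self):
        records, _, _ = synth_proteins(FixtureSpec(n_proteins=4000, seed=2))
        frac = np.mean([len(r.sequence) > 1000 for r in records])
        assert 0.06 < frac < 0.18

    def test_linear_labels_correlate_with_generating_projection(self):
        spec = FixtureSpec(n_proteins=300, label_model="linear-regression",
                           noise_sigma=0.1, seed=3)
        _, labels, meta = synth_proteins(spec)
        assert spearman(meta["signal"], labels) >= 0.95

    def test_logistic_labels_are_binary_and_signal_linked(self):
        spec = FixtureSpec(n_proteins=400, label_model="logistic", seed=4)
        _, labels, meta = synth_proteins(spec)
        assert set(np.unique(labels)) <= {0, 1}
        assert labels[meta["signal"] > 1].mean() > labels[meta["signal"] < -1].mean()

    def test_embedding_label_noise_floor(self):
        model = synth_tiny_model(tiny_config("rotary"), seed=0)
        records, _, _ = synth_proteins(
            FixtureSpec(n_proteins=80, median_length=40, sigma_log=0.3, seed=6))
        y, w, z = embedding_labels(model, records, seed=6, sigma=0.1)
        assert spearman(z, y) >= 0.95


class TestModelArchive:
    def test_same_seed_identical_archives(self, tmp_path):
        a = synth_tiny_model(tiny_config("rotary"), seed=9)
        b = synth_tiny_model(tiny_config("rotary"), seed=9)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)

    def test_archive_round_trip_bitwise(self, tmp_path, rng):
        model = synth_tiny_model(tiny_config("learned", max_positions=64), seed=3)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.config == model.config
        for k in model.params:
            assert np.array_equal(model.params[k].data, back.params[k].data)

    def test_loaded_model_forward_finite_and_non_constant(self, tmp_path, rng):
        model = synth_tiny_model(tiny_config("rotary"), seed=4)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        toks = np.array(back.alphabet.encode("MKVLATGEWILKAC"))
        logits = back.forward(toks)
        assert np.all(np.isfinite(logits))
        assert logits.std() > 0

    def test_adapter_archive_round_trip(self, tmp_path):
        from plmkit.io import load_adapters
        from plmkit.peft import attach

        model = synth_tiny_model(tiny_config("rotary"), seed=5)
        attach(model, rank=3, seed=1)
        path = tmp_path / "adapters.npz"
        save_adapters(model, path)
        back = load_adapters(path)
        assert set(back) == set(model.adapters)
        for k, (a, b, s) in model.adapters.items():
            assert np.array_equal(back[k][0].data, a.data)


class TestVariantTables:
    def test_variant_tsv_round_trip(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("# comment line\nprotein_id\tposition\tref\talt\n"
                     "p1\t5\tA\tC\np2\t10\tW\tG\n")
        df = read_variants(p)
        assert len(df) == 2
        assert df.iloc[0].position == 5 and df.iloc[1].alt == "G"

    def test_score_output_header_documents_units(self, tmp_path):
        from plmkit.scoring import ScoreRecord
        p = tmp_path / "s.tsv"
        write_scores([ScoreRecord("p", 1, "A", "C", -0.5)], p)
        text = p.read_text()
        assert text.startswith("#")
        assert "nats" in text and "1-based" in text


class TestCli:
    @pytest.fixture()
    def workspace(self, tmp_path):
        runner = CliRunner()
        fasta = tmp_path / "prot.fa"
        weights = tmp_path / "model.npz"
        res = runner.invoke(cli_main, [
            "make-fixtures", "--n-proteins", "6", "--median-length", "30",
            "--seed", "1", "--out-fasta", str(fasta),
            "--out-weights", str(weights)])
        assert res.exit_code == 0, res.output
        return runner, tmp_path, fasta, weights

    def test_pack_stats_reports_utilization(self, workspace):
        runner, tmp_path, fasta, _ = workspace
        res = runner.invoke(cli_main, ["pack-stats", "--fasta", str(fasta),
                                       "--max-tokens", "64"])
        assert res.exit_code == 0, res.output
        assert "utilization" in res.output and "n_batches" in res.output

    def test_ppl_writes_tsv(self, workspace):
        runner, tmp_path, fasta, weights = workspace
        out = tmp_path / "ppl.tsv"
        res = runner.invoke(cli_main, ["ppl", "--fasta", str(fasta),
                                       "--weights", str(weights),
                                       "--max-tokens", "256", "--out", str(out)])
        assert res.exit_code == 0, res.output
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert lines[0].split("\t") == ["id", "length", "pseudo_perplexity"]
        assert len(lines) == 7
        values = [float(l.split("\t")[2]) for l in lines[1:]]
        assert all(v >= 1 for v in values)

    def test_variants_cli_scores_and_is_reproducible(self, workspace):
        runner, tmp_path, fasta, weights = workspace
        records = read_fasta(fasta)
        vt = tmp_path / "vars.tsv"
        seq = records[0].sequence
        vt.write_text(f"{records[0].id}\t3\t{seq[2]}\tW\n"
                      f"{records[0].id}\t5\t{seq[4]}\tA\n")
        outs = []
        for name in ("s1.tsv", "s2.tsv"):
            out = tmp_path / name
            res = runner.invoke(cli_main, ["variants", "--fasta", str(fasta),
                                           "--variants", str(vt),
                                           "--weights", str(weights),
                                           "--out", str(out)])
            assert res.exit_code == 0, res.output
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]

    def test_quantized_scoring_flag(self, workspace):
        runner, tmp_path, fasta, weights = workspace
        out = tmp_path / "pplq.tsv"
        res = runner.invoke(cli_main, ["ppl", "--fasta", str(fasta),
                                       "--weights", str(weights),
                                       "--quantize", "int8",
                                       "--max-tokens", "256", "--out", str(out)])
        assert res.exit_code == 0, res.output

    def test_finetune_cli_writes_log(self, workspace):
        runner, tmp_path, fasta, weights = workspace
        labels = tmp_path / "labels.tsv"
        records = read_fasta(fasta)
        rng = np.random.default_rng(0)
        with open(labels, "w") as fh:
            fh.write("protein_id\tlabel\n")
            for r in records:
                fh.write(f"{r.id}\t{rng.normal():.4f}\n")
        out = tmp_path / "log.tsv"
        res = runner.invoke(cli_main, ["finetune", "--fasta", str(fasta),
                                       "--labels", str(labels),
                                       "--weights", str(weights),
                                       "--epochs", "2", "--minibatch-tokens", "256",
                                       "--out-log", str(out)])
        assert res.exit_code == 0, res.output
        assert "val_spearman" in out.read_text()


class TestQuantizedArchive:
    def test_round_trip_preserves_dequantized_weights(self, tmp_path):
        from plmkit.io import load_quantized, save_quantized
        from plmkit.quantize import dequantize, quantize_model_weights

        model = synth_tiny_model(tiny_config("rotary"), seed=2)
        for mode in ("int8", "nf4"):
            _, archive = quantize_model_weights(model, mode)
            path = tmp_path / f"{mode}.npz"
            save_quantized(archive, model.config, path)
            back, config = load_quantized(path)
            assert config == model.config
            assert set(back) == set(archive)
            for name in archive:
                assert back[name].bits == archive[name].bits
                assert back[name].block_size == archive[name].block_size
                assert np.array_equal(dequantize(back[name]),
                                      dequantize(archive[name]))

    def test_foreign_archive_rejected(self, tmp_path):
        from plmkit.io import load_quantized
        import json
        path = tmp_path / "bad.npz"
        meta = np.frombuffer(json.dumps({"format": "other"}).encode(), dtype=np.uint8)
        np.savez(path, __meta__=meta)
        with pytest.raises(ValueError, match="quantized archive"):
            load_quantized(path)


class TestTrainConfigYaml:
    def test_yaml_round_trip(self, tmp_path):
        from plmkit.training import TrainConfig
        cfg = TrainConfig(lr=5e-4, epochs=7, minibatch_tokens=1234, seed=3,
                          loss="bce", activation_checkpointing=True)
        path = tmp_path / "train.yaml"
        cfg.to_yaml(path)
        assert TrainConfig.from_yaml(path) == cfg
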