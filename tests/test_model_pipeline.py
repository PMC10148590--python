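"""Model/Results interface, end-to-end pipeline and CLI plumbing."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from pseudospace import (
    PseudoSpaceModel,
    RunConfig,
    load_run_config,
    run_pipeline,
)
from pseudospace.cli import main as cli_main
from pseudospace import io as psio


@pytest.fixture(scope="module")
def pair_on_disk(tmp_path_factory, mini_pair):
    d = tmp_path_factory.mktemp("pair")
    psio.write_expression(mini_pair.sc, d / "sc.csv")
    psio.write_expression(mini_pair.st.expr, d / "st.csv")
    psio.write_coords(mini_pair.st.expr.obs_ids, mini_pair.st.coords,
                      d / "st_coords.csv")
    psio.write_coords(mini_pair.sc.obs_ids, mini_pair.truth_coords_sc,
                      d / "sc_truth_coords.csv")
    psio.write_labels(mini_pair.sc.obs_ids, mini_pair.sc.labels,
                      d / "sc_labels.csv")
    return d


def _run_config(pair_dir, out_dir, **overrides):
    kwargs = dict(
        sc_path=str(pair_dir / "sc.csv"),
        st_expr_path=str(pair_dir / "st.csv"),
        st_coords_path=str(pair_dir / "st_coords.csv"),
        out_dir=str(out_dir),
        m=20,
        n_hvg=None,
        target_k=3,
        sc_labels_path=str(pair_dir / "sc_labels.csv"),
        sc_truth_coords_path=str(pair_dir / "sc_truth_coords.csv"),
        seed=11,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


class TestModelResults:
    def test_fit_produces_consistent_shapes(self, mini_pair, mini_results):
        assert mini_results.latent_sc.shape == (mini_pair.sc.n_obs, 20)
        assert mini_results.latent_st.shape == (mini_pair.st.n_obs, 20)
        assert mini_results.pseudo_space.coords.shape == (
            mini_pair.sc.n_obs, 2,
        )

    def test_embedding_shrinks_mmd(self, mini_results):
        d = mini_results.diagnostics
        assert d["mmd_after_embedding"] < d["mmd_before"]

    def test_summary_mentions_key_quantities(self, mini_results):
        text = mini_results.summary()
        assert "SC cells" in text and "latent dimension" in text
        assert str(mini_results.diagnostics["n_sc"]) in text

    def test_cluster_and_evaluate(self, mini_pair, mini_results):
        k = len(set(mini_pair.sc.labels))
        cr = mini_results.cluster(target_k=k)
        report = mini_results.evaluate(
            truth_coords=mini_pair.truth_coords_sc,
            truth_labels=mini_pair.sc.labels,
            cluster_result=cr,
        )
        assert -1.0 <= report.pairwise_pcc <= 1.0
        assert report.ari is not None and report.nmi is not None

    def test_from_files_matches_in_memory(self, pair_on_disk, mini_pair):
        model = PseudoSpaceModel.from_files(
            pair_on_disk / "sc.csv", pair_on_disk / "st.csv",
            pair_on_disk / "st_coords.csv", m=20, n_hvg=None, seed=11,
        )
        res = model.fit()
        ref = PseudoSpaceModel(mini_pair.sc, mini_pair.st, m=20, n_hvg=None,
                               seed=11).fit()
        np.testing.assert_allclose(
            res.pseudo_space.coords, ref.pseudo_space.coords, atol=1e-8
        )


class TestRunPipeline:
    def test_outputs_and_manifest(self, pair_on_disk, tmp_path):
        cfg = _run_config(pair_on_disk, tmp_path / "out")
        run_pipeline(cfg)
        out = tmp_path / "out"
        for name in ("latent_sc.csv", "latent_st.csv", "pseudo_space.csv",
                     "clusters.csv", "evaluation.json", "manifest.json",
                     "summary.txt"):
            assert (out / name).exists(), name
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["global_seed"] == 11
        assert set(manifest["stage_seeds"]) == {"tca", "space", "cluster"}
        report = json.loads((out / "evaluation.json").read_text())
        assert "pairwise_pcc" in report and "ari" in report

    def test_repeat_run_is_byte_identical(self, pair_on_disk, tmp_path):
        cfg1 = _run_config(pair_on_disk, tmp_path / "a")
        cfg2 = _run_config(pair_on_disk, tmp_path / "b")
        run_pipeline(cfg1)
        run_pipeline(cfg2)
        assert (tmp_path / "a" / "clusters.csv").read_bytes() == (
            tmp_path / "b" / "clusters.csv"
        ).read_bytes()
        assert (tmp_path / "a" / "pseudo_space.csv").read_bytes() == (
            tmp_path / "b" / "pseudo_space.csv"
        ).read_bytes()

    def test_clustering_skipped_without_mode(self, pair_on_disk, tmp_path):
        cfg = _run_config(pair_on_disk, tmp_path / "out", target_k=None,
                          sc_labels_path=None)
        run_pipeline(cfg)
        assert (tmp_path / "out" / "pseudo_space.csv").exists()
        assert not (tmp_path / "out" / "clusters.csv").exists()

    def test_stage_error_names_stage(self, pair_on_disk, tmp_path):
        cfg = _run_config(pair_on_disk, tmp_path / "out",
                          sc_path=str(pair_on_disk / "missing.csv"))
        with pytest.raises(RuntimeError, match="load"):
            run_pipeline(cfg)


class TestConfigFile:
    def test_flat_key_value_parsing(self, tmp_path):
        p = tmp_path / "run.cfg"
        p.write_text(
            "sc_path = sc.csv\n"
            "st_expr_path = st.csv\n"
            "st_coords_path = coords.csv\n"
            "out_dir = out\n"
            "m = 30\n"
            "mu = 0.5\n"
            "target_k = 4\n"
            "seed = 3  # trailing comment\n"
            "space.epochs = 200\n"
            "weights.l = 10\n"
        )
        cfg = load_run_config(p)
        assert cfg.m == 30 and cfg.mu == 0.5 and cfg.target_k == 4
        assert cfg.seed == 3
        assert cfg.space.epochs == 200
        assert cfg.weights.l == 10

    def test_unknown_nested_key_rejected(self, tmp_path):
        p = tmp_path / "bad.cfg"
        p.write_text("weights.wavelength = 3\n")
        with pytest.raises(ValueError, match="wavelength"):
            load_run_config(p)


class TestCli:
    def test_simulate_then_run(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        r = runner.invoke(cli_main, [
            "simulate", "--out-dir", str(sim_dir), "--n-genes", "300",
            "--n-sc", "80", "--n-st", "80", "--n-pops", "3", "--seed", "4",
        ])
        assert r.exit_code == 0, r.output
        cfg = tmp_path / "run.cfg"
        cfg.write_text(
            f"sc_path = {sim_dir / 'sc.csv'}\n"
            f"st_expr_path = {sim_dir / 'st.csv'}\n"
            f"st_coords_path = {sim_dir / 'st_coords.csv'}\n"
            f"out_dir = {tmp_path / 'out'}\n"
            "m = 15\n"
            "n_hvg = none\n"
            "target_k = 3\n"
            f"sc_labels_path = {sim_dir / 'sc_labels.csv'}\n"
            f"sc_truth_coords_path = {sim_dir / 'sc_truth_coords.csv'}\n"
            "space.epochs = 300\n"
            "seed = 4\n"
        )
        r = runner.invoke(cli_main, ["run", "--config", str(cfg)])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "out" / "pseudo_space.csv").exists()
        assert "Pseudo-space reconstruction results" in r.output

    def test_evaluate_subcommand(self, tmp_path, mini_pair):
        runner = CliRunner()
        psio.write_coords(mini_pair.sc.obs_ids, mini_pair.truth_coords_sc,
                          tmp_path / "truth.csv")
        psio.write_coords(mini_pair.sc.obs_ids, mini_pair.truth_coords_sc,
                          tmp_path / "pseudo.csv")
        r = runner.invoke(cli_main, [
            "evaluate", "--pseudo", str(tmp_path / "pseudo.csv"),
            "--truth-coords", str(tmp_path / "truth.csv"),
            "--out", str(tmp_path / "report.json"),
        ])
        assert r.exit_code == 0, r.output
        report = json.loads((tmp_path / "report.json").read_text())
        assert report["pairwise_pcc"] == pytest.approx(1.0)
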