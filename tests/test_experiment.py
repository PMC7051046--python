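import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from ratebound.cli import main as cli_main
from ratebound.experiment import (
    PER_FIT_COLUMNS,
    ExperimentConfig,
    default_bias_spec,
    read_per_fit_csv,
    run_experiment,
    summarize,
    write_per_fit_csv,
)
from ratebound.simulate import RateLaw, SimulationSpec, make_collection


def _tiny_spec(**kw):
    base = dict(n_sites=60, seed=0, n_taxa=4, branch_length_mean=0.12,
                syn_law=RateLaw.constant(), nonsyn_law=RateLaw.constant(),
                nonsyn_scale=0.5)
    base.update(kw)
    return SimulationSpec(**base)


def _synthetic_rows():
    """Hand-built per-fit table: 10 discrete-gamma K=3 fits, 2 at bound."""
    rows = []
    bound = np.sqrt(2.0)
    for i in range(10):
        at = i < 2
        rows.append({
            **dict.fromkeys(PER_FIT_COLUMNS),
            "alignment": f"rep{i}", "method": "discrete_gamma",
            "k_syn": 3, "k_nonsyn": 3, "log_likelihood": -100.0 - i,
            "cv_syn": 0.4, "cv_nonsyn": bound if at else 0.9,
            "at_bound_syn": False, "at_bound_nonsyn": at,
            "at_bound_either": at, "converged": True, "status": "ok",
            "nonsyn_scale": 0.5, "branch_scale": 1.0, "kappa": 2.0,
        })
    return pd.DataFrame(rows, columns=PER_FIT_COLUMNS)


class TestConfig:
    def test_json_round_trip(self, tmp_path):
        cfg = ExperimentConfig(simulation=default_bias_spec(),
                               n_alignments=5, master_seed=9,
                               dg_k_list=(3, 5), gdd_k_list=(4,),
                               bound_tolerance=2e-3)
        path = tmp_path / "cfg.json"
        cfg.save(path)
        back = ExperimentConfig.load(path)
        assert back == cfg

    def test_validation(self):
        with pytest.raises(ValueError):
            ExperimentConfig(dg_k_list=(1, 3))
        with pytest.raises(ValueError):
            ExperimentConfig(dg_k_list=(), gdd_k_list=())

    def test_default_bias_spec_values(self):
        spec = default_bias_spec()
        assert spec.n_sites == 300
        assert spec.n_taxa == 8
        assert spec.nonsyn_law == RateLaw.gamma(0.2)
        assert spec.nonsyn_law.analytic_cv() == pytest.approx(np.sqrt(5.0))


class TestSummarize:
    def test_fractions_from_synthetic_rows(self):
        summary = summarize(_synthetic_rows())
        assert summary.n_alignments == 10
        assert summary.at_bound_fraction("discrete_gamma", 3, "nonsyn") == \
            pytest.approx(0.2)
        assert summary.at_bound_fraction("discrete_gamma", 3, "syn") == 0.0
        assert summary.at_bound_fraction("discrete_gamma", 3, "either") == \
            pytest.approx(0.2)
        row = summary.table.iloc[0]
        assert row["n_converged"] == 10 and row["n_failed"] == 0

    def test_saturation_recomputed_from_cv_columns(self):
        # a CV just under the tolerance window is not counted; just inside is
        df = _synthetic_rows()
        df.loc[5, "cv_nonsyn"] = np.sqrt(2.0) * (1 - 5e-4)   # inside 1e-3
        df.loc[6, "cv_nonsyn"] = np.sqrt(2.0) * (1 - 5e-3)   # outside
        summary = summarize(df, tolerance=1e-3)
        assert summary.at_bound_fraction("discrete_gamma", 3, "nonsyn") == \
            pytest.approx(0.3)

    def test_non_converged_fits_become_attrition(self):
        df = _synthetic_rows()
        df.loc[0:3, "converged"] = False
        summary = summarize(df)
        assert summary.attrition == {("discrete_gamma", 3): 4}
        row = summary.table.iloc[0]
        assert row["n_converged"] == 6
        # fractions computed over converged fits only (no at-bound left)
        assert summary.at_bound_fraction("discrete_gamma", 3, "nonsyn") == 0.0

    def test_all_failed_cell_has_missing_quantiles(self):
        df = _synthetic_rows()
        df["converged"] = False
        summary = summarize(df)
        row = summary.table.iloc[0]
        assert row["n_converged"] == 0
        assert "cv_nonsyn_median" not in row or pd.isna(row.get("cv_nonsyn_median"))

    def test_gdd_cells_have_no_bound_fraction(self):
        df = _synthetic_rows()
        df["method"] = "gdd"
        summary = summarize(df)
        assert np.isnan(summary.at_bound_fraction("gdd", 3, "nonsyn"))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=PER_FIT_COLUMNS))


class TestPerFitCsv:
    def test_round_trip_exact(self, tmp_path):
        df = _synthetic_rows()
        path = tmp_path / "per_fit.csv"
        write_per_fit_csv(df, path)
        back = read_per_fit_csv(path)
        assert list(back.columns) == PER_FIT_COLUMNS
        assert back.at_bound_nonsyn.tolist() == df.at_bound_nonsyn.tolist()
        assert np.allclose(back.cv_nonsyn, df.cv_nonsyn)
        s1 = summarize(df).table
        s2 = summarize(back).table
        pd.testing.assert_frame_equal(s1, s2)

    def test_deterministic_modulo_header(self, tmp_path):
        df = _synthetic_rows()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_per_fit_csv(df, p1)
        write_per_fit_csv(df, p2)
        body1 = p1.read_text().splitlines()[1:]
        body2 = p2.read_text().splitlines()[1:]
        assert body1 == body2


class TestRunExperiment:
    def test_constant_rate_collection_not_at_bound(self, tmp_path):
        # without rate variation the fitted CVs sit far below the ceiling
        cfg = ExperimentConfig(
            simulation=_tiny_spec(), n_alignments=2, master_seed=7,
            dg_k_list=(3,), gdd_k_list=(), output_dir=str(tmp_path / "out"))
        df, summary = run_experiment(cfg)
        assert len(df) == 2
        assert df.converged.all()
        assert summary.at_bound_fraction("discrete_gamma", 3, "either") == 0.0
        out = tmp_path / "out"
        assert (out / "per_fit.csv").exists()
        assert (out / "summary.csv").exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["config"]["n_alignments"] == 2
        back = read_per_fit_csv(out / "per_fit.csv")
        assert np.allclose(back.log_likelihood, df.log_likelihood)

    def test_input_dir_collection(self, tmp_path):
        # the pipeline consumes user-supplied FASTA + Newick pairs
        data_dir = tmp_path / "data"
        make_collection(_tiny_spec(), 2, master_seed=3, out_dir=data_dir)
        cfg = ExperimentConfig(input_dir=str(data_dir), dg_k_list=(3,),
                               gdd_k_list=())
        df, summary = run_experiment(cfg)
        assert sorted(df.alignment) == ["rep001", "rep002"]
        assert df.converged.all()

    def test_unreadable_alignment_recorded(self, tmp_path):
        data_dir = tmp_path / "data"
        make_collection(_tiny_spec(), 1, master_seed=3, out_dir=data_dir)
        (data_dir / "bad.fasta").write_text(">x\nATGTAA\n")  # stop codon
        (data_dir / "bad.nwk").write_text("(x:0.1,y:0.1);\n")
        cfg = ExperimentConfig(input_dir=str(data_dir), dg_k_list=(3,),
                               gdd_k_list=())
        df, _summary = run_experiment(cfg)
        bad = df[df.alignment == "bad"]
        assert len(bad) == 1
        assert bad.iloc[0]["method"] == "unreadable"
        assert "stop codon" in bad.iloc[0]["status"]
        assert df[df.alignment == "rep001"].converged.all()

    def test_missing_input_dir(self, tmp_path):
        cfg = ExperimentConfig(input_dir=str(tmp_path / "nothing"),
                               dg_k_list=(3,), gdd_k_list=())
        with pytest.raises(FileNotFoundError):
            run_experiment(cfg)


class TestCli:
    def test_simulate_and_fit_smoke(self, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "sim"
        res = runner.invoke(cli_main, [
            "simulate", "--n-alignments", "1", "--n-taxa", "4",
            "--n-sites", "50", "--syn-law", "constant",
            "--nonsyn-law", "constant", "--seed", "5",
            "--out-dir", str(out_dir)])
        assert res.exit_code == 0, res.output
        fasta = out_dir / "rep001.fasta"
        nwk = out_dir / "rep001.nwk"
        assert fasta.exists() and nwk.exists()

        json_out = tmp_path / "fit.json"
        res = runner.invoke(cli_main, [
            "fit", str(fasta), str(nwk), "--k-syn", "3",
            "--json-out", str(json_out)])
        assert res.exit_code == 0, res.output
        assert "Dual-rate codon model fit" in res.output
        record = json.loads(json_out.read_text())
        assert record["method"] == "discrete_gamma"
        assert record["k_syn"] == 3

    def test_summarize_command(self, tmp_path):
        path = tmp_path / "per_fit.csv"
        write_per_fit_csv(_synthetic_rows(), path)
        runner = CliRunner()
        res = runner.invoke(cli_main, ["summarize", str(path),
                                       "--out", str(tmp_path / "s.csv")])
        assert res.exit_code == 0, res.output
        assert "discrete_gamma" in res.output
        assert (tmp_path / "s.csv").exists()
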