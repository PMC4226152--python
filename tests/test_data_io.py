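"""Long-format data model, validation, fixtures and the CLI shell."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from stoppedsums.cli import main as cli_main
from stoppedsums.data import (
    FixtureConfig,
    RSSDataset,
    ValidationError,
    generate_fixture,
    read_long_table,
    write_long_table,
)


def toy_frame():
    return pd.DataFrame({
        "subject": ["A", "A", "B"],
        "magnitude": [100.0, 200.0, 50.0],
        "condition": [0.0, 0.0, 1.0],
    })


class TestRSSDataset:
    def test_derived_counts_and_sums(self):
        ds = RSSDataset(toy_frame(), subject_predictors=["condition"])
        assert ds.counts.to_dict() == {"A": 2, "B": 1}
        assert ds.sums.to_dict() == {"A": 300.0, "B": 50.0}

    def test_zero_magnitude_rejected(self):
        bad = toy_frame()
        bad.loc[1, "magnitude"] = 0.0
        with pytest.raises(ValidationError, match="magnitude"):
            RSSDataset(bad)

    def test_subject_predictor_must_be_constant(self):
        bad = toy_frame()
        bad.loc[1, "condition"] = 1.0
        with pytest.raises(ValidationError, match="condition"):
            RSSDataset(bad, subject_predictors=["condition"])

    def test_missing_column_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            RSSDataset(toy_frame().drop(columns=["magnitude"]))

    def test_file_roundtrip(self, tmp_path):
        ds = RSSDataset(toy_frame(), subject_predictors=["condition"])
        path = tmp_path / "data.csv"
        write_long_table(ds, path)
        back = read_long_table(path, subject_predictors=["condition"])
        pd.testing.assert_frame_equal(ds.frame, back.frame)

    def test_three_level_units(self):
        df = pd.DataFrame({
            "subject": ["A", "A", "A", "B"],
            "round": ["r0", "r0", "r1", "r0"],
            "magnitude": [1.0, 2.0, 3.0, 4.0],
        })
        ds = RSSDataset(df, round_col="round")
        units = ds.unit_frame(levels=3)
        assert len(units) == 3
        assert units.loc[("A", "r0"), "n"] == 2
        z, idx = ds.observations(levels=3)
        assert len(z) == 4 and idx.max() == 2


class TestFixtureGeneration:
    def test_baseline_moments(self):
        # negbin(0.5, 10) x gamma(4, 250): counts 10/20, magnitudes 1000/500
        cfg = FixtureConfig(J=3000, mag_family="gamma",
                            mag_params={"shape": 4.0},
                            alpha={"const": math.log(10.0)},
                            beta={"const": math.log(1000.0)}, seed=11)
        ds = generate_fixture(cfg)
        counts = ds.counts.to_numpy()
        # subjects with zero counts never reach the magnitude table
        p0 = 0.5**10
        assert counts.mean() == pytest.approx(10.0 / (1 - p0), rel=0.03)
        assert counts.var() == pytest.approx(20.0, rel=0.12)
        z = ds.frame["magnitude"]
        assert z.mean() == pytest.approx(1000.0, rel=0.01)
        assert z.std() == pytest.approx(500.0, rel=0.02)

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = FixtureConfig(J=50, seed=5,
                            alpha={"const": 2.0, "condition": 0.1},
                            beta={"const": 6.0, "condition": 0.1})
        a, b = generate_fixture(cfg), generate_fixture(cfg)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_long_table(a, pa)
        write_long_table(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_null_fixture_has_no_sums_effect(self):
        from stoppedsums.glm import fit_sums_glm

        cfg = FixtureConfig(J=400, seed=21,
                            alpha={"const": math.log(10.0), "condition": 0.0},
                            beta={"const": 6.81, "condition": 0.0})
        ds = generate_fixture(cfg)
        units = ds.unit_frame(2)
        res = fit_sums_glm(units["S"].to_numpy(),
                           units[["condition"]], family="LN")
        est = res.coefficients["condition"]
        assert abs(est) < 3 * res.standard_errors["condition"]

    def test_three_level_structure(self):
        cfg = FixtureConfig(levels=3, J=30, rounds=4, seed=9,
                            alpha={"const": 2.0},
                            beta={"const": 6.0},
                            round_intercepts=[6.2, 6.1, 6.0, 5.9])
        ds = generate_fixture(cfg)
        assert ds.round_col == "round"
        assert ds.frame["round"].nunique() == 4
        assert len(ds.unit_frame(levels=3)) <= 120

    def test_truth_recorded_in_metadata(self):
        cfg = FixtureConfig(J=10, seed=1)
        ds = generate_fixture(cfg)
        assert ds.metadata["truth"]["seed"] == 1


class TestCLI:
    def test_fixture_then_fit_smoke(self, tmp_path):
        runner = CliRunner()
        fdir = tmp_path / "fx"
        r = runner.invoke(cli_main, [
            "fixture", "--subjects", "80", "--seed", "3",
            "--alpha", '{"const": 2.3, "condition": 0.2}',
            "--beta", '{"const": 6.8, "condition": 0.1}',
            "--out", str(fdir)])
        assert r.exit_code == 0, r.output
        assert (fdir / "fixture.csv").exists()
        assert (fdir / "fixture_manifest.json").exists()

        odir = tmp_path / "fit"
        r = runner.invoke(cli_main, [
            "fit", "--data", str(fdir / "fixture.csv"),
            "--predictors", "condition", "--out", str(odir)])
        assert r.exit_code == 0, r.output
        table = pd.read_csv(odir / "sums_coefficients.csv")
        assert {"coefficient", "estimate", "se", "wald_p"} <= set(table.columns)

    def test_power_single_cell(self, tmp_path):
        runner = CliRunner()
        odir = tmp_path / "pw"
        r = runner.invoke(cli_main, [
            "power", "--reps", "200", "--seed", "4", "--out", str(odir)])
        assert r.exit_code == 0, r.output
        rates = pd.read_csv(odir / "scenario_rates.csv")
        assert set(rates["model"]) == {"magnitude", "frequency", "sums"}
        manifest = json.loads((odir / "power_manifest.json").read_text())
        assert manifest["parameters"]["seed"] == 4

    def test_simulate_with_config(self, tmp_path):
        import yaml

        cfgp = tmp_path / "specs.yaml"
        cfgp.write_text(yaml.safe_dump({
            "frequency": {"kind": "frequency", "family": "negbin",
                          "pi": 0.5, "phi": 10.0},
            "magnitude": {"kind": "magnitude", "family": "gamma",
                          "shape": 4.0, "scale": 250.0},
        }))
        runner = CliRunner()
        odir = tmp_path / "sim"
        r = runner.invoke(cli_main, [
            "simulate", "--config", str(cfgp), "--subjects", "20",
            "--runs", "200", "--seed", "5", "--out", str(odir)])
        assert r.exit_code == 0, r.output
        summary = pd.read_csv(odir / "sums_summary.csv")
        mean = summary.loc[summary["statistic"] == "mean", "value"].iloc[0]
        assert mean == pytest.approx(10_000, rel=0.1)

    def test_unknown_subcommand_errors(self):
        r = CliRunner().invoke(cli_main, ["frobnicate"])
        assert r.exit_code != 0


class TestCLIBayesDiagnose:
    def test_bayes_subcommand_smoke(self, tmp_path):
        runner = CliRunner()
        fdir = tmp_path / "fx"
        r = runner.invoke(cli_main, [
            "fixture", "--subjects", "40", "--seed", "6",
            "--alpha", '{"const": 2.0, "condition": 0.1}',
            "--beta", '{"const": 6.5, "condition": 0.1}',
            "--out", str(fdir)])
        assert r.exit_code == 0, r.output
        odir = tmp_path / "bayes"
        r = runner.invoke(cli_main, [
            "bayes", "--data", str(fdir / "fixture.csv"),
            "--predictors", "condition", "--family", "GG",
            "--chains", "2", "--burn-in", "150", "--draws", "150",
            "--seed", "7", "--out", str(odir)])
        assert r.exit_code == 0, r.output
        summary = pd.read_csv(odir / "posterior_summary.csv")
        assert "rhat" in summary.columns
        dic = pd.read_csv(odir / "dic.csv")
        assert list(dic["submodel"]) == ["frequency", "magnitude", "sums"]
        assert (odir / "predicted.csv").exists()

    def test_diagnose_subcommand_smoke(self, tmp_path):
        import yaml

        runner = CliRunner()
        fdir = tmp_path / "fx"
        r = runner.invoke(cli_main, [
            "fixture", "--subjects", "30", "--seed", "8", "--out", str(fdir)])
        assert r.exit_code == 0, r.output
        cfgp = tmp_path / "specs.yaml"
        cfgp.write_text(yaml.safe_dump({
            "frequency": {"kind": "frequency", "family": "negbin",
                          "pi": 0.5, "phi": 10.0},
            "magnitude": {"kind": "magnitude", "family": "lognormal",
                          "mu_log": 6.81, "sigma_log": 0.447},
        }))
        odir = tmp_path / "diag"
        r = runner.invoke(cli_main, [
            "diagnose", "--data", str(fdir / "fixture.csv"),
            "--config", str(cfgp), "--runs", "200", "--seed", "9",
            "--out", str(odir)])
        assert r.exit_code == 0, r.output
        table = pd.read_csv(odir / "quantile_comparison.csv", index_col=0)
        assert list(table.index) == ["model", "observed"]
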