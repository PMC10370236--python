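"""Pipeline orchestration, report serialization, prediction intervals, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from emuhet.cli import main as cli_main
from emuhet.pairwise import pair_differences
from emuhet.regression import INTERCEPT, build_design, fit_dataset, fit_weighted
from emuhet.report import (
    AnalysisConfig,
    analyze,
    prediction_intervals,
    run_full_analysis,
    write_report,
)
from emuhet.simulate import SimulationConfig, make_fixture, simulate_dataset
from emuhet.study_io import CLOSE_EMULATION, ValidationError, write_covariates, write_estimates

from conftest import make_covariates, make_dataset


@pytest.fixture(scope="module")
def paper_shaped_report():
    synth = make_fixture("paper_shaped", seed=4)
    return synth, analyze(synth.dataset)


class TestAnalyze:
    def test_pipeline_equals_stage_composition(self, paper_shaped_report):
        synth, rep = paper_shaped_report
        direct_simple = fit_dataset(synth.dataset)
        assert rep.simple_fit.coefficients == direct_simple.coefficients
        assert rep.simple_fit.phi == direct_simple.phi
        direct_close = fit_dataset(synth.dataset, (CLOSE_EMULATION,))
        assert rep.close_emulation_fit.phi == direct_close.phi

    def test_univariate_fits_cover_all_varying_candidates(self, paper_shaped_report):
        synth, rep = paper_shaped_report
        varying = {
            name
            for name in rep.config.candidates
            if len(set(synth.dataset.covariate_column(name))) > 1
        }
        assert varying <= set(rep.univariate_fits) <= set(rep.config.candidates)
        for name, fit in rep.univariate_fits.items():
            assert fit.columns == (INTERCEPT, name)

    def test_report_json_roundtrip(self, paper_shaped_report):
        _, rep = paper_shaped_report
        d = rep.to_dict()
        assert json.loads(json.dumps(d)) == d

    def test_tables_have_expected_shape(self, paper_shaped_report):
        _, rep = paper_shaped_report
        assert list(rep.table2()["model"]) == ["simple", "close_emulation"]
        assert len(rep.table3()) == len(rep.univariate_fits)
        t4 = rep.table4()
        assert t4["size"].iloc[0] == 0
        assert (t4["loo_mse"].values >= 0).all()
        assert len(rep.fig2_data()) == rep.dataset.n
        assert set(rep.fig3_data()[CLOSE_EMULATION]) <= {0, 1}

    def test_null_fixture_yields_little_heterogeneity(self):
        phis = []
        sizes = []
        for seed in range(8):
            ds = make_fixture("null_small", seed=seed).dataset
            rep = analyze(ds, AnalysisConfig(candidates=("placebo_control", "dose_titration")))
            phis.append(rep.simple_fit.phi)
            sizes.append(rep.selection.selected_model.size)
        assert np.mean(phis) < 1.35
        assert sum(s == 0 for s in sizes) >= 6


class TestRunFullAnalysis:
    def test_from_csv_matches_in_memory_dataset(self, tmp_path):
        synth = simulate_dataset(SimulationConfig(seed=21, n_databases=3, db_se_inflation=1.4))
        # write per-database rows only: the pooling stage must rebuild the pooled estimates
        db_and_rct = [e for e in synth.estimates if e.source.value != "RWE_POOLED"]
        write_estimates(db_and_rct, tmp_path / "estimates.csv")
        write_covariates(synth.covariates, tmp_path / "covariates.csv")
        rep = run_full_analysis(tmp_path / "estimates.csv", tmp_path / "covariates.csv")
        direct = analyze(synth.dataset)
        assert rep.dataset.n == direct.dataset.n
        assert rep.simple_fit.phi == pytest.approx(direct.simple_fit.phi, abs=1e-9)
        assert rep.overall_test.q_total == pytest.approx(direct.overall_test.q_total, abs=1e-9)

    def test_write_report_emits_all_files(self, tmp_path, paper_shaped_report):
        _, rep = paper_shaped_report
        write_report(rep, tmp_path)
        for name in [
            "table2.csv",
            "table3.csv",
            "table4.csv",
            "fig2_data.csv",
            "fig3_data.csv",
            "fig5_data.csv",
            "report.json",
            "manifest.json",
        ]:
            assert (tmp_path / name).exists(), name
        table2 = pd.read_csv(tmp_path / "table2.csv")
        assert {"intercept", "phi"} <= set(table2.columns)


class TestPredictionIntervals:
    def test_intercept_only_single_interval(self, rng):
        ds = make_dataset(rng.normal(0, 0.3, 8), rng.uniform(0.1, 0.3, 8))
        diffs = pair_differences(ds)
        X = build_design(ds, ())
        fit = fit_weighted(diffs, X)
        out = prediction_intervals(fit, X, diffs)
        assert len(out) == 1
        assert out.loc[0, "predicted"] == pytest.approx(fit.coefficients[INTERCEPT])
        assert out.loc[0, "lower"] < out.loc[0, "predicted"] < out.loc[0, "upper"]

    def test_interval_widens_with_phi(self, rng):
        se = rng.uniform(0.1, 0.3, 10)
        narrow = make_dataset(rng.normal(0, 0.5 * se), se)
        wide = make_dataset(np.array([d.diff for d in pair_differences(narrow)]) * 4, se)
        out_n = prediction_intervals(
            fit_weighted(pair_differences(narrow), build_design(narrow, ())),
            build_design(narrow, ()),
            pair_differences(narrow),
        )
        out_w = prediction_intervals(
            fit_weighted(pair_differences(wide), build_design(wide, ())),
            build_design(wide, ()),
            pair_differences(wide),
        )
        assert (out_w["upper"] - out_w["lower"]).iloc[0] > (out_n["upper"] - out_n["lower"]).iloc[0]

    def test_unobserved_pattern_rejected(self, rng):
        covs = [
            make_covariates(f"t{i}", placebo_control=i % 2) for i in range(8)
        ]
        ds = make_dataset(rng.normal(0, 0.3, 8), [0.2] * 8, covs)
        diffs = pair_differences(ds)
        X = build_design(ds, ("placebo_control",))
        fit = fit_weighted(diffs, X)
        observed = prediction_intervals(fit, X, diffs, patterns=[{"placebo_control": 1.0}])
        assert len(observed) == 1
        with pytest.raises(ValidationError, match="not observed"):
            prediction_intervals(fit, X, diffs, patterns=[{"placebo_control": 2.0}])

    def test_matches_predictive_simulation_oracle(self, rng):
        """Interval endpoints agree with draws from the fitted model."""
        n = 200
        se = np.full(n, 0.2)
        ds = make_dataset(rng.normal(0.1, 0.3, n), se)
        diffs = pair_differences(ds)
        X = build_design(ds, ())
        fit = fit_weighted(diffs, X)
        out = prediction_intervals(fit, X, diffs)
        draws = rng.normal(
            fit.coefficients[INTERCEPT],
            fit.phi * np.sqrt(fit.cov_unscaled[0, 0] + np.median(se**2)),
            200_000,
        )
        lo, hi = np.quantile(draws, [0.025, 0.975])
        width_mc = hi - lo
        width = out.loc[0, "upper"] - out.loc[0, "lower"]
        assert width == pytest.approx(width_mc, rel=0.02)


class TestCli:
    def test_simulate_then_report_end_to_end(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        res = runner.invoke(
            cli_main,
            ["simulate", "--fixture", "paper_shaped", "--seed", "3", "--out-dir", str(sim_dir)],
        )
        assert res.exit_code == 0, res.output
        assert (sim_dir / "truth.json").exists()
        rep_dir = tmp_path / "rep"
        res = runner.invoke(
            cli_main,
            [
                "report",
                str(sim_dir / "estimates.csv"),
                str(sim_dir / "covariates.csv"),
                "--out-dir",
                str(rep_dir),
            ],
        )
        assert res.exit_code == 0, res.output
        report = json.loads((rep_dir / "report.json").read_text())
        # the homogeneity gate may exclude a few trials by chance
        assert report["n_pairs"] + len(report["excluded_trials"]) == 29
        assert report["selection"]["n_models"] == 1024

    def test_stage_subcommands(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        runner.invoke(
            cli_main,
            ["simulate", "--fixture", "null_small", "--seed", "1", "--out-dir", str(sim_dir)],
        )
        args = [str(sim_dir / "estimates.csv"), str(sim_dir / "covariates.csv")]
        for cmd, extra in [
            ("pairwise", []),
            ("fit", ["--covariates", "close_emulation"]),
            ("select", ["--candidates", "placebo_control,dose_titration"]),
        ]:
            out_dir = tmp_path / cmd
            res = runner.invoke(cli_main, [cmd, *args, *extra, "--out-dir", str(out_dir)])
            assert res.exit_code == 0, f"{cmd}: {res.output}"

    def test_pool_subcommand(self, tmp_path):
        runner = CliRunner()
        synth = simulate_dataset(SimulationConfig(seed=6, n_databases=3))
        write_estimates(synth.estimates, tmp_path / "est.csv")
        res = runner.invoke(
            cli_main, ["pool", str(tmp_path / "est.csv"), "--out-dir", str(tmp_path / "out")]
        )
        assert res.exit_code == 0, res.output
        pooled = pd.read_csv(tmp_path / "out" / "pooled.csv")
        exclusions = json.loads((tmp_path / "out" / "exclusions.json").read_text())
        assert len(pooled) + len(exclusions["excluded"]) == 29
        assert (pooled["k"] == 3).all()
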