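"""Numeric oracle convergence, batch plumbing, fixtures and the CLI."""

import json

import numpy as np
import pytest
from typer.testing import CliRunner

from vilipower import (
    VentilationScenario,
    generate_fixtures,
    hr_drive,
    hr_elastic,
    load_batch,
    oracle_hr,
    partition,
    run_report,
)
from vilipower.batch import batch_from_rows, batch_to_json, write_report
from vilipower.cli import app

runner = CliRunner()


class TestOracle:
    def test_matches_closed_forms_at_reference(self):
        assert oracle_hr(25, 5, 20, "drive") == pytest.approx(0.4375, abs=1e-9)
        assert oracle_hr(25, 5, 20, "elastic") == pytest.approx(0.375, abs=1e-9)

    def test_threshold_at_plateau_gives_zero(self):
        assert oracle_hr(25, 5, 25, "drive") == 0.0
        assert oracle_hr(25, 5, 25, "elastic") == 0.0

    def test_convergence_with_panel_count(self):
        # the integrand along the linear P–V line is itself linear, so the
        # trapezoid rule is already exact up to roundoff at any panel count;
        # the quadrature must sit at the closed form from 1e3 panels on
        exact = hr_elastic(25.0, 5.0, 13.7)
        errs = [abs(oracle_hr(25.0, 5.0, 13.7, "elastic", n) - exact) for n in (1000, 100_000)]
        assert max(errs) < 1e-9

    def test_panel_floor_and_variant_checked(self):
        with pytest.raises(ValueError):
            oracle_hr(25, 5, 20, "drive", n_panels=10)
        with pytest.raises(ValueError):
            oracle_hr(25, 5, 20, "total")


class TestFixtures:
    def test_determinism(self):
        a = batch_to_json(generate_fixtures(seed=1, n=5))
        b = batch_to_json(generate_fixtures(seed=1, n=5))
        assert a == b
        assert batch_to_json(generate_fixtures(seed=2, n=5)) != a

    def test_all_rows_valid_and_in_range(self):
        batch = generate_fixtures(seed=3, n=50)
        assert not batch.errors
        for record in batch:
            s = record.scenario
            assert 0.0 <= s.peep <= 15.0
            assert 5.0 <= s.dp <= 25.0
            assert s.peep <= s.pt <= s.ps
            assert 0.2 <= s.vt <= 0.8
            assert 10.0 <= s.f <= 35.0


class TestBatchReport:
    def test_empty_batch(self):
        report = run_report(batch_from_rows([]), log=False)
        assert len(report) == 0

    def test_single_scenario_row_matches_partition(self, reference_scenario):
        rows = [dict(name="ref", ps=25, peep=5, vt=0.5, f=20, pt=20)]
        report = run_report(batch_from_rows(rows), log=False)
        expected = partition(reference_scenario)
        row = report.iloc[0]
        assert row["hr_drive"] == pytest.approx(expected.hr_drive)
        assert row["damaging_power_drive"] == pytest.approx(expected.damaging_power_drive)
        assert row["damaging_power_drive_j"] == pytest.approx(expected.damaging_power_drive_j)

    def test_invalid_row_reported_not_fatal(self):
        rows = [
            dict(name="good", ps=25, peep=5, vt=0.5, f=20, pt=20),
            dict(name="bad", ps=4, peep=5, vt=0.5, f=20, pt=4),  # Ps < PEEP
        ]
        report = run_report(batch_from_rows(rows), log=False)
        assert len(report) == 2
        assert report["error"].notna().tolist() == [False, True]
        assert np.isfinite(report.iloc[0]["w_elastic"])

    def test_duplicate_names_flagged(self):
        rows = [dict(name="x", ps=25, peep=5, vt=0.5, f=20, pt=20)] * 2
        batch = batch_from_rows(rows)
        assert len(batch.errors) == 1

    def test_targets_and_regional_columns(self):
        rows = [dict(name="ref", ps=25, peep=5, vt=0.5, f=20, pt=20)]
        report = run_report(
            batch_from_rows(rows), desired_ratio=0.2, variant="elastic", regional=True, log=False
        )
        assert report.iloc[0]["target_ps"] == pytest.approx(
            np.sqrt((400 - 0.2 * 25) / 0.8)
        )
        assert report.iloc[0]["hr_drive_nondependent"] >= report.iloc[0]["hr_drive_dependent"]

    def test_csv_and_json_round_trip(self, tmp_path):
        batch = generate_fixtures(seed=5, n=4)
        json_path = tmp_path / "batch.json"
        json_path.write_text(batch_to_json(batch))
        reloaded = load_batch(json_path)
        assert not reloaded.errors
        for orig, back in zip(batch.valid, reloaded.valid):
            assert back.scenario.ps == pytest.approx(orig.scenario.ps, rel=1e-12)
            assert back.scenario.pt == pytest.approx(orig.scenario.pt, rel=1e-12)

    def test_write_report_formats(self, tmp_path):
        report = run_report(generate_fixtures(seed=5, n=3), log=False)
        tsv, js = tmp_path / "r.tsv", tmp_path / "r.json"
        write_report(report, tsv)
        write_report(report, js)
        assert tsv.read_text().splitlines()[0].startswith("name\t")
        assert len(json.loads(js.read_text())) == 3


class TestCLI:
    def test_compute_matches_library(self, reference_scenario):
        result = runner.invoke(
            app,
            ["compute", "--ps", "25", "--peep", "5", "--vt", "0.5", "--f", "20", "--pt", "20"],
        )
        assert result.exit_code == 0
        payload = json.loads(result.stdout)
        expected = partition(reference_scenario)
        assert payload["hr_drive"] == pytest.approx(expected.hr_drive)
        assert payload["elastic_power"] == pytest.approx(expected.elastic_power)

    def test_compute_strict_rejects_out_of_range_threshold(self):
        result = runner.invoke(
            app,
            ["compute", "--ps", "25", "--peep", "5", "--vt", "0.5", "--f", "20",
             "--pt", "30", "--strict"],
        )
        assert result.exit_code == 1

    def test_scenario_file_round_trip(self, tmp_path, reference_scenario):
        scenario_file = tmp_path / "scenario.json"
        scenario_file.write_text(json.dumps({"ps": 25, "peep": 5, "vt": 0.5, "f": 20, "pt": 20}))
        result = runner.invoke(app, ["compute", "--file", str(scenario_file)])
        assert result.exit_code == 0
        assert json.loads(result.stdout)["hr_elastic"] == pytest.approx(0.375)

    def test_target_verb(self):
        result = runner.invoke(
            app,
            ["target", "0.4375", "--ps", "25", "--peep", "5", "--vt", "0.5", "--pt", "20"],
        )
        assert result.exit_code == 0
        payload = json.loads(result.stdout)
        assert payload["target_dp"] == pytest.approx(2.857142857, abs=1e-9)
        assert payload["target_vt"] == pytest.approx(0.0714285714, abs=1e-9)

    def test_batch_and_fixtures_verbs(self, tmp_path):
        fixtures_path = tmp_path / "fixtures.json"
        report_path = tmp_path / "report.tsv"
        made = runner.invoke(app, ["fixtures", str(fixtures_path), "--seed", "9", "--n", "6"])
        assert made.exit_code == 0
        ran = runner.invoke(app, ["batch", str(fixtures_path), str(report_path)])
        assert ran.exit_code == 0
        lines = report_path.read_text().splitlines()
        assert len(lines) == 7  # header + 6 rows
        # spot-check a row against the library
        batch = load_batch(fixtures_path)
        report = run_report(batch, log=False)
        s = batch.valid[0].scenario
        assert report.iloc[0]["hr_elastic"] == pytest.approx(
            hr_elastic(s.ps, s.peep, s.pt)
        )

    def test_simulate_and_regional_verbs(self, tmp_path):
        trace_path = tmp_path / "trace.csv"
        sim = runner.invoke(
            app,
            ["simulate", str(trace_path), "--ps", "25", "--peep", "5", "--vt", "0.5",
             "--pt", "20", "--ti", "1.0"],
        )
        assert sim.exit_code == 0
        summary = json.loads(sim.stdout)
        assert summary["elastic_energy"] == pytest.approx(7.5, rel=1e-6)
        assert summary["time_above_pt"] == pytest.approx(0.25, abs=1e-6)
        reg = runner.invoke(
            app,
            ["regional", "--ps", "25", "--peep", "5", "--vt", "0.5", "--pt", "20",
             "--gradient-span", "6"],
        )
        assert reg.exit_code == 0
        assert reg.stdout.splitlines()[0].startswith("position\t")
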