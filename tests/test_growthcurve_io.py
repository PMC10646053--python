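import json
import math

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from growthcurve.cli import main as cli_main
from growthcurve.comparators import two_sample_t
from growthcurve.growthcurve_io import (
    FixtureSpec,
    analyze_curves,
    generate_fixture,
    read_growth_csv,
    render_report,
    report_frame,
    report_json,
    to_long,
    write_growth_csv,
)
from growthcurve.homologous_core import DatasetError, GrowthCurveDataset, homologous_test


def _write(tmp_path, text, name="data.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


WIDE = """animal_id,group,3,5,7
m1,0,10,20,40
m2,0,12,25,49
m3,1,11,18,30
m4,1,9,15,26
"""


class TestReadCsv:
    def test_wide(self, tmp_path):
        ds = read_growth_csv(_write(tmp_path, WIDE))
        assert ds.volumes.shape == (4, 3)
        np.testing.assert_array_equal(ds.times, [3, 5, 7])
        np.testing.assert_array_equal(ds.group, [0, 0, 1, 1])
        assert ds.scale == "raw"

    def test_long_matches_wide(self, tmp_path):
        wide = read_growth_csv(_write(tmp_path, WIDE))
        records = []
        for i, a in enumerate(wide.animal_ids):
            for j, t in enumerate(wide.times):
                records.append(f"{a},{wide.group[i]},{t},{wide.volumes[i, j]}")
        long_text = "animal_id,group,time,volume\n" + "\n".join(records) + "\n"
        longds = read_growth_csv(_write(tmp_path, long_text, "long.csv"), dialect="long")
        np.testing.assert_allclose(longds.volumes, wide.volumes)
        np.testing.assert_array_equal(longds.group, wide.group)
        np.testing.assert_array_equal(longds.times, wide.times)

    def test_missing_cell_names_row_and_column(self, tmp_path):
        text = WIDE.replace("12,25,49", "12,,49")
        with pytest.raises(DatasetError, match=r"'m2'.*'5'"):
            read_growth_csv(_write(tmp_path, text))

    def test_non_numeric_volume(self, tmp_path):
        text = WIDE.replace("40", "high")
        with pytest.raises(DatasetError, match="missing or non-numeric"):
            read_growth_csv(_write(tmp_path, text))

    def test_duplicate_animal(self, tmp_path):
        text = WIDE.replace("m2", "m1")
        with pytest.raises(DatasetError, match="duplicate animal_id"):
            read_growth_csv(_write(tmp_path, text))

    def test_named_groups_need_control(self, tmp_path):
        text = WIDE.replace(",0,", ",ctrl,").replace(",1,", ",drug,")
        with pytest.raises(DatasetError, match="control"):
            read_growth_csv(_write(tmp_path, text))
        ds = read_growth_csv(_write(tmp_path, text), control="ctrl")
        np.testing.assert_array_equal(ds.group, [0, 0, 1, 1])
        with pytest.raises(DatasetError, match="not among"):
            read_growth_csv(_write(tmp_path, text), control="nope")

    def test_unknown_group_count(self, tmp_path):
        text = WIDE.replace("m4,1", "m4,2x")
        with pytest.raises(DatasetError, match="two group labels"):
            read_growth_csv(_write(tmp_path, text), control="0")

    def test_log_transform(self, tmp_path):
        ds = read_growth_csv(_write(tmp_path, WIDE), log_transform=True)
        assert ds.scale == "log"
        assert ds.volumes[0, 0] == pytest.approx(math.log(10))

    def test_log_transform_rejects_nonpositive(self, tmp_path):
        text = WIDE.replace("10,20,40", "-1,20,40")
        with pytest.raises(DatasetError, match="positive"):
            read_growth_csv(_write(tmp_path, text), log_transform=True)

    def test_roundtrip(self, tmp_path, fixture_dataset):
        path = tmp_path / "rt.csv"
        write_growth_csv(fixture_dataset, path)
        back = read_growth_csv(path)
        np.testing.assert_allclose(back.volumes, fixture_dataset.volumes)
        np.testing.assert_array_equal(back.group, fixture_dataset.group)
        np.testing.assert_allclose(back.times, fixture_dataset.times)
        assert back.animal_ids == fixture_dataset.animal_ids


class TestAnalyzeCurves:
    def test_identical_groups_all_p_one(self):
        rng = np.random.default_rng(0)
        half = np.cumsum(rng.lognormal(0, 0.2, (4, 5)), axis=1) + 1
        ds = GrowthCurveDataset(
            animal_ids=tuple(range(8)),
            group=np.repeat([0, 1], 4),
            times=np.arange(1.0, 6.0),
            volumes=np.vstack([half, half]),
        )
        rows = analyze_curves(ds)
        for row in rows:
            assert row.p_ttest == pytest.approx(1.0)
            if row.p_homologous is not None:
                assert row.p_homologous == pytest.approx(1.0)

    def test_composition_with_direct_calls(self, fixture_dataset):
        rows = analyze_curves(fixture_dataset, sides="two", alpha=0.05)
        assert len(rows) == fixture_dataset.n_times
        assert rows[0].flag == "baseline"
        assert rows[0].p_homologous is None
        for j, row in enumerate(rows[1:], start=2):
            res = homologous_test(fixture_dataset, j, sides="two")
            assert row.p_homologous == pytest.approx(res.p_two_sided, rel=1e-12)
            tt = two_sample_t(
                fixture_dataset.volumes_at(j, 0), fixture_dataset.volumes_at(j, 1)
            )
            assert row.p_ttest == pytest.approx(tt.p_two_sided, rel=1e-12)
            s0, s1 = res.group_summaries
            assert row.rho_0 == pytest.approx(s0.rho)
            assert row.rho_1 == pytest.approx(s1.rho)
            f0, f1 = res.group_fits
            assert row.se_homologous_0 == pytest.approx(f0.se_conditional_mean)
            assert row.se_homologous_1 == pytest.approx(f1.se_conditional_mean)

    def test_report_columns(self, fixture_dataset):
        frame = report_frame(analyze_curves(fixture_dataset))
        expected = {
            "time",
            "j",
            "mean_0",
            "mean_1",
            "se_homologous_0",
            "se_homologous_1",
            "se_standard_0",
            "se_standard_1",
            "rho_0",
            "rho_1",
            "p_homologous",
            "p_ttest",
            "flag",
        }
        assert set(frame.columns) == expected

    def test_se_ordering_invariant(self, fixture_dataset):
        n = fixture_dataset.group_size(0)
        bound = math.sqrt((n - 1) / (n - 2))
        for row in analyze_curves(fixture_dataset)[1:]:
            assert row.se_homologous_0 <= row.se_standard_0 * bound + 1e-12
            assert row.se_homologous_1 <= row.se_standard_1 * bound + 1e-12

    def test_degenerate_column_flags_row(self):
        vols = np.array(
            [
                [1.0, 2.0, 4.0],
                [1.0, 3.0, 5.0],
                [1.0, 2.5, 4.5],
                [1.0, 2.2, 4.1],
                [1.0, 3.1, 5.2],
                [1.0, 2.8, 4.8],
            ]
        )  # baseline constant in both groups -> j=2 fit degenerate
        ds = GrowthCurveDataset(
            animal_ids=tuple(range(6)),
            group=np.repeat([0, 1], 3),
            times=[1.0, 2.0, 3.0],
            volumes=vols,
        )
        rows = analyze_curves(ds)
        assert rows[1].flag.startswith("degenerate")
        assert rows[1].p_homologous is None
        assert rows[2].p_homologous is not None  # report continues

    def test_render_rounds_to_3_decimals(self, fixture_dataset):
        text = render_report(analyze_curves(fixture_dataset))
        cell = text.splitlines()[1].split("\t")[2]
        assert len(cell.split(".")[-1]) <= 3

    def test_json_full_precision(self, fixture_dataset):
        rows = analyze_curves(fixture_dataset)
        doc = json.loads(report_json(rows, {"seed": 42}))
        assert doc["metadata"]["seed"] == 42
        assert doc["rows"][3]["p_homologous"] == rows[3].p_homologous


class TestFixtureGenerator:
    def test_deterministic(self):
        a = generate_fixture(FixtureSpec(seed=11))
        b = generate_fixture(FixtureSpec(seed=11))
        np.testing.assert_array_equal(a.volumes, b.volumes)
        c = generate_fixture(FixtureSpec(seed=12))
        assert not np.array_equal(a.volumes, c.volumes)

    def test_positive_volumes(self, fixture_dataset):
        assert (fixture_dataset.volumes > 0).all()
        assert fixture_dataset.n_animals == 8
        assert fixture_dataset.n_times == 9

    def test_lag_correlation_near_target(self):
        spec = FixtureSpec(n_per_group=50, rho=0.9, seed=3, scale="log")
        ds = generate_fixture(spec)
        rhos = []
        for g in (0, 1):
            v = ds.volumes[ds.group == g]
            for j in range(1, ds.n_times):
                rhos.append(np.corrcoef(v[:, j - 1], v[:, j])[0, 1])
        assert np.mean(rhos) == pytest.approx(0.9, abs=0.05)

    def test_null_t_rejection_rate_near_alpha(self):
        # identical mean curves: the t test's rejection rate across seeds ~ alpha
        rejections = 0
        n_seeds = 400
        for seed in range(n_seeds):
            spec = FixtureSpec(
                growth_rates=(0.2, 0.2), seed=seed, scale="log", times=(1, 2, 3)
            )
            ds = generate_fixture(spec)
            tt = two_sample_t(ds.volumes_at(3, 0), ds.volumes_at(3, 1))
            rejections += tt.p_two_sided <= 0.05
        rate = rejections / n_seeds
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_seeds)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            FixtureSpec(rho=1.0)
        with pytest.raises(ValueError):
            FixtureSpec(noise_sd=0.0)
        with pytest.raises(ValueError):
            FixtureSpec(n_per_group=2)


class TestLongConversion:
    def test_to_long_shape(self, fixture_dataset):
        long = to_long(fixture_dataset)
        assert len(long) == fixture_dataset.n_animals * fixture_dataset.n_times
        assert set(long.columns) == {"animal", "group", "time", "volume"}
        pivot = long.pivot(index="animal", columns="time", values="volume")
        pivot = pivot.loc[list(fixture_dataset.animal_ids)]
        np.testing.assert_allclose(pivot.to_numpy(), fixture_dataset.volumes)


class TestCli:
    @pytest.fixture
    def csv_path(self, tmp_path, fixture_dataset):
        p = tmp_path / "study.csv"
        write_growth_csv(fixture_dataset, p)
        return str(p)

    def test_test_command(self, csv_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["test", "--input", csv_path, "--j", "9"])
        assert result.exit_code == 0, result.output
        doc = json.loads(result.output)
        assert 0 <= doc["p_two_sided"] <= 1
        assert doc["df"] == 4

    def test_report_command_deterministic(self, csv_path, tmp_path):
        runner = CliRunner()
        args = ["report", "--input", csv_path]
        out1 = runner.invoke(cli_main, args)
        out2 = runner.invoke(cli_main, args)
        assert out1.exit_code == 0, out1.output
        assert out1.output == out2.output
        json_path = tmp_path / "rep.json"
        res = runner.invoke(cli_main, args + ["--json-out", str(json_path)])
        assert res.exit_code == 0
        doc = json.loads(json_path.read_text())
        assert len(doc["rows"]) == 9

    def test_power_command(self):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["power", "--test", "t", "--n", "16", "--delta", "1", "--sd", "1"],
        )
        assert res.exit_code == 0
        assert round(json.loads(res.output)["power"], 2) == 0.78

    def test_simulate_study1_command(self):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["simulate-study1", "--sigma", "0.4", "--reps", "500", "--seed", "1"],
        )
        assert res.exit_code == 0, res.output
        doc = json.loads(res.output)
        assert doc["homologous"]["power"] > doc["t_test"]["power"]

    def test_simulate_study2_command(self):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["simulate-study2", "--scenario", "null", "--reps", "50", "--seed", "2"],
        )
        assert res.exit_code == 0, res.output
        doc = json.loads(res.output)
        assert set(doc) == {"homologous", "t_test", "lmm"}

    def test_fixture_command_roundtrip(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "fix.csv"
        res = runner.invoke(
            cli_main, ["fixture", "--out", str(out), "--seed", "7"]
        )
        assert res.exit_code == 0, res.output
        ds = read_growth_csv(out)
        assert ds.volumes.shape == (8, 9)
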