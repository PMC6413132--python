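import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from cytomorph.cli import main
from cytomorph.config import (
    RunConfig,
    config_from_dict,
    config_hash,
    config_to_dict,
    load_config,
    save_config,
)
from cytomorph.errors import ConfigError
from cytomorph.io import read_json, read_table


class TestConfig:
    def test_round_trip(self, tmp_path):
        cfg = RunConfig(seed=7, n_frames=12)
        path = tmp_path / "config.yaml"
        save_config(cfg, path)
        loaded = load_config(path)
        assert config_to_dict(loaded) == config_to_dict(cfg)
        assert config_hash(loaded) == config_hash(cfg)

    def test_unknown_top_level_key_named(self):
        with pytest.raises(ConfigError, match="bogus_key"):
            config_from_dict({"bogus_key": 1})

    def test_unknown_section_key_named(self):
        section = config_to_dict(RunConfig())["pulse"]
        section["unknown_field"] = 5
        with pytest.raises(ConfigError, match="unknown_field"):
            config_from_dict({"pulse": section})

    def test_missing_section_key_named(self):
        section = config_to_dict(RunConfig())["geometry"]
        del section["delta_um"]
        with pytest.raises(ConfigError, match="delta_um"):
            config_from_dict({"geometry": section})

    def test_invalid_value_rejected(self):
        section = config_to_dict(RunConfig())["pulse"]
        section["duration_us"] = -1.0
        with pytest.raises(ConfigError):
            config_from_dict({"pulse": section})

    def test_defaults_audit(self):
        # every externally anchored constant at its documented value
        cfg = RunConfig()
        assert cfg.thresholds.trigger_area_um2 == 300.0
        assert cfg.geometry.delta_um == 8.3
        assert cfg.pulse.voltage_v == 40.0
        assert cfg.pulse.duration_us == 100.0
        assert cfg.thresholds.fl_floor == 16
        assert cfg.thresholds.reference_nucleus_area_um2 == 20.0
        assert cfg.thresholds.area_floor_um2 == 10.0
        assert cfg.histograms["area_um2"] == {"width": 20.0, "start": 10.0}
        assert cfg.histograms["aspect_ratio"] == {"width": 0.2, "start": 1.0}
        assert cfg.stream.frame_rate == 200.0
        assert cfg.stream.channel_width == 50.0
        assert cfg.stream.channel_height == 22.0
        assert cfg.geometry.electrode_width_um == 13.0
        assert cfg.stream.flow_speed == 3.0
        assert cfg.rules.large_single_band == (90.0, 150.0)
        assert cfg.rules.cluster_2plus_band == (150.0, 270.0)
        assert cfg.rules.cluster_3plus_min == 270.0


@pytest.fixture(scope="module")
def sim_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    runner = CliRunner()
    result = runner.invoke(main, ["simulate", "--seed", "5", "--n-frames", "25", "--out", str(out)])
    assert result.exit_code == 0, result.output
    return out


class TestSimulateCLI:
    def test_outputs_exist(self, sim_dir):
        for name in ("frames.tif", "masks.tif", "ground_truth.csv", "background.tif", "manifest.json", "config.yaml"):
            assert (sim_dir / name).exists(), name

    def test_manifest_hash_reproducible(self, sim_dir, tmp_path):
        runner = CliRunner()
        result = runner.invoke(main, ["simulate", "--seed", "5", "--n-frames", "25", "--out", str(tmp_path)])
        assert result.exit_code == 0
        m1 = read_json(sim_dir / "manifest.json")
        m2 = read_json(tmp_path / "manifest.json")
        assert m1["config_hash"] == m2["config_hash"]
        assert (
            open(sim_dir / "ground_truth.csv").read() == open(tmp_path / "ground_truth.csv").read()
        )

    def test_zero_frames_rejected(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(main, ["simulate", "--n-frames", "0", "--out", str(tmp_path)])
        assert result.exit_code != 0

    def test_missing_config_key_fails_with_name(self, tmp_path):
        bad = config_to_dict(RunConfig())
        del bad["thresholds"]["fl_floor"]
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(bad))
        runner = CliRunner()
        result = runner.invoke(main, ["simulate", "--config", str(path), "--out", str(tmp_path / "o")])
        assert result.exit_code != 0
        assert "fl_floor" in str(result.exception or result.output)


class TestAnalyzeCLI:
    def test_fixture_object_count_matches_truth(self, sim_dir, tmp_path):
        runner = CliRunner()
        out_csv = tmp_path / "objects.csv"
        result = runner.invoke(
            main,
            [
                "analyze", "--frames", str(sim_dir / "frames.tif"),
                "--background", str(sim_dir / "background.tif"),
                "--ground-truth", str(sim_dir / "ground_truth.csv"),
                "--out", str(out_csv),
            ],
        )
        assert result.exit_code == 0, result.output
        objects = read_table(out_csv)
        truth = read_table(sim_dir / "ground_truth.csv")
        assert len(objects) == len(truth)

    def test_empty_stack_gives_header_only_csv(self, tmp_path):
        import tifffile

        from cytomorph.synthgen import OpticsModel

        optics = OpticsModel(noise_sd=0.0)
        page = np.hstack(
            [
                np.full((optics.frame_height, optics.frame_width), 200, np.uint8),
                np.full((optics.frame_height, optics.frame_width), 8, np.uint8),
            ]
        )
        tifffile.imwrite(tmp_path / "frames.tif", page[None])
        tifffile.imwrite(tmp_path / "bg.tif", page)
        runner = CliRunner()
        out_csv = tmp_path / "objects.csv"
        result = runner.invoke(
            main,
            ["analyze", "--frames", str(tmp_path / "frames.tif"),
             "--background", str(tmp_path / "bg.tif"), "--out", str(out_csv)],
        )
        assert result.exit_code == 0, result.output
        table = read_table(out_csv)
        assert len(table) == 0
        assert "area_um2" in table.columns

    def test_corrupt_tiff_reports_filename(self, tmp_path):
        bad = tmp_path / "corrupt.tif"
        bad.write_bytes(b"this is not a tiff")
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["analyze", "--frames", str(bad), "--background", str(bad), "--out", str(tmp_path / "o.csv")],
        )
        assert result.exit_code != 0
        assert "corrupt.tif" in result.output


@pytest.fixture(scope="module")
def objects_csv(sim_dir, tmp_path_factory):
    out_csv = tmp_path_factory.mktemp("obj") / "objects.csv"
    runner = CliRunner()
    result = runner.invoke(
        main,
        ["analyze", "--frames", str(sim_dir / "frames.tif"),
         "--background", str(sim_dir / "background.tif"),
         "--ground-truth", str(sim_dir / "ground_truth.csv"),
         "--out", str(out_csv)],
    )
    assert result.exit_code == 0, result.output
    return out_csv


class TestSortDistCLI:
    def test_sort_outputs(self, objects_csv, tmp_path):
        runner = CliRunner()
        result = runner.invoke(main, ["sort", "--objects", str(objects_csv), "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output
        events = read_table(tmp_path / "events.csv")
        summary = read_json(tmp_path / "summary.json")
        assert len(events) == summary["n_total"]
        assert summary["n_collection"] + summary["n_discard"] == summary["n_total"]
        triggered = events[events["triggered"]]
        if len(triggered):
            assert (triggered["voltage_v"] == 40.0).all()
            assert (triggered["duration_us"] == 100.0).all()

    def test_dist_single_input(self, objects_csv, tmp_path):
        runner = CliRunner()
        result = runner.invoke(main, ["dist", str(objects_csv), "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output
        summary = read_json(tmp_path / "summary.json")
        assert len(summary["inputs"]) == 1
        assert (tmp_path / f"hist_area_um2_{objects_csv.stem}.csv").exists()

    def test_dist_five_inputs_timecourse(self, objects_csv, tmp_path):
        paths = []
        table = read_table(objects_csv)
        for day in (2, 4, 7, 9, 11):
            p = tmp_path / f"day{day}.csv"
            table.to_csv(p, index=False)
            paths.append(str(p))
        runner = CliRunner()
        result = runner.invoke(main, ["dist", *paths, "--out", str(tmp_path / "rep")])
        assert result.exit_code == 0, result.output
        summary = read_json(tmp_path / "rep" / "summary.json")
        assert len(summary["inputs"]) == 5
        assert len(summary["pairwise_tv"]) == 10
        for entry in summary["pairwise_tv"]:
            assert entry["tv_distance"] == pytest.approx(0.0)

    def test_report_renders_png(self, objects_csv, tmp_path):
        runner = CliRunner()
        result = runner.invoke(main, ["report", str(objects_csv), "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / f"report_{objects_csv.stem}.png").exists()


class TestEndToEndDeterminism:
    def test_full_chain_bit_reproducible(self, tmp_path):
        runner = CliRunner()
        outputs = []
        for rep in ("a", "b"):
            d = tmp_path / rep
            r = runner.invoke(main, ["simulate", "--seed", "9", "--n-frames", "15", "--out", str(d)])
            assert r.exit_code == 0, r.output
            r = runner.invoke(
                main,
                ["analyze", "--frames", str(d / "frames.tif"), "--background", str(d / "background.tif"),
                 "--ground-truth", str(d / "ground_truth.csv"), "--out", str(d / "objects.csv")],
            )
            assert r.exit_code == 0, r.output
            r = runner.invoke(main, ["sort", "--objects", str(d / "objects.csv"), "--out", str(d / "sorted")])
            assert r.exit_code == 0, r.output
            r = runner.invoke(main, ["dist", str(d / "objects.csv"), "--out", str(d / "dist")])
            assert r.exit_code == 0, r.output
            outputs.append(
                (
                    (d / "objects.csv").read_text(),
                    (d / "sorted" / "events.csv").read_text(),
                    (d / "sorted" / "summary.json").read_text(),
                    (d / "dist" / "summary.json").read_text(),
                )
            )
        assert outputs[0] == outputs[1]
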