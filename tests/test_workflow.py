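"""Workflow I/O, pipeline determinism, and CLI wiring."""

import json
from pathlib import Path

import numpy as np
import pytest
from click.testing import CliRunner

import ishquant as iq
from ishquant import io as iio
from ishquant.cli import cli
from ishquant.config import ImageInput, RunConfig, StudyConfig
from ishquant.errors import FormatError
from ishquant.pipeline import run_pipeline

SMALL_STUDY = StudyConfig(n_animals=1, sections_per_animal=2, images_per_section=2,
                          sim=iq.SimConfig(n_cells=15, field_size_px=(192, 192)))


class TestImageStackIO:
    def test_round_trip_bit_identical(self, default_field, tmp_path):
        stack, _ = default_field
        path = tmp_path / "field.tif"
        iio.write_image_stack(stack, path)
        back = iio.read_image_stack(path)
        assert set(back.channels) == set(stack.channels)
        for ch in stack.channels:
            assert back.channels[ch].tobytes() == stack.channels[ch].tobytes()
        assert back.pixel_size_um == stack.pixel_size_um
        assert back.channel_roles == stack.channel_roles

    def test_channel_count_mismatch_is_format_error(self, default_field, tmp_path):
        stack, _ = default_field
        path = tmp_path / "field.tif"
        iio.write_image_stack(stack, path)
        with pytest.raises(FormatError, match="4"):
            iio.read_image_stack(path, channel_names=("DAPI", "Gprc5b", "Gad1"))

    def test_configured_names_match_page_count(self, default_field, tmp_path):
        stack, _ = default_field
        path = tmp_path / "field.tif"
        iio.write_image_stack(stack, path)
        names = tuple(stack.channels)
        back = iio.read_image_stack(path, channel_names=names)
        assert list(back.channels) == list(names)

    def test_missing_file_is_io_error(self):
        with pytest.raises(FormatError, match="nowhere.tif"):
            iio.read_image_stack("nowhere.tif")

    def test_cell_table_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({"cell_id": [1, 2], "Gprc5b_dot_count": [3, 0]})
        path = tmp_path / "cells.csv"
        iio.write_cell_table(df, path)
        assert Path(path).read_text().startswith(f"# {iio.CELL_TABLE_SCHEMA}")
        back = iio.read_cell_table(path)
        pd.testing.assert_frame_equal(back, df)


class TestRunPipeline:
    def test_end_to_end_on_small_study(self, tmp_path):
        cfg = RunConfig(study=SMALL_STUDY, make_plots=False)
        res = run_pipeline(cfg, out_dir=tmp_path / "run", seed=1)
        n_gt = SMALL_STUDY.n_images * SMALL_STUDY.sim.n_cells
        # one row per segmented cell; segmentation misses are rare
        assert res.cell_table.shape[0] >= 0.9 * n_gt
        assert {"animal_id", "section_id", "image_id", "cell_id",
                "type_label", "positive_Gprc5b"} <= set(res.cell_table.columns)
        for name in ("cell_table.csv", "manifest.json", "summary.json"):
            assert (tmp_path / "run" / name).exists()
        manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert manifest["seed"] == 1 and manifest["n_images"] == 4

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = RunConfig(study=SMALL_STUDY, make_plots=False)
        for d in ("a", "b"):
            run_pipeline(cfg, out_dir=tmp_path / d, seed=5)
        for name in ("cell_table.csv", "summary.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_unknown_probe_rejected_before_compute(self):
        with pytest.raises(Exception, match="Nope"):
            RunConfig(study=SMALL_STUDY,
                      positivity=iq.PositivityOptions(target_channel="Nope"))

    def test_disk_inputs_match_simulated_run(self, tmp_path):
        """Quantifying written TIFFs reproduces the simulated-study table."""
        cfg = RunConfig(study=SMALL_STUDY, make_plots=False)
        res_sim = run_pipeline(cfg, seed=3)
        img_dir = tmp_path / "imgs"
        img_dir.mkdir()
        inputs = []
        for ids, stack, _ in iq.simulate_study(SMALL_STUDY, seed=3):
            p = img_dir / f"{ids['image_id']}.tif"
            iio.write_image_stack(stack, p)
            inputs.append(ImageInput(path=str(p), **ids))
        cfg2 = RunConfig(inputs=tuple(inputs), make_plots=False)
        res_disk = run_pipeline(cfg2)
        a = res_sim.cell_table.drop(columns=["animal_id", "section_id", "image_id"])
        b = res_disk.cell_table.drop(columns=["animal_id", "section_id", "image_id"])
        assert a.equals(b)


class TestCli:
    def test_simulate_writes_files(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "study.yaml"
        cfg.write_text(
            "n_animals: 1\nsections_per_animal: 1\nimages_per_section: 2\n"
            "sim:\n  n_cells: 8\n  field_size_px: [160, 160]\n"
        )
        out = tmp_path / "sim"
        res = runner.invoke(cli, ["simulate", "--config", str(cfg),
                                  "--seed", "7", "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert len(list(out.glob("*.tif"))) == 2
        assert len(list(out.glob("*ground_truth_cells.csv"))) == 2

    def test_quantify_then_compare(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "run.yaml"
        cfg.write_text(
            "study:\n  n_animals: 1\n  sections_per_animal: 2\n  images_per_section: 2\n"
            "  sim:\n    n_cells: 15\n    field_size_px: [192, 192]\n"
            "make_plots: false\n"
        )
        out = tmp_path / "run"
        res = runner.invoke(cli, ["quantify", "--config", str(cfg),
                                  "--seed", "2", "--out", str(out)])
        assert res.exit_code == 0, res.output
        summary_path = tmp_path / "cmp.json"
        res = runner.invoke(cli, ["compare", "--cell-table", str(out / "cell_table.csv"),
                                  "--pop-a", "glutamatergic", "--pop-b", "GABAergic",
                                  "--out", str(summary_path)])
        assert res.exit_code == 0, res.output
        payload = json.loads(summary_path.read_text())
        assert "p_two_sided" in payload["rank_sum"]
        res = runner.invoke(cli, ["report", "--summary", str(summary_path),
                                  "--out", str(tmp_path / "plots")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "plots" / "histograms.png").exists()

    def test_missing_input_file_fails_with_path(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "bad.yaml"
        cfg.write_text(
            "inputs:\n  - path: /no/such/image.tif\nchannel_names: [DAPI, Gprc5b]\n"
            "pixel_size_um: 0.5\nmake_plots: false\n"
        )
        res = runner.invoke(cli, ["quantify", "--config", str(cfg),
                                  "--out", str(tmp_path / "o")])
        assert res.exit_code != 0
        assert "image.tif" in str(res.output) + str(res.exception)

    def test_unknown_flag_exits_2(self):
        res = CliRunner().invoke(cli, ["simulate", "--bogus"])
        assert res.exit_code == 2


class TestManifestExtras:
    def test_positivity_sensitivity_reported_and_monotone(self, tmp_path):
        cfg = RunConfig(study=SMALL_STUDY, make_plots=False)
        res = run_pipeline(cfg, seed=4)
        sens = res.manifest["percent_positive_sensitivity"]
        assert set(sens) == {"min_dots=1", "min_dots=2", "min_dots=3"}
        for pop in ("glutamatergic", "GABAergic"):
            series = [sens[f"min_dots={m}"][pop] for m in (1, 2, 3)]
            assert series == sorted(series, reverse=True)

    def test_intensity_sum_mode_available(self, tmp_path):
        cfg = RunConfig(study=SMALL_STUDY, make_plots=False)
        res = run_pipeline(cfg, seed=4)
        col = res.cell_table["Gprc5b_intensity_sum"]
        assert (col >= 0).all()
        # cells with no dots carry zero summed intensity
        zero = res.cell_table["Gprc5b_dot_count"] == 0
        assert (col[zero] == 0).all()
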