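import numpy as np
import pytest
import tifffile
from click.testing import CliRunner

from neuromorph import RunConfig, SceneSpec, explore, read_image, render_scene, run_batch
from neuromorph.cli import main
from neuromorph.interface import INTERMEDIATE_NAMES, write_image


@pytest.fixture(scope="module")
def scene_dir(tmp_path_factory, params):
    d = tmp_path_factory.mktemp("scenes")
    for i in range(3):
        img, _ = render_scene(SceneSpec(seed=i, shape=(192, 192), n_somata=2))
        write_image(d / f"scene_{i}.tif", img)
    return d


class TestReadImage:
    def test_8bit_gets_gmax_255(self, tmp_path):
        p = tmp_path / "a.tif"
        tifffile.imwrite(p, np.full((8, 8), 200, np.uint8))
        assert read_image(p).gmax == 255

    def test_12bit_data_in_16bit_container(self, tmp_path):
        p = tmp_path / "b.tif"
        tifffile.imwrite(p, np.full((8, 8), 4000, np.uint16))
        assert read_image(p).gmax == 4095

    def test_full_16bit_range(self, tmp_path):
        p = tmp_path / "c.tif"
        tifffile.imwrite(p, np.full((8, 8), 60000, np.uint16))
        assert read_image(p).gmax == 65535

    def test_missing_file_error_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.tif"):
            read_image(tmp_path / "nope.tif")

    def test_multichannel_rejected_with_guidance(self, tmp_path):
        p = tmp_path / "rgb.tif"
        tifffile.imwrite(p, np.zeros((8, 8, 3), np.uint8))
        with pytest.raises(ValueError, match="channel"):
            read_image(p)


class TestRunBatch:
    def test_batch_rows_failures_and_determinism(self, scene_dir, tmp_path, params):
        (scene_dir / "corrupt.tif").write_bytes(b"not a tiff")
        files = sorted(scene_dir.glob("*.tif"))
        out1 = tmp_path / "r1.csv"
        summary = run_batch(RunConfig(inputs=files, output_csv=out1, params=params))
        assert summary.processed == 3 and summary.failed == 1
        assert summary.failures[0][0] == "corrupt.tif"
        lines = out1.read_text().splitlines()
        assert lines[0].startswith("#") and "lowc=" in lines[0]
        assert len(lines) == 2 + 3  # params comment + header + one row per image
        out2 = tmp_path / "r2.csv"
        run_batch(RunConfig(inputs=files, output_csv=out2, params=params))
        assert out1.read_text() == out2.read_text()

    def test_empty_input_rejected(self, tmp_path, params):
        with pytest.raises(ValueError):
            run_batch(RunConfig(inputs=[], output_csv=tmp_path / "x.csv",
                                params=params))

    def test_physical_units_columns(self, scene_dir, tmp_path, params):
        files = [sorted(scene_dir.glob("scene_*.tif"))[0]]
        out = tmp_path / "um.csv"
        run_batch(RunConfig(inputs=files, output_csv=out, params=params,
                            pixel_size_um=0.65))
        header = out.read_text().splitlines()[1]
        assert "neurite_length_um" in header and "soma_total_area_um2" in header


class TestExplore:
    def test_writes_named_intermediates_and_tables(self, scene_dir, tmp_path, params):
        src = sorted(scene_dir.glob("scene_*.tif"))[0]
        outdir = tmp_path / "explore"
        result = explore(src, params, outdir)
        assert len(INTERMEDIATE_NAMES) == 12
        for name in INTERMEDIATE_NAMES:
            assert (outdir / f"{name}.tif").exists()
        hist = (outdir / "histogram.csv").read_text().splitlines()[1:]
        n_pixels = 192 * 192
        assert sum(int(r.split(",")[1]) for r in hist) == n_pixels
        assert sum(int(r.split(",")[2]) for r in hist) == n_pixels
        assert (outdir / "quantification.csv").exists()
        assert result["soma_count"] >= 1

    def test_rerun_is_identical(self, scene_dir, tmp_path, params):
        src = sorted(scene_dir.glob("scene_*.tif"))[0]
        d1, d2 = tmp_path / "e1", tmp_path / "e2"
        explore(src, params, d1)
        explore(src, params, d2)
        assert (d1 / "I-new.tif").read_bytes() == (d2 / "I-new.tif").read_bytes()


class TestCli:
    def test_simulate_then_run(self, tmp_path):
        runner = CliRunner()
        scenes = tmp_path / "sim"
        r = runner.invoke(main, ["simulate", "--outdir", str(scenes),
                                 "--n-scenes", "1", "--seed", "4"])
        assert r.exit_code == 0, r.output
        assert (scenes / "scene_000.tif").exists()
        assert (scenes / "scene_000.truth.json").exists()
        out = tmp_path / "batch.csv"
        r = runner.invoke(main, ["run", str(scenes), "--out", str(out),
                                 "--lowc", "15", "--lowi", "40"])
        assert r.exit_code == 0, r.output
        assert out.exists() and "processed 1" in r.output

    def test_config_file_with_cli_override(self, tmp_path):
        runner = CliRunner()
        scenes = tmp_path / "sim"
        runner.invoke(main, ["simulate", "--outdir", str(scenes), "--n-scenes", "1"])
        cfg = tmp_path / "params.cfg"
        cfg.write_text("lowc=15\nlowi=999\npsize=20\n")
        out = tmp_path / "b.csv"
        r = runner.invoke(main, ["run", str(scenes), "--out", str(out),
                                 "--config", str(cfg), "--lowi", "40"])
        assert r.exit_code == 0, r.output
        assert "lowi=40" in out.read_text().splitlines()[0]

    def test_evaluate_and_fit_dose(self, tmp_path):
        runner = CliRunner()
        table = tmp_path / "counts.csv"
        table.write_text("image,ma,ne,tp,fp,fn\n1,12,16,12,4,0\n2,15,15,15,0,0\n")
        r = runner.invoke(main, ["evaluate", str(table)])
        assert r.exit_code == 0 and "error_rate=25.00%" in r.output
        dose = tmp_path / "dose.csv"
        rows = ["dose,response"] + [
            f"{d},{100 / (1 + d / 42.0):.6f}" for d in (10, 50, 100, 200, 1000)
        ]
        dose.write_text("\n".join(rows) + "\n")
        r = runner.invoke(main, ["fit-dose", str(dose)])
        assert r.exit_code == 0 and "IC50=42" in r.output
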