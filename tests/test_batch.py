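"""Table building, plotting, and the batch driver's isolation contracts."""

import hashlib
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import ephysbatch as eb
from ephysbatch.batch import AP_GROUPS, _firing_columns, validate_properties
from ephysbatch.errors import ConfigError
from conftest import WINDOW


def run_on(folder, **kwargs):
    cfg = eb.AnalysisConfig(window=WINDOW, **kwargs)
    return eb.run_batch(eb.scan_folder(str(folder)), cfg), cfg


def cell_values_digest(out_dir):
    """Order-stable digest of every cell value in every CSV mirror."""
    h = hashlib.sha256()
    for csv in sorted(Path(out_dir).rglob("*.csv")):
        h.update(csv.name.encode())
        h.update(csv.read_bytes())
    return h.hexdigest()


class TestCanonicalPropertyLists:
    def test_counts(self):
        assert len(eb.FIRING_PROPERTIES) == 24
        assert len(eb.PASSIVE_PROPERTIES) == 10
        assert len(eb.OVERVIEW_PROPERTIES) == 22
        assert len(eb.FIRING_PROPERTIES) + len(eb.PASSIVE_PROPERTIES) == 34

    def test_unknown_property_listed_in_error(self):
        with pytest.raises(ConfigError, match="Sag ratio"):
            validate_properties({"Banana"}, "passive")

    def test_waveform_properties_expand_to_five_groups(self):
        cols = _firing_columns({"AP amplitude"})
        assert cols == [f"AP amplitude ({g})" for g in AP_GROUPS]
        # the combined rise/fall selectables expand to two features x 5 groups
        assert len(_firing_columns({"AP rise/fall rate"})) == 10


@pytest.fixture(scope="module")
def results(fixture_batch):
    folder, manifest, _ = fixture_batch
    cfg = eb.AnalysisConfig(window=WINDOW)
    return {name: eb.analyze_recording(eb.read_recording(path), cfg)
            for name, path in manifest.recordings}


class TestTables:
    def test_sweep_partition_is_exact(self, results):
        for res in results.values():
            fire, quiet = set(res.firing), set(res.passive)
            assert fire.isdisjoint(quiet)
            assert fire | quiet == {sw.index for sw in res.recording}
            assert all(res.firing[i].n_spikes >= 1 for i in fire)

    def test_sheets_named_after_recordings(self, results):
        firing = eb.build_firing_table(results)
        passive = eb.build_passive_table(results)
        assert set(firing) == set(passive) == set(results)

    def test_firing_and_passive_row_counts_partition_sweeps(self, results):
        firing = eb.build_firing_table(results)
        passive = eb.build_passive_table(results)
        for name, res in results.items():
            assert len(firing[name]) == len(res.firing)
            assert len(passive[name]) == len(res.passive)
            assert len(firing[name]) + len(passive[name]) == len(res.recording)

    def test_overview_shape(self, results):
        ov = eb.build_overview_table(results)
        assert ov.shape == (len(results), 22)
        assert list(ov.index) == sorted(results)

    def test_fully_subthreshold_recording_gives_empty_firing_sheet(self, caplog):
        rec, _ = eb.simulate_recording(eb.CellParams(rheobase=1e9), name="quiet")
        res = {"quiet": eb.analyze_recording(rec, eb.AnalysisConfig(window=WINDOW))}
        with caplog.at_level("WARNING", logger="ephysbatch"):
            firing = eb.build_firing_table(res)
        assert len(firing["quiet"]) == 0
        assert any("empty firing sheet" in r.message for r in caplog.records)

    def test_property_selection_subsets_columns(self, results):
        passive = eb.build_passive_table(results, {"Current step", "Input resistance"})
        assert list(passive[next(iter(results))].columns) == [
            "Current step", "Input resistance"]


class TestRunBatch:
    def test_full_run_outputs(self, fixture_batch):
        folder, _, _ = fixture_batch
        report, _ = run_on(folder, output_folder_name="full_run")
        assert report.exit_code == 0
        out = folder / "full_run"
        assert sorted(p.name for p in out.glob("*.xlsx")) == [
            "firing_properties.xlsx", "neuron_overview.xlsx",
            "passive_membrane_properties.xlsx"]
        # four plots per recording
        for name in report.recording_status:
            assert len(list(out.glob(f"{name}_*.png"))) == 4
        assert (out / "run_log.txt").exists()

    def test_missing_values_are_empty_cells(self, fixture_batch):
        folder, _, _ = fixture_batch
        out = folder / "full_run"
        df = pd.read_csv(sorted((out / "passive_membrane_properties_csv").glob("*.csv"))[0],
                         index_col=0)
        # the 0 pA sweep has no per-sweep input resistance: empty cell -> NaN
        assert math.isnan(df.loc[10, "Input resistance"])
        raw = sorted((out / "passive_membrane_properties_csv").glob("*.csv"))[0].read_text()
        assert "nan" not in raw  # missing cells are empty, not sentinel text

    def test_determinism_identical_inputs_identical_cell_values(self, tmp_path):
        eb.write_fixture_batch(str(tmp_path), 2, seed=5)
        d1 = cell_values_digest_for_run(tmp_path, "out_a")
        d2 = cell_values_digest_for_run(tmp_path, "out_b")
        assert d1 == d2

    def test_error_isolation_corrupt_file(self, tmp_path):
        eb.write_fixture_batch(str(tmp_path), 3, seed=9)
        report, _ = run_on(tmp_path, output_folder_name="ref")
        ref = cell_values_digest(tmp_path / "ref")
        assert report.exit_code == 0
        # corrupt one recording: it is skipped, everything else is unchanged
        (tmp_path / "cell_02.tsv").write_text("garbage\nrows\n")
        report2, _ = run_on(tmp_path, output_folder_name="broken")
        assert report2.exit_code == 1
        assert report2.recording_status["cell_01"] == "ok"
        assert report2.recording_status["cell_02"].startswith("skipped")
        ov = pd.read_csv(tmp_path / "broken" / "neuron_overview_csv" / "Overview.csv",
                         index_col=0)
        assert list(ov.index) == ["cell_01", "cell_03"]
        ov_ref = pd.read_csv(tmp_path / "ref" / "neuron_overview_csv" / "Overview.csv",
                             index_col=0)
        pd.testing.assert_frame_equal(ov.loc[["cell_01", "cell_03"]],
                                      ov_ref.loc[["cell_01", "cell_03"]])
        ref_firing = (tmp_path / "ref" / "firing_properties_csv" / "cell_01.csv").read_bytes()
        new_firing = (tmp_path / "broken" / "firing_properties_csv" / "cell_01.csv").read_bytes()
        assert ref_firing == new_firing

    def test_total_failure_produces_no_outputs(self, tmp_path):
        (tmp_path / "only.tsv").write_text("not\ta\tvalid\tfile\n")
        report, _ = run_on(tmp_path, output_folder_name="nothing")
        assert report.exit_code == 2
        assert not (tmp_path / "nothing" / "firing_properties.xlsx").exists()
        assert all(s.startswith("blocked") for s in report.output_status.values())

    def test_duration_mismatch_skips_recording(self, tmp_path):
        eb.write_fixture_batch(str(tmp_path), 2, seed=2)
        proto = eb.ProtocolSpec(sweep_duration=900.0)
        rec, _ = eb.simulate_recording(eb.CellParams(), proto, name="a_short")
        eb.write_delimited(rec, str(tmp_path / "a_short.tsv"))
        report, _ = run_on(tmp_path, output_folder_name="mix")
        # a_short sorts first so it sets the reference; the two standard-length
        # recordings are what get rejected — either way exactly one duration
        # cohort survives
        ok = [n for n, s in report.recording_status.items() if s == "ok"]
        skipped = [n for n, s in report.recording_status.items() if s != "ok"]
        assert report.exit_code == 1
        assert ok == ["a_short"] and sorted(skipped) == ["cell_01", "cell_02"]

    def test_iv_plot_slope_equals_overview_resistance(self, fixture_batch, tmp_path):
        # the regression drawn on the current-voltage plot is literally the
        # overview membrane input resistance (same object, same number)
        folder, manifest, _ = fixture_batch
        name, path = manifest.recordings[0]
        res = eb.analyze_recording(eb.read_recording(path),
                                   eb.AnalysisConfig(window=WINDOW))
        written = eb.render_plots(res, WINDOW, {"current_voltage"}, tmp_path)
        assert written["current_voltage"].name == f"{name}_current_voltage.png"
        amps = np.array([p.step_amplitude for p in res.passive.values()])
        steadies = np.array([p.steady_voltage for p in res.passive.values()])
        slope = np.polyfit(amps, steadies, 1)[0]
        assert slope == pytest.approx(res.overview.membrane_input_resistance, abs=1e-9)


def cell_values_digest_for_run(folder, out_name):
    report, _ = run_on(folder, output_folder_name=out_name)
    assert report.exit_code == 0
    return cell_values_digest(Path(folder) / out_name)
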