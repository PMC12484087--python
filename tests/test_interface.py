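"""Config loading/validation, trace CSV round trips, and the CLI contract."""

import json
import subprocess
import sys

import numpy as np
import pytest
from click.testing import CliRunner

from photodipole import (
    ConfigError,
    Trace,
    TraceFormatError,
    default_config,
    load_config,
    read_trace,
    write_trace,
)
from photodipole.cli import cli


class TestLoadConfig:
    def test_defaults_load_and_match_documented_values(self):
        cfg = load_config(None)
        assert cfg.membrane.cm0 == pytest.approx(26.67)
        assert cfg.membrane.rm == pytest.approx(1.0)
        assert cfg.membrane.vr == pytest.approx(-60.0)
        assert cfg.photoswitch.dcm_rel == pytest.approx(-0.15)
        assert cfg.photoswitch.dvs == pytest.approx(5.0)
        assert cfg.protocol.duration == pytest.approx(20.0)
        assert cfg.simulation.rate == pytest.approx(20.0)
        # the -15 % capacitance step is the documented 4 pF
        assert -cfg.photoswitch.dcm_rel * cfg.membrane.cm0 == pytest.approx(4.0, abs=0.01)

    def test_partial_override_preserves_other_defaults(self, tmp_path):
        p = tmp_path / "override.yaml"
        p.write_text("membrane:\n  vr_mV: -21\n", encoding="utf-8")
        cfg = load_config(p)
        base = default_config()
        assert cfg.membrane.vr == -21.0
        assert cfg.membrane.cm0 == base.membrane.cm0
        assert cfg.photoswitch == base.photoswitch

    def test_json_config_accepted(self, tmp_path):
        p = tmp_path / "override.json"
        p.write_text(json.dumps({"membrane": {"vr_mV": -45}}), encoding="utf-8")
        assert load_config(p).membrane.vr == -45.0

    def test_invalid_value_rejected_naming_field(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("membrane:\n  cm0_pF: -5\n", encoding="utf-8")
        with pytest.raises(ConfigError, match="cm0"):
            load_config(p)

    def test_unknown_key_rejected_naming_key(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("membrane:\n  capacitance: 25\n", encoding="utf-8")
        with pytest.raises(ConfigError, match="capacitance"):
            load_config(p)

    def test_all_violations_reported_together(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text(
            "membrane:\n  cm0_pF: -5\n  bogus: 1\nphotoswitch:\n  tau_on_c_ms: 0\n",
            encoding="utf-8",
        )
        with pytest.raises(ConfigError) as err:
            load_config(p)
        msg = str(err.value)
        assert "cm0" in msg and "bogus" in msg and "tau_on_c" in msg

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(ConfigError):
            load_config(tmp_path / "nope.yaml")


class TestTraceIO:
    def test_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        tr = Trace(t=np.arange(200) / 20.0, v=-60.0 + rng.normal(0, 1, 200), rate=20.0)
        path = tmp_path / "trace.csv"
        write_trace(tr, path)
        back = read_trace(path)
        assert back.rate == pytest.approx(tr.rate, rel=1e-9)
        np.testing.assert_allclose(back.v, tr.v, atol=1e-12)
        np.testing.assert_allclose(back.t, tr.t, atol=1e-12)

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time,voltage\n0.0,-60\n0.05,-60\n", encoding="utf-8")
        with pytest.raises(TraceFormatError, match="header"):
            read_trace(p)

    def test_shuffled_rows_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_ms,vm_mV\n0.05,-60\n0.0,-61\n0.1,-62\n", encoding="utf-8")
        with pytest.raises(TraceFormatError, match="increasing"):
            read_trace(p)

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_ms,vm_mV\n0.0,-60\n0.05,oops\n", encoding="utf-8")
        with pytest.raises(TraceFormatError, match=":3"):
            read_trace(p)


FAST_CFG = "simulation:\n  t_end_ms: 300\n"


class TestCli:
    def test_simulate_writes_outputs(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(FAST_CFG, encoding="utf-8")
        out = tmp_path / "out"
        runner = CliRunner()
        res = runner.invoke(cli, ["simulate", "--config", str(cfg), "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert (out / "simulate_simulation.csv").is_file()
        assert (out / "simulate_metrics.csv").is_file()
        summary = json.loads((out / "simulate_summary.json").read_text())
        assert summary["peak_deflection_mV"] < 0

    def test_synth_writes_ground_truth(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(FAST_CFG, encoding="utf-8")
        out = tmp_path / "synth"
        runner = CliRunner()
        res = runner.invoke(cli, [
            "synth", "--config", str(cfg), "--out", str(out),
            "--n", "2", "--seed", "1", "--sigma", "0.2",
        ])
        assert res.exit_code == 0, res.output
        truths = json.loads((out / "ground_truth.json").read_text())
        assert set(truths) == {"cell_000", "cell_001"}
        tr = read_trace(out / "cell_000.csv")
        assert len(tr.v) == 300 * 20 + 1

    def test_validation_failure_exits_2(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("membrane:\n  cm0_pF: -5\n", encoding="utf-8")
        proc = subprocess.run(
            [sys.executable, "-m", "photodipole", "simulate", "--config", str(cfg)],
            capture_output=True, text=True,
        )
        assert proc.returncode == 2
        assert "cm0" in proc.stderr

    def test_help_available_for_every_subcommand(self):
        runner = CliRunner()
        for sub in ["simulate", "dual-pathway", "vr-sweep", "polarity-panel",
                    "representative-cell", "synth"]:
            res = runner.invoke(cli, [sub, "--help"])
            assert res.exit_code == 0
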