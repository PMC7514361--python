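import json

import numpy as np
import pytest
from click.testing import CliRunner

from spectrank import (
    InvalidInputError,
    InvalidParameterError,
    RunConfig,
    multitone,
    read_signal,
    write_signal_csv,
    write_signal_wav,
)
from spectrank.cli import main


def write_csv(path, values, rate=None):
    with open(path, "w") as handle:
        if rate is not None:
            handle.write(f"# rate={rate}\n")
        for v in values:
            handle.write(f"{v}\n")


class TestReadCsv:
    def test_rate_header_and_length(self, tmp_path, rng):
        path = tmp_path / "semg.csv"
        write_csv(path, rng.normal(0, 1, 3000), rate=500)
        signal = read_signal(path)
        assert len(signal) == 3000
        assert signal.rate == 500.0
        assert signal.duration == pytest.approx(6.0)

    def test_odd_length_truncated(self, tmp_path, caplog):
        path = tmp_path / "odd.csv"
        write_csv(path, range(7))
        with caplog.at_level("WARNING"):
            signal = read_signal(path)
        assert len(signal) == 6
        assert "truncating" in caplog.text

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("1.0\n2.0\noops\n4.0\n")
        with pytest.raises(InvalidInputError, match="bad.csv:3"):
            read_signal(path)

    def test_rate_argument_overrides_header(self, tmp_path):
        path = tmp_path / "r.csv"
        write_csv(path, [0.0, 1.0, 0.0, -1.0], rate=100)
        assert read_signal(path, rate=200.0).rate == 200.0

    def test_csv_round_trip(self, tmp_path, rng):
        signal = multitone(64, 250.0, [(4, 1.0)], noise_sd=0.2, seed=3)
        path = tmp_path / "sig.csv"
        write_signal_csv(path, signal)
        back = read_signal(path)
        assert back.rate == 250.0
        assert np.array_equal(back.samples, signal.samples)  # repr round-trips floats


class TestReadWav:
    def test_float32_round_trip(self, tmp_path):
        signal = multitone(128, 8000.0, [(10, 0.5)], noise_sd=0.05, seed=1)
        path = tmp_path / "tone.wav"
        write_signal_wav(path, signal)
        back = read_signal(path)
        assert back.rate == 8000.0
        assert back.samples == pytest.approx(signal.samples, abs=1e-6)

    def test_pcm16_scaled_to_unit_range(self, tmp_path):
        from scipy.io import wavfile

        data = (np.sin(np.linspace(0, 20, 64)) * 2**14).astype(np.int16)
        path = tmp_path / "pcm.wav"
        wavfile.write(path, 1000, data)
        signal = read_signal(path)
        assert signal.samples == pytest.approx(data / 2.0**15, abs=1e-9)

    def test_stereo_uses_first_channel_with_warning(self, tmp_path):
        from scipy.io import wavfile

        data = np.stack([np.ones(64), -np.ones(64)], axis=1).astype(np.float32)
        path = tmp_path / "stereo.wav"
        wavfile.write(path, 1000, data)
        with pytest.warns(UserWarning, match="first channel"):
            signal = read_signal(path)
        assert np.all(signal.samples == 1.0)


class TestFormatHandling:
    def test_unknown_extension_rejected(self, tmp_path):
        path = tmp_path / "data.xyz"
        path.write_text("1\n2\n")
        with pytest.raises(InvalidParameterError):
            read_signal(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(InvalidInputError):
            read_signal(tmp_path / "nope.csv")


class TestRunConfig:
    def test_validation(self):
        RunConfig(input_path="x.csv")  # defaults valid
        with pytest.raises(InvalidParameterError):
            RunConfig(input_path="x.csv", q=0.0)
        with pytest.raises(InvalidParameterError):
            RunConfig(input_path="x.csv", window_length=1023)
        with pytest.raises(InvalidParameterError):
            RunConfig(input_path="x.csv", step=0)


class TestCli:
    def test_analyze_tail_of_recording(self, tmp_path, rng):
        path = tmp_path / "rec.csv"
        write_csv(path, rng.normal(0, 1, 3000), rate=500)
        out = tmp_path / "result.json"
        result = CliRunner().invoke(
            main, ["analyze", str(path), "--last", "2048", "--no-demean", "-o", str(out)]
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(out.read_text())
        assert payload["n_total"] == 1024
        assert payload["n_used"] == 1024  # q = 1 with all-positive bins keeps all

    def test_track_csv_output(self, tmp_path, rng):
        path = tmp_path / "long.csv"
        write_csv(path, rng.normal(0, 1, 2048), rate=8000)
        out = tmp_path / "track.csv"
        result = CliRunner().invoke(
            main,
            ["track", str(path), "--window", "1024", "--step", "128",
             "--q", "0.9", "-o", str(out)],
        )
        assert result.exit_code == 0, result.output
        lines = out.read_text().splitlines()
        assert len(lines) == 1 + (2048 - 1024) // 128 + 1
        assert lines[0].startswith("end_index,end_time_s,cid")

    def test_null_runs_are_byte_identical(self, tmp_path):
        args = ["null", "--n", "32", "--descriptor", "cod", "--reps", "500",
                "--seed", "1", "--samples"]
        runner = CliRunner()
        outs = []
        for name in ("a.json", "b.json"):
            out = tmp_path / name
            result = runner.invoke(main, args + ["-o", str(out)])
            assert result.exit_code == 0, result.output
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]

    def test_synth_multitone_writes_fixture_and_sidecar(self, tmp_path):
        out = tmp_path / "fix.wav"
        result = CliRunner().invoke(
            main,
            ["synth", "multitone", "--n-samples", "128", "--rate", "8000",
             "--component", "5:2.0", "--component", "9:1.0", "-o", str(out)],
        )
        assert result.exit_code == 0, result.output
        sidecar = json.loads((tmp_path / "fix.wav.json").read_text())
        assert sidecar["components"] == [[5, 2.0], [9, 1.0]]
        assert read_signal(out).rate == 8000.0

    def test_aeeg_command_produces_trace_and_track(self, tmp_path):
        from spectrank import burst_signal

        signal, _ = burst_signal(200.0, 64.0, [(90.0, 110.0, "seizure")], seed=4)
        path = tmp_path / "eeg.csv"
        write_signal_csv(path, signal)
        trace_out, track_out = tmp_path / "trace.csv", tmp_path / "track.csv"
        result = CliRunner().invoke(
            main,
            ["aeeg", str(path), "--window", "64", "--step", "2",
             "--trace-out", str(trace_out), "--track-out", str(track_out)],
        )
        assert result.exit_code == 0, result.output
        assert len(trace_out.read_text().splitlines()) == 201
        assert len(track_out.read_text().splitlines()) == 1 + (200 - 64) // 2 + 1

    def test_usage_error_exits_2(self):
        assert CliRunner().invoke(main, ["analyze"]).exit_code == 2

    def test_data_error_exits_1(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("1.0\nnope\n")
        result = CliRunner().invoke(main, ["analyze", str(path)])
        assert result.exit_code == 1
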