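"""Containers, normalization and bundle I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import psnsleep as ps
from psnsleep.data import EPS_NORM, segment_continuous


def _recording(signal, sr=1):
    return ps.EpochedRecording(signal=np.asarray(signal, dtype=float),
                               sampling_rate=sr, epoch_seconds=np.asarray(signal).shape[1] // sr)


class TestNormalize:
    def test_closed_form_epoch(self):
        rec = _recording([[1.0, 2.0, 3.0]], sr=1)
        out, params = ps.normalize(rec, scope="per_epoch")
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        assert np.allclose(out.signal[0], expected, atol=1e-5)
        assert params.scope == "per_epoch"

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        rec = _recording(rng.standard_normal((4, 30)), sr=1)
        once, _ = ps.normalize(rec)
        twice, _ = ps.normalize(once)
        assert np.allclose(once.signal, twice.signal, atol=1e-6)
        assert np.allclose(once.signal.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(once.signal.std(axis=1), 1.0, atol=1e-9)

    def test_constant_epoch_guarded_with_warning(self):
        rec = _recording([[5.0] * 10, [1.0, 2.0] * 5], sr=1)
        with pytest.warns(RuntimeWarning, match="constant"):
            out, params = ps.normalize(rec)
        assert np.allclose(out.signal[0], 0.0)
        assert params.sigma[0] == EPS_NORM

    def test_per_recording_scope(self):
        rng = np.random.default_rng(1)
        rec = _recording(rng.standard_normal((5, 20)) * 3 + 1, sr=1)
        out, params = ps.normalize(rec, scope="per_recording")
        assert abs(out.signal.mean()) < 1e-9
        assert abs(out.signal.std() - 1.0) < 1e-9
        assert params.scope == "per_recording"

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError, match="scope"):
            ps.normalize(_recording([[1.0, 2.0]], sr=1), scope="per_dataset")

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_idempotence_property(self, seed):
        rng = np.random.default_rng(seed)
        sig = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 10), size=(3, 40))
        once, _ = ps.normalize(_recording(sig, sr=1))
        twice, _ = ps.normalize(once)
        assert np.allclose(once.signal, twice.signal, atol=1e-6)


class TestSegmentation:
    def test_continuous_300s_at_100hz_gives_10_epochs(self):
        rec = segment_continuous(np.arange(30000.0), sampling_rate=100)
        assert rec.n_epochs == 10
        assert rec.epoch_samples == 3000

    def test_partial_trailing_epoch_dropped_and_samples_conserved(self):
        samples = np.arange(30000.0 + 1234)
        rec = segment_continuous(samples, sampling_rate=100)
        assert rec.n_epochs == 10
        assert np.array_equal(rec.signal.ravel(), samples[:30000])

    def test_shorter_than_one_epoch_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            segment_continuous(np.arange(100.0), sampling_rate=100)


class TestRecordingValidation:
    def test_epoch_length_must_match_rate(self):
        with pytest.raises(ValueError, match="epoch length"):
            ps.EpochedRecording(signal=np.zeros((2, 100)), sampling_rate=100)

    def test_non_finite_rejected(self):
        sig = np.zeros((1, 30))
        sig[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ps.EpochedRecording(signal=sig, sampling_rate=1)

    def test_hypnogram_label_range(self):
        with pytest.raises(ValueError, match="5-class"):
            ps.Hypnogram(stages=np.array([0, 1, 7]))


class TestBundleIO:
    @pytest.mark.parametrize("format", ["npz_bundle", "csv_bundle"])
    def test_round_trip_with_hypnogram(self, tmp_path, format):
        rng = np.random.default_rng(2)
        rec = ps.EpochedRecording(signal=rng.standard_normal((4, 300)),
                                  sampling_rate=10, channel="Fpz-Cz", subject_id="S1")
        hyp = ps.Hypnogram(stages=np.array([0, 2, 2, 4]))
        stem = tmp_path / "rec"
        ps.write_recording(rec, hyp, stem, format=format)
        back, hyp_back = ps.read_recording(stem, format=format)
        if format == "npz_bundle":
            assert np.array_equal(back.signal, rec.signal)  # bit-exact
        else:
            assert np.allclose(back.signal, rec.signal)
        assert np.array_equal(hyp_back.stages, hyp.stages)
        assert (back.sampling_rate, back.channel, back.subject_id) == (10, "Fpz-Cz", "S1")

    def test_round_trip_without_hypnogram(self, tmp_path):
        rec = ps.EpochedRecording(signal=np.zeros((2, 30)) + 1.5, sampling_rate=1)
        ps.write_recording(rec, None, tmp_path / "r", format="npz_bundle")
        _, hyp = ps.read_recording(tmp_path / "r")
        assert hyp is None

    def test_wrong_length_hypnogram_rejected_before_writing(self, tmp_path):
        rec = ps.EpochedRecording(signal=np.zeros((3, 30)) + 1.0, sampling_rate=1)
        with pytest.raises(ValueError, match="length"):
            ps.write_recording(rec, ps.Hypnogram(stages=np.array([0, 1])), tmp_path / "r")
        assert not (tmp_path / "r.npz").exists()

    def test_label_epoch_mismatch_on_read(self, tmp_path):
        rec = ps.EpochedRecording(signal=np.ones((6, 30)), sampling_rate=1)
        ps.write_recording(rec, None, tmp_path / "r", format="csv_bundle")
        np.savetxt(tmp_path / "r.labels.csv", np.zeros((5, 1)), fmt="%d")
        with pytest.raises(ValueError, match="do not match"):
            ps.read_recording(tmp_path / "r", format="csv_bundle")

    def test_missing_sidecar_reported(self, tmp_path):
        np.savez(tmp_path / "r.npz", signal=np.ones((1, 30)))
        with pytest.raises(FileNotFoundError, match="sidecar"):
            ps.read_recording(tmp_path / "r")


def _write_minimal_edf(path, data, sr, label="EEG Fpz-Cz"):
    """Single-channel EDF with 1-s records, int16 samples, +/-100 uV physical range."""
    ns, nrec = 1, data.size // sr

    def pad(s, n):
        return s.ljust(n)[:n].encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80), pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (ns + 1)), 8), pad("", 44), pad(str(nrec), 8), pad("1", 8),
        pad(str(ns), 4), pad(label, 16), pad("", 80), pad("uV", 8), pad("-100", 8),
        pad("100", 8), pad("-32768", 8), pad("32767", 8), pad("", 80),
        pad(str(sr), 8), pad("", 32)])
    scaled = np.clip(np.round(data / 100 * 32767), -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(scaled.tobytes())


def test_edf_channel_read_and_resegmented(tmp_path):
    """A continuous EDF channel is re-segmented into 30-s epochs on read."""
    sr = 100
    t = np.arange(sr * 90) / sr
    data = 50 * np.sin(2 * np.pi * 1.0 * t)
    path = tmp_path / "subject_raw.edf"
    _write_minimal_edf(path, data, sr)
    rec, hyp = ps.read_recording(path, format="edf", channel="EEG Fpz-Cz")
    assert hyp is None
    assert rec.n_epochs == 3
    assert rec.epoch_samples == 3000
    # waveform preserved up to the EDF digitization and unit conversion
    assert np.corrcoef(rec.signal.ravel(), data)[0, 1] > 0.999

    with pytest.raises(ValueError, match="channel"):
        ps.read_recording(path, format="edf", channel="EOG")
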