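"""Recording I/O and preprocessing tests.

Filter behaviour is checked against spectral oracles (periodogram power
ratios, FFT peak locations) rather than implementation details.
"""

import numpy as np
import pytest
from scipy.signal import periodogram

from conftest import write_minimal_edf
from pesp.errors import ConfigurationError, ValidationError
from pesp.signal_io import (
    PreprocessConfig,
    Recording,
    SeizureAnnotation,
    notch_filter,
    read_annotations,
    read_recording,
    resample_to,
    select_channels,
    write_annotations,
    write_matrix_recording,
)


def tone(freq, fs=256.0, seconds=8.0, n_channels=1):
    t = np.arange(int(seconds * fs)) / fs
    return Recording(np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1)), fs, [f"c{i}" for i in range(n_channels)])


class TestRecording:
    def test_duration_identity(self):
        rec = Recording(np.zeros((6, 921_600)), 256.0, [f"c{i}" for i in range(6)])
        assert rec.duration == 3600.0

    def test_annotations_sorted_and_bounded(self):
        rec = Recording(
            np.zeros((1, 2560)),
            256.0,
            ["a"],
            [SeizureAnnotation(5, 6), SeizureAnnotation(1, 2)],
        )
        assert [a.onset for a in rec.annotations] == [1, 5]
        with pytest.raises(ValidationError):
            Recording(np.zeros((1, 2560)), 256.0, ["a"], [SeizureAnnotation(9, 11)])

    def test_invalid_annotation_interval(self):
        with pytest.raises(ValidationError):
            SeizureAnnotation(5.0, 5.0)


class TestMatrixIO:
    def test_roundtrip_with_header_and_annotations(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = Recording(
            rng.normal(size=(3, 512)), 256.0, ["A", "B", "C"], [SeizureAnnotation(0.5, 1.0)]
        )
        sig_path = tmp_path / "sig.txt"
        ann_path = tmp_path / "ann.txt"
        write_matrix_recording(rec, sig_path, ann_path)
        back = read_recording(sig_path, format="matrix", annotation_path=ann_path)
        np.testing.assert_allclose(back.signal, rec.signal, rtol=1e-4)
        assert back.fs == 256.0
        assert back.channel_ids == ["A", "B", "C"]
        assert back.annotations[0].onset == pytest.approx(0.5)

    def test_fs_hint_required_without_header(self, tmp_path):
        path = tmp_path / "bare.txt"
        np.savetxt(path, np.zeros((2, 10)))
        with pytest.raises(ConfigurationError):
            read_recording(path, format="matrix")
        rec = read_recording(path, format="matrix", fs_hint=128.0)
        assert rec.fs == 128.0 and rec.n_channels == 2

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError):
            read_recording(tmp_path / "nope.txt", format="matrix", fs_hint=1.0)

    def test_annotation_outside_duration_rejected(self, tmp_path):
        path = tmp_path / "sig.txt"
        ann = tmp_path / "ann.txt"
        rec = Recording(np.zeros((1, 256)), 256.0, ["a"])  # 1 s
        write_matrix_recording(rec, path)
        write_annotations([SeizureAnnotation(2.0, 3.0)], ann)
        with pytest.raises(ValidationError):
            read_recording(path, format="matrix", annotation_path=ann)

    def test_annotation_parser(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("# comment\n10 20\n30.5, 40\n")
        anns = read_annotations(p)
        assert [(a.onset, a.offset) for a in anns] == [(10.0, 20.0), (30.5, 40.0)]


class TestEDF:
    def test_read_minimal_edf(self, tmp_path):
        fs = 128
        t = np.arange(10 * fs) / fs
        sig = np.vstack([100 * np.sin(2 * np.pi * 5 * t), 50 * np.cos(2 * np.pi * 2 * t)])
        path = write_minimal_edf(tmp_path / "two.edf", sig, fs, ["EEG1", "EEG2"])
        rec = read_recording(path, format="edf")
        assert rec.n_channels == 2
        assert rec.n_samples == 10 * rec.fs
        assert rec.fs == fs
        np.testing.assert_allclose(rec.signal, sig, atol=0.1)


class TestNotch:
    def test_attenuates_50hz_tone(self):
        rec = tone(50.0)
        out = notch_filter(rec, PreprocessConfig())
        assert np.sqrt(np.mean(out.signal**2)) < 0.1 * np.sqrt(np.mean(rec.signal**2))
        f_in, p_in = periodogram(rec.signal[0], fs=256.0)
        f_out, p_out = periodogram(out.signal[0], fs=256.0)
        band = (f_in > 49) & (f_in < 51)
        # >= 20 dB power attenuation at the notch
        assert p_out[band].sum() < 1e-2 * p_in[band].sum()

    def test_passband_tone_preserved(self):
        rec = tone(10.0)
        out = notch_filter(rec, PreprocessConfig())
        rms_in = np.sqrt(np.mean(rec.signal**2))
        rms_out = np.sqrt(np.mean(out.signal**2))
        assert abs(rms_out - rms_in) < 0.05 * rms_in

    def test_dc_unchanged(self):
        rec = Recording(np.full((1, 2560), 3.7), 256.0, ["a"])
        out = notch_filter(rec, PreprocessConfig())
        np.testing.assert_allclose(out.signal[:, 200:-200], 3.7, rtol=1e-6)

    def test_notch_above_nyquist_rejected(self):
        rec = tone(10.0, fs=80.0)
        with pytest.raises(ConfigurationError):
            notch_filter(rec, PreprocessConfig(notch_freq=50.0, target_fs=256.0))

    def test_input_not_mutated(self):
        rec = tone(50.0)
        before = rec.signal.copy()
        notch_filter(rec, PreprocessConfig())
        np.testing.assert_array_equal(rec.signal, before)


class TestResample:
    def test_downsample_halves_samples(self):
        rec = Recording(np.random.default_rng(0).normal(size=(2, 1024)), 512.0, ["a", "b"])
        out = resample_to(rec, 256.0)
        assert out.n_samples == 512
        assert out.fs == 256.0
        assert abs(out.duration - rec.duration) <= 1.0 / 256.0

    def test_identity_when_rate_matches(self):
        rec = Recording(np.arange(100.0)[None, :], 256.0, ["a"])
        out = resample_to(rec, 256.0)
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_spectral_peak_preserved(self):
        rec = tone(5.0, fs=512.0, seconds=8.0)
        out = resample_to(rec, 256.0)
        f, p = periodogram(out.signal[0], fs=256.0)
        assert abs(f[np.argmax(p)] - 5.0) < 0.2

    def test_commutes_with_notch_on_bandlimited_tone(self):
        rec = tone(12.0, fs=512.0, seconds=8.0)
        cfg = PreprocessConfig(target_fs=256.0)
        a = resample_to(notch_filter(rec, cfg), 256.0)
        b = notch_filter(resample_to(rec, 256.0), cfg)
        # compare away from filter edge transients
        np.testing.assert_allclose(a.signal[:, 200:-200], b.signal[:, 200:-200], atol=5e-3)


class TestSelectChannels:
    def test_subset_and_reorder(self):
        rec = Recording(np.arange(12.0).reshape(4, 3), 10.0, ["a", "b", "c", "d"])
        out = select_channels(rec, ["d", "b"])
        assert out.channel_ids == ["d", "b"]
        np.testing.assert_array_equal(out.signal, rec.signal[[3, 1]])

    def test_identity_order(self):
        rec = Recording(np.arange(6.0).reshape(2, 3), 10.0, ["a", "b"])
        out = select_channels(rec, ["a", "b"])
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_unknown_id_rejected(self):
        rec = Recording(np.zeros((2, 4)), 10.0, ["a", "b"])
        with pytest.raises(ValidationError):
            select_channels(rec, ["a", "CH999"])

    def test_annotations_carried_over(self):
        rec = Recording(np.zeros((2, 100)), 10.0, ["a", "b"], [SeizureAnnotation(1, 2)])
        out = select_channels(rec, ["b"])
        assert out.annotations == rec.annotations
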