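"""Front-end contracts: loading, DC removal, segmentation, log-Mel, CMVN, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.io import wavfile

from depvox.audio import (
    ValidationError,
    Waveform,
    apply_scaler,
    cmvn,
    fit_scaler,
    frame_count,
    frontend_segments,
    load_waveform,
    logmel,
    mel_center_frequencies,
    mel_filterbank,
    remove_dc,
    save_waveform,
    segment_recording,
)


def sine(freq=440.0, dur=1.0, sr=16000, amp=0.5):
    t = np.arange(int(dur * sr)) / sr
    return Waveform(amp * np.sin(2 * np.pi * freq * t), sr)


class TestLoadWaveform:
    def test_int16_roundtrip_and_scaling(self, tmp_path):
        sr = 44100
        data = np.zeros(sr, dtype=np.int16)
        data[0] = 16384
        path = tmp_path / "x.wav"
        wavfile.write(path, sr, data)
        w = load_waveform(path)
        assert w.sample_rate == sr and w.samples.size == sr
        assert w.samples[0] == pytest.approx(0.5, abs=1.0 / 32768)

    def test_stereo_opposite_channels_cancel(self, tmp_path):
        sr = 8000
        x = (np.sin(2 * np.pi * 100 * np.arange(sr) / sr) * 20000).astype(np.int16)
        stereo = np.stack([x, -x], axis=1)
        path = tmp_path / "st.wav"
        wavfile.write(path, sr, stereo)
        w = load_waveform(path)
        assert np.allclose(w.samples, 0.0)

    def test_missing_file_raises_oserror_naming_path(self, tmp_path):
        with pytest.raises(OSError, match="nope.wav"):
            load_waveform(tmp_path / "nope.wav")

    def test_save_load_roundtrip(self, tmp_path):
        w = sine()
        path = tmp_path / "r.wav"
        save_waveform(path, w)
        back = load_waveform(path)
        assert np.allclose(back.samples, w.samples, atol=1e-4)


class TestRemoveDc:
    @pytest.mark.parametrize("samples,expected", [
        (np.full(100, 0.3), np.zeros(100)),
        (np.array([0.1, 0.3]), np.array([-0.1, 0.1])),
    ])
    def test_mean_subtraction(self, samples, expected):
        out = remove_dc(Waveform(samples, 8000))
        assert np.allclose(out.samples, expected)

    def test_zero_mean_input_unchanged(self):
        w = sine()
        out = remove_dc(w)
        assert np.allclose(out.samples, w.samples, atol=1e-9)


class TestSegmentRecording:
    def test_counts(self):
        w = sine(dur=10.0)
        segs = segment_recording(w, 2.5, 1.25)
        assert len(segs) == 7  # floor((10-2.5)/1.25)+1
        assert all(s.samples.size == int(2.5 * 16000) for s in segs)

    def test_exact_length_gives_one_segment(self):
        segs = segment_recording(sine(dur=2.5), 2.5, 1.25)
        assert len(segs) == 1

    def test_too_short_raises(self):
        with pytest.raises(ValidationError, match="shorter"):
            segment_recording(sine(dur=2.4), 2.5, 1.25)

    def test_subject_id_inherited(self):
        w = sine(dur=4.0)
        w.subject_id = "subj7"
        assert all(s.subject_id == "subj7" for s in segment_recording(w, 2.0, 1.0))


class TestLogmel:
    def test_frame_count_example(self):
        w = sine(dur=1.0, sr=44100)
        L = logmel(w, 0.030, 0.010, n_fft=2048, n_mels=64)
        assert L.n_frames == 98  # floor((44100-1323)/441)+1

    def test_default_band_count(self):
        L = logmel(sine(), n_fft=2048)
        assert L.values.shape[0] == 64

    def test_all_zero_waveform_hits_energy_floor(self):
        L = logmel(Waveform(np.zeros(16000) + 0.0, 16000), n_fft=512)
        assert np.allclose(L.values, L.values.flat[0])
        assert np.all(np.isfinite(L.values))

    def test_tone_peaks_in_matching_band(self):
        sr, f = 16000, 1000.0
        L = logmel(sine(freq=f, sr=sr), n_fft=512)
        centers = mel_center_frequencies(64, sr)
        expected_band = int(np.argmin(np.abs(centers - f)))
        peak_band = int(np.argmax(L.values.mean(axis=1)))
        assert abs(peak_band - expected_band) <= 1

    def test_window_longer_than_nfft_rejected(self):
        with pytest.raises(ValidationError, match="n_fft"):
            logmel(sine(sr=44100), 0.030, 0.010, n_fft=512)


@settings(max_examples=60, derandomize=True)
@given(st.integers(2, 5000), st.integers(1, 400), st.integers(1, 200))
def test_frame_count_formula_matches_loop_oracle(n, w, h):
    if n < w:
        with pytest.raises(ValidationError):
            frame_count(n, w, h)
        return
    count, start = 0, 0
    while start + w <= n:
        count += 1
        start += h
    assert frame_count(n, w, h) == count


class TestCmvn:
    def test_band_statistics(self, rng):
        from conftest import make_spectrogram
        L = make_spectrogram(rng.standard_normal((64, 120)) * 3 + 5)
        out = cmvn(L)
        assert np.all(np.abs(out.values.mean(axis=1)) < 1e-6)
        assert np.allclose(out.values.var(axis=1), 1.0, atol=1e-3)

    def test_constant_band_maps_to_zeros(self):
        from conftest import make_spectrogram
        vals = np.vstack([np.full(50, 2.0), np.random.default_rng(0).normal(size=50)])
        out = cmvn(make_spectrogram(vals))
        assert np.allclose(out.values[0], 0.0)

    def test_single_frame_rejected(self):
        from conftest import make_spectrogram
        with pytest.raises(ValidationError):
            cmvn(make_spectrogram(np.ones((4, 1))))


class TestScaler:
    def test_two_frame_band_hand_example(self):
        from conftest import make_spectrogram
        L = make_spectrogram(np.array([[1.0, 3.0]]))
        scaler = fit_scaler([L])
        out = apply_scaler(scaler, L)
        assert np.allclose(out.values, [[-1.0, 1.0]])  # mean 2, population std 1

    def test_self_transform_standardizes_pooled_frames(self, rng):
        from conftest import make_spectrogram
        Ls = [make_spectrogram(rng.standard_normal((8, 30)) * 2 + 1) for _ in range(3)]
        scaler = fit_scaler(Ls)
        outs = np.concatenate([apply_scaler(scaler, L).values for L in Ls], axis=1)
        assert np.allclose(outs.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(outs.std(axis=1), 1.0, atol=1e-6)

    def test_unfitted_scaler_raises(self):
        from depvox.audio import FeatureScaler
        from conftest import make_spectrogram
        with pytest.raises(RuntimeError):
            FeatureScaler().transform(make_spectrogram(np.ones((2, 4))))


class TestFrontendDeterminism:
    def test_bitwise_identical_outputs(self):
        w = sine(dur=4.0)
        a = frontend_segments(w, n_fft=512, segment_s=1.25, hop_segment_s=1.25)
        b = frontend_segments(w, n_fft=512, segment_s=1.25, hop_segment_s=1.25)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)


def test_mel_filterbank_covers_spectrum():
    fb = mel_filterbank(64, 512, 16000)
    assert fb.shape == (64, 257)
    # every interior FFT bin is covered by at least one filter
    assert np.all(fb[:, 2:-2].sum(axis=0) > 0)
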