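"""Synthetic cohort: parameter monotonicity, determinism, class structure."""

import numpy as np
import pytest
from scipy.stats import kstest

from depvox.audio import ValidationError, logmel
from depvox.synth import (
    FEMALE_BASE,
    MALE_BASE,
    VoiceParams,
    generate_cohort,
    generate_utterance,
    severity_to_params,
)


class TestSeverityToParams:
    def test_zero_severity_is_anchor(self):
        assert severity_to_params(0.0, MALE_BASE, effect=1.0) == MALE_BASE

    def test_zero_effect_is_null(self):
        for s in (0.1, 0.5, 1.0):
            assert severity_to_params(s, MALE_BASE, effect=0.0) == MALE_BASE

    def test_monotone_directions(self):
        mid = severity_to_params(0.5, MALE_BASE, effect=1.0)
        high = severity_to_params(1.0, MALE_BASE, effect=1.0)
        assert high.f0_sd_hz < mid.f0_sd_hz < MALE_BASE.f0_sd_hz
        assert high.pause_rate_hz < mid.pause_rate_hz < MALE_BASE.pause_rate_hz
        assert high.tilt_db_oct < mid.tilt_db_oct < MALE_BASE.tilt_db_oct
        assert high.rate_factor < mid.rate_factor < MALE_BASE.rate_factor
        assert high.formant_bw_hz[0] > mid.formant_bw_hz[0] > MALE_BASE.formant_bw_hz[0]
        assert high.pause_dur_s > mid.pause_dur_s > MALE_BASE.pause_dur_s

    def test_invalid_severity_rejected(self):
        with pytest.raises(ValidationError):
            severity_to_params(1.5, MALE_BASE, 1.0)


class TestGenerateUtterance:
    def test_deterministic_per_seed(self):
        a = generate_utterance(MALE_BASE, 2.0, 16000, seed=42)
        b = generate_utterance(MALE_BASE, 2.0, 16000, seed=42)
        assert np.array_equal(a.samples, b.samples)
        c = generate_utterance(MALE_BASE, 2.0, 16000, seed=43)
        assert not np.array_equal(a.samples, c.samples)

    def test_peak_normalized(self):
        w = generate_utterance(FEMALE_BASE, 2.0, 16000, seed=0)
        assert np.abs(w.samples).max() == pytest.approx(0.9, abs=1e-6)

    def test_zero_pause_rate_has_no_long_gaps(self):
        p = VoiceParams(pause_rate_hz=0.0, noise_floor=0.0)
        w = generate_utterance(p, 3.0, 16000, seed=1)
        # RMS in 50 ms windows never collapses to silence
        win = 800
        frames = w.samples[: w.samples.size // win * win].reshape(-1, win)
        rms = np.sqrt((frames ** 2).mean(axis=1))
        assert rms.min() > 1e-3

    def test_formant_peaks_visible_in_mel_spectrum(self):
        p = VoiceParams(f0_hz=110.0, pause_rate_hz=0.0, tilt_db_oct=0.0)
        w = generate_utterance(p, 3.0, 16000, seed=5)
        L = logmel(w, n_fft=1024)
        centers = L.band_center_frequencies_hz()
        mean_spec = L.values.mean(axis=1)
        for fc in p.formants_hz:
            band = int(np.argmin(np.abs(centers - fc)))
            lo, hi = max(band - 3, 0), min(band + 4, 64)
            near = mean_spec[lo:hi].max()
            far = np.delete(mean_spec, np.arange(max(band - 6, 0), min(band + 7, 64)))
            assert near > np.percentile(far, 25)


class TestGenerateCohort:
    def test_counts_and_hamd_ranges(self):
        manifest, waves = generate_cohort(24, 0.5, effect=1.0, duration_s=1.0,
                                          sample_rate=8000, seed=0)
        df = manifest.df
        assert (df["label"] == "Healthy").sum() == 12
        assert (df["label"] == "Depressed").sum() == 12
        assert df.loc[df.label == "Healthy", "hamd"].max() <= 7
        assert df.loc[df.label == "Depressed", "hamd"].min() >= 8
        assert df["hamd"].between(0, 52).all()
        assert len(waves) == 24

    def test_deterministic(self):
        m1, w1 = generate_cohort(6, 0.5, 1.0, 1.0, 8000, seed=3)
        m2, w2 = generate_cohort(6, 0.5, 1.0, 1.0, 8000, seed=3)
        assert m1.df.equals(m2.df)
        for s in m1.subjects:
            assert np.array_equal(w1[s].samples, w2[s].samples)

    def test_one_recording_per_subject(self):
        manifest, _ = generate_cohort(10, 0.5, 1.0, 1.0, 8000, seed=1)
        assert manifest.df["subject_id"].is_unique

    def test_writes_wavs_and_manifest(self, tmp_path):
        from depvox.audio import load_waveform
        manifest, _ = generate_cohort(4, 0.5, 1.0, 1.0, 8000, seed=2,
                                      out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        w = load_waveform(manifest.df["path"].iloc[0])
        assert w.sample_rate == 8000

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValidationError):
            generate_cohort(1, 0.5, 1.0, 1.0, 8000, seed=0)

    def test_depressed_hamd_close_to_uniform(self):
        manifest, _ = generate_cohort(400, 0.5, 1.0, 0.15, 4000, seed=7)
        dep = manifest.df.loc[manifest.df.label == "Depressed", "hamd"]
        stat = kstest(dep, "uniform", args=(8, 52 - 8 + 1))
        assert stat.pvalue > 0.01

    def test_mean_spectra_linearly_separable_at_default_effect(self):
        """A per-band energy ratio must split the class mean spectra."""
        manifest, waves = generate_cohort(16, 0.5, effect=1.0, duration_s=2.0,
                                          sample_rate=16000, seed=11)
        ratios, labels = [], []
        for s in manifest.subjects:
            L = logmel(waves[s], n_fft=512)
            spec = L.values.mean(axis=1)
            ratios.append(spec[:20].mean() - spec[40:].mean())  # low/high balance
            labels.append(manifest.label_of(s))
        ratios = np.array(ratios)
        dep = ratios[[l == "Depressed" for l in labels]]
        heal = ratios[[l == "Healthy" for l in labels]]
        # a threshold between the class extremes separates them
        assert dep.min() > heal.max()

    def test_effect_zero_classes_exchangeable(self):
        manifest, waves = generate_cohort(12, 0.5, effect=0.0, duration_s=2.0,
                                          sample_rate=16000, seed=13)
        ratios = {}
        for s in manifest.subjects:
            L = logmel(waves[s], n_fft=512)
            spec = L.values.mean(axis=1)
            ratios[s] = spec[:20].mean() - spec[40:].mean()
        dep = [ratios[s] for s in manifest.subjects if manifest.label_of(s) == "Depressed"]
        heal = [ratios[s] for s in manifest.subjects if manifest.label_of(s) == "Healthy"]
        # class means indistinguishable relative to within-class spread
        pooled_sd = np.std(dep + heal)
        assert abs(np.mean(dep) - np.mean(heal)) < 1.5 * pooled_sd
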