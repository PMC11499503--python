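"""Synthetic speech cohort with class-dependent spectral/temporal structure.

The study corpus (one read-speech recording per subject, a clinical
diagnosis and a HAMD severity score each) is not redistributable, so this
module emulates its *shape*: a roughly class-balanced cohort whose
depressed voices change continuously with severity.  Each voice is a
harmonic source (jittered fundamental) passed through formant resonators,
shaped by a spectral tilt, amplitude-modulated at a syllabic rate and
interrupted by pauses.  Severity monotonically (a) reduces pitch
variability, (b) reduces the pause rate while lengthening pauses, (c)
steepens the spectral tilt toward low-frequency emphasis, (d) slows the
syllabic rate, and (e) widens formant bandwidths — the qualitative cues
clinical speech studies associate with depressed speech, scaled by a
single ``effect`` knob.  ``effect=0`` makes the classes exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .audio import ValidationError, Waveform, save_waveform

HEALTHY = "Healthy"
DEPRESSED = "Depressed"


@dataclass(frozen=True)
class VoiceParams:
    """Physical knobs of one synthetic voice."""

    f0_hz: float = 120.0              # mean fundamental
    f0_sd_hz: float = 18.0            # slow pitch wander (std)
    formants_hz: tuple = (500.0, 1500.0, 2500.0)
    formant_bw_hz: tuple = (80.0, 110.0, 160.0)
    pause_rate_hz: float = 0.5        # pauses per second
    pause_dur_s: float = 0.25
    tilt_db_oct: float = -3.0         # spectral slope above the reference
    rate_factor: float = 1.0          # scales the 4 Hz syllabic modulation
    noise_floor: float = 0.003

    def __post_init__(self) -> None:
        if min(self.f0_hz, self.f0_sd_hz, self.pause_dur_s, self.rate_factor) <= 0:
            raise ValidationError("voice parameters must be positive")
        if self.pause_rate_hz < 0 or self.noise_floor < 0:
            raise ValidationError("pause rate and noise floor must be non-negative")
        if list(self.formants_hz) != sorted(self.formants_hz):
            raise ValidationError("formant frequencies must ascend")


#: f0-register presets; gender enters only through the fundamental register.
MALE_BASE = VoiceParams(f0_hz=120.0)
FEMALE_BASE = VoiceParams(f0_hz=210.0, formants_hz=(550.0, 1650.0, 2750.0))


def severity_to_params(s: float, base: VoiceParams, effect: float) -> VoiceParams:
    """Map a severity in [0, 1] onto voice parameters.

    The response saturates (``g = 1 - exp(-3 s)``): mild clinical severity
    already shifts the voice audibly while the ceiling stays finite.  All
    changes are strictly monotone in ``s`` and scale with ``effect``;
    ``s = 0`` or ``effect = 0`` return ``base`` exactly.
    """
    if not (0.0 <= s <= 1.0):
        raise ValidationError("severity s must lie in [0, 1]")
    g = effect * (1.0 - np.exp(-3.0 * s))
    return replace(
        base,
        f0_hz=base.f0_hz * float(np.exp(-0.08 * g)),
        f0_sd_hz=base.f0_sd_hz * float(np.exp(-0.9 * g)),
        pause_rate_hz=base.pause_rate_hz * float(np.exp(-1.0 * g)),
        pause_dur_s=base.pause_dur_s * (1.0 + 0.8 * g),
        tilt_db_oct=base.tilt_db_oct - 6.0 * g,
        rate_factor=base.rate_factor * float(np.exp(-0.5 * g)),
        formant_bw_hz=tuple(bw * (1.0 + 0.8 * g) for bw in base.formant_bw_hz),
    )


def _smooth_noise(n: int, rng: np.random.Generator, sigma: float) -> np.ndarray:
    x = gaussian_filter1d(rng.standard_normal(n), sigma, mode="reflect")
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_utterance(p: VoiceParams, duration_s: float, sample_rate: int,
                       seed: int) -> Waveform:
    """Render one synthetic utterance; bitwise-deterministic per seed."""
    if duration_s <= 0.1:
        raise ValidationError("duration too short to synthesize")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate

    # jittered fundamental: slow wander around the register
    f0 = p.f0_hz + p.f0_sd_hz * _smooth_noise(n, rng, sigma=0.05 * sample_rate)
    f0 = np.maximum(f0, 40.0)
    phase = 2.0 * np.pi * np.cumsum(f0) / sample_rate
    n_harm = max(2, min(15, int((sample_rate / 2 - 200) / p.f0_hz)))
    source = np.zeros(n)
    for h in range(1, n_harm + 1):
        source += np.sin(h * phase) / h

    # syllabic amplitude modulation (speech-rate cue)
    syl_hz = 4.0 * p.rate_factor
    env = 0.55 + 0.45 * np.sin(2.0 * np.pi * syl_hz * t + rng.uniform(0, 2 * np.pi))

    # pause gating: Poisson pause starts, jittered durations, 10 ms ramps
    gate = np.ones(n)
    n_pauses = rng.poisson(p.pause_rate_hz * duration_s)
    for _ in range(n_pauses):
        dur = p.pause_dur_s * rng.uniform(0.7, 1.3)
        start = rng.uniform(0.0, max(duration_s - dur, 1e-3))
        i0, i1 = int(start * sample_rate), int((start + dur) * sample_rate)
        gate[i0:min(i1, n)] = 0.0
    ramp = max(1, int(0.010 * sample_rate))
    gate = np.convolve(gate, np.ones(ramp) / ramp, mode="same")

    voiced = source * env * gate

    # vocal-tract resonances: cascade of second-order sections
    for fc, bw in zip(p.formants_hz, p.formant_bw_hz):
        if fc >= sample_rate / 2:
            continue
        r = np.exp(-np.pi * bw / sample_rate)
        theta = 2.0 * np.pi * fc / sample_rate
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        voiced = lfilter([1.0 - r], a, voiced)

    # spectral tilt applied as a frequency-domain slope (dB per octave)
    spectrum = np.fft.rfft(voiced)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    ref = np.maximum(freqs, 60.0) / 1000.0
    gain = ref ** (p.tilt_db_oct / (20.0 * np.log10(2.0)))
    voiced = np.fft.irfft(spectrum * gain, n=n)

    samples = voiced + p.noise_floor * rng.standard_normal(n)
    peak = np.abs(samples).max()
    if peak > 0:
        samples *= 0.9 / peak
    return Waveform(samples=samples, sample_rate=sample_rate)


@dataclass
class CohortManifest:
    """Subject/label/HAMD bookkeeping for one (synthetic) cohort."""

    df: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        required = {"subject_id", "label", "hamd", "duration_s", "seed"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"manifest missing columns {sorted(missing)}")
        if self.df["subject_id"].duplicated().any():
            raise ValidationError("one recording per subject: duplicate subject_id")

    @property
    def subjects(self) -> list:
        return list(self.df["subject_id"])

    def label_of(self, subject: str) -> str:
        return str(self.df.set_index("subject_id").loc[subject, "label"])

    def hamd_of(self, subject: str) -> float:
        return float(self.df.set_index("subject_id").loc[subject, "hamd"])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, seed: int = 0) -> "CohortManifest":
        return cls(df=pd.read_csv(path), seed=seed)


def generate_cohort(
    n_subjects: int,
    class_fraction: float = 0.5,
    effect: float = 1.0,
    duration_s: float = 12.0,
    sample_rate: int = 16000,
    seed: int = 0,
    female_fraction: float = 0.66,
    healthy_max_hamd: int = 7,
    depressed_min_hamd: int = 8,
    hamd_max: int = 52,
    out_dir=None,
):
    """Generate a cohort manifest plus one waveform per subject.

    Healthy subjects draw HAMD uniformly in [0, healthy_max] and map to a
    near-zero severity; depressed subjects draw HAMD uniformly in
    [depressed_min, hamd_max] with severity HAMD / hamd_max.  Per-subject
    seeds derive from the cohort seed.  When ``out_dir`` is given, WAV
    files and ``manifest.csv`` are written there.

    Returns ``(manifest, waveforms)`` with ``waveforms`` a subject -> Waveform dict.
    """
    if n_subjects < 2:
        raise ValidationError("need at least 2 subjects")
    if not (0.0 < class_fraction < 1.0):
        raise ValidationError("class_fraction must be in (0, 1)")
    n_dep = int(round(n_subjects * class_fraction))
    n_heal = n_subjects - n_dep
    if n_dep == 0 or n_heal == 0:
        raise ValidationError("n_subjects too small to populate both classes")
    rng = np.random.default_rng(seed)
    rows, waves = [], {}
    for i in range(n_subjects):
        depressed = i < n_dep
        label = DEPRESSED if depressed else HEALTHY
        if depressed:
            hamd = int(rng.integers(depressed_min_hamd, hamd_max + 1))
            s = hamd / hamd_max
        else:
            hamd = int(rng.integers(0, healthy_max_hamd + 1))
            # subclinical scores barely move the voice
            s = 0.04 * hamd / max(healthy_max_hamd, 1)
        base = FEMALE_BASE if rng.random() < female_fraction else MALE_BASE
        params = severity_to_params(s, base, effect)
        subj_seed = int(rng.integers(0, 2 ** 31 - 1))
        subject = f"S{i:03d}"
        w = generate_utterance(params, duration_s, sample_rate, subj_seed)
        w.subject_id = subject
        waves[subject] = w
        path = ""
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            path = str(out_dir / f"{subject}.wav")
            save_waveform(path, w)
        rows.append(dict(subject_id=subject, path=path, label=label, hamd=hamd,
                         duration_s=duration_s, seed=subj_seed))
    manifest = CohortManifest(df=pd.DataFrame(rows), seed=seed)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv")
    return manifest, waves
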