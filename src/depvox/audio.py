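"""Audio front end: waveform loading and the standardized log-Mel representation.

The pipeline is deterministic and its order is fixed: DC-offset removal ->
fixed-length segmentation -> log-Mel spectrogram -> per-segment CMVN ->
global z-score with training-fold statistics.  Every stage is a pure
function of its inputs, so identical audio and configuration yield
bitwise-identical features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile
from scipy.signal.windows import hann

#: Floor added to mel energies before the natural log (silence must stay finite).
LOG_FLOOR = 1e-10
#: Epsilon added to standard deviations in divisions (constant bands must not blow up).
DIV_EPS = 1e-8

#: Stage order recorded in provenance metadata wherever features are persisted.
PIPELINE_ORDER = ("dc_removal", "segmentation", "logmel", "cmvn", "zscore")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class Waveform:
    """A monophonic audio signal.

    Parameters
    ----------
    samples
        1-D float array of amplitudes, nominal range [-1, 1].
    sample_rate
        Sampling frequency in Hz.
    subject_id
        Optional identifier of the speaker the recording belongs to.
    """

    samples: np.ndarray
    sample_rate: int
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("waveform must be a non-empty 1-D signal")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class LogMelSpectrogram:
    """Log-energy mel spectrogram, shape ``(mel_bands, n_frames)``."""

    values: np.ndarray
    frame_hop_s: float
    window_s: float
    mel_bands: int
    sample_rate: int
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("spectrogram values must be 2-D")
        if self.values.shape[0] != self.mel_bands:
            raise ValidationError(
                f"expected {self.mel_bands} mel rows, got {self.values.shape[0]}"
            )
        if self.values.shape[1] < 1:
            raise ValidationError("spectrogram must contain at least one frame")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("spectrogram contains non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def band_center_frequencies_hz(self) -> np.ndarray:
        """Center frequency (Hz) of each mel band of this spectrogram."""
        return mel_center_frequencies(self.mel_bands, self.sample_rate)


# ---------------------------------------------------------------------------
# Slaney-style mel filterbank
# ---------------------------------------------------------------------------

_F_SP = 200.0 / 3.0          # linear region: mels per Hz below the break
_BREAK_HZ = 1000.0
_BREAK_MEL = _BREAK_HZ / _F_SP
_LOGSTEP = np.log(6.4) / 27.0  # 27 mel steps per factor 6.4 above the break


def hz_to_mel(f: np.ndarray | float) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    mel = f / _F_SP
    above = f >= _BREAK_HZ
    mel = np.where(above, _BREAK_MEL + np.log(np.maximum(f, _BREAK_HZ) / _BREAK_HZ) / _LOGSTEP, mel)
    return mel


def mel_to_hz(m: np.ndarray | float) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    f = m * _F_SP
    above = m >= _BREAK_MEL
    f = np.where(above, _BREAK_HZ * np.exp(_LOGSTEP * (np.maximum(m, _BREAK_MEL) - _BREAK_MEL)), f)
    return f


def mel_band_edges(n_mels: int, sample_rate: int) -> np.ndarray:
    """Edge frequencies (Hz) of ``n_mels`` triangular filters spanning 0..Nyquist."""
    mel_edges = np.linspace(hz_to_mel(0.0), hz_to_mel(sample_rate / 2.0), n_mels + 2)
    return mel_to_hz(mel_edges)


def mel_center_frequencies(n_mels: int, sample_rate: int) -> np.ndarray:
    return mel_band_edges(n_mels, sample_rate)[1:-1]


def mel_filterbank(n_mels: int, n_fft: int, sample_rate: int) -> np.ndarray:
    """Slaney-style, area-normalized triangular filterbank.

    Returns a ``(n_mels, n_fft // 2 + 1)`` weight matrix acting on the
    one-sided power spectrum.
    """
    edges = mel_band_edges(n_mels, sample_rate)
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_mels, fft_freqs.size))
    for b in range(n_mels):
        lo, center, hi = edges[b], edges[b + 1], edges[b + 2]
        rise = (fft_freqs - lo) / max(center - lo, 1e-12)
        fall = (hi - fft_freqs) / max(hi - center, 1e-12)
        fb[b] = np.maximum(0.0, np.minimum(rise, fall))
        fb[b] *= 2.0 / (hi - lo)  # equal-area normalization
    return fb


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def load_waveform(path, subject_id: str | None = None) -> Waveform:
    """Read a WAV file into a float waveform scaled to [-1, 1].

    Stereo files are mixed down by channel average.  Integer PCM is scaled
    by the magnitude of its type minimum (so int16 -32768 maps to -1.0).
    """
    try:
        sample_rate, data = wavfile.read(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"could not read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise ValidationError(f"WAV file {path!r} contains no audio")
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if info.min < 0:
            samples = data.astype(np.float64) / -float(info.min)
        else:  # unsigned 8-bit: offset binary
            half = (info.max + 1) / 2.0
            samples = (data.astype(np.float64) - half) / half
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return Waveform(samples=samples, sample_rate=int(sample_rate), subject_id=subject_id)


def save_waveform(path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, w.sample_rate, pcm)


def remove_dc(w: Waveform) -> Waveform:
    """Subtract the arithmetic mean of the signal (DC-offset removal)."""
    return Waveform(w.samples - w.samples.mean(), w.sample_rate, w.subject_id)


def segment_recording(w: Waveform, seg_len_s: float, hop_s: float) -> list[Waveform]:
    """Cut a recording into fixed-length, possibly overlapping segments.

    The final partial window is dropped; each segment inherits the source
    ``subject_id``.
    """
    if not (seg_len_s >= hop_s > 0):
        raise ValidationError("need seg_len_s >= hop_s > 0")
    seg = int(round(seg_len_s * w.sample_rate))
    hop = int(round(hop_s * w.sample_rate))
    if w.samples.size < seg:
        raise ValidationError(
            f"recording of {w.duration_s:.3f}s is shorter than the {seg_len_s}s segment; "
            "pad the audio or choose a shorter seg_len_s"
        )
    frames = sliding_window_view(w.samples, seg)[::hop]
    return [Waveform(frame.copy(), w.sample_rate, w.subject_id) for frame in frames]


def frame_count(n_samples: int, window: int, hop: int) -> int:
    """Number of full analysis windows: ``floor((N - W) / H) + 1``."""
    if n_samples < window:
        raise ValidationError("signal shorter than one analysis window")
    return (n_samples - window) // hop + 1


def logmel(
    w: Waveform,
    window_s: float = 0.030,
    hop_s: float = 0.010,
    n_fft: int = 2048,
    n_mels: int = 64,
) -> LogMelSpectrogram:
    """Compute the log-Mel spectrogram of a waveform.

    Hann-windowed frames are zero-padded to ``n_fft``, the one-sided power
    spectrum is pooled by a Slaney mel filterbank and the natural log of
    ``energy + LOG_FLOOR`` is taken.
    """
    window = int(round(window_s * w.sample_rate))
    hop = int(round(hop_s * w.sample_rate))
    if window > n_fft:
        raise ValidationError(f"window of {window} samples exceeds n_fft={n_fft}")
    if n_mels < 1:
        raise ValidationError("n_mels must be >= 1")
    if w.samples.size < window:
        raise ValidationError("waveform shorter than one analysis window")
    frames = sliding_window_view(w.samples, window)[::hop]
    taper = hann(window, sym=False)
    spectrum = np.fft.rfft(frames * taper, n=n_fft, axis=1)
    power = np.abs(spectrum) ** 2
    fb = mel_filterbank(n_mels, n_fft, w.sample_rate)
    energy = power @ fb.T
    values = np.log(energy + LOG_FLOOR).T
    return LogMelSpectrogram(
        values=values,
        frame_hop_s=hop / w.sample_rate,
        window_s=window / w.sample_rate,
        mel_bands=n_mels,
        sample_rate=w.sample_rate,
        subject_id=w.subject_id,
    )


def cmvn(L: LogMelSpectrogram) -> LogMelSpectrogram:
    """Cepstral mean and variance normalization over the time axis.

    Each mel band of this one spectrogram is standardized to mean 0 and
    (for non-degenerate bands) variance 1; constant bands map to zeros.
    """
    if L.n_frames < 2:
        raise ValidationError("CMVN needs at least 2 frames")
    mu = L.values.mean(axis=1, keepdims=True)
    sd = L.values.std(axis=1, keepdims=True)
    values = (L.values - mu) / (sd + DIV_EPS)
    return LogMelSpectrogram(values, L.frame_hop_s, L.window_s, L.mel_bands, L.sample_rate, L.subject_id)


@dataclass
class FeatureScaler:
    """Global per-band z-score fitted on training-fold frames only."""

    mean_: np.ndarray | None = None
    std_: np.ndarray | None = None
    fitted_on: int = 0

    def fit(self, spectrograms: list[LogMelSpectrogram]) -> "FeatureScaler":
        if not spectrograms:
            raise ValidationError("cannot fit scaler on an empty list")
        stacked = np.concatenate([L.values for L in spectrograms], axis=1)
        self.mean_ = stacked.mean(axis=1)
        self.std_ = np.maximum(stacked.std(axis=1), DIV_EPS)
        self.fitted_on = stacked.shape[1]
        return self

    def transform(self, L: LogMelSpectrogram) -> LogMelSpectrogram:
        if self.mean_ is None or self.std_ is None:
            raise RuntimeError("scaler has not been fitted")
        if self.mean_.size != L.mel_bands:
            raise ValidationError("scaler band count does not match spectrogram")
        values = (L.values - self.mean_[:, None]) / self.std_[:, None]
        return LogMelSpectrogram(values, L.frame_hop_s, L.window_s, L.mel_bands, L.sample_rate, L.subject_id)


def fit_scaler(training: list[LogMelSpectrogram]) -> FeatureScaler:
    return FeatureScaler().fit(training)


def apply_scaler(scaler: FeatureScaler, L: LogMelSpectrogram) -> LogMelSpectrogram:
    return scaler.transform(L)


def frontend_segments(
    w: Waveform,
    window_s: float = 0.030,
    hop_s: float = 0.010,
    n_fft: int = 2048,
    n_mels: int = 64,
    segment_s: float = 2.5,
    hop_segment_s: float = 1.25,
    apply_cmvn: bool = True,
    cmvn_scope: str = "segment",
) -> list[LogMelSpectrogram]:
    """Full per-recording front end: DC removal -> segment -> log-Mel -> CMVN.

    ``cmvn_scope`` selects whether CMVN statistics come from each segment
    ("segment", the default) or from the whole recording ("recording").
    The global z-score stage is fold-dependent and applied separately via
    :class:`FeatureScaler`.
    """
    clean = remove_dc(w)
    pieces = segment_recording(clean, segment_s, hop_segment_s)
    mels = [logmel(p, window_s, hop_s, n_fft, n_mels) for p in pieces]
    if not apply_cmvn:
        return mels
    if cmvn_scope == "segment":
        return [cmvn(L) for L in mels]
    if cmvn_scope == "recording":
        pooled = np.concatenate([L.values for L in mels], axis=1)
        mu = pooled.mean(axis=1, keepdims=True)
        sd = pooled.std(axis=1, keepdims=True)
        out = []
        for L in mels:
            vals = (L.values - mu) / (sd + DIV_EPS)
            out.append(LogMelSpectrogram(vals, L.frame_hop_s, L.window_s, L.mel_bands, L.sample_rate, L.subject_id))
        return out
    raise ValidationError(f"unknown cmvn_scope {cmvn_scope!r}")
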