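"""Explanation layer: relevance localization on activation maps, audio
cropping of the localized content, and similar/dissimilar neighbor queries.

The relevance rule is deliberately simple and stated in the output: channel
activations are aggregated by the mean absolute value, upsampled to the
input's time-frequency grid, and thresholded at the smallest level whose
super-level set carries at least the requested fraction of total
activation; the bounding box of that set is reported in seconds and Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .audio import LogMelSpectrogram, ValidationError, Waveform


@dataclass
class TFRegion:
    """A time-frequency box referenced to the source segment."""

    t_start_s: float
    t_end_s: float
    f_low_hz: float
    f_high_hz: float
    frame_lo: int
    frame_hi: int
    band_lo: int
    band_hi: int
    layer: str
    mass_fraction: float

    def __post_init__(self) -> None:
        if not (0 < self.mass_fraction <= 1):
            raise ValidationError("relevance mass fraction must be in (0, 1]")
        if self.t_end_s <= self.t_start_s:
            raise ValidationError("empty time extent")


@dataclass
class RankedNeighbors:
    entries: list               # (segment_id, subject_id, score) tuples
    mode: str                   # "similar" | "dissimilar"


def _upsample_nearest(m: np.ndarray, rows: int, cols: int) -> np.ndarray:
    r = np.floor(np.arange(rows) * m.shape[0] / rows).astype(int)
    c = np.floor(np.arange(cols) * m.shape[1] / cols).astype(int)
    return m[np.ix_(r, c)]


def relevance_region(A, L: LogMelSpectrogram, layer: int, mass: float = 0.5) -> TFRegion:
    """Bounding box of the most relevant time-frequency content.

    Parameters
    ----------
    A
        :class:`~depvox.siamese.ActivationMaps` of the segment.
    L
        The spectrogram the maps were computed from (axis calibration).
    layer
        Convolutional layer index, 0-based.
    mass
        Fraction of total activation the reported region must carry.
    """
    if not (0 < mass <= 1):
        raise ValidationError("mass must be in (0, 1]")
    if not (0 <= layer < len(A.maps)):
        raise ValidationError(f"layer index {layer} out of range")
    rel = np.abs(np.asarray(A.maps[layer], dtype=np.float64)).mean(axis=0)
    total = rel.sum()
    if total <= 0:
        raise ValidationError("no relevance signal: activation map is all zero")
    up = _upsample_nearest(rel, L.mel_bands, L.n_frames)
    flat = np.sort(up.ravel())[::-1]
    csum = np.cumsum(flat)
    idx = int(np.searchsorted(csum, mass * csum[-1]))
    threshold = flat[min(idx, flat.size - 1)]
    mask = up >= threshold
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    band_lo, band_hi = int(rows[0]), int(rows[-1])
    frame_lo, frame_hi = int(cols[0]), int(cols[-1])
    centers = L.band_center_frequencies_hz()
    return TFRegion(
        t_start_s=frame_lo * L.frame_hop_s,
        t_end_s=frame_hi * L.frame_hop_s + L.window_s,
        f_low_hz=float(centers[band_lo]),
        f_high_hz=float(centers[band_hi]),
        frame_lo=frame_lo,
        frame_hi=frame_hi,
        band_lo=band_lo,
        band_hi=band_hi,
        layer=A.labels[layer],
        mass_fraction=mass,
    )


def crop_audio(w: Waveform, r: TFRegion) -> Waveform:
    """Time-crop the waveform to the region for listening.

    The frequency bounds travel as metadata on the region; the crop is not
    band-pass filtered (the clinician listens to the whole segment of
    interest).
    """
    i0 = int(round(r.t_start_s * w.sample_rate))
    i1 = int(round(r.t_end_s * w.sample_rate))
    if i0 < 0 or i1 > w.samples.size or i1 <= i0:
        raise ValidationError(
            f"region [{r.t_start_s}, {r.t_end_s})s outside the {w.duration_s:.3f}s waveform"
        )
    return Waveform(w.samples[i0:i1].copy(), w.sample_rate, w.subject_id)


def query_neighbors(L_t, bank: list, model, n: int, mode: str,
                    support_ids: set | None = None) -> RankedNeighbors:
    """Rank bank segments by (dis)similarity to the query segment.

    ``bank`` holds ``(segment_id, subject_id, spectrogram)`` triples.
    Support-set members form the first stratum (the most characteristic
    recordings per class), remaining training segments the second; each
    stratum is sorted by the raw SNN score — ascending for ``similar``,
    descending for ``dissimilar`` — and the scores stay visible in the
    output.
    """
    if mode not in ("similar", "dissimilar"):
        raise ValidationError("mode must be 'similar' or 'dissimilar'")
    if not bank:
        raise ValidationError("neighbor bank is empty")
    support_ids = support_ids or set()
    if n > len(bank):
        warnings.warn(f"requested {n} neighbors from a bank of {len(bank)}; truncating")
        n = len(bank)
    segs = [entry[2] for entry in bank]
    scores = np.asarray(model.pairwise_distances([L_t], segs))[0].astype(np.float64)
    entries = []
    for stratum_support in (True, False):
        idx = [i for i, e in enumerate(bank) if (e[0] in support_ids) == stratum_support]
        keys = scores[idx] if mode == "similar" else -scores[idx]
        for j in np.argsort(keys, kind="stable"):
            i = idx[j]
            entries.append((bank[i][0], bank[i][1], float(scores[i])))
    return RankedNeighbors(entries=entries[:n], mode=mode)
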