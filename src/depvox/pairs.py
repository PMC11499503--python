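"""Balanced similar/dissimilar spectrogram-pair construction.

Similar pairs (target 0) join two distinct segments of one recording;
dissimilar pairs (target 1) join segments of different recordings — by
default recordings of opposite classes, since the downstream tasks are
class-discriminative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import LogMelSpectrogram, ValidationError

SIMILAR = 0
DISSIMILAR = 1


@dataclass
class SpectroPair:
    left: LogMelSpectrogram
    right: LogMelSpectrogram
    target: int
    left_subject: str
    right_subject: str
    left_index: int = 0
    right_index: int = 0

    def __post_init__(self) -> None:
        if self.target == SIMILAR and self.left_subject != self.right_subject:
            raise ValidationError("similar pair must come from a single recording")
        if self.target == DISSIMILAR and self.left_subject == self.right_subject:
            raise ValidationError("dissimilar pair must join different recordings")


@dataclass
class PairSet:
    pairs: list
    seed: int
    n_similar: int = field(init=False)
    n_dissimilar: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_similar = sum(1 for p in self.pairs if p.target == SIMILAR)
        self.n_dissimilar = len(self.pairs) - self.n_similar

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def build_pairs(
    labels: dict,
    segments: dict,
    n_pairs: int,
    cross_class_only: bool = True,
    seed: int = 0,
) -> PairSet:
    """Draw a balanced pair set from per-subject segment lists.

    Parameters
    ----------
    labels
        Mapping subject_id -> class label ("Healthy" / "Depressed").
    segments
        Mapping subject_id -> list of that recording's spectrograms.
    n_pairs
        Total number of pairs; similar and dissimilar counts differ by at
        most one when ``n_pairs`` is odd.
    cross_class_only
        When True (default) dissimilar pairs join recordings of opposite
        classes; when False any two different recordings qualify.
    seed
        Seed for the sampling generator; fixed seed gives identical pairs.
    """
    if n_pairs < 2:
        raise ValidationError("need n_pairs >= 2 for a balanced pair set")
    subjects = sorted(segments)
    if len(subjects) < 2:
        raise ValidationError("need at least 2 subjects to form dissimilar pairs")
    rng = np.random.default_rng(seed)

    sim_sources = [s for s in subjects if len(segments[s]) >= 2]
    if not sim_sources:
        raise ValidationError("no subject has >= 2 segments; cannot form similar pairs")

    if cross_class_only:
        healthy = [s for s in subjects if labels[s] == "Healthy" and segments[s]]
        depressed = [s for s in subjects if labels[s] == "Depressed" and segments[s]]
        if not healthy or not depressed:
            raise ValidationError(
                "cross-class dissimilar pairs need at least one subject per class"
            )

    n_sim = n_pairs - n_pairs // 2
    pairs = []
    for _ in range(n_sim):
        s = sim_sources[rng.integers(len(sim_sources))]
        i, j = rng.choice(len(segments[s]), size=2, replace=False)
        pairs.append(SpectroPair(segments[s][i], segments[s][j], SIMILAR, s, s,
                                 int(i), int(j)))
    for _ in range(n_pairs // 2):
        if cross_class_only:
            a = healthy[rng.integers(len(healthy))]
            b = depressed[rng.integers(len(depressed))]
        else:
            a, b = (subjects[q] for q in rng.choice(len(subjects), size=2, replace=False))
        i = int(rng.integers(len(segments[a])))
        j = int(rng.integers(len(segments[b])))
        pairs.append(SpectroPair(segments[a][i], segments[b][j], DISSIMILAR, a, b, i, j))
    return PairSet(pairs=pairs, seed=seed)
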