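"""Experiment configuration: dataclasses, YAML round-trip, and named profiles.

Three profiles ship with the package:

``full_profile``
    Mirrors the published operating point: 44.1 kHz audio, 2048-point FFT,
    64 mel bands, a four-layer CNN with shrinking kernels, batch 50,
    learning rate 6e-5, up to 3000 iterations, support sizes 12/1, k=24.
``acceptance_profile``
    A desk-scale synthetic-cohort experiment (24 subjects, 16 kHz, reduced
    CNN) sized so a full leave-one-subject-out run completes on one CPU in
    minutes.
``tiny_profile``
    A minimal deterministic profile used for end-to-end determinism tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class FrontEndConfig:
    sample_rate: int = 44100
    window_ms: float = 30.0
    overlap_ms: float = 20.0
    n_fft: int = 2048
    n_mels: int = 64
    segment_s: float = 2.5
    hop_segment_s: float = 1.25
    cmvn_scope: str = "segment"       # "segment" | "recording"
    zscore_scope: str = "global"      # "global" | "per_speaker"

    @property
    def window_s(self) -> float:
        return self.window_ms / 1000.0

    @property
    def hop_s(self) -> float:
        # hop = window - overlap: "30 ms overlapped by 20 ms" -> 10 ms hop
        return (self.window_ms - self.overlap_ms) / 1000.0


@dataclass
class ArchConfig:
    channels: tuple = (32, 64, 64, 128)
    kernels: tuple = (10, 7, 5, 3)
    embedding: int = 256
    init: str = "narrow_normal"       # "narrow_normal" | "fan_in"
    init_std: float = 0.01


@dataclass
class TrainConfig:
    batch_size: int = 50
    learning_rate: float = 6e-5
    momentum: float = 0.0
    max_iterations: int = 3000
    eval_every: int = 50
    patience: int = 10
    min_delta: float = 1e-4
    max_restarts: int = 0             # re-init attempts when training stalls
    restart_threshold: float = 0.5    # val BCE above which a restart is tried
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_iterations, self.eval_every, self.patience) <= 0:
            raise ValueError("batch_size, max_iterations, eval_every, patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience >= self.max_iterations:
            raise ValueError("patience must be smaller than max_iterations")


@dataclass
class PairConfig:
    n_pairs: int = 10000
    n_val_pairs: int = 1000
    cross_class_only: bool = True


@dataclass
class CohortConfig:
    n_subjects: int = 218
    class_fraction: float = 0.5       # fraction of depressed subjects
    effect: float = 1.0
    duration_s: float = 12.0
    sample_rate: int = 44100
    female_fraction: float = 0.66
    healthy_max_hamd: int = 7
    depressed_min_hamd: int = 8
    hamd_max: int = 52


@dataclass
class SupportConfig:
    v_h: int = 12
    v_d: int = 1
    tune: bool = False
    v_range: tuple = (1, 12)          # inclusive candidate range for tuning


@dataclass
class SeverityConfig:
    k: int = 24
    tune: bool = False
    k_range: tuple = (1, 24)
    n_clusters: int | None = None     # None -> max(k, ceil(sqrt(n_items)))


@dataclass
class ExperimentConfig:
    frontend: FrontEndConfig = field(default_factory=FrontEndConfig)
    arch: ArchConfig = field(default_factory=ArchConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    pairs: PairConfig = field(default_factory=PairConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    support: SupportConfig = field(default_factory=SupportConfig)
    severity: SeverityConfig = field(default_factory=SeverityConfig)
    val_fraction: float = 0.1
    n_repeats: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for sec in ("arch",):
            d[sec]["channels"] = list(d[sec]["channels"])
            d[sec]["kernels"] = list(d[sec]["kernels"])
        d["support"]["v_range"] = list(d["support"]["v_range"])
        d["severity"]["k_range"] = list(d["severity"]["k_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        kw = {}
        sections = {
            "frontend": FrontEndConfig, "arch": ArchConfig, "train": TrainConfig,
            "pairs": PairConfig, "cohort": CohortConfig, "support": SupportConfig,
            "severity": SeverityConfig,
        }
        for name, typ in sections.items():
            if name in d:
                sub = dict(d.pop(name))
                for key in ("channels", "kernels", "v_range", "k_range"):
                    if key in sub and sub[key] is not None:
                        sub[key] = tuple(sub[key])
                kw[name] = typ(**sub)
        kw.update(d)
        return cls(**kw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def full_profile(seed: int = 0) -> ExperimentConfig:
    """The published operating point (full scale; not desk-runnable)."""
    return ExperimentConfig(seed=seed, train=TrainConfig(seed=seed))


def acceptance_profile(seed: int = 0, effect: float = 1.0) -> ExperimentConfig:
    """Desk-scale synthetic-cohort experiment: 24 subjects, 16 kHz, reduced CNN."""
    return ExperimentConfig(
        frontend=FrontEndConfig(sample_rate=16000, n_fft=512,
                                segment_s=1.25, hop_segment_s=1.25),
        arch=ArchConfig(channels=(2, 4, 4, 8), kernels=(5, 3, 3, 3),
                        embedding=32, init="fan_in"),
        train=TrainConfig(batch_size=12, learning_rate=0.01, momentum=0.9,
                          max_iterations=300, eval_every=30, patience=5,
                          min_delta=1e-4, max_restarts=2, restart_threshold=0.5,
                          seed=seed),
        pairs=PairConfig(n_pairs=600, n_val_pairs=64),
        cohort=CohortConfig(n_subjects=24, duration_s=12.0, sample_rate=16000,
                            effect=effect),
        support=SupportConfig(tune=True, v_range=(1, 12)),
        severity=SeverityConfig(k=4, tune=True, k_range=(1, 8)),
        seed=seed,
    )


def tiny_profile(seed: int = 0) -> ExperimentConfig:
    """Minimal deterministic end-to-end profile (determinism/property tests)."""
    return ExperimentConfig(
        frontend=FrontEndConfig(sample_rate=16000, n_fft=512,
                                segment_s=2.0, hop_segment_s=1.0),
        arch=ArchConfig(channels=(2, 2, 2, 4), kernels=(3, 3, 3, 3),
                        embedding=16, init="fan_in"),
        train=TrainConfig(batch_size=6, learning_rate=0.05, max_iterations=30,
                          eval_every=10, patience=3, seed=seed),
        pairs=PairConfig(n_pairs=60, n_val_pairs=20),
        cohort=CohortConfig(n_subjects=6, duration_s=6.0, sample_rate=16000),
        support=SupportConfig(v_h=2, v_d=2, tune=False),
        severity=SeverityConfig(k=2, tune=False, n_clusters=4),
        seed=seed,
    )
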