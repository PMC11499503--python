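import numpy as np
import pytest

from depvox._nn import sigmoid
from depvox.audio import LogMelSpectrogram
from depvox.config import ArchConfig
from depvox.siamese import init_model


def make_spectrogram(values, subject=None, sample_rate=16000):
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    return LogMelSpectrogram(values, frame_hop_s=0.01, window_s=0.03,
                             mel_bands=values.shape[0], sample_rate=sample_rate,
                             subject_id=subject)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_arch():
    return ArchConfig(channels=(2, 3, 3, 4), kernels=(3, 3, 3, 3),
                      embedding=8, init="fan_in")


@pytest.fixture
def small_model(small_arch):
    return init_model(small_arch, (48, 60), seed=0)


@pytest.fixture
def small_inputs(rng):
    return [make_spectrogram(rng.standard_normal((48, 60)), subject=f"S{i}")
            for i in range(6)]


class StubEmbedModel:
    """Distance-head-compatible stub: embeddings are the input band means.

    Mimics the real model's interface (distance, pairwise_distances,
    identity_constant) with trivially predictable geometry.
    """

    def __init__(self, w=4.0, b=0.0):
        self.w, self.b = w, b

    def _embed(self, L):
        vals = L.values if hasattr(L, "values") else np.asarray(L)
        return vals.mean(axis=-1) if vals.ndim > 1 else vals

    def distance(self, a, b):
        d = np.abs(self._embed(a) - self._embed(b)).mean()
        return float(sigmoid(np.asarray(self.w * d + self.b)))

    def pairwise_distances(self, A, B=None):
        B = A if B is None else B
        return np.array([[self.distance(a, b) for b in B] for a in A])

    @property
    def identity_constant(self):
        return float(sigmoid(np.asarray(self.b, dtype=np.float64)))
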