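"""Support-set formation (vs brute-force oracle) and classification rules."""

import numpy as np
import pytest

from conftest import StubEmbedModel, make_spectrogram
from depvox.audio import ValidationError
from depvox.support import (
    centrality_order,
    classify_from_distances,
    classify_recording,
    classify_segment,
    form_support_set,
    select_support_indices,
    tune_support_sizes,
    SupportSet,
)


def brute_force_support(D, v):
    """Explicit pairwise sum + full sort oracle."""
    n = D.shape[0]
    sums = [sum(D[i, j] for j in range(n) if j != i) for i in range(n)]
    order = sorted(range(n), key=lambda i: (sums[i], i))
    return order[:v]


class TestSelection:
    def test_hand_example(self):
        # rows summing to (3.0, 1.2, 2.5, 0.9) -> picks items 3 and 1 (0-based)
        D = np.zeros((4, 4))
        sums = [3.0, 1.2, 2.5, 0.9]
        for i in range(4):
            D[i, (i + 1) % 4] = sums[i]  # off-diagonal mass equal to target sum
        picked = select_support_indices(D, 2)
        assert list(picked) == [3, 1]

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 51))
            # dyadic grid keeps sums order-independent (exact float addition)
            D = rng.integers(0, 65, size=(n, n)) / 64.0
            D = (D + D.T) / 2
            v = int(rng.integers(1, min(n, 10) + 1))
            assert list(select_support_indices(D, v)) == brute_force_support(D, v)

    def test_tie_breaks_to_lower_index(self):
        D = np.ones((4, 4)) - np.eye(4)  # all sums equal
        assert list(select_support_indices(D, 2)) == [0, 1]

    def test_v_boundary_whole_class(self, rng):
        D = rng.random((5, 5))
        assert sorted(select_support_indices(D, 5)) == [0, 1, 2, 3, 4]

    def test_v_too_large_rejected(self, rng):
        with pytest.raises(ValidationError):
            select_support_indices(rng.random((3, 3)), 4)

    def test_diagonal_excluded_from_sums(self):
        D = np.array([[9.0, 0.1], [0.1, 0.0]])  # huge self-distance must not matter
        assert list(centrality_order(D)) == [0, 1]


class TestFormSupportSet:
    def test_exemplars_are_subset_with_requested_sizes(self, rng):
        h = [make_spectrogram(rng.standard_normal(4) + 0, subject=f"H{i}") for i in range(5)]
        d = [make_spectrogram(rng.standard_normal(4) + 3, subject=f"D{i}") for i in range(4)]
        S = form_support_set(h, d, StubEmbedModel(), v_h=3, v_d=2)
        assert S.v_h == 3 and S.v_d == 2
        assert all(any(s is x for x in h) for s in S.healthy)
        assert all(any(s is x for x in d) for s in S.depressed)

    def test_oversized_v_rejected(self, rng):
        h = [make_spectrogram(rng.standard_normal(4)) for _ in range(2)]
        with pytest.raises(ValidationError):
            form_support_set(h, h, StubEmbedModel(), v_h=3, v_d=1)


class TestClassify:
    def test_dominance(self):
        label, _ = classify_from_distances([0.1, 0.1, 0.1], [0.9, 0.9])
        assert label == "Healthy"

    def test_hand_aggregation(self):
        # healthy mean 0.3 vs depressed mean 0.25 -> Depressed
        label, vec = classify_from_distances([0.2, 0.4], [0.25])
        assert label == "Depressed"
        assert vec.healthy_aggregate == pytest.approx(0.3)
        assert vec.depressed_aggregate == pytest.approx(0.25)

    def test_exact_tie_goes_depressed(self):
        label, _ = classify_from_distances([0.5], [0.5])
        assert label == "Depressed"

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            classify_from_distances([], [0.5])

    def test_invariant_to_exemplar_order(self, rng):
        d_h, d_d = rng.random(6), rng.random(3)
        base = classify_from_distances(d_h, d_d)[0]
        for _ in range(5):
            assert classify_from_distances(rng.permutation(d_h),
                                           rng.permutation(d_d))[0] == base

    def test_classify_segment_via_model(self, rng):
        S = SupportSet(
            healthy=[make_spectrogram(np.zeros(4))],
            depressed=[make_spectrogram(np.full(4, 5.0))],
            healthy_subjects=["H"], depressed_subjects=["D"],
        )
        label, vec = classify_segment(make_spectrogram(np.full(4, 0.2)),
                                      StubEmbedModel(), S)
        assert label == "Healthy"
        assert vec.healthy[0] < vec.depressed[0]


class TestClassifyRecording:
    def test_single_segment_reduces_to_segment_rule(self, rng):
        S = SupportSet([make_spectrogram(np.zeros(4))], [make_spectrogram(np.full(4, 5.0))],
                       ["H"], ["D"])
        seg = make_spectrogram(np.full(4, 0.1))
        assert classify_recording([seg], StubEmbedModel(), S) == \
            classify_segment(seg, StubEmbedModel(), S)[0]

    def test_average_then_argmin(self, rng):
        S = SupportSet([make_spectrogram(np.zeros(4))], [make_spectrogram(np.full(4, 4.0))],
                       ["H"], ["D"])
        segs = [make_spectrogram(np.full(4, 0.5)), make_spectrogram(np.full(4, 1.0))]
        assert classify_recording(segs, StubEmbedModel(), S) == "Healthy"

    def test_segment_order_irrelevant(self, rng):
        S = SupportSet([make_spectrogram(rng.standard_normal(4))],
                       [make_spectrogram(rng.standard_normal(4))], ["H"], ["D"])
        segs = [make_spectrogram(rng.standard_normal(4)) for _ in range(5)]
        model = StubEmbedModel()
        assert classify_recording(segs, model, S) == \
            classify_recording(segs[::-1], model, S)


class TestTuneSupportSizes:
    def test_single_candidate_returned(self, rng):
        D_vh, D_vd = rng.random((6, 4)), rng.random((6, 4))
        v_h, v_d = tune_support_sizes(D_vh, D_vd, ["Healthy"] * 3 + ["Depressed"] * 3,
                                      np.arange(4), np.arange(4), v_range=(2, 2))
        assert (v_h, v_d) == (2, 2)

    def test_flat_accuracy_returns_smallest_v(self):
        # constant distances: every v gives the same decisions
        D_vh = np.full((4, 5), 0.3)
        D_vd = np.full((4, 5), 0.6)
        v_h, v_d = tune_support_sizes(D_vh, D_vd, ["Healthy"] * 2 + ["Depressed"] * 2,
                                      np.arange(5), np.arange(5), v_range=(1, 5))
        assert (v_h, v_d) == (1, 1)

    def test_informative_prefix_found(self):
        # only the 2 most central healthy exemplars are discriminative
        D_vh = np.array([[0.1, 0.1, 0.9, 0.9, 0.9]] * 2 + [[0.8, 0.8, 0.8, 0.8, 0.8]] * 2)
        D_vd = np.array([[0.7] * 3] * 2 + [[0.2] * 3] * 2)
        labels = ["Healthy"] * 2 + ["Depressed"] * 2
        v_h, _ = tune_support_sizes(D_vh, D_vd, labels, np.arange(5), np.arange(3),
                                    v_range=(1, 5))
        assert v_h <= 2

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValidationError):
            tune_support_sizes(rng.random((2, 3)), rng.random((2, 3)),
                               ["Healthy", "Depressed"], np.arange(3), np.arange(3),
                               v_range=(3, 1))
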