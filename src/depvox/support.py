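"""Support-set classification: exemplar selection and nearest-class decision.

The support set S holds, per class, the v most *central* training
segments: those whose summed distance to all other same-class segments is
smallest (maximal intra-class similarity).  An unknown segment is assigned
the class whose exemplars it is closest to on average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import ValidationError

HEALTHY = "Healthy"
DEPRESSED = "Depressed"


@dataclass
class SupportSet:
    healthy: list
    depressed: list
    healthy_subjects: list
    depressed_subjects: list

    @property
    def v_h(self) -> int:
        return len(self.healthy)

    @property
    def v_d(self) -> int:
        return len(self.depressed)


@dataclass
class ClassDistanceVectors:
    """Distances of one test segment to every exemplar of each class."""

    healthy: np.ndarray
    depressed: np.ndarray

    @property
    def healthy_aggregate(self) -> float:
        return float(np.mean(self.healthy))

    @property
    def depressed_aggregate(self) -> float:
        return float(np.mean(self.depressed))


def centrality_order(D: np.ndarray) -> np.ndarray:
    """Rank same-class samples by ascending summed distance to the others.

    ``D`` is the intra-class distance matrix; the diagonal (self-distance)
    is excluded from the sums.  Ties break toward the lower original index
    (stable sort), so selection never depends on input permutation of
    non-tied samples.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("intra-class distance matrix must be square")
    sums = D.sum(axis=1) - np.diag(D)
    return np.argsort(sums, kind="stable")


def select_support_indices(D: np.ndarray, v: int) -> np.ndarray:
    """Indices of the v most central samples of one class (ascending sums)."""
    if not (1 <= v <= D.shape[0]):
        raise ValidationError(f"support size v={v} outside [1, {D.shape[0]}]")
    return centrality_order(D)[:v]


def form_support_set(
    healthy_segments: list,
    depressed_segments: list,
    model,
    v_h: int,
    v_d: int,
    healthy_subjects: list | None = None,
    depressed_subjects: list | None = None,
) -> SupportSet:
    """Select per-class exemplars maximizing intra-class similarity.

    For each class the model's pairwise distances among that class's
    training segments are summed per sample, sorted ascending, and the
    top-v (most central) samples become the exemplars.
    """
    if v_h > len(healthy_segments) or v_d > len(depressed_segments):
        raise ValidationError("support size exceeds class size")
    picks = {}
    for name, segs, v in (("h", healthy_segments, v_h), ("d", depressed_segments, v_d)):
        D = model.pairwise_distances(segs)
        picks[name] = select_support_indices(np.asarray(D), v)
    h_subj = healthy_subjects or [getattr(s, "subject_id", None) for s in healthy_segments]
    d_subj = depressed_subjects or [getattr(s, "subject_id", None) for s in depressed_segments]
    return SupportSet(
        healthy=[healthy_segments[i] for i in picks["h"]],
        depressed=[depressed_segments[i] for i in picks["d"]],
        healthy_subjects=[h_subj[i] for i in picks["h"]],
        depressed_subjects=[d_subj[i] for i in picks["d"]],
    )


def decide_label(agg_healthy: float, agg_depressed: float) -> str:
    """Argmin over class aggregates; exact ties resolve to Depressed
    (screening-conservative)."""
    return HEALTHY if agg_healthy < agg_depressed else DEPRESSED


def classify_from_distances(d_healthy: np.ndarray, d_depressed: np.ndarray):
    """Argmin-of-mean class decision from per-exemplar distance vectors.

    The per-class aggregate is the *mean* distance (support sizes differ
    across classes, so raw sums are incomparable).  Exact ties resolve to
    Depressed — the screening-conservative choice.
    """
    if len(d_healthy) == 0 or len(d_depressed) == 0:
        raise ValidationError("both classes need at least one exemplar")
    vectors = ClassDistanceVectors(np.asarray(d_healthy, dtype=np.float64),
                                   np.asarray(d_depressed, dtype=np.float64))
    label = decide_label(vectors.healthy_aggregate, vectors.depressed_aggregate)
    return label, vectors


def classify_segment(L_t, model, S: SupportSet):
    """Classify one unknown segment against the support set."""
    d_h = np.array([model.distance(L_t, s) for s in S.healthy])
    d_d = np.array([model.distance(L_t, s) for s in S.depressed])
    return classify_from_distances(d_h, d_d)


def classify_recording(segments: list, model, S: SupportSet):
    """Subject-level decision: average per-segment class aggregates, argmin.

    A recording carries one mental state throughout, so its segments'
    per-class mean distances are themselves averaged before the argmin.
    """
    if not segments:
        raise ValidationError("need at least one segment")
    agg_h, agg_d = [], []
    for L in segments:
        _, vec = classify_segment(L, model, S)
        agg_h.append(vec.healthy_aggregate)
        agg_d.append(vec.depressed_aggregate)
    return decide_label(float(np.mean(agg_h)), float(np.mean(agg_d)))


def tune_support_sizes(
    D_val_h: np.ndarray,
    D_val_d: np.ndarray,
    val_labels: list,
    order_h: np.ndarray,
    order_d: np.ndarray,
    v_range: tuple = (1, 12),
):
    """Grid-search per-class support sizes on a validation fold.

    Parameters
    ----------
    D_val_h, D_val_d
        Distances from each validation segment (rows) to every healthy /
        depressed support *candidate* (columns, original order).
    val_labels
        Per-validation-segment true labels.
    order_h, order_d
        Centrality orderings of the candidates (from
        :func:`centrality_order`), so the size-v support set is the first
        v entries.
    v_range
        Inclusive (lo, hi) candidate range, clipped to candidate counts.

    Returns ``(v_h, v_d)``: v_h maximizes the healthy recognition rate and
    v_d the depressed recognition rate, each marginalized over the other
    class's candidate sizes; ties resolve to the smaller size.
    """
    lo, hi = v_range
    if lo > hi:
        raise ValidationError("empty support-size candidate range")
    D_val_h = np.asarray(D_val_h, dtype=np.float64)[:, order_h]
    D_val_d = np.asarray(D_val_d, dtype=np.float64)[:, order_d]
    hs = np.arange(lo, min(hi, D_val_h.shape[1]) + 1)
    ds = np.arange(lo, min(hi, D_val_d.shape[1]) + 1)
    if hs.size == 0 or ds.size == 0:
        raise ValidationError("candidate range exceeds candidate counts")
    # prefix means: column v-1 is the mean distance to the top-v exemplars
    pm_h = np.cumsum(D_val_h, axis=1) / np.arange(1, D_val_h.shape[1] + 1)
    pm_d = np.cumsum(D_val_d, axis=1) / np.arange(1, D_val_d.shape[1] + 1)
    labels = np.asarray(val_labels)
    is_h = labels == HEALTHY
    # decision for every (segment, v_h, v_d): healthy iff mean_h < mean_d
    healthy_rate = np.zeros((hs.size, ds.size))
    depressed_rate = np.zeros((hs.size, ds.size))
    for a, vh in enumerate(hs):
        for b, vd in enumerate(ds):
            pred_h = pm_h[:, vh - 1] < pm_d[:, vd - 1]
            if is_h.any():
                healthy_rate[a, b] = np.mean(pred_h[is_h])
            if (~is_h).any():
                depressed_rate[a, b] = np.mean(~pred_h[~is_h])
    marg_h = healthy_rate.mean(axis=1)
    marg_d = depressed_rate.mean(axis=0)
    v_h = int(hs[np.argmax(marg_h)])   # argmax returns the first (smallest v) on ties
    v_d = int(ds[np.argmax(marg_d)])
    return v_h, v_d
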