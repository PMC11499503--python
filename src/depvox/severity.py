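"""HAMD severity regression: PAM k-medoids over learned pair distances.

The training segments' pairwise SNN dissimilarities form a distance
matrix; Partitioning Around Medoids (BUILD + SWAP) selects representative
segments (medoids), and an unknown segment's HAMD score is predicted as
the arithmetic mean of the scores of its k nearest medoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import ValidationError


@dataclass
class DistanceMatrix:
    """Pairwise SNN dissimilarities over training segments plus metadata."""

    values: np.ndarray
    subject_ids: list
    hamd: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.hamd = np.asarray(self.hamd, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix must be square")
        if len(self.subject_ids) != n or self.hamd.size != n:
            raise ValidationError("metadata length must match matrix size")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]


def build_distance_matrix(segments: list, model, subject_ids: list, hamd) -> DistanceMatrix:
    """Fill d_ij = M(L_i, L_j) for every unordered pair, then mirror.

    The absolute-difference head makes the score symmetric, so each pair is
    computed once and copied; the diagonal holds the model's identity
    constant sigmoid(b).
    """
    full = np.asarray(model.pairwise_distances(segments), dtype=np.float64)
    n = len(segments)
    D = np.empty((n, n))
    iu = np.triu_indices(n, k=1)
    D[iu] = full[iu]
    D.T[iu] = full[iu]
    np.fill_diagonal(D, model.identity_constant)
    return DistanceMatrix(values=D, subject_ids=list(subject_ids), hamd=hamd)


# ---------------------------------------------------------------------------
# Partitioning Around Medoids
# ---------------------------------------------------------------------------

@dataclass
class MedoidModel:
    medoid_indices: np.ndarray
    assignment: np.ndarray
    medoid_hamd: np.ndarray
    cost: float
    medoid_subjects: list = field(default_factory=list)
    medoid_segments: list = field(default_factory=list)

    @property
    def n_medoids(self) -> int:
        return len(self.medoid_indices)


def _zero_diag(D: np.ndarray) -> np.ndarray:
    Dz = np.array(D, dtype=np.float64, copy=True)
    np.fill_diagonal(Dz, 0.0)  # item-to-own-medoid costs nothing (PAM convention)
    return Dz


def pam_cost(D: np.ndarray, medoids) -> float:
    """Total cost of a medoid set: sum of nearest-medoid distances (self = 0)."""
    Dz = _zero_diag(D)
    return float(Dz[:, sorted(medoids)].min(axis=1).sum())


def _build_init(Dz: np.ndarray, n_clusters: int) -> list:
    """Greedy BUILD: start from the 1-medoid optimum, then add the item
    giving the largest cost reduction (ties to the lowest index)."""
    n = Dz.shape[0]
    medoids = [int(np.argmin(Dz.sum(axis=0)))]
    d_near = Dz[:, medoids[0]].copy()
    while len(medoids) < n_clusters:
        candidates = np.setdiff1d(np.arange(n), medoids)
        gains = np.maximum(0.0, d_near[:, None] - Dz[:, candidates]).sum(axis=0)
        best = candidates[int(np.argmax(gains))]
        medoids.append(int(best))
        d_near = np.minimum(d_near, Dz[:, best])
    return sorted(medoids)


def _swap_descent(Dz: np.ndarray, medoids: list) -> tuple:
    """Best-improvement SWAP until no single exchange lowers the cost."""
    n = Dz.shape[0]
    medoids = sorted(medoids)
    while True:
        med = np.array(medoids)
        Dm = Dz[:, med]                                   # (n, k)
        order = np.argsort(Dm, axis=1, kind="stable")
        d1 = Dm[np.arange(n), order[:, 0]]
        n1 = order[:, 0]                                  # column of nearest medoid
        d2 = Dm[np.arange(n), order[:, 1]] if len(med) > 1 else np.full(n, np.inf)
        candidates = np.setdiff1d(np.arange(n), med)
        if candidates.size == 0:
            break
        Dc = Dz[:, candidates]                            # (n, m)
        best_delta, best_swap = -1e-12, None
        for col, m in enumerate(med):
            loses = n1 == col
            new_d = np.where(loses[:, None], np.minimum(d2[:, None], Dc), np.minimum(d1[:, None], Dc))
            deltas = new_d.sum(axis=0) - d1.sum()
            j = int(np.argmin(deltas))
            if deltas[j] < best_delta:
                best_delta = float(deltas[j])
                best_swap = (m, int(candidates[j]))
        if best_swap is None:
            break
        m_out, h_in = best_swap
        medoids = sorted(set(medoids) - {m_out} | {h_in})
    med = np.array(sorted(medoids))
    cost = float(Dz[:, med].min(axis=1).sum())
    return medoids, cost


def fit_pam(D, n_clusters: int, seed: int = 0, n_starts: int = 5) -> MedoidModel:
    """PAM with multi-start SWAP local search.

    The first start is the classical greedy BUILD initialization; the
    remaining ``n_starts - 1`` starts are seeded uniform medoid draws.
    Each start runs best-improvement SWAP passes to a local optimum and the
    lowest-cost solution wins (BUILD's on ties).  Deterministic for a fixed
    seed; single-swap local optima are rare but real, hence the restarts.
    """
    meta = D if isinstance(D, DistanceMatrix) else None
    Dmat = D.values if meta is not None else np.asarray(D, dtype=np.float64)
    n = Dmat.shape[0]
    if not (1 <= n_clusters <= n):
        raise ValidationError(f"n_clusters={n_clusters} outside [1, {n}]")
    Dz = _zero_diag(Dmat)

    medoids, cost = _swap_descent(Dz, _build_init(Dz, n_clusters))
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - 1)):
        init = sorted(int(i) for i in rng.choice(n, size=n_clusters, replace=False))
        cand_medoids, cand_cost = _swap_descent(Dz, init)
        if cand_cost < cost - 1e-12:
            medoids, cost = cand_medoids, cand_cost

    med = np.array(sorted(medoids))
    assignment = np.argmin(Dz[:, med], axis=1)
    cost = float(Dz[np.arange(n), med[assignment]].sum())
    hamd = meta.hamd[med] if meta is not None else np.full(len(med), np.nan)
    subjects = [meta.subject_ids[i] for i in med] if meta is not None else []
    return MedoidModel(medoid_indices=med, assignment=assignment,
                       medoid_hamd=hamd, cost=cost, medoid_subjects=subjects)


# ---------------------------------------------------------------------------
# HAMD prediction
# ---------------------------------------------------------------------------

@dataclass
class SeverityPrediction:
    xi_u: float
    neighbor_indices: np.ndarray
    neighbor_hamd: np.ndarray
    neighbor_distances: np.ndarray
    k: int

    def __post_init__(self) -> None:
        lo, hi = self.neighbor_hamd.min(), self.neighbor_hamd.max()
        if not (lo - 1e-9 <= self.xi_u <= hi + 1e-9):
            raise ValidationError("prediction outside its neighbors' score range")


def k_nearest_mean(distances: np.ndarray, scores: np.ndarray, k: int) -> SeverityPrediction:
    """Mean score of the k nearest items (ascending distance, then index)."""
    distances = np.asarray(distances, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    if not (1 <= k <= distances.size):
        raise ValidationError(f"k={k} outside [1, {distances.size}]")
    order = np.argsort(distances, kind="stable")[:k]
    return SeverityPrediction(
        xi_u=float(scores[order].mean()),
        neighbor_indices=order,
        neighbor_hamd=scores[order],
        neighbor_distances=distances[order],
        k=k,
    )


def predict_hamd(L_u, model, medoids: MedoidModel, k: int,
                 medoid_segments: list | None = None) -> SeverityPrediction:
    """Predict an unknown segment's HAMD as the mean of its k nearest medoids.

    ``medoid_segments`` are the spectrograms of ``medoids.medoid_indices``
    (taken from ``medoids.medoid_segments`` when stored there).
    """
    segs = medoid_segments if medoid_segments is not None else medoids.medoid_segments
    if len(segs) != medoids.n_medoids:
        raise ValidationError("need one spectrogram per medoid")
    if k > medoids.n_medoids:
        raise ValidationError(f"k={k} exceeds the {medoids.n_medoids} medoids")
    d = np.array([model.distance(L_u, s) for s in segs], dtype=np.float64)
    return k_nearest_mean(d, medoids.medoid_hamd, k)


def select_k(val_distances: np.ndarray, val_hamd, medoid_hamd, k_range: tuple):
    """Choose k minimizing RMSE(k) + MAE(k) on a validation fold.

    ``val_distances`` holds each validation item's distances to every
    medoid (rows = items).  Ties resolve to the smaller k.
    """
    lo, hi = k_range
    val_distances = np.asarray(val_distances, dtype=np.float64)
    val_hamd = np.asarray(val_hamd, dtype=np.float64)
    medoid_hamd = np.asarray(medoid_hamd, dtype=np.float64)
    n_med = val_distances.shape[1]
    ks = np.arange(lo, min(hi, n_med) + 1)
    if ks.size == 0 or lo > hi:
        raise ValidationError("empty k candidate range")
    order = np.argsort(val_distances, axis=1, kind="stable")
    sorted_scores = medoid_hamd[order]
    prefix_means = np.cumsum(sorted_scores, axis=1) / np.arange(1, n_med + 1)
    best_k, best_obj = None, np.inf
    for k in ks:
        pred = prefix_means[:, k - 1]
        err = pred - val_hamd
        obj = float(np.sqrt(np.mean(err ** 2)) + np.mean(np.abs(err)))
        if obj < best_obj - 1e-12:
            best_obj, best_k = obj, int(k)
    return best_k
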