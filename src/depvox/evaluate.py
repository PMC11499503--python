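"""Leave-one-subject-out protocol, figures of merit and orchestration.

Every fold holds one subject out, carves a ~10% validation split from the
remaining subjects, and rebuilds the entire downstream chain — feature
scaler, training pairs, Siamese network, support set and medoid model —
from that fold's training subjects only, so no information from the test
subject leaks into any fitted component.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from . import support as sup
from .audio import ValidationError, fit_scaler, frontend_segments
from .config import ExperimentConfig
from .pairs import build_pairs
from .severity import build_distance_matrix, fit_pam, k_nearest_mean, select_k
from .siamese import init_model, train
from .synth import CohortManifest, generate_cohort

DEPRESSED = sup.DEPRESSED
HEALTHY = sup.HEALTHY


@dataclass
class LosoFold:
    test_subject: str
    train_subjects: list
    val_subjects: list


def loso_folds(manifest: CohortManifest, val_fraction: float = 0.1,
               seed: int = 0) -> list:
    """One fold per subject; validation subjects drawn per class when possible."""
    subjects = sorted(manifest.subjects)
    if len(subjects) < 3:
        raise ValidationError("LOSO needs at least 3 subjects")
    labels = {s: manifest.label_of(s) for s in subjects}
    folds = []
    for fi, test in enumerate(subjects):
        pool = [s for s in subjects if s != test]
        rng = np.random.default_rng(np.random.SeedSequence([seed, fi]))
        by_class = {c: [s for s in pool if labels[s] == c] for c in (HEALTHY, DEPRESSED)}
        val: list = []
        if all(by_class.values()):
            for c in (HEALTHY, DEPRESSED):
                n_c = max(1, round(val_fraction * len(by_class[c])))
                val += list(rng.choice(by_class[c], size=min(n_c, len(by_class[c])),
                                       replace=False))
        else:
            warnings.warn("single-class training pool; using pooled validation split")
            n_v = max(1, round(val_fraction * len(pool)))
            val = list(rng.choice(pool, size=n_v, replace=False))
        train_s = [s for s in pool if s not in set(val)]
        folds.append(LosoFold(test_subject=test, train_subjects=sorted(train_s),
                              val_subjects=sorted(val)))
    return folds


def classification_metrics(tp: int, tn: int, fp: int, fn: int):
    """(accuracy, sensitivity, specificity) with Depressed as positive.

    A rate with a zero denominator is reported as None, not 0.
    """
    total = tp + tn + fp + fn
    if total == 0:
        raise ValidationError("confusion counts are all zero")
    if min(tp, tn, fp, fn) < 0:
        raise ValidationError("confusion counts must be non-negative")
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    return accuracy, sensitivity, specificity


def severity_metrics(predicted, true):
    """(RMSE, MAE) of HAMD predictions, in HAMD units."""
    predicted = np.asarray(predicted, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    if predicted.shape != true.shape or predicted.size == 0:
        raise ValidationError("prediction and truth lists must match and be non-empty")
    err = predicted - true
    return float(np.sqrt(np.mean(err ** 2))), float(np.mean(np.abs(err)))


@dataclass
class EvalReport:
    """Aggregated LOSO results plus per-fold records and provenance."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    rmse: float
    mae: float
    null_rmse: float
    pair_auc: float
    spearman: float
    confusion: dict
    folds: list
    config: dict
    seed: int
    repeats: list = field(default_factory=list)
    std: dict | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "rmse": self.rmse, "mae": self.mae,
            "null_rmse": self.null_rmse, "pair_auc": self.pair_auc,
            "spearman": self.spearman, "confusion": self.confusion,
            "folds": self.folds, "config": self.config, "seed": self.seed,
            "repeats": self.repeats, "std": self.std,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _fold_seed(base: int, fold_index: int) -> int:
    return int((base * 100003 + fold_index * 7919 + 17) % (2 ** 31))


def _run_once(cfg: ExperimentConfig, manifest, waves, base_seed: int) -> dict:
    fe = cfg.frontend
    segments = {
        subj: frontend_segments(
            waves[subj], fe.window_s, fe.hop_s, fe.n_fft, fe.n_mels,
            fe.segment_s, fe.hop_segment_s, cmvn_scope=fe.cmvn_scope,
        )
        for subj in manifest.subjects
    }
    labels = {s: manifest.label_of(s) for s in manifest.subjects}
    hamd = {s: manifest.hamd_of(s) for s in manifest.subjects}
    input_shape = (fe.n_mels, segments[manifest.subjects[0]][0].n_frames)

    folds = loso_folds(manifest, cfg.val_fraction, seed=base_seed)
    records = []
    pair_scores, pair_targets = [], []

    for fi, fold in enumerate(folds):
        fseed = _fold_seed(base_seed, fi)
        train_subj, val_subj, test_subj = fold.train_subjects, fold.val_subjects, fold.test_subject
        assert test_subj not in train_subj and test_subj not in val_subj

        train_Ls = [L for s in train_subj for L in segments[s]]
        scaler = fit_scaler(train_Ls)
        scaled = {
            s: [scaler.transform(L) for L in segments[s]]
            for s in train_subj + val_subj + [test_subj]
        }

        tr_pairs = build_pairs(labels, {s: scaled[s] for s in train_subj},
                               cfg.pairs.n_pairs, cfg.pairs.cross_class_only,
                               seed=fseed)
        try:
            va_pairs = build_pairs(labels, {s: scaled[s] for s in val_subj},
                                   cfg.pairs.n_val_pairs, cfg.pairs.cross_class_only,
                                   seed=fseed + 1)
        except ValidationError:
            va_pairs = build_pairs(labels, {s: scaled[s] for s in val_subj},
                                   cfg.pairs.n_val_pairs, cross_class_only=False,
                                   seed=fseed + 1)

        model = init_model(cfg.arch, input_shape, seed=fseed + 2)
        tcfg = replace(cfg.train, seed=fseed + 3)
        hist = train(model, tr_pairs, tcfg, va_pairs)

        # ---- downstream task 1: support-set classification ----
        h_subj = [s for s in train_subj if labels[s] == HEALTHY]
        d_subj = [s for s in train_subj if labels[s] == DEPRESSED]
        h_segs = [L for s in h_subj for L in scaled[s]]
        d_segs = [L for s in d_subj for L in scaled[s]]
        order_h = sup.centrality_order(model.pairwise_distances(h_segs))
        order_d = sup.centrality_order(model.pairwise_distances(d_segs))
        val_segs = [L for s in val_subj for L in scaled[s]]
        val_seg_labels = [labels[s] for s in val_subj for _ in scaled[s]]
        if cfg.support.tune:
            D_vh = model.pairwise_distances(val_segs, h_segs)
            D_vd = model.pairwise_distances(val_segs, d_segs)
            v_h, v_d = sup.tune_support_sizes(D_vh, D_vd, val_seg_labels,
                                              order_h, order_d, cfg.support.v_range)
        else:
            v_h = min(cfg.support.v_h, len(h_segs))
            v_d = min(cfg.support.v_d, len(d_segs))
        sup_h = [h_segs[i] for i in order_h[:v_h]]
        sup_d = [d_segs[i] for i in order_d[:v_d]]
        test_segs = scaled[test_subj]
        D_th = model.pairwise_distances(test_segs, sup_h)
        D_td = model.pairwise_distances(test_segs, sup_d)
        agg_h, agg_d = [], []
        for r in range(len(test_segs)):
            _, vec = sup.classify_from_distances(D_th[r], D_td[r])
            agg_h.append(vec.healthy_aggregate)
            agg_d.append(vec.depressed_aggregate)
        pred_label = sup.decide_label(float(np.mean(agg_h)), float(np.mean(agg_d)))

        # ---- downstream task 2: severity regression ----
        seg_subjects = [s for s in train_subj for _ in scaled[s]]
        seg_hamd = np.array([hamd[s] for s in seg_subjects])
        D = build_distance_matrix(train_Ls_scaled := [L for s in train_subj for L in scaled[s]],
                                  model, seg_subjects, seg_hamd)
        k_hi = cfg.severity.k_range[1] if cfg.severity.tune else cfg.severity.k
        n_clusters = cfg.severity.n_clusters or max(
            min(k_hi, D.n_items), math.ceil(math.sqrt(D.n_items))
        )
        n_clusters = min(n_clusters, D.n_items)
        medoids = fit_pam(D, n_clusters, seed=fseed + 4)
        assert set(medoids.medoid_subjects) <= set(train_subj)
        medoid_segs = [train_Ls_scaled[i] for i in medoids.medoid_indices]
        if cfg.severity.tune:
            D_vm = model.pairwise_distances(val_segs, medoid_segs)
            val_hamd = np.array([hamd[s] for s in val_subj for _ in scaled[s]])
            k = select_k(D_vm, val_hamd, medoids.medoid_hamd, cfg.severity.k_range)
        else:
            k = min(cfg.severity.k, medoids.n_medoids)
        D_tm = model.pairwise_distances(test_segs, medoid_segs)
        xi = [k_nearest_mean(D_tm[r], medoids.medoid_hamd, k).xi_u
              for r in range(len(test_segs))]
        pred_hamd = float(np.mean(xi))
        null_pred = float(np.mean([hamd[s] for s in train_subj]))

        # ---- held-out pair scores for AUC ----
        rng = np.random.default_rng(fseed + 5)
        St = np.asarray(model.pairwise_distances(test_segs), dtype=np.float64)
        iu = np.triu_indices(len(test_segs), k=1)
        sims = St[iu]
        opp = d_segs if labels[test_subj] == HEALTHY else h_segs
        Sd = np.asarray(model.pairwise_distances(test_segs, opp), dtype=np.float64).ravel()
        take = min(len(sims), Sd.size)
        sims = sims[rng.choice(len(sims), size=take, replace=False)]
        diss = Sd[rng.choice(Sd.size, size=take, replace=False)]
        pair_scores += list(sims) + list(diss)
        pair_targets += [0] * take + [1] * take

        records.append(dict(
            subject=test_subj, true_label=labels[test_subj], pred_label=pred_label,
            true_hamd=float(hamd[test_subj]), pred_hamd=pred_hamd,
            null_pred=null_pred, v_h=int(v_h), v_d=int(v_d), k=int(k),
            n_medoids=int(medoids.n_medoids), pam_cost=float(medoids.cost),
            train_iterations=int(hist.best_iteration),
            best_val_loss=float(hist.best_val_loss),
        ))

    tp = sum(1 for r in records if r["true_label"] == DEPRESSED and r["pred_label"] == DEPRESSED)
    tn = sum(1 for r in records if r["true_label"] == HEALTHY and r["pred_label"] == HEALTHY)
    fp = sum(1 for r in records if r["true_label"] == HEALTHY and r["pred_label"] == DEPRESSED)
    fn = sum(1 for r in records if r["true_label"] == DEPRESSED and r["pred_label"] == HEALTHY)
    accuracy, sensitivity, specificity = classification_metrics(tp, tn, fp, fn)
    pred = [r["pred_hamd"] for r in records]
    true = [r["true_hamd"] for r in records]
    rmse, mae = severity_metrics(pred, true)
    null_rmse, _ = severity_metrics([r["null_pred"] for r in records], true)
    auc = float(roc_auc_score(pair_targets, pair_scores))
    rho = spearmanr(pred, true).statistic
    rho = float(rho) if np.isfinite(rho) else 0.0
    return dict(
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        rmse=rmse, mae=mae, null_rmse=null_rmse, pair_auc=auc, spearman=rho,
        confusion=dict(tp=tp, tn=tn, fp=fp, fn=fn), folds=records,
    )


def run_experiment(cfg: ExperimentConfig, cohort=None) -> EvalReport:
    """Run the full LOSO evaluation and aggregate an :class:`EvalReport`.

    ``cohort`` may supply a pre-generated ``(manifest, waveforms)`` tuple;
    otherwise a synthetic cohort is generated from ``cfg.cohort``.  With
    ``cfg.n_repeats > 1`` the whole downstream chain is re-run with fresh
    derived seeds on the same cohort and the headline metrics are reported
    as means with a ``std`` block.
    """
    if cohort is None:
        co = cfg.cohort
        manifest, waves = generate_cohort(
            co.n_subjects, co.class_fraction, co.effect, co.duration_s,
            co.sample_rate, seed=cfg.seed, female_fraction=co.female_fraction,
            healthy_max_hamd=co.healthy_max_hamd,
            depressed_min_hamd=co.depressed_min_hamd, hamd_max=co.hamd_max,
        )
    else:
        manifest, waves = cohort

    runs = [
        _run_once(cfg, manifest, waves, base_seed=int((cfg.seed + 7717 * rep) % (2 ** 31)))
        for rep in range(cfg.n_repeats)
    ]
    keys = ("accuracy", "sensitivity", "specificity", "rmse", "mae",
            "null_rmse", "pair_auc", "spearman")
    mean = {
        k: (float(np.mean([r[k] for r in runs]))
            if all(r[k] is not None for r in runs) else None)
        for k in keys
    }
    std = (
        {k: float(np.std([r[k] for r in runs])) for k in keys
         if all(r[k] is not None for r in runs)}
        if len(runs) > 1 else None
    )
    return EvalReport(
        **mean,
        confusion=runs[0]["confusion"], folds=runs[0]["folds"],
        config=cfg.to_dict(), seed=cfg.seed,
        repeats=[{k: r[k] for k in keys} for r in runs] if len(runs) > 1 else [],
        std=std,
    )
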