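"""The Siamese network: twin CNNs with a shared weight store and a
sigmoid-normalized L1 distance head.

Architecture (per twin): four valid-mode stride-1 convolutional layers;
layers 1-3 are each followed by ReLU and 2x2/stride-2 max pooling; the
final feature maps feed one fully connected embedding layer.  The two
twins are literally the same parameter dictionary applied twice, so weight
sharing is structural, and the joint endpoint scores a pair as

    d(L_i, L_j) = sigmoid( w . |e_i - e_j| + b )  in (0, 1),

trained with binary cross-entropy against targets similar=0 / dissimilar=1.
The absolute-difference head makes d exactly symmetric in its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import DTYPE, bce, relu, sigmoid
from .audio import LogMelSpectrogram, ValidationError
from .config import ArchConfig, TrainConfig

LAYER_LABELS = ("conv1_relu", "conv2_relu", "conv3_relu", "conv4")


@dataclass
class ActivationMaps:
    """Per-convolutional-layer feature maps for one input spectrogram.

    Layers 1-3 are captured post-ReLU (before pooling); layer 4 post-conv.
    """

    maps: list
    labels: tuple = LAYER_LABELS

    def __post_init__(self) -> None:
        if len(self.maps) != 4:
            raise ValidationError("expected one activation stack per convolutional layer")


def spatial_chain(arch: ArchConfig, input_shape: tuple) -> list:
    """Per-layer (H, W) sizes after conv (and pooling for layers 1-3).

    Raises if any layer collapses a dimension below 1, naming the layer.
    """
    h, w = input_shape
    sizes = []
    for l, k in enumerate(arch.kernels):
        h, w = h - k + 1, w - k + 1
        if h < 1 or w < 1:
            raise ValidationError(
                f"conv layer {l + 1} (kernel {k}) collapses the input to {h}x{w}"
            )
        if l < 3:
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise ValidationError(f"pooling after layer {l + 1} collapses the input")
        sizes.append((h, w))
    return sizes


class SiameseModel:
    """Twin CNN + distance head over a single shared parameter store."""

    def __init__(self, arch: ArchConfig, input_shape: tuple, seed: int = 0):
        if len(arch.channels) != 4 or len(arch.kernels) != 4:
            raise ValidationError("architecture must specify exactly 4 convolutional layers")
        self.arch = arch
        self.input_shape = tuple(input_shape)
        self.seed = seed
        self.sizes = spatial_chain(arch, input_shape)
        h4, w4 = self.sizes[-1]
        self.flat_dim = arch.channels[-1] * h4 * w4
        self.params: dict[str, np.ndarray] = {}
        self.iteration = 0
        self.best_val_loss: float | None = None
        self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng: np.random.Generator) -> None:
        arch = self.arch
        in_ch = 1
        for l, (cout, k) in enumerate(zip(arch.channels, arch.kernels), start=1):
            shape_w, shape_b = (cout, in_ch, k, k), (cout,)
            if arch.init == "narrow_normal":
                W = rng.normal(0.0, arch.init_std, shape_w)
                b = rng.normal(0.0, arch.init_std, shape_b)
            elif arch.init == "fan_in":
                W = rng.normal(0.0, np.sqrt(2.0 / (in_ch * k * k)), shape_w)
                b = np.zeros(shape_b)
            else:
                raise ValidationError(f"unknown init scheme {arch.init!r}")
            self.params[f"conv{l}_W"] = W.astype(DTYPE)
            self.params[f"conv{l}_b"] = b.astype(DTYPE)
            in_ch = cout
        if arch.init == "narrow_normal":
            fcW = rng.normal(0.0, arch.init_std, (arch.embedding, self.flat_dim))
            fcb = rng.normal(0.0, arch.init_std, (arch.embedding,))
            hw = rng.normal(0.0, arch.init_std, (arch.embedding,))
            hb = rng.normal(0.0, arch.init_std, ())
        else:
            fcW = rng.normal(0.0, np.sqrt(2.0 / self.flat_dim), (arch.embedding, self.flat_dim))
            fcb = np.zeros((arch.embedding,))
            hw = rng.normal(0.0, 1.0 / np.sqrt(arch.embedding), (arch.embedding,))
            hb = np.zeros(())
        self.params["fc_W"] = fcW.astype(DTYPE)
        self.params["fc_b"] = fcb.astype(DTYPE)
        self.params["head_w"] = hw.astype(DTYPE)
        self.params["head_b"] = hb.astype(DTYPE)

    # -- forward / backward ------------------------------------------------

    def _check_input(self, values: np.ndarray) -> None:
        if values.shape != self.input_shape:
            raise ValidationError(
                f"input shape {values.shape} does not match model input {self.input_shape}"
            )

    def _as_batch(self, Ls) -> np.ndarray:
        out = np.empty((len(Ls), 1) + self.input_shape, dtype=DTYPE)
        for i, L in enumerate(Ls):
            vals = L.values if isinstance(L, LogMelSpectrogram) else np.asarray(L)
            self._check_input(vals)
            out[i, 0] = vals
        return out

    def _trunk_forward(self, x: np.ndarray, keep_cache: bool = False):
        caches = []
        h = x
        for l in range(1, 5):
            out, col = _nn.conv2d_forward(h, self.params[f"conv{l}_W"], self.params[f"conv{l}_b"])
            if l < 4:
                act = relu(out)
                pooled, pc = _nn.maxpool2_forward(act)
                if keep_cache:
                    caches.append((h.shape, col, out, pc))
                h = pooled
            else:
                if keep_cache:
                    caches.append((h.shape, col, None, None))
                h = out
        flat = h.reshape(h.shape[0], -1)
        emb = flat @ self.params["fc_W"].T + self.params["fc_b"]
        cache = (caches, flat, h.shape) if keep_cache else None
        return emb, cache

    def _trunk_backward(self, demb: np.ndarray, cache, grads: dict) -> None:
        caches, flat, h_shape = cache
        grads["fc_W"] += demb.T @ flat
        grads["fc_b"] += demb.sum(axis=0)
        dh = (demb @ self.params["fc_W"]).reshape(h_shape)
        for l in range(4, 0, -1):
            x_shape, col, pre_act, pool_cache = caches[l - 1]
            if l < 4:
                dact = _nn.maxpool2_backward(dh, pool_cache)
                dh = dact * (pre_act > 0)
            dh, dW, db = _nn.conv2d_backward(dh, col, self.params[f"conv{l}_W"], x_shape)
            grads[f"conv{l}_W"] += dW
            grads[f"conv{l}_b"] += db

    # -- public API --------------------------------------------------------

    def embed(self, L) -> np.ndarray:
        return self.embed_many([L])[0]

    def embed_many(self, Ls, batch: int = 64) -> np.ndarray:
        out = np.empty((len(Ls), self.arch.embedding), dtype=DTYPE)
        for start in range(0, len(Ls), batch):
            chunk = self._as_batch(Ls[start:start + batch])
            out[start:start + len(chunk)], _ = self._trunk_forward(chunk)
        return out

    def scores_from_embeddings(self, E1: np.ndarray, E2: np.ndarray) -> np.ndarray:
        """Distance scores for aligned embedding rows."""
        d = np.abs(E1 - E2)
        z = d @ self.params["head_w"] + self.params["head_b"]
        return sigmoid(z)

    def distance(self, L_i, L_j) -> float:
        """Eq.-style pair dissimilarity d_ij = M(L_i, L_j) in (0, 1).

        Each spectrogram is embedded independently, so the score is exactly
        symmetric under argument swap.
        """
        e_i = self.embed(L_i)
        e_j = self.embed(L_j)
        return float(self.scores_from_embeddings(e_i[None, :], e_j[None, :])[0])

    @property
    def identity_constant(self) -> float:
        """d(A, A) = sigmoid(head bias), the same constant for every input."""
        return float(sigmoid(np.asarray(self.params["head_b"], dtype=np.float64)))

    def pairwise_distances(self, A, B=None) -> np.ndarray:
        """Distance matrix between two spectrogram lists (B=None: A vs A)."""
        EA = self.embed_many(A)
        EB = EA if B is None else self.embed_many(B)
        out = np.empty((len(EA), len(EB)), dtype=DTYPE)
        w, b = self.params["head_w"], self.params["head_b"]
        for i in range(len(EA)):
            d = np.abs(EA[i][None, :] - EB)
            out[i] = sigmoid(d @ w + b)
        return out

    def activations(self, L) -> ActivationMaps:
        """Per-layer activation maps (post-ReLU for layers 1-3, post-conv for 4)."""
        x = self._as_batch([L])
        maps = []
        h = x
        for l in range(1, 5):
            out, _ = _nn.conv2d_forward(h, self.params[f"conv{l}_W"], self.params[f"conv{l}_b"])
            if l < 4:
                act = relu(out)
                maps.append(act[0].copy())
                h, _ = _nn.maxpool2_forward(act)
            else:
                maps.append(out[0].copy())
        return ActivationMaps(maps=maps)

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}


def init_model(arch: ArchConfig, input_shape: tuple, seed: int = 0) -> SiameseModel:
    """Build a Siamese model with all parameters freshly initialized."""
    return SiameseModel(arch, input_shape, seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingHistory:
    iterations: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_iterations: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_iteration: int = 0
    best_val_loss: float = float("inf")
    stopped_early: bool = False
    restarts: int = 0


def _pair_arrays(pairs, model: SiameseModel):
    XL = model._as_batch([p.left for p in pairs])
    XR = model._as_batch([p.right for p in pairs])
    t = np.array([p.target for p in pairs], dtype=DTYPE)
    return XL, XR, t


def _forward_scores(model: SiameseModel, XL, XR, keep_cache=False):
    x = np.concatenate([XL, XR], axis=0)
    emb, cache = model._trunk_forward(x, keep_cache=keep_cache)
    n = XL.shape[0]
    e1, e2 = emb[:n], emb[n:]
    diff = e1 - e2
    d = np.abs(diff)
    z = d @ model.params["head_w"] + model.params["head_b"]
    return sigmoid(z), (diff, d, cache, n)


def _batched_val_loss(model, XL, XR, t, batch=64) -> float:
    losses, total = 0.0, 0
    for s in range(0, len(t), batch):
        p, _ = _forward_scores(model, XL[s:s + batch], XR[s:s + batch])
        losses += bce(p, t[s:s + batch]) * len(p)
        total += len(p)
    return losses / total


def train(model: SiameseModel, pair_set, cfg: TrainConfig, val_pairs) -> TrainingHistory:
    """SGD training of the twin network on a balanced pair set.

    Gradients flow through both twins into the single shared parameter
    store (the per-twin gradients sum automatically).  Validation BCE is
    evaluated every ``cfg.eval_every`` iterations; training stops when it
    has not improved by ``cfg.min_delta`` for ``cfg.patience`` consecutive
    evaluations, and the best-validation parameters are restored.

    Mini-batch non-convex optimization from a random init occasionally
    stalls on the initial plateau; when the best validation BCE stays
    above ``cfg.restart_threshold`` and ``cfg.max_restarts`` allows, the
    network is re-initialized from a derived seed and retrained, keeping
    the best attempt (the usual multi-start rule for such optimizers).
    """
    best_hist, best_params = None, None
    chance_bce = float(np.log(2.0))   # BCE of a constant 0.5 score on balanced pairs
    no_learn_streak = 0
    for attempt in range(cfg.max_restarts + 1):
        if attempt > 0:
            model._init_params(np.random.default_rng(model.seed + 7700 + attempt))
        hist = _train_once(model, pair_set, cfg, val_pairs, attempt)
        hist.restarts = attempt
        if best_hist is None or hist.best_val_loss < best_hist.best_val_loss:
            best_hist, best_params = hist, model.copy_params()
        if best_hist.best_val_loss <= cfg.restart_threshold:
            break
        # two consecutive attempts stuck at the chance plateau: the pair task
        # itself is uninformative for this fold, further restarts are futile
        no_learn_streak = no_learn_streak + 1 if hist.best_val_loss > chance_bce - 0.05 else 0
        if no_learn_streak >= 2:
            break
    model.params = best_params
    model.best_val_loss = best_hist.best_val_loss
    return best_hist


def _train_once(model: SiameseModel, pair_set, cfg: TrainConfig, val_pairs,
                attempt: int = 0) -> TrainingHistory:
    pairs = list(pair_set.pairs) if hasattr(pair_set, "pairs") else list(pair_set)
    vpairs = list(val_pairs.pairs) if hasattr(val_pairs, "pairs") else list(val_pairs)
    if not pairs or not vpairs:
        raise ValidationError("training and validation pair sets must be non-empty")
    XL, XR, t = _pair_arrays(pairs, model)
    VXL, VXR, vt = _pair_arrays(vpairs, model)
    rng = np.random.default_rng(cfg.seed + 31 * attempt)
    n = len(t)
    hist = TrainingHistory()
    best_params = model.copy_params()
    evals_since_best = 0
    lr = DTYPE(cfg.learning_rate)
    mom = DTYPE(getattr(cfg, "momentum", 0.0))
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()} if mom > 0 else None

    for it in range(1, cfg.max_iterations + 1):
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        p, (diff, d, cache, nb) = _forward_scores(model, XL[idx], XR[idx], keep_cache=True)
        tb = t[idx]
        loss = bce(p, tb)
        if not np.isfinite(loss):
            raise RuntimeError(
                "training diverged (non-finite loss); try lowering the learning rate"
            )
        hist.iterations.append(it)
        hist.train_loss.append(loss)

        dz = ((p - tb) / nb).astype(DTYPE)
        grads = {k: np.zeros_like(v) for k, v in model.params.items()}
        grads["head_w"] += d.T @ dz
        grads["head_b"] += dz.sum()
        dd = dz[:, None] * model.params["head_w"][None, :]
        de1 = dd * np.sign(diff)
        demb = np.concatenate([de1, -de1], axis=0)
        model._trunk_backward(demb, cache, grads)
        if velocity is None:
            for k in model.params:
                model.params[k] -= lr * grads[k]
        else:
            for k in model.params:
                velocity[k] = mom * velocity[k] - lr * grads[k]
                model.params[k] += velocity[k]
        model.iteration = it

        if it % cfg.eval_every == 0 or it == cfg.max_iterations:
            vloss = _batched_val_loss(model, VXL, VXR, vt)
            hist.val_iterations.append(it)
            hist.val_loss.append(vloss)
            if vloss < hist.best_val_loss - cfg.min_delta:
                hist.best_val_loss = vloss
                hist.best_iteration = it
                best_params = model.copy_params()
                evals_since_best = 0
            else:
                evals_since_best += 1
                if evals_since_best >= cfg.patience:
                    hist.stopped_early = True
                    break

    model.params = best_params
    model.best_val_loss = hist.best_val_loss
    return hist
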