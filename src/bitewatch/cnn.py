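"""The 10-block 1-D convolutional eating classifier.

Architecture: ten blocks of (valid 1-D convolution, stride 1) -> batch
normalization -> ReLU -> max-pooling, followed by a global max-pool over
time and a fully connected layer emitting one sigmoid probability. Filter
counts grow (8, 16, 16, 32, 32, 64, 64, 128, 128, 256) with kernel sizes
(11, 10, 10, 8, 9, 6, 7, 4, 5, 2). Weights are Glorot-uniform initialized
and trained with Adam on binary cross-entropy; a best-epoch callback
restores the weights from the epoch with the best validation performance.

Pooling sizes default to a halving cascade (pool 2 wherever the remaining
length still supports the next kernel, else 1) so the same stack accepts
the full 15000-sample input or reduced-rate inputs.

The network, its backpropagation and the optimizer are implemented directly
on NumPy arrays; convolutions are evaluated as im2col matrix products so
CPU training at synthetic-cohort scale stays fast. Forward inference is a
pure function of (weights, input).

Ensembling: five members trained on resampled train/validation subject
splits (test subjects fixed); the ensemble score is the arithmetic mean of
member scores. Personalization: each member is fine-tuned for two epochs on
60% of a held-out individual's days (20% validation, 20% test).
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .records import SensorDay
from .transforms import TransformConfig, apply_eval_transforms, apply_training_transforms
from .windowing import WindowSet, make_windows, oversample

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "SplitPlan",
    "ConvNet",
    "TrainedEnsemble",
    "build_model",
    "plan_pools",
    "make_split_plan",
    "train_member",
    "train_ensemble",
    "finetune_personal",
    "score_window_set",
]

DEFAULT_FILTERS = (8, 16, 16, 32, 32, 64, 64, 128, 128, 256)
DEFAULT_KERNELS = (11, 10, 10, 8, 9, 6, 7, 4, 5, 2)

_MODALITY_CHANNELS = {"gyro": 3, "accl": 3, "both": 6}


class ModelConfigError(ValueError):
    """The model specification is internally inconsistent."""


def plan_pools(input_length: int, kernels: tuple[int, ...]) -> tuple[int, ...]:
    """Per-block max-pool sizes: 2 while the next kernel still fits, else 1.

    The final block is followed by a global max-pool, so its entry is always
    1. Raises :class:`ModelConfigError` naming the first block whose kernel
    no longer fits.
    """
    # minimum input each suffix of the stack needs with no further pooling
    req = [0] * len(kernels)
    req[-1] = kernels[-1]
    for i in range(len(kernels) - 2, -1, -1):
        req[i] = kernels[i] + req[i + 1] - 1
    L = int(input_length)
    pools = []
    for i, k in enumerate(kernels):
        if L < k:
            raise ModelConfigError(
                f"input length too short for the pooling cascade: block {i + 1} "
                f"needs {k} samples but receives {L}"
            )
        L = L - k + 1
        if i < len(kernels) - 1 and L // 2 >= req[i + 1]:
            pools.append(2)
            L //= 2
        else:
            pools.append(1)
    return tuple(pools)


@dataclasses.dataclass
class ModelSpec:
    """Hyperparameters of the convolutional classifier."""

    n_blocks: int = 10
    filters_per_block: tuple[int, ...] = DEFAULT_FILTERS
    kernel_sizes: tuple[int, ...] = DEFAULT_KERNELS
    input_channels: int = 3
    input_length: int = 15000
    #: None -> derive with :func:`plan_pools`
    pool_sizes: tuple[int, ...] | None = None
    #: which sensor triples feed the network; gyroscope alone performs best
    modality: str = "gyro"

    def validate(self) -> None:
        if len(self.filters_per_block) != self.n_blocks:
            raise ModelConfigError(
                f"filters_per_block has {len(self.filters_per_block)} entries, expected {self.n_blocks}"
            )
        if len(self.kernel_sizes) != self.n_blocks:
            raise ModelConfigError(
                f"kernel_sizes has {len(self.kernel_sizes)} entries, expected {self.n_blocks}"
            )
        if self.modality not in _MODALITY_CHANNELS:
            raise ModelConfigError(f"modality must be one of {sorted(_MODALITY_CHANNELS)}")
        if self.input_channels != _MODALITY_CHANNELS[self.modality]:
            raise ModelConfigError(
                f"modality {self.modality!r} implies {_MODALITY_CHANNELS[self.modality]} "
                f"input channels, got {self.input_channels}"
            )
        if self.pool_sizes is not None and len(self.pool_sizes) != self.n_blocks:
            raise ModelConfigError("pool_sizes must have one entry per block")

    def resolved_pools(self) -> tuple[int, ...]:
        if self.pool_sizes is not None:
            return self.pool_sizes
        return plan_pools(self.input_length, self.kernel_sizes)


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings. Defaults follow the study protocol; the
    ``max_*`` caps subsample very large window sets for desk-scale runs."""

    learning_rate: float = 3e-5
    epochs: int = 5
    batch_size: int = 64
    best_epoch_restore: bool = True
    #: 'loss' (minimum validation BCE) or 'auc' (maximum validation AUC)
    best_epoch_metric: str = "loss"
    finetune_epochs: int = 2
    n_members: int = 5
    seed: int = 0
    max_train_positives: int | None = None
    max_train_negatives: int | None = None
    max_val_windows: int | None = None

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.best_epoch_metric not in ("loss", "auc"):
            raise ValueError("best_epoch_metric must be 'loss' or 'auc'")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv1d:
    """Valid 1-D convolution, stride 1; weights (K, Cin, Cout)."""

    def __init__(self, kernel: int, cin: int, cout: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (kernel * cin + kernel * cout))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(kernel, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.cin, self.cout = kernel, cin, cout
        self._cache = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, _ = x.shape
        lout = L - self.k + 1
        cols = sliding_window_view(x, self.k, axis=1)  # (B, Lout, Cin, K)
        xc = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B * lout, self.k * self.cin)
        y = xc @ self.W.reshape(self.k * self.cin, self.cout) + self.b
        if train:
            self._cache = (xc, B, L, lout)
        return y.reshape(B, lout, self.cout)

    def backward(self, dy: np.ndarray):
        xc, B, L, lout = self._cache
        dyf = dy.reshape(B * lout, self.cout)
        dW = (xc.T @ dyf).reshape(self.k, self.cin, self.cout)
        db = dyf.sum(axis=0)
        dxc = (dyf @ self.W.reshape(self.k * self.cin, self.cout).T).reshape(
            B, lout, self.k, self.cin
        )
        dx = np.zeros((B, L, self.cin), dtype=np.float32)
        for kk in range(self.k):
            dx[:, kk : kk + lout, :] += dxc[:, :, kk, :]
        self._cache = None
        return dx, {"W": dW, "b": db}


class _BatchNorm:
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * istd
        if train:
            self._cache = (xhat.astype(np.float32), istd.astype(np.float32))
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, dy: np.ndarray):
        xhat, istd = self._cache
        n = dy.shape[0] * dy.shape[1]
        dgamma = (dy * xhat).sum(axis=(0, 1))
        dbeta = dy.sum(axis=(0, 1))
        dx = (self.gamma * istd) * (dy - dbeta / n - xhat * (dgamma / n))
        self._cache = None
        return dx.astype(np.float32), {"gamma": dgamma, "beta": dbeta}


class _ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray):
        dx = dy * self._mask
        self._mask = None
        return dx, {}


class _MaxPool:
    """Non-overlapping max-pool along time; trailing remainder is dropped."""

    def __init__(self, pool: int):
        self.pool = pool
        self._cache = None

    def params(self):
        return {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.pool == 1:
            if train:
                self._cache = ("identity", x.shape)
            return x
        B, L, C = x.shape
        lh = L // self.pool
        xv = x[:, : lh * self.pool].reshape(B, lh, self.pool, C)
        idx = xv.argmax(axis=2)
        y = np.take_along_axis(xv, idx[:, :, None, :], axis=2)[:, :, 0, :]
        if train:
            self._cache = (idx, (B, L, C))
        return y

    def backward(self, dy: np.ndarray):
        cache, shape = self._cache
        self._cache = None
        if isinstance(cache, str):
            return dy, {}
        idx = cache
        B, L, C = shape
        lh = L // self.pool
        g = np.zeros((B, lh, self.pool, C), dtype=np.float32)
        np.put_along_axis(g, idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C), dtype=np.float32)
        dx[:, : lh * self.pool] = g.reshape(B, lh * self.pool, C)
        return dx, {}


class _GlobalMaxPool:
    def __init__(self):
        self._cache = None

    def params(self):
        return {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        idx = x.argmax(axis=1)  # (B, C)
        y = np.take_along_axis(x, idx[:, None, :], axis=1)[:, 0, :]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray):
        idx, shape = self._cache
        self._cache = None
        dx = np.zeros(shape, dtype=np.float32)
        np.put_along_axis(dx, idx[:, None, :], dy[:, None, :], axis=1)
        return dx, {}


class _Dense:
    """Fully connected layer to a single logit."""

    def __init__(self, cin: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (cin + 1))
        self.W = rng.uniform(-limit, limit, size=(cin,)).astype(np.float32)
        self.b = np.float32(0.0)
        self._cache = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.W + self.b

    def backward(self, dz: np.ndarray):
        x = self._cache
        self._cache = None
        dW = x.T @ dz
        db = dz.sum()
        dx = np.outer(dz, self.W).astype(np.float32)
        return dx, {"W": dW, "b": db}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class ConvNet:
    """The assembled network with explicit forward/backward passes."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        spec.validate()
        pools = spec.resolved_pools()
        rng = np.random.Generator(np.random.PCG64(seed))
        self.spec = spec
        self.layers: list = []
        cin = spec.input_channels
        L = spec.input_length
        for i in range(spec.n_blocks):
            k, cout, p = spec.kernel_sizes[i], spec.filters_per_block[i], pools[i]
            if L < k:
                raise ModelConfigError(
                    f"input length too short for the pooling cascade: block {i + 1} "
                    f"needs {k} samples but receives {L}"
                )
            self.layers.append(_Conv1d(k, cin, cout, rng))
            self.layers.append(_BatchNorm(cout))
            self.layers.append(_ReLU())
            self.layers.append(_MaxPool(p))
            L = (L - k + 1) // p
            cin = cout
        self.layers.append(_GlobalMaxPool())
        self.dense = _Dense(cin, rng)

    # -- weights ---------------------------------------------------------

    def _stateful(self):
        return [l for l in self.layers] + [self.dense]

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self._stateful():
            for name in sorted(layer.params()):
                out.append(np.copy(layer.params()[name]))
            if isinstance(layer, _BatchNorm):
                out.append(layer.running_mean.copy())
                out.append(layer.running_var.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self._stateful():
            for name in sorted(layer.params()):
                val = np.asarray(next(it))
                if np.ndim(layer.params()[name]) == 0:
                    setattr(layer, name, np.float32(val))
                else:
                    layer.params()[name][...] = val
            if isinstance(layer, _BatchNorm):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)

    @property
    def n_parameters(self) -> int:
        return int(sum(np.size(v) for l in self._stateful() for v in l.params().values()))

    # -- passes ----------------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            h = layer.forward(h, train)
        return self.dense.forward(h, train)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Scores in [0,1]; pure function of (weights, input)."""
        x = np.asarray(x, dtype=np.float32)
        out = np.empty(len(x), dtype=np.float64)
        for s in range(0, len(x), batch_size):
            out[s : s + batch_size] = _sigmoid(self.forward_logits(x[s : s + batch_size]))
        return out

    def train_step(self, xb: np.ndarray, yb: np.ndarray, opt: "_Adam") -> float:
        z = self.forward_logits(xb, train=True)
        p = _sigmoid(z)
        loss = _bce(p, yb)
        dz = ((p - yb) / len(yb)).astype(np.float32)
        grads: dict[int, dict[str, np.ndarray]] = {}
        dx, g = self.dense.backward(dz)
        grads[id(self.dense)] = g
        for layer in reversed(self.layers):
            dx, g = layer.backward(dx)
            if g:
                grads[id(layer)] = g
        opt.step(self, grads)
        return loss


class _Adam:
    def __init__(self, model: ConvNet, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}
        for layer in model._stateful():
            for name, val in layer.params().items():
                self.m[(id(layer), name)] = np.zeros_like(np.asarray(val, dtype=np.float32))
                self.v[(id(layer), name)] = np.zeros_like(np.asarray(val, dtype=np.float32))

    def step(self, model: ConvNet, grads: dict[int, dict[str, np.ndarray]]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for layer in model._stateful():
            lg = grads.get(id(layer))
            if not lg:
                continue
            for name, g in lg.items():
                key = (id(layer), name)
                g = np.asarray(g, dtype=np.float32)
                self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
                self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
                update = self.lr * (self.m[key] / bc1) / (np.sqrt(self.v[key] / bc2) + self.eps)
                val = layer.params()[name]
                if np.ndim(val) == 0:
                    setattr(layer, name, np.float32(val - update))
                else:
                    val -= update.astype(np.float32)


def build_model(spec: ModelSpec, seed: int = 0) -> ConvNet:
    """Construct an untrained network; deterministic given ``seed``."""
    return ConvNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SplitPlan:
    """Subject-wise test/val/train partition with resampled train/val splits.

    The test subjects stay fixed; each resample redraws the validation
    subjects from the remainder, one resample per ensemble member.
    """

    test_ids: list[str]
    resamples: list[tuple[list[str], list[str]]]  # (train_ids, val_ids)

    def validate(self) -> None:
        test = set(self.test_ids)
        for train_ids, val_ids in self.resamples:
            tr, va = set(train_ids), set(val_ids)
            if tr & va or tr & test or va & test:
                raise ValueError("train/val/test subject sets must be pairwise disjoint")
            if not tr or not va:
                raise ValueError("each resample needs non-empty train and val subject sets")


def make_split_plan(
    participants: list[str],
    rng_state: np.random.Generator,
    n_test: int = 3,
    n_val: int = 2,
    n_resamples: int = 5,
) -> SplitPlan:
    """Draw a subject-wise split plan (3 test / 2 val / rest train by default)."""
    participants = list(participants)
    if len(participants) < n_test + n_val + 1:
        raise ValueError(
            f"need at least {n_test + n_val + 1} participants, got {len(participants)}"
        )
    perm = list(rng_state.permutation(participants))
    test_ids = perm[:n_test]
    rest = perm[n_test:]
    resamples = []
    for _ in range(n_resamples):
        order = list(rng_state.permutation(rest))
        resamples.append((order[n_val:], order[:n_val]))
    plan = SplitPlan(test_ids=test_ids, resamples=resamples)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _subsample(ws: WindowSet, rng: np.random.Generator, max_pos: int | None, max_neg: int | None) -> WindowSet:
    labels = ws.labels
    keep = []
    for cls, cap in ((1, max_pos), (0, max_neg)):
        idx = np.flatnonzero(labels == cls)
        if cap is not None and len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return ws.subset(keep)


def _val_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    if len(np.unique(labels)) < 2:
        return 0.5
    return float(roc_auc_score(labels, scores))


def train_member(
    model: ConvNet,
    train: WindowSet,
    val: WindowSet,
    cfg: TrainConfig,
    transforms: TransformConfig,
    rng_state: np.random.Generator | None = None,
    keep_snapshots: bool = False,
) -> tuple[ConvNet, dict]:
    """Train one network with on-the-fly augmentation and best-epoch restore.

    ``train`` should be oversampled/balanced; ``val`` keeps the original
    imbalance. Returns the (mutated) model plus a history dict with per-epoch
    train loss, validation metric, and the restored epoch index.
    """
    cfg.validate()
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and val window sets must be non-empty")
    rng = rng_state if rng_state is not None else np.random.Generator(np.random.PCG64(cfg.seed))
    modality = model.spec.modality
    opt = _Adam(model, cfg.learning_rate)
    y_train = train.labels.astype(np.float64)
    xv = apply_eval_transforms(val.batch(np.arange(len(val)), modality), transforms)
    yv = val.labels.astype(np.float64)

    history: dict = {"train_loss": [], "val_metric": [], "best_epoch": None, "snapshots": []}
    best_metric = None
    best_weights = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train))
        losses = []
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            xb = apply_training_transforms(train.batch(idx, modality), transforms, rng)
            losses.append(model.train_step(xb, y_train[idx], opt))
        pv = model.predict_proba(xv)
        if cfg.best_epoch_metric == "loss":
            metric = _bce(pv, yv)
            better = best_metric is None or metric < best_metric
        else:
            metric = _val_auc(pv, yv)
            better = best_metric is None or metric > best_metric
        history["train_loss"].append(float(np.mean(losses)))
        history["val_metric"].append(metric)
        if keep_snapshots:
            history["snapshots"].append(model.get_weights())
        if better:
            best_metric = metric
            history["best_epoch"] = epoch
            if cfg.best_epoch_restore:
                best_weights = model.get_weights()
    if cfg.best_epoch_restore and best_weights is not None:
        model.set_weights(best_weights)
    return model, history


@dataclasses.dataclass
class TrainedEnsemble:
    """Five trained members; the combined score is their arithmetic mean."""

    members: list[ConvNet]
    transforms: TransformConfig

    def member_scores(self, x: np.ndarray) -> np.ndarray:
        """(n_members, n_windows) member probabilities on normalized input."""
        return np.stack([m.predict_proba(x) for m in self.members])

    def score(self, x: np.ndarray) -> np.ndarray:
        return self.member_scores(x).mean(axis=0)


def score_window_set(
    scorer: TrainedEnsemble | ConvNet,
    ws: WindowSet,
    transforms: TransformConfig,
    batch_size: int = 512,
    return_members: bool = False,
) -> np.ndarray:
    """Ensemble (or single-model) scores for every window in ``ws``.

    With ``return_members`` the (n_members, n_windows) member score matrix
    is returned instead of its mean.
    """
    if isinstance(scorer, ConvNet):
        members = [scorer]
        modality = scorer.spec.modality
    else:
        members = scorer.members
        modality = members[0].spec.modality
    out = np.zeros((len(members), len(ws)), dtype=np.float64)
    for s in range(0, len(ws), batch_size):
        idx = np.arange(s, min(s + batch_size, len(ws)))
        x = apply_eval_transforms(ws.batch(idx, modality), transforms)
        for j, m in enumerate(members):
            out[j, idx] = m.predict_proba(x)
    if return_members:
        return out
    return out.mean(axis=0)


def train_ensemble(
    plan: SplitPlan,
    windows: WindowSet,
    spec: ModelSpec,
    cfg: TrainConfig,
    transforms: TransformConfig,
) -> TrainedEnsemble:
    """Train one member per resampled train/val split; test subjects untouched."""
    plan.validate()
    cfg.validate()
    if len(plan.resamples) < cfg.n_members:
        raise ValueError(
            f"plan provides {len(plan.resamples)} resamples but {cfg.n_members} members requested"
        )
    labeled = windows.labeled()
    root = np.random.SeedSequence(cfg.seed)
    members = []
    for i, seq in enumerate(root.spawn(cfg.n_members)):
        train_ids, val_ids = plan.resamples[i]
        seeds = seq.generate_state(2)
        rng = np.random.Generator(np.random.PCG64(seq.spawn(1)[0]))
        train_ws = _subsample(
            labeled.for_participants(train_ids), rng, cfg.max_train_positives, cfg.max_train_negatives
        )
        train_ws = oversample(train_ws, rng)
        val_ws = labeled.for_participants(val_ids)
        if cfg.max_val_windows is not None and len(val_ws) > cfg.max_val_windows:
            sel = np.sort(rng.choice(len(val_ws), size=cfg.max_val_windows, replace=False))
            val_ws = val_ws.subset(sel)
        model = build_model(spec, seed=int(seeds[0]))
        model, _ = train_member(model, train_ws, val_ws, cfg, transforms, rng_state=rng)
        members.append(model)
    return TrainedEnsemble(members=members, transforms=transforms)


# ---------------------------------------------------------------------------
# personalization
# ---------------------------------------------------------------------------

def finetune_personal(
    global_ensemble: TrainedEnsemble,
    person_days: list[SensorDay],
    cfg: TrainConfig,
    window_seconds: float = 300.0,
    step_seconds: float = 20.0,
    rng_state: np.random.Generator | None = None,
) -> tuple[TrainedEnsemble, dict[str, list[SensorDay]]]:
    """Fine-tune each member on one individual's day-partitioned data.

    Days are split 60/20/20 into train/validation/test; each member copies
    the global weights and continues for ``cfg.finetune_epochs`` epochs on
    the oversampled training windows. Returns the personalized ensemble and
    the day partition (the test days were never seen during tuning).
    """
    if len(person_days) < 5:
        raise ValueError(
            "fine-tuning needs >= 5 days so the 60/20/20 day split is non-degenerate "
            "(personalization is intended for individuals with >= 7 recorded days)"
        )
    rng = rng_state if rng_state is not None else np.random.Generator(np.random.PCG64(cfg.seed))
    order = rng.permutation(len(person_days))
    n = len(person_days)
    n_test = max(1, int(round(0.2 * n)))
    n_val = max(1, int(round(0.2 * n)))
    test_days = [person_days[i] for i in order[:n_test]]
    val_days = [person_days[i] for i in order[n_test : n_test + n_val]]
    train_days = [person_days[i] for i in order[n_test + n_val :]]
    partition = {"train": train_days, "val": val_days, "test": test_days}

    if cfg.finetune_epochs == 0:
        return TrainedEnsemble(members=list(global_ensemble.members), transforms=global_ensemble.transforms), partition

    def _ws(days: list[SensorDay]) -> WindowSet:
        return WindowSet.concat(
            [make_windows(d, window_seconds, step_seconds) for d in days]
        ).labeled()

    train_ws = _subsample(_ws(train_days), rng, cfg.max_train_positives, cfg.max_train_negatives)
    train_ws = oversample(train_ws, rng)
    val_ws = _ws(val_days)
    if cfg.max_val_windows is not None and len(val_ws) > cfg.max_val_windows:
        sel = np.sort(rng.choice(len(val_ws), size=cfg.max_val_windows, replace=False))
        val_ws = val_ws.subset(sel)

    ft_cfg = dataclasses.replace(cfg, epochs=cfg.finetune_epochs)
    members = []
    for member in global_ensemble.members:
        clone = copy.deepcopy(member)
        clone, _ = train_member(
            clone, train_ws, val_ws, ft_cfg, global_ensemble.transforms, rng_state=rng
        )
        members.append(clone)
    return TrainedEnsemble(members=members, transforms=global_ensemble.transforms), partition
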