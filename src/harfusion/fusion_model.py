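"""The three-branch feature-fusion CNN classifier and its 1-D baseline.

Architecture: each 64x64x3 input image passes through five convolutional
blocks (3x3 same-padding convolution, ReLU, 2x2 max pooling), halving the
spatial size each block (64 -> 32 -> 16 -> 8 -> 4 -> 2) and ending at 2x2x64,
i.e. a flattened vector of 256, which a dense layer expands to a
1024-dimensional branch feature.  The three branch features are concatenated
(3072) and classified by dense layers of 256 and ``n_classes`` units with a
softmax output.  Branches do not share weights and the whole network is
trained end-to-end with categorical cross-entropy, Adam (lr 0.005, batch 8)
and a reduce-on-plateau schedule (factor 0.7, patience 3 epochs on the
validation loss).

The 1-D baseline mirrors the branch topology with 1-D convolutions over the
raw (2500, 3) segment as a single input.

Everything is exposed both as plain builder/train functions and as
sklearn-style estimators (:class:`FusionImageClassifier`,
:class:`Baseline1DClassifier`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .signal_core import HarfusionError, EmptyDatasetError

__all__ = [
    "BranchSpec",
    "FusionSpec",
    "TrainConfig",
    "FusionNet",
    "build_branch",
    "build_fusion",
    "build_baseline_1d",
    "train",
    "predict",
    "top_k_labels",
    "FusionImageClassifier",
    "Baseline1DClassifier",
    "save_checkpoint",
    "load_checkpoint",
]


class InputShapeError(HarfusionError, ValueError):
    """An input tensor does not match the model's expected shape."""


class LabelError(HarfusionError, ValueError):
    """A label is outside the model's taxonomy."""


@dataclass(frozen=True)
class BranchSpec:
    """One convolutional branch: five factor-2 blocks ending at 2x2x64."""

    input_shape: tuple[int, int, int] = (64, 64, 3)
    n_blocks: int = 5
    block_channels: tuple[int, ...] = (32, 64, 128, 128, 64)
    kernel_size: int = 3
    feature_units: int = 1024

    def __post_init__(self) -> None:
        if len(self.block_channels) != self.n_blocks:
            raise ValueError("block_channels length must equal n_blocks")
        if self.block_channels[-1] != 64:
            raise ValueError("final block must have 64 channels")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValueError("kernel_size must be a positive odd integer")
        side = self.input_shape[0]
        if side % (2 ** self.n_blocks):
            raise ValueError("input side must be divisible by 2**n_blocks")

    @property
    def final_spatial(self) -> int:
        return self.input_shape[0] // (2 ** self.n_blocks)

    @property
    def flattened_units(self) -> int:
        return self.final_spatial ** 2 * self.block_channels[-1]


@dataclass(frozen=True)
class FusionSpec:
    """Fusion head: concatenated branch features -> 256 -> n_classes."""

    n_classes: int = 15
    n_branches: int = 3
    head_units: int = 256

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")

    def fused_dim(self, feature_units: int = 1024) -> int:
        return self.n_branches * feature_units


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (the defaults are the operating point)."""

    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 0.005
    lr_factor: float = 0.7
    lr_patience: int = 3
    seed: int = 0
    #: return the weights of the epoch with the lowest validation loss
    #: (validation-based model selection; the test set is never consulted)
    restore_best: bool = True

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.lr_patience) <= 0:
            raise ValueError("epochs, batch_size and lr_patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")


def build_branch(spec: BranchSpec, rng: np.random.Generator,
                 input_grad: bool = False) -> nn.Sequential:
    """Feature extractor mapping (N, 64, 64, 3) to (N, feature_units)."""
    layers: list[nn.Layer] = []
    cin = spec.input_shape[2]
    first = True
    for cout in spec.block_channels:
        layers.append(nn.Conv2D(cin, cout, spec.kernel_size, rng,
                                input_grad=input_grad or not first))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool2D())
        cin = cout
        first = False
    layers.append(nn.Flatten())
    layers.append(nn.Dense(spec.flattened_units, spec.feature_units, rng))
    layers.append(nn.ReLU())
    return nn.Sequential(layers)


class FusionNet:
    """Multi-branch network: per-branch feature extractors plus a dense head.

    ``forward`` takes a list of per-branch float arrays scaled to [0, 1]
    (one array for a single-branch model is also accepted).
    """

    def __init__(self, branches: list[nn.Sequential], head: nn.Sequential,
                 n_classes: int, feature_units: int) -> None:
        self.branches = branches
        self.head = head
        self.n_classes = n_classes
        self.feature_units = feature_units

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def params(self) -> list[np.ndarray]:
        out = [p for b in self.branches for p in b.params]
        return out + self.head.params

    @property
    def grads(self) -> list[np.ndarray]:
        out = [g for b in self.branches for g in b.grads]
        return out + self.head.grads

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def _as_branch_list(self, xs) -> list[np.ndarray]:
        if isinstance(xs, np.ndarray) and xs.ndim == 4:
            xs = [xs]
        if len(xs) != self.n_branches:
            raise InputShapeError(
                f"expected {self.n_branches} branch inputs, got {len(xs)}")
        return list(xs)

    def forward(self, xs) -> np.ndarray:
        xs = self._as_branch_list(xs)
        feats = [b.forward(x) for b, x in zip(self.branches, xs)]
        fused = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        return self.head.forward(fused)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        u = self.feature_units
        for i, b in enumerate(self.branches):
            b.backward(dfused[:, i * u:(i + 1) * u])

    def predict_proba(self, xs, batch_size: int = 32) -> np.ndarray:
        xs = self._as_branch_list(xs)
        n = xs[0].shape[0]
        out = np.empty((n, self.n_classes))
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            out[sl] = nn.softmax(self.forward([x[sl] for x in xs]))
        return out


def build_fusion(fusion_spec: FusionSpec, branch_spec: BranchSpec | None = None,
                 seed: int = 0) -> FusionNet:
    """Independent (non-weight-shared) branches plus the dense fusion head."""
    branch_spec = branch_spec or BranchSpec()
    rng = np.random.default_rng(seed)
    branches = [build_branch(branch_spec, rng) for _ in range(fusion_spec.n_branches)]
    fused = fusion_spec.fused_dim(branch_spec.feature_units)
    head = nn.Sequential([
        nn.Dense(fused, fusion_spec.head_units, rng),
        nn.ReLU(),
        nn.Dense(fusion_spec.head_units, fusion_spec.n_classes, rng),
    ])
    return FusionNet(branches, head, fusion_spec.n_classes, branch_spec.feature_units)


class _Baseline1DNet:
    """Single-input 1-D mirror of the branch topology over raw segments."""

    def __init__(self, net: nn.Sequential, n_classes: int, segment_length: int) -> None:
        self.net = net
        self.n_classes = n_classes
        self.segment_length = segment_length

    @property
    def params(self) -> list[np.ndarray]:
        return self.net.params

    @property
    def grads(self) -> list[np.ndarray]:
        return self.net.grads

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x) -> np.ndarray:
        if isinstance(x, (list, tuple)):
            x = x[0]
        if x.ndim != 3 or x.shape[1] != self.segment_length or x.shape[2] != 3:
            raise InputShapeError(
                f"expected (N, {self.segment_length}, 3), got {x.shape}")
        return self.net.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        self.net.backward(dlogits)

    def predict_proba(self, x, batch_size: int = 32) -> np.ndarray:
        if isinstance(x, (list, tuple)):
            x = x[0]
        n = x.shape[0]
        out = np.empty((n, self.n_classes))
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            out[sl] = nn.softmax(self.forward(x[sl]))
        return out


def build_baseline_1d(n_classes: int, segment_length: int = 2500,
                      block_channels: tuple[int, ...] = (32, 64, 128, 128, 64),
                      kernel_size: int = 3, feature_units: int = 1024,
                      head_units: int = 256, seed: int = 0) -> _Baseline1DNet:
    """1-D convolutional baseline over raw (segment_length, 3) input.

    Pooling uses floor semantics (an odd trailing sample is dropped), so the
    2500-sample default shrinks 2500 -> 1250 -> 625 -> 312 -> 156 -> 78.
    A named error is raised if the chain would collapse below 2 samples.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    length = segment_length
    for _ in block_channels:
        if length < 2:
            raise InputShapeError(
                f"segment_length {segment_length} collapses below 2 in the "
                "downsampling chain")
        length //= 2
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    cin = 3
    first = True
    for cout in block_channels:
        layers.append(nn.Conv1D(cin, cout, kernel_size, rng, input_grad=not first))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool1D())
        cin = cout
        first = False
    layers.append(nn.Flatten())
    layers.append(nn.Dense(length * block_channels[-1], feature_units, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(feature_units, head_units, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(head_units, n_classes, rng))
    return _Baseline1DNet(nn.Sequential(layers), n_classes, segment_length)


# ---------------------------------------------------------------------------
# training

def _encode_labels(classes: np.ndarray, y) -> np.ndarray:
    """Map labels to indices in ``classes``; unknown labels raise LabelError."""
    y = np.asarray(y)
    idx = np.searchsorted(classes, y)
    capped = np.minimum(idx, len(classes) - 1)
    if np.any((idx >= len(classes)) | (classes[capped] != y)):
        raise LabelError("labels outside the training taxonomy")
    return idx


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.asarray(y)
    if y.min() < 0 or y.max() >= n_classes:
        raise LabelError(f"labels must lie in [0, {n_classes}), got range "
                         f"[{y.min()}, {y.max()}]")
    return np.eye(n_classes, dtype=np.float32)[y]


def train(model, train_inputs, y_train: np.ndarray, val_inputs, y_val: np.ndarray,
          cfg: TrainConfig | None = None) -> tuple[object, dict]:
    """Optimise the network; returns (model, history).

    ``history`` holds per-epoch lists: loss, accuracy, val_loss, val_accuracy
    and the learning rate in force during the epoch.  Deterministic for a
    fixed seed under a fixed thread configuration (numpy/BLAS floating-point
    reductions can differ across builds).
    """
    cfg = cfg or TrainConfig()
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    if y_train.size == 0 or y_val.size == 0:
        raise EmptyDatasetError("training and validation sets must be non-empty")
    onehot = _one_hot(y_train, model.n_classes)
    yv = np.asarray(y_val)
    _one_hot(yv, model.n_classes)  # label validation

    xs = train_inputs if isinstance(train_inputs, (list, tuple)) else [train_inputs]
    xs = [np.asarray(x, dtype=np.float32) for x in xs]
    n = xs[0].shape[0]

    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    sched = nn.ReduceLROnPlateau(opt, factor=cfg.lr_factor, patience=cfg.lr_patience)
    history: dict[str, list] = {k: [] for k in
                                ("loss", "accuracy", "val_loss", "val_accuracy", "lr")}
    best_val = np.inf
    best_params: list[np.ndarray] | None = None
    for _ in range(cfg.epochs):
        lr_epoch = opt.lr
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward([x[idx] for x in xs])
            loss, dlogits = nn.softmax_cross_entropy(logits, onehot[idx])
            model.backward(dlogits)
            opt.step(model.grads)
            epoch_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == y_train[idx]).sum())
        val_probs = model.predict_proba(val_inputs)
        val_loss = float(-np.log(np.clip(
            val_probs[np.arange(len(yv)), yv], 1e-12, None)).mean())
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(correct / n)
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(float((val_probs.argmax(axis=1) == yv).mean()))
        history["lr"].append(lr_epoch)
        if cfg.restore_best and val_loss < best_val:
            best_val = val_loss
            best_params = [p.copy() for p in model.params]
        sched.step(val_loss)
    if cfg.restore_best and best_params is not None:
        for p, best in zip(model.params, best_params):
            p[...] = best
    return model, history


def predict(model, inputs, batch_size: int = 32) -> np.ndarray:
    """Class-probability matrix; rows sum to 1; argmax is the top-1 label."""
    return model.predict_proba(inputs, batch_size=batch_size)


def top_k_labels(probs: np.ndarray, k: int = 3) -> np.ndarray:
    """Indices of the k most probable classes per row, most probable first.

    Argmax ties break toward the lowest class index.
    """
    probs = np.asarray(probs)
    k = min(k, probs.shape[1])
    # stable sort on -probs keeps the lowest index first among ties
    return np.argsort(-probs, axis=1, kind="stable")[:, :k]


# ---------------------------------------------------------------------------
# sklearn-style estimators

class FusionImageClassifier(BaseEstimator, ClassifierMixin):
    """Feature-fusion CNN over reconstructed image triples.

    X has shape (n_samples, n_branches, 64, 64, 3) with 8-bit pixel values;
    pixels are scaled to [0, 1] at entry.  With ``n_branches=1`` this is the
    single-reconstruction ablation model.
    """

    def __init__(self, n_branches: int = 3,
                 block_channels: tuple[int, ...] = (32, 64, 128, 128, 64),
                 kernel_size: int = 3, feature_units: int = 1024,
                 head_units: int = 256, epochs: int = 50, batch_size: int = 8,
                 learning_rate: float = 0.005, lr_factor: float = 0.7,
                 lr_patience: int = 3, seed: int = 0,
                 restore_best: bool = True) -> None:
        self.n_branches = n_branches
        self.block_channels = block_channels
        self.kernel_size = kernel_size
        self.feature_units = feature_units
        self.head_units = head_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_factor = lr_factor
        self.lr_patience = lr_patience
        self.seed = seed
        self.restore_best = restore_best

    def _branch_arrays(self, X: np.ndarray) -> list[np.ndarray]:
        X = np.asarray(X)
        if X.ndim != 5 or X.shape[1] != self.n_branches or X.shape[2:] != (64, 64, 3):
            raise InputShapeError(
                f"X must have shape (n, {self.n_branches}, 64, 64, 3), got {X.shape}")
        return [(X[:, b].astype(np.float32) / 255.0) for b in range(self.n_branches)]

    def _train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           learning_rate=self.learning_rate, lr_factor=self.lr_factor,
                           lr_patience=self.lr_patience, seed=self.seed,
                           restore_best=self.restore_best)

    def fit(self, X, y, validation_data: tuple | None = None):
        xs = self._branch_arrays(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise LabelError("need at least two classes")
        if validation_data is not None:
            Xv, yv = validation_data
            xv = self._branch_arrays(Xv)
            yv_idx = _encode_labels(self.classes_, yv)
        else:
            xv, yv_idx = xs, y_idx
        net = build_fusion(
            FusionSpec(n_classes=len(self.classes_), n_branches=self.n_branches,
                       head_units=self.head_units),
            BranchSpec(block_channels=tuple(self.block_channels),
                       kernel_size=self.kernel_size, feature_units=self.feature_units),
            seed=self.seed)
        self.net_, history = train(net, xs, y_idx, xv, yv_idx, self._train_config())
        self.history_ = history
        self.n_parameters_ = net.parameter_count()
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(self._branch_arrays(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class Baseline1DClassifier(BaseEstimator, ClassifierMixin):
    """1-D convolutional baseline over raw (n, segment_length, 3) segments.

    Raw counts are divided by a single fixed scale (the training set's pooled
    standard deviation unless ``input_scale`` is given) — one affine rescale,
    analogous to dividing image pixels by 255; no per-sample normalisation.
    """

    def __init__(self, segment_length: int = 2500,
                 block_channels: tuple[int, ...] = (32, 64, 128, 128, 64),
                 kernel_size: int = 3, feature_units: int = 1024,
                 head_units: int = 256, epochs: int = 50, batch_size: int = 8,
                 learning_rate: float = 0.005, lr_factor: float = 0.7,
                 lr_patience: int = 3, seed: int = 0,
                 input_scale: float | None = None,
                 restore_best: bool = True) -> None:
        self.segment_length = segment_length
        self.block_channels = block_channels
        self.kernel_size = kernel_size
        self.feature_units = feature_units
        self.head_units = head_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_factor = lr_factor
        self.lr_patience = lr_patience
        self.seed = seed
        self.input_scale = input_scale
        self.restore_best = restore_best

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != self.segment_length or X.shape[2] != 3:
            raise InputShapeError(
                f"X must have shape (n, {self.segment_length}, 3), got {X.shape}")
        return X

    def fit(self, X, y, validation_data: tuple | None = None):
        X = self._check_X(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise LabelError("need at least two classes")
        self.scale_ = float(self.input_scale) if self.input_scale else float(np.std(X))
        if self.scale_ <= 0:
            self.scale_ = 1.0
        if validation_data is not None:
            Xv, yv = validation_data
            xv = self._check_X(Xv) / self.scale_
            yv_idx = _encode_labels(self.classes_, yv)
        else:
            xv, yv_idx = X / self.scale_, y_idx
        net = build_baseline_1d(
            n_classes=len(self.classes_), segment_length=self.segment_length,
            block_channels=tuple(self.block_channels), kernel_size=self.kernel_size,
            feature_units=self.feature_units, head_units=self.head_units,
            seed=self.seed)
        cfg = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                          learning_rate=self.learning_rate, lr_factor=self.lr_factor,
                          lr_patience=self.lr_patience, seed=self.seed,
                          restore_best=self.restore_best)
        self.net_, self.history_ = train(net, X / self.scale_, y_idx, xv, yv_idx, cfg)
        self.n_parameters_ = net.parameter_count()
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(self._check_X(X) / self.scale_)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, estimator) -> None:
    """Weights as NPZ plus a JSON sidecar with the estimator parameters."""
    from .signal_core import savez_deterministic

    check_is_fitted(estimator, "net_")
    arrays = {f"param_{i:04d}": p for i, p in enumerate(estimator.net_.params)}
    arrays["classes"] = np.asarray(estimator.classes_, dtype=str)
    if hasattr(estimator, "scale_"):
        arrays["scale"] = np.array([estimator.scale_])
    savez_deterministic(path, **arrays)
    sidecar = {
        "estimator": type(estimator).__name__,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in estimator.get_params().items()},
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path):
    """Rebuild a fitted estimator from an NPZ checkpoint and its sidecar."""
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    params = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in sidecar["params"].items()}
    cls = {"FusionImageClassifier": FusionImageClassifier,
           "Baseline1DClassifier": Baseline1DClassifier}[sidecar["estimator"]]
    est = cls(**params)
    with np.load(path, allow_pickle=False) as data:
        classes = data["classes"]
        if cls is FusionImageClassifier:
            net = build_fusion(
                FusionSpec(n_classes=len(classes), n_branches=est.n_branches,
                           head_units=est.head_units),
                BranchSpec(block_channels=tuple(est.block_channels),
                           kernel_size=est.kernel_size,
                           feature_units=est.feature_units),
                seed=est.seed)
        else:
            net = build_baseline_1d(
                n_classes=len(classes), segment_length=est.segment_length,
                block_channels=tuple(est.block_channels),
                kernel_size=est.kernel_size, feature_units=est.feature_units,
                head_units=est.head_units, seed=est.seed)
            est.scale_ = float(data["scale"][0])
        for i, p in enumerate(net.params):
            p[...] = data[f"param_{i:04d}"]
        est.net_ = net
        est.classes_ = classes
    return est
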