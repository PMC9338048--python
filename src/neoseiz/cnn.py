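"""A small sequential convolutional binary classifier, in pure numpy.

The network mirrors a compact Keras-style architecture: three blocks of
[2-D convolution → batch normalization → ReLU → 2×2 max-pooling] over
inputs of shape (window·fs, 18, 1), a flatten, dropout, two dense layers
with an L2 weight penalty (0.001), and a single sigmoid output trained with
binary cross-entropy under SGD (learning rate 0.01, momentum 0.5, Nesterov
off, batch size 16). Pooling shrinks the short electrode axis until it is
exhausted, after which it pools over the time axis only.

Everything — forward pass, backpropagation, the optimizer — is implemented
here with vectorized numpy (im2col convolutions), which is entirely adequate
at the problem sizes this package targets and keeps training exactly
reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .dataset_store import TensorDataset
from .evaluation import EvalReport, aggregate_folds, evaluate


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyperparameters.

    Layer counts, the L2 coefficient and the optimizer settings are fixed
    defaults of the method; filter counts, kernel, pooling and dense widths
    are configuration.
    """

    conv_filters: tuple[int, ...] = (16, 32, 64)
    conv_kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    batch_norm: bool = True
    dropout: float = 0.5
    dense_units: tuple[int, ...] = (64, 32)
    l2_coeff: float = 0.001
    learning_rate: float = 0.01
    momentum: float = 0.5
    nesterov: bool = False
    batch_size: int = 16
    epochs: int = 300
    seed: int = 0
    standardize: bool = False  # optional per-channel z-score of the input

    def __post_init__(self) -> None:
        if self.l2_coeff < 0:
            raise ValueError("l2_coeff must be non-negative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be at least 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


# ---------------------------------------------------------------------------
# layers


class _Param:
    __slots__ = ("value", "grad", "l2")

    def __init__(self, value: np.ndarray, l2: float = 0.0) -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.l2 = l2


class _Layer:
    params: list[_Param] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Conv2D(_Layer):
    """Valid-padding 2-D convolution on channels-last inputs (N, H, W, C)."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 rng: np.random.Generator) -> None:
        kh, kw = kernel
        fan_in, fan_out = kh * kw * c_in, kh * kw * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.kh, self.kw = kh, kw
        self.w = _Param(rng.uniform(-limit, limit, size=(kh, kw, c_in, c_out)))
        self.b = _Param(np.zeros(c_out))
        self.params = [self.w, self.b]

    def forward(self, x, train):
        self._windows = sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        return (
            np.einsum("nhwcij,ijcf->nhwf", self._windows, self.w.value, optimize=True)
            + self.b.value
        )

    def backward(self, grad):
        self.w.grad = np.einsum(
            "nhwcij,nhwf->ijcf", self._windows, grad, optimize=True
        )
        self.b.grad = grad.sum(axis=(0, 1, 2))
        padded = np.pad(
            grad, ((0, 0), (self.kh - 1, self.kh - 1), (self.kw - 1, self.kw - 1), (0, 0))
        )
        gwin = sliding_window_view(padded, (self.kh, self.kw), axis=(1, 2))
        w_flip = self.w.value[::-1, ::-1]
        return np.einsum("nhwfij,ijcf->nhwc", gwin, w_flip, optimize=True)


class _BatchNorm(_Layer):
    """Per-channel normalization over the batch and spatial axes."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = _Param(np.ones(n_channels))
        self.beta = _Param(np.zeros(n_channels))
        self.params = [self.gamma, self.beta]
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._ivar = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean) * self._ivar
            self._m = x.size // x.shape[-1]
            return self.gamma.value * self._xhat + self.beta.value
        ivar = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma.value * (x - self.running_mean) * ivar + self.beta.value

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        self.gamma.grad = (grad * self._xhat).sum(axis=axes)
        self.beta.grad = grad.sum(axis=axes)
        g = grad * self.gamma.value
        m = self._m
        return (self._ivar / m) * (
            m * g - g.sum(axis=axes) - self._xhat * (g * self._xhat).sum(axis=axes)
        )


class _ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class _MaxPool(_Layer):
    """Max-pooling that degrades gracefully on short axes: an axis shorter
    than the pool size is left unpooled. Trailing remainders are dropped."""

    def __init__(self, pool: tuple[int, int]) -> None:
        self.pool = pool

    def forward(self, x, train):
        n, h, w, c = x.shape
        ph = self.pool[0] if h >= self.pool[0] else 1
        pw = self.pool[1] if w >= self.pool[1] else 1
        h2, w2 = h // ph, w // pw
        self._in_shape, self._ph, self._pw = x.shape, ph, pw
        xr = x[:, : h2 * ph, : w2 * pw].reshape(n, h2, ph, w2, pw, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        return out

    def backward(self, grad):
        n, h, w, c = self._in_shape
        ph, pw = self._ph, self._pw
        h2, w2 = h // ph, w // pw
        dx = np.zeros(self._in_shape)
        dx[:, : h2 * ph, : w2 * pw] = (
            self._mask * grad[:, :, None, :, None, :]
        ).reshape(n, h2 * ph, w2 * pw, c)
        return dx


class _Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class _Dropout(_Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, l2: float, rng: np.random.Generator) -> None:
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = _Param(rng.uniform(-limit, limit, size=(n_in, n_out)), l2=l2)
        self.b = _Param(np.zeros(n_out))
        self.params = [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        return grad @ self.w.value.T


# ---------------------------------------------------------------------------
# model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SequentialCNN:
    """The convolutional seizure/non-seizure classifier.

    Input shape is (window·fs, 18, 1); the single output unit, passed
    through a sigmoid, is the seizure probability of the chunk.
    """

    def __init__(self, cfg: ModelConfig, input_shape: tuple[int, int, int]) -> None:
        if len(input_shape) != 3:
            raise ValueError("input_shape must be (time, channels, 1)")
        self.cfg = cfg
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(cfg.seed)
        h, w, c = input_shape
        kh, kw = cfg.conv_kernel
        layers: list[_Layer] = []
        for f in cfg.conv_filters:
            if h < kh or w < kw:
                raise ValueError(
                    f"feature map {h}x{w} too small for a {kh}x{kw} convolution; "
                    "use a larger window"
                )
            layers.append(_Conv2D(c, f, cfg.conv_kernel, rng))
            h, w, c = h - kh + 1, w - kw + 1, f
            if cfg.batch_norm:
                layers.append(_BatchNorm(c))
            layers.append(_ReLU())
            layers.append(_MaxPool(cfg.pool))
            h = h // cfg.pool[0] if h >= cfg.pool[0] else h
            w = w // cfg.pool[1] if w >= cfg.pool[1] else w
            if h < 1 or w < 1:
                raise ValueError(
                    "pooling pyramid exhausted the feature map; use a larger window"
                )
        layers.append(_Flatten())
        n_feat = h * w * c
        layers.append(_Dropout(cfg.dropout, rng))
        for units in cfg.dense_units:
            layers.append(_Dense(n_feat, units, cfg.l2_coeff, rng))
            layers.append(_ReLU())
            n_feat = units
        layers.append(_Dense(n_feat, 1, cfg.l2_coeff, rng))
        self.layers = layers

    # -- parameters ---------------------------------------------------------

    @property
    def parameters(self) -> list[_Param]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def param_count(self) -> int:
        return sum(p.value.size for p in self.parameters)

    def get_weights(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.parameters]
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                state.extend([layer.running_mean.copy(), layer.running_var.copy()])
        return state

    def set_weights(self, state: Sequence[np.ndarray]) -> None:
        state = list(state)
        n = len(self.parameters)
        for p, v in zip(self.parameters, state[:n]):
            p.value = v.copy()
        extra = iter(state[n:])
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                layer.running_mean = next(extra).copy()
                layer.running_var = next(extra).copy()

    # -- passes -------------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return out[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        for p in self.parameters:
            if p.l2:
                p.grad = p.grad + 2.0 * p.l2 * p.value

    def l2_penalty(self) -> float:
        return float(sum(p.l2 * (p.value ** 2).sum() for p in self.parameters if p.l2))

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = np.empty(len(x))
        for i in range(0, len(x), batch_size):
            out[i : i + batch_size] = _sigmoid(self.forward(x[i : i + batch_size], train=False))
        return out


def build_model(cfg: ModelConfig, input_shape: tuple[int, int, int]) -> SequentialCNN:
    """Construct the (untrained) classifier for the given input shape."""
    return SequentialCNN(cfg, input_shape)


# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitPlan:
    """A held-out test subset (20%) plus K stratified folds over the rest."""

    test_idx: np.ndarray
    folds: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        trainval = np.concatenate(self.folds) if self.folds else np.array([], int)
        if np.intersect1d(self.test_idx, trainval).size:
            raise ValueError("test indices leak into the train/validation folds")
        if len(np.unique(trainval)) != len(trainval):
            raise ValueError("folds overlap")
        sizes = [len(f) for f in self.folds]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes differ by more than 1: {sizes}")

    @property
    def k(self) -> int:
        return len(self.folds)

    @property
    def trainval_idx(self) -> np.ndarray:
        return np.concatenate(self.folds)

    def fold_split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train indices over K−1 folds, validation indices of ``fold``)."""
        train = np.concatenate([f for i, f in enumerate(self.folds) if i != fold])
        return train, self.folds[fold]


def make_split(
    labels: np.ndarray, test_frac: float = 0.2, k: int = 5, seed: int = 0
) -> SplitPlan:
    """Label-stratified 80/20 split plus K near-equal stratified folds."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < 2 * k:
        raise ValueError(f"{n} samples are too few for {k} folds")
    n_test = int(round(n * test_frac))
    if n_test == 0:
        trainval_idx = np.arange(n)
        test_idx = np.array([], dtype=int)
    else:
        sss = StratifiedShuffleSplit(n_splits=1, test_size=n_test, random_state=seed)
        trainval_idx, test_idx = next(sss.split(np.zeros(n), labels))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        trainval_idx[val]
        for _, val in skf.split(np.zeros(len(trainval_idx)), labels[trainval_idx])
    ]
    return SplitPlan(test_idx=test_idx, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# training


@dataclass
class FoldHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_acc: float = -np.inf


@dataclass
class TrainResult:
    """Per-fold histories, best checkpoints and test-set evaluations."""

    histories: list[FoldHistory]
    fold_reports: list[EvalReport]
    mean_report: EvalReport
    checkpoints: list[list[np.ndarray]]

    @property
    def mean_test_accuracy(self) -> float:
        return self.mean_report.accuracy

    def save_checkpoints(self, directory: str | Path, dataset_name: str) -> list[Path]:
        """Write ``best_model_<dataset>_fold_<k>.npz`` weight archives."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for fold, weights in enumerate(self.checkpoints):
            path = directory / f"best_model_{dataset_name}_fold_{fold}.npz"
            np.savez(path, **{f"arr_{i}": w for i, w in enumerate(weights)})
            paths.append(path)
        return paths

    def histories_frame(self):
        import pandas as pd

        rows = []
        for fold, h in enumerate(self.histories):
            for epoch in range(len(h.train_loss)):
                rows.append(
                    {
                        "fold": fold,
                        "epoch": epoch,
                        "train_loss": h.train_loss[epoch],
                        "train_acc": h.train_acc[epoch],
                        "val_loss": h.val_loss[epoch],
                        "val_acc": h.val_acc[epoch],
                    }
                )
        return pd.DataFrame(rows)


def _bce_from_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy and its logit gradient."""
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    grad = (_sigmoid(logits) - y) / len(y)
    return loss, grad


def _evaluate_loss(model: SequentialCNN, x: np.ndarray, y: np.ndarray,
                   batch_size: int = 256) -> tuple[float, float]:
    total, correct = 0.0, 0
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i : i + batch_size], train=False)
        yb = y[i : i + batch_size]
        total += float(np.sum(np.logaddexp(0.0, logits) - yb * logits))
        correct += int(np.sum((logits > 0.0) == (yb > 0.5)))
    return total / len(y) + model.l2_penalty(), correct / len(y)


def fit(
    model: SequentialCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: ModelConfig,
    shuffle_seed: int = 0,
) -> FoldHistory:
    """Minibatch SGD with momentum; checkpoints the best-validation weights.

    The returned history carries per-epoch training/validation loss and
    accuracy; on exit the model holds its *best* (not last) weights.
    """
    rng = np.random.default_rng(shuffle_seed)
    velocities = [np.zeros_like(p.value) for p in model.parameters]
    history = FoldHistory()
    best_weights = model.get_weights()
    n = len(x_train)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = _bce_from_logits(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {i // cfg.batch_size}"
                )
            model.backward(dlogits)
            for p, v in zip(model.parameters, velocities):
                v *= cfg.momentum
                v -= cfg.learning_rate * p.grad
                p.value = p.value + (cfg.momentum * v - cfg.learning_rate * p.grad
                                     if cfg.nesterov else v)
            epoch_loss += loss * len(idx)
            epoch_correct += int(np.sum((logits > 0.0) == (yb > 0.5)))
        history.train_loss.append(epoch_loss / n + model.l2_penalty())
        history.train_acc.append(epoch_correct / n)
        val_loss, val_acc = _evaluate_loss(model, x_val, y_val)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        if val_acc > history.best_val_acc:
            history.best_val_acc = val_acc
            history.best_epoch = epoch
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return history


def dataset_inputs(ds: TensorDataset, standardize: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Tensor dataset → network inputs (n, time, 18, 1) and float labels."""
    x = np.asarray(ds.data, dtype=np.float64)[..., None]
    if standardize:
        mean = x.mean(axis=(0, 1), keepdims=True)
        std = x.std(axis=(0, 1), keepdims=True)
        std[std == 0] = 1.0
        x = (x - mean) / std
    return x, ds.labels.astype(np.float64)


def train_kfold(
    ds: TensorDataset,
    plan: SplitPlan,
    cfg: ModelConfig,
    complete: bool = True,
) -> TrainResult:
    """Train one model per fold and evaluate each on the held-out test set.

    With ``complete=False`` only fold 0 is trained — five times faster but
    the resulting average rests on a single model. The final score is the
    mean of the per-fold test evaluations.
    """
    x, y = dataset_inputs(ds, standardize=cfg.standardize)
    if len(x) != len(np.concatenate([plan.test_idx, plan.trainval_idx])):
        raise ValueError("split plan size does not match the dataset")
    histories, reports, checkpoints = [], [], []
    x_test, y_test = x[plan.test_idx], y[plan.test_idx]
    n_folds = plan.k if complete else 1
    for fold in range(n_folds):
        train_idx, val_idx = plan.fold_split(fold)
        model = build_model(
            replace(cfg, seed=cfg.seed + fold),
            input_shape=(x.shape[1], x.shape[2], 1),
        )
        history = fit(
            model, x[train_idx], y[train_idx], x[val_idx], y[val_idx], cfg,
            shuffle_seed=cfg.seed + 1000 + fold,
        )
        scores = model.predict_proba(x_test)
        reports.append(evaluate(scores, y_test.astype(int)))
        histories.append(history)
        checkpoints.append(model.get_weights())
    return TrainResult(
        histories=histories,
        fold_reports=reports,
        mean_report=aggregate_folds(reports),
        checkpoints=checkpoints,
    )
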