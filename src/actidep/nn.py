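"""A small 2D convolutional classifier for 30x48 actigraphy images.

The architecture is fixed by design: three convolution blocks of 48 filters
each (conv -> ReLU -> 3x3 max-pool with stride 2 and ceil rounding ->
dropout), then fully connected layers 900 -> 300 -> 100 -> 2 with ReLU and
dropout after the first three and a sigmoid head trained with binary
cross-entropy on one-hot targets.

Two architecture modes are provided.  The default ``reconstructed`` mode uses
a 5x5 valid first kernel and 3x3 valid kernels after, with valid-mode pools;
this is the unique configuration whose feature maps are 26x44, 13x22, 11x20,
5x10, 3x8 and finally 1x4 (x48 channels, flatten 192) before the 900-unit
dense layer.  The ``literal`` mode keeps every kernel 3x3 with padding 1 and
padded pools, producing larger maps; both modes are selectable because the
correct reading of the published layer table is ambiguous.

Layers are implemented directly in NumPy (float64): convolution as an
im2col matrix product (cross-correlation, the standard framework
convention), pooling with -inf edge padding so ceil-mode windows clip
cleanly, inverted dropout, and Adam updates.  ``conv2d_reference`` is a
deliberately naive double-sum *convolution* (kernel flipped relative to
cross-correlation) kept as an independent numerical oracle for the
vectorized layer.

All randomness (weight init, shuffling, dropout) flows from explicit seeds,
so a fixed seed reproduces training bit for bit on a fixed thread count.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

INPUT_SHAPE = (30, 48)

# predict() warns if inputs look like raw counts rather than z-scores.
_RAW_INPUT_THRESHOLD = 50.0


class ArchitectureError(ValueError):
    """The requested layer stack collapses below a 1x1 feature map."""


# ---------------------------------------------------------------------------
# Elementary operations and the reference convolution oracle
# ---------------------------------------------------------------------------


def relu(x):
    """Rectified linear unit y = max(0, x), elementwise."""
    return np.maximum(0, x)


def conv2d_reference(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Naive valid-mode 2-D convolution by the literal double sum.

    ``out[t, j] = sum_m sum_n x[m, n] * w[t - m, j - n]`` over all index
    pairs where ``w`` is defined — true convolution, i.e. the kernel is
    flipped relative to the cross-correlation used by conv layers.  Used as
    a slow independent oracle; O(H*W*kh*kw) per output pixel on purpose.
    """
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    H, W = x.shape
    kh, kw = w.shape
    if kh > H or kw > W:
        raise ValueError(f"kernel {w.shape} larger than input {x.shape}")
    out = np.zeros((H - kh + 1, W - kw + 1))
    for t in range(kh - 1, H):
        for j in range(kw - 1, W):
            acc = 0.0
            for m in range(H):
                for n in range(W):
                    tm, jn = t - m, j - n
                    if 0 <= tm < kh and 0 <= jn < kw:
                        acc += x[m, n] * w[tm, jn]
            out[t - kh + 1, j - kw + 1] = acc
    return out


def _pool_out_len(size: int, k: int, stride: int, pad: int, ceil_mode: bool) -> int:
    span = size + 2 * pad - k
    n = (math.ceil(span / stride) if ceil_mode else span // stride) + 1
    # a ceil-mode window may not start beyond the (padded) input's real extent
    while n > 1 and (n - 1) * stride >= size + pad:
        n -= 1
    return n


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Conv2D:
    """Cross-correlation layer with ``filters`` output channels, valid mode
    plus optional symmetric zero padding."""

    def __init__(self, in_channels: int, filters: int, kernel: int, padding: int = 0):
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        self.padding = padding
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def init_params(self, rng: np.random.Generator) -> None:
        fan_in = self.in_channels * self.kernel * self.kernel
        self.params["W"] = rng.normal(
            0.0, math.sqrt(2.0 / fan_in), (self.filters, fan_in)
        )
        self.params["b"] = np.zeros(self.filters)

    def out_shape(self, c: int, h: int, w: int) -> tuple[int, int, int]:
        h2 = h + 2 * self.padding - self.kernel + 1
        w2 = w + 2 * self.padding - self.kernel + 1
        if h2 < 1 or w2 < 1:
            raise ArchitectureError(
                f"conv kernel {self.kernel} collapses {h}x{w} to {h2}x{w2}"
            )
        return self.filters, h2, w2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.padding:
            x = np.pad(
                x, ((0, 0), (0, 0), (self.padding,) * 2, (self.padding,) * 2)
            )
        k = self.kernel
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        # (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(
            x.shape[0], win.shape[2], win.shape[3], -1
        )
        self._cols = cols
        self._x_shape = x.shape
        out = cols @ self.params["W"].T + self.params["b"]
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, F, Ho, Wo = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, F)
        cols_flat = self._cols.reshape(-1, self._cols.shape[-1])
        self.grads["W"] = dflat.T @ cols_flat
        self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"]).reshape(N, Ho, Wo, self.in_channels,
                                                   self.kernel, self.kernel)
        dx = np.zeros(self._x_shape)
        for a in range(self.kernel):
            for b in range(self.kernel):
                dx[:, :, a : a + Ho, b : b + Wo] += dcols[:, :, :, :, a, b].transpose(
                    0, 3, 1, 2
                )
        if self.padding:
            p = self.padding
            dx = dx[:, :, p:-p, p:-p]
        del self._cols
        return dx


class ReLULayer:
    params: dict = {}
    grads: dict = {}

    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool2D:
    """Max pooling with ceil-mode output rounding; clipped edge windows are
    realised by padding with -inf so they never win the max."""

    params: dict = {}
    grads: dict = {}

    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 0):
        self.kernel = kernel
        self.stride = stride
        self.padding = padding

    def out_shape(self, c: int, h: int, w: int) -> tuple[int, int, int]:
        h2 = _pool_out_len(h, self.kernel, self.stride, self.padding, ceil_mode=True)
        w2 = _pool_out_len(w, self.kernel, self.stride, self.padding, ceil_mode=True)
        if h2 < 1 or w2 < 1:
            raise ArchitectureError(f"pool collapses {h}x{w}")
        return c, h2, w2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        _, Ho, Wo = self.out_shape(C, H, W)
        k, s, p = self.kernel, self.stride, self.padding
        need_h = (Ho - 1) * s + k
        need_w = (Wo - 1) * s + k
        xp = np.full((N, C, need_h, need_w), -np.inf)
        xp[:, :, p : p + H, p : p + W] = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s][:, :, :Ho, :Wo].reshape(N, C, Ho, Wo, k * k)
        self._argmax = win.argmax(axis=-1)
        self._x_shape = (N, C, H, W)
        self._padded_shape = (N, C, need_h, need_w)
        return win.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, Ho, Wo = dout.shape
        k, s, p = self.kernel, self.stride, self.padding
        dxp = np.zeros(self._padded_shape)
        for flat in range(k * k):
            mask = self._argmax == flat
            if not mask.any():
                continue
            a, b = divmod(flat, k)
            # fixed offset (a, b): stride-s slices hit distinct cells
            dxp[:, :, a : a + Ho * s : s, b : b + Wo * s : s] += dout * mask
        H, W = self._x_shape[2], self._x_shape[3]
        return dxp[:, :, p : p + H, p : p + W]


class Dropout:
    """Inverted dropout; identity at inference."""

    params: dict = {}
    grads: dict = {}

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x, train: bool = False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten:
    params: dict = {}
    grads: dict = {}

    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, in_features: int, out_features: int, final: bool = False):
        self.in_features = in_features
        self.out_features = out_features
        self.final = final
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def init_params(self, rng: np.random.Generator) -> None:
        scale = math.sqrt((1.0 if self.final else 2.0) / self.in_features)
        self.params["W"] = rng.normal(0.0, scale, (self.in_features, self.out_features))
        self.params["b"] = np.zeros(self.out_features)

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


# ---------------------------------------------------------------------------
# Architecture specification and model assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of the classifier stack.

    ``mode="reconstructed"`` (default) reproduces the published feature-map
    sizes exactly; ``mode="literal"`` keeps every kernel 3x3 with padding 1.
    """

    mode: Literal["reconstructed", "literal"] = "reconstructed"
    filters: int = 48
    fc_sizes: tuple[int, ...] = (900, 300, 100, 2)
    dropout_p: float = 0.5
    input_shape: tuple[int, int] = INPUT_SHAPE

    @property
    def conv_kernels(self) -> tuple[int, int, int]:
        return (5, 3, 3) if self.mode == "reconstructed" else (3, 3, 3)

    @property
    def conv_padding(self) -> int:
        return 0 if self.mode == "reconstructed" else 1

    @property
    def pool_padding(self) -> int:
        return 0 if self.mode == "reconstructed" else 1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainingConfig:
    epochs: int = 14
    batch_size: int = 32
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch train/validation loss and accuracy."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["epoch,train_loss,train_acc,val_loss,val_acc"]
        for i in range(len(self)):
            lines.append(
                f"{i + 1},{self.train_loss[i]!r},{self.train_acc[i]!r},"
                f"{self.val_loss[i]!r},{self.val_acc[i]!r}"
            )
        path.write_text("\n".join(lines) + "\n")
        return path


class Model:
    """A plain sequential stack with explicit forward/backward passes."""

    def __init__(self, layers: list, spec: ArchitectureSpec):
        self.layers = layers
        self.spec = spec

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"layer{li}.{name}", layer

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def layer_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        """Name and output shape (per sample, channels-last for conv stages)
        of every layer, computed analytically from the spec."""
        h, w = self.spec.input_shape
        c = 1
        shapes: list[tuple[str, tuple[int, ...]]] = [("input", (h, w, c))]
        for layer in self.layers:
            if isinstance(layer, (Conv2D, MaxPool2D)):
                c, h, w = layer.out_shape(c, h, w)
                name = "conv" if isinstance(layer, Conv2D) else "pool"
                shapes.append((name, (h, w, c)))
            elif isinstance(layer, Flatten):
                shapes.append(("flatten", (h * w * c,)))
            elif isinstance(layer, Dense):
                shapes.append(("fc", (layer.out_features,)))
        return shapes


def build_model(spec: ArchitectureSpec = ArchitectureSpec(), seed: int = 0) -> Model:
    """Assemble and initialise the classifier; weight init is seeded.

    Raises :class:`ArchitectureError` if the requested stack collapses a
    feature map below 1x1.
    """
    rng = np.random.default_rng(seed)
    layers: list = []
    c, h, w = 1, *spec.input_shape
    for kernel in spec.conv_kernels:
        conv = Conv2D(c, spec.filters, kernel, padding=spec.conv_padding)
        c, h, w = conv.out_shape(c, h, w)
        pool = MaxPool2D(3, 2, padding=spec.pool_padding)
        c, h, w = pool.out_shape(c, h, w)
        layers += [conv, ReLULayer(), pool, Dropout(spec.dropout_p)]
    layers.append(Flatten())
    in_features = c * h * w
    for i, width in enumerate(spec.fc_sizes):
        is_final = i == len(spec.fc_sizes) - 1
        layers.append(Dense(in_features, width, final=is_final))
        if not is_final:
            layers += [ReLULayer(), Dropout(spec.dropout_p)]
        in_features = width
    for layer in layers:
        if hasattr(layer, "init_params"):
            layer.init_params(rng)
    return Model(layers, spec)


# ---------------------------------------------------------------------------
# Loss, optimizer, training loop
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over samples and the two sigmoid output
    units, with the gradient w.r.t. the logits."""
    p = _sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(onehot * np.log(p + eps) + (1 - onehot) * np.log(1 - p + eps))
    dlogits = (p - onehot) / onehot.size
    return float(loss), dlogits


def one_hot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    return np.eye(n_classes)[np.asarray(y, dtype=np.int64)]


class Adam:
    def __init__(self, model: Model, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.model.layers):
            for name, grad in layer.grads.items():
                key = f"{li}.{name}"
                if key not in self.m:
                    self.m[key] = np.zeros_like(grad)
                    self.v[key] = np.zeros_like(grad)
                self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * grad
                self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * grad**2
                mhat = self.m[key] / (1 - self.beta1**self.t)
                vhat = self.v[key] / (1 - self.beta2**self.t)
                layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def evaluate(model: Model, images: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(BCE loss, accuracy) in inference mode."""
    logits = model.forward(images, train=False)
    loss, _ = bce_with_logits(logits, one_hot(y))
    acc = float(np.mean(logits.argmax(axis=1) == y))
    return loss, acc


def train(
    model: Model,
    train_set: tuple[np.ndarray, np.ndarray],
    validation_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainingConfig = TrainingConfig(),
) -> TrainingHistory:
    """Mini-batch Adam training; records per-epoch train/validation metrics.

    Train metrics are running averages over the epoch's batches (pre-update),
    validation metrics are full inference-mode passes after each epoch.
    Deterministic for a fixed seed and thread count.
    """
    Xtr, ytr = train_set
    if len(ytr) == 0:
        raise ValueError("empty training set")
    if cfg.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    rng = np.random.default_rng(cfg.seed)
    model.set_dropout_rng(np.random.default_rng(rng.integers(2**31)))
    optimizer = Adam(model, lr=cfg.learning_rate)
    history = TrainingHistory()
    n = len(ytr)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = bce_with_logits(logits, one_hot(yb))
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss * len(idx))
            correct += int(np.sum(logits.argmax(axis=1) == yb))
        history.train_loss.append(float(np.sum(losses) / n))
        history.train_acc.append(correct / n)
        val_loss, val_acc = evaluate(model, *validation_set)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
    return history


def predict(model: Model, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-image sigmoid scores (N, 2) and hard argmax labels (N,).

    The class-1 score column is the ROC score.  Dropout is off, so repeated
    calls on the same input are identical.  Raw-count-looking input (values
    far outside the z-score range) triggers a distribution-shift warning.
    """
    images = np.asarray(images, dtype=np.float64)
    if np.abs(images).max(initial=0.0) > _RAW_INPUT_THRESHOLD:
        warnings.warn(
            "input values look like raw activity counts, not z-scores; "
            "did you forget to apply the fitted normalizer?",
            UserWarning,
            stacklevel=2,
        )
    scores = _sigmoid(model.forward(images, train=False))
    return scores, scores.argmax(axis=1)


def overfitting_check(
    history: TrainingHistory, tol: float = 0.05, margin: float = 0.25
) -> str:
    """Classify the final epoch's validation-vs-training loss gap.

    Validation loss similar to or slightly above training loss is the
    acceptable fit pattern; clearly below means underfitting (train longer),
    clearly above means overfitting.
    """
    if len(history) == 0:
        raise ValueError("empty history")
    gap = history.val_loss[-1] - history.train_loss[-1]
    if gap < -tol:
        return "underfit"
    if gap <= margin:
        return "acceptable"
    return "overfit"


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(
    model: Model,
    path: str | Path,
    cfg: TrainingConfig | None = None,
    history: TrainingHistory | None = None,
) -> Path:
    """Write parameters (.npz) plus a JSON sidecar with spec/config/history."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for li, layer in enumerate(model.layers):
        for name, value in layer.params.items():
            arrays[f"{li}.{name}"] = value
    np.savez(path, **arrays)
    sidecar = {
        "spec": model.spec.to_dict(),
        "config": asdict(cfg) if cfg else None,
        "history": history.to_dict() if history else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path: str | Path) -> tuple[Model, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec_dict = dict(sidecar["spec"])
    spec_dict["fc_sizes"] = tuple(spec_dict["fc_sizes"])
    spec_dict["input_shape"] = tuple(spec_dict["input_shape"])
    model = build_model(ArchitectureSpec(**spec_dict), seed=0)
    with np.load(path) as data:
        for key in data.files:
            li, name = key.split(".", 1)
            model.layers[int(li)].params[name] = data[key]
    return model, sidecar
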