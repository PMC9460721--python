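"""Multi-level-feature CNN: a VGG16-style backbone whose five block
outputs are each projected by a 1x1 convolution, brought to a common
spatial size (transposed convolution upward, stride-2 projection downward
for the first block), concatenated along channels and classified by a
two-layer fully-connected head with dropout and softmax.

Implemented directly on NumPy (forward and backward passes) so it runs in
a plain scientific-Python environment; training is CPU-scale and fully
deterministic for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .evaluation import ConfusionMatrix, confusion
from .segmentation import Label
from .tf_image import TFImage

__all__ = [
    "ModelConfig",
    "MLFCNN",
    "TrainedModel",
    "FoldResult",
    "build_model",
    "train_fold",
    "predict",
    "cross_validate",
    "images_to_arrays",
]

_DTYPE = np.float32


@dataclass(frozen=True)
class ModelConfig:
    input_shape: tuple[int, int, int] = (128, 128, 18)
    block_convs: tuple[int, ...] = (2, 2, 3, 2, 2)
    block_widths: tuple[int, ...] = (64, 128, 256, 512, 512)
    projection_channels: int = 64
    fusion_size: int = 32
    fc_sizes: tuple[int, int] = (256, 64)
    dropout_rates: tuple[float, float] = (0.5, 0.5)
    n_classes: int = 2
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        h, w, _ = self.input_shape
        if len(self.block_convs) != 5 or len(self.block_widths) != 5:
            raise ValueError("exactly five convolutional blocks are required")
        if h % 32 != 0 or w % 32 != 0:
            raise ValueError("input spatial size must be divisible by 2**5")
        if h != w:
            raise ValueError("square inputs only")
        for k in range(5):
            size = h // 2 ** (k + 1)
            if size >= self.fusion_size:
                if size % self.fusion_size != 0:
                    raise ValueError(
                        f"block {k + 1} size {size} not an integer multiple of "
                        f"fusion size {self.fusion_size}"
                    )
            elif self.fusion_size % size != 0:
                raise ValueError(
                    f"fusion size {self.fusion_size} not an integer multiple of "
                    f"block {k + 1} size {size}"
                )
        if self.fusion_size > h // 2 or h // 2 // self.fusion_size > 2:
            raise ValueError("fusion size must be the size of block 1 or 2")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs/batch size")


# ---------------------------------------------------------------------------
# layers (NHWC, float32)


class _Conv:
    """k x k convolution, stride 1 'same' padding for k > 1; 1 x 1
    convolutions additionally support stride 2 (used to downsample the
    first block to the fusion size)."""

    def __init__(self, cin, cout, k, stride, rng, input_layer=False):
        if k > 1 and stride != 1:
            raise ValueError("strided convolution only supported for 1x1 kernels")
        self.k, self.stride = k, stride
        self.input_layer = input_layer  # skip the (unused) input gradient
        std = math.sqrt(2.0 / (k * k * cin))
        self.w = rng.normal(0.0, std, size=(k, k, cin, cout)).astype(_DTYPE)
        self.b = np.zeros(cout, dtype=_DTYPE)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        k, s = self.k, self.stride
        if k == 1:
            self._x = x[:, ::s, ::s, :]
            out = self._x @ self.w[0, 0] + self.b
            return out
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        b_, h, w_, _ = x.shape
        out = np.broadcast_to(self.b, (b_, h, w_, self.w.shape[3])).copy()
        for di in range(k):
            for dj in range(k):
                out += xp[:, di : di + h, dj : dj + w_, :] @ self.w[di, dj]
        return out

    def backward(self, grad):
        k, s = self.k, self.stride
        self.gb = grad.sum(axis=(0, 1, 2))
        if k == 1:
            x = self._x
            self.gw = np.zeros_like(self.w)
            self.gw[0, 0] = x.reshape(-1, x.shape[3]).T @ grad.reshape(-1, grad.shape[3])
            gx_small = grad @ self.w[0, 0].T
            if s == 1:
                return gx_small
            b_, h, w_, c = x.shape
            gx = np.zeros((b_, h * s, w_ * s, c), dtype=_DTYPE)
            gx[:, ::s, ::s, :] = gx_small
            return gx
        xp = self._xp
        b_, hp, wp, _ = xp.shape
        h, w_ = grad.shape[1:3]
        gflat = grad.reshape(-1, grad.shape[3])
        self.gw = np.empty_like(self.w)
        gxp = None if self.input_layer else np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                sl = xp[:, di : di + h, dj : dj + w_, :]
                self.gw[di, dj] = sl.reshape(-1, sl.shape[3]).T @ gflat
                if gxp is not None:
                    gxp[:, di : di + h, dj : dj + w_, :] += grad @ self.w[di, dj].T
        if gxp is None:
            return None
        p = k // 2
        return gxp[:, p : hp - p, p : wp - p, :]

    def grads(self):
        return [self.gw, self.gb]


class _ReLU:
    def params(self):
        return []

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask

    def grads(self):
        return []


class _MaxPool2:
    def params(self):
        return []

    def forward(self, x, train=False):
        b, h, w, c = x.shape
        xr = (
            x.reshape(b, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h // 2, w // 2, 4, c)
        )
        self._idx = xr.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, grad):
        b, h, w, c = self._shape
        gxr = np.zeros((b, h // 2, w // 2, 4, c), dtype=grad.dtype)
        np.put_along_axis(gxr, self._idx[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        return (
            gxr.reshape(b, h // 2, w // 2, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h, w, c)
        )

    def grads(self):
        return []


class _ConvTranspose:
    """Transposed convolution with kernel size equal to the integer
    upsampling factor (non-overlapping output blocks)."""

    def __init__(self, cin, cout, factor, rng):
        std = math.sqrt(2.0 / cin)
        self.f = factor
        self.w = rng.normal(0.0, std, size=(cin, factor, factor, cout)).astype(_DTYPE)
        self.b = np.zeros(cout, dtype=_DTYPE)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        b, h, w_, _ = x.shape
        f = self.f
        y = np.einsum("bhwc,cijo->bhiwjo", x, self.w, optimize=True)
        return y.reshape(b, h * f, w_ * f, self.w.shape[3]) + self.b

    def backward(self, grad):
        b, hf, wf, o = grad.shape
        f = self.f
        g6 = grad.reshape(b, hf // f, f, wf // f, f, o)
        self.gb = grad.sum(axis=(0, 1, 2))
        self.gw = np.einsum("bhwc,bhiwjo->cijo", self._x, g6, optimize=True)
        return np.einsum("bhiwjo,cijo->bhwc", g6, self.w, optimize=True)

    def grads(self):
        return [self.gw, self.gb]


class _Identity:
    def params(self):
        return []

    def forward(self, x, train=False):
        return x

    def backward(self, grad):
        return grad

    def grads(self):
        return []


class _Dense:
    def __init__(self, nin, nout, rng):
        std = math.sqrt(2.0 / nin)
        self.w = rng.normal(0.0, std, size=(nin, nout)).astype(_DTYPE)
        self.b = np.zeros(nout, dtype=_DTYPE)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    def grads(self):
        return [self.gw, self.gb]


class _Dropout:
    """Inverted dropout; active only during training passes."""

    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def params(self):
        return []

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_DTYPE) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def grads(self):
        return []


# ---------------------------------------------------------------------------
# model


class MLFCNN:
    """Layer graph per the architecture contract: five conv blocks, per-
    block 1x1 projections, fusion at a common spatial size, concatenation,
    FC/dropout/softmax head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        init_rng, self.dropout_rng = (np.random.default_rng(s) for s in ss.spawn(2))

        h, w, cin = config.input_shape
        self.blocks: list[list] = []
        c_prev = cin
        first = True
        for n_convs, width in zip(config.block_convs, config.block_widths):
            layers: list = []
            for _ in range(n_convs):
                layers.append(_Conv(c_prev, width, 3, 1, init_rng, input_layer=first))
                first = False
                layers.append(_ReLU())
                c_prev = width
            layers.append(_MaxPool2())
            self.blocks.append(layers)

        self.projections: list[_Conv] = []
        self.upsamplers: list = []
        size = h
        self.fused_channels = 5 * config.projection_channels
        for k, width in enumerate(config.block_widths):
            size //= 2
            if size > config.fusion_size:
                stride = size // config.fusion_size  # only 2 permitted by config
                self.projections.append(
                    _Conv(width, config.projection_channels, 1, stride, init_rng)
                )
                self.upsamplers.append(_Identity())
            else:
                self.projections.append(
                    _Conv(width, config.projection_channels, 1, 1, init_rng)
                )
                factor = config.fusion_size // size
                self.upsamplers.append(
                    _Identity()
                    if factor == 1
                    else _ConvTranspose(
                        config.projection_channels,
                        config.projection_channels,
                        factor,
                        init_rng,
                    )
                )

        flat = config.fusion_size * config.fusion_size * self.fused_channels
        self.head: list = [
            _Dense(flat, config.fc_sizes[0], init_rng),
            _ReLU(),
            _Dropout(config.dropout_rates[0], self.dropout_rng),
            _Dense(config.fc_sizes[0], config.fc_sizes[1], init_rng),
            _ReLU(),
            _Dropout(config.dropout_rates[1], self.dropout_rng),
            _Dense(config.fc_sizes[1], config.n_classes, init_rng),
        ]

    # -- plumbing ----------------------------------------------------------

    def _layers(self):
        for block in self.blocks:
            yield from block
        yield from self.projections
        yield from self.upsamplers
        yield from self.head

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def gradients(self):
        out = []
        for layer in self._layers():
            out.extend(layer.grads())
        return out

    def count_params(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward ------------------------------------------------

    def fusion_maps(self, x: np.ndarray, train: bool = False) -> list[np.ndarray]:
        """The five projected/resized feature maps (identical spatial dims)."""
        maps = []
        out = x
        for block, proj, up in zip(self.blocks, self.projections, self.upsamplers):
            for layer in block:
                out = layer.forward(out, train)
            maps.append(up.forward(proj.forward(out, train), train))
        return maps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities (softmax), shape (batch, n_classes)."""
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        if x.shape[1:] != self.config.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match configured "
                f"{self.config.input_shape}"
            )
        out = x
        maps = []
        for block, proj, up in zip(self.blocks, self.projections, self.upsamplers):
            for layer in block:
                out = layer.forward(out, train)
            maps.append(up.forward(proj.forward(out, train), train))
        fused = np.concatenate(maps, axis=-1)
        self._fused_shape = fused.shape
        z = fused.reshape(fused.shape[0], -1)
        for layer in self.head:
            z = layer.forward(z, train)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._probs = e / e.sum(axis=1, keepdims=True)
        return self._probs

    def backward(self, y_onehot: np.ndarray) -> None:
        """Backprop of mean cross-entropy; call after a training forward."""
        n = y_onehot.shape[0]
        grad = (self._probs - y_onehot).astype(_DTYPE) / n
        for layer in reversed(self.head):
            grad = layer.backward(grad)
        grad = grad.reshape(self._fused_shape)
        pc = self.config.projection_channels
        branch = [grad[..., i * pc : (i + 1) * pc] for i in range(5)]
        grad_next = None  # gradient flowing into the output of block k
        for k in range(4, -1, -1):
            g = self.projections[k].backward(self.upsamplers[k].backward(branch[k]))
            if grad_next is not None:
                g = g + grad_next
            for layer in reversed(self.blocks[k]):
                g = layer.backward(g)
            grad_next = g


@dataclass
class TrainedModel:
    model: MLFCNN
    config: ModelConfig
    history: list[dict]  # one entry per epoch actually run


@dataclass
class FoldResult:
    fold: int
    confusion: ConfusionMatrix
    history: list[dict]
    val_indices: np.ndarray
    probabilities: np.ndarray


def build_model(config: ModelConfig) -> MLFCNN:
    return MLFCNN(config)


class _Adam:
    """Adam with preallocated scratch (the update runs every batch over
    millions of parameters, so temporaries matter on CPU)."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self._tmp = [np.empty_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = self.lr * math.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        b1, b2, eps = self.b1, self.b2, self.eps
        for p, g, m, v, tmp in zip(params, grads, self.m, self.v, self._tmp):
            np.multiply(m, b1, out=m)
            np.multiply(g, 1 - b1, out=tmp)
            np.add(m, tmp, out=m)
            np.multiply(v, b2, out=v)
            np.multiply(g, g, out=tmp)
            np.multiply(tmp, 1 - b2, out=tmp)
            np.add(v, tmp, out=v)
            np.sqrt(v, out=tmp)
            np.add(tmp, eps, out=tmp)
            np.divide(m, tmp, out=tmp)
            np.multiply(tmp, lr_t, out=tmp)
            np.subtract(p, tmp, out=p)


def images_to_arrays(images: list[TFImage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack TFImages into (X, y) with y = 1 for preictal, 0 otherwise."""
    X = np.stack([im.pixels for im in images]).astype(_DTYPE)
    y = np.array([1 if im.label is Label.PREICTAL else 0 for im in images])
    return X, y


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple):
        X, y = data
        return np.asarray(X, dtype=_DTYPE), np.asarray(y, dtype=int)
    return images_to_arrays(list(data))


def _eval(model: MLFCNN, X, y, batch: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(X), batch):
        probs = model.forward(X[i : i + batch], train=False)
        yy = y[i : i + batch]
        losses.append(-np.log(np.clip(probs[np.arange(len(yy)), yy], 1e-12, None)))
        correct += int(((probs[:, 1] > probs[:, 0]).astype(int) == yy).sum())
    return float(np.concatenate(losses).mean()), correct / len(X)


def train_fold(model: MLFCNN, train_segments, val_segments, config: ModelConfig) -> TrainedModel:
    """Minimize mean cross-entropy with Adam for ``config.epochs`` epochs.

    ``train_segments``/``val_segments`` are lists of :class:`TFImage` or
    ``(X, y)`` tuples.  Deterministic for a given ``config.seed``.
    """
    Xtr, ytr = _as_xy(train_segments)
    Xva, yva = _as_xy(val_segments) if val_segments is not None else (None, None)
    classes = np.unique(ytr)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")

    onehot = np.eye(config.n_classes, dtype=_DTYPE)[ytr]
    opt = _Adam(model.parameters(), config.learning_rate)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(3)[2].generate_state(1)[0]
    )
    history: list[dict] = []
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(Xtr))
        ep_losses, ep_correct = [], 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            probs = model.forward(Xtr[idx], train=True)
            yy = ytr[idx]
            ep_losses.append(
                -np.log(np.clip(probs[np.arange(len(yy)), yy], 1e-12, None)).sum()
            )
            ep_correct += int(((probs[:, 1] > probs[:, 0]).astype(int) == yy).sum())
            model.backward(onehot[idx])
            opt.step(model.parameters(), model.gradients())
        entry = {
            "epoch": _epoch + 1,
            "train_loss": float(np.sum(ep_losses) / len(Xtr)),
            "train_acc": ep_correct / len(Xtr),
        }
        if Xva is not None and len(Xva):
            entry["val_loss"], entry["val_acc"] = _eval(model, Xva, yva, config.batch_size)
        history.append(entry)
    return TrainedModel(model=model, config=config, history=history)


def predict(model: MLFCNN | TrainedModel, images, batch_size: int = 64):
    """Class probabilities and hard labels (1 = preictal; exact ties go to
    interictal, the non-alarm class)."""
    net = model.model if isinstance(model, TrainedModel) else model
    if isinstance(images, tuple):
        X = np.asarray(images[0], dtype=_DTYPE)
    elif isinstance(images, np.ndarray):
        X = images.astype(_DTYPE)
    else:
        X, _ = images_to_arrays(list(images))
    probs = np.concatenate(
        [net.forward(X[i : i + batch_size], train=False) for i in range(0, len(X), batch_size)]
    )
    labels = (probs[:, 1] > probs[:, 0]).astype(int)
    return probs, labels


def cross_validate(
    dataset,
    k: int = 5,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> list[FoldResult]:
    """Stratified k-fold cross-validation; every segment is validated in
    exactly one fold, class proportions preserved per fold.  A fresh model
    (seeded per fold) is trained on each split."""
    X, y = _as_xy(dataset)
    config = config or ModelConfig()
    if len(X) < k:
        raise ValueError("dataset smaller than the number of folds")
    for cls in np.unique(y):
        if int((y == cls).sum()) < k:
            raise ValueError(f"class {cls} has fewer members than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    results = []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        fold_cfg = replace(config, seed=config.seed + 1000 * fold)
        model = build_model(fold_cfg)
        trained = train_fold(model, (X[tr], y[tr]), (X[va], y[va]), fold_cfg)
        probs, pred = predict(trained, (X[va], None))
        results.append(
            FoldResult(
                fold=fold,
                confusion=confusion(y[va], pred),
                history=trained.history,
                val_indices=va,
                probabilities=probs,
            )
        )
    return results
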