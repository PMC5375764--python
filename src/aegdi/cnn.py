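"""Compact numpy convolutional network for AE-GDI classification.

The classifier is a seven-layer stack — conv1, mp1, conv2, conv3, mp2,
fl1 (ReLU), fl2 — topped by softmax.  Convolutions use no zero padding
(each 3x3 layer shrinks both spatial dimensions by 2), pooling is 2x2
with stride 2 and floor on odd sizes, dropout (p = 0.5) precedes each
fully connected layer during training, weights are initialised randomly
and orthogonally, and training minimises cross-entropy with Adam on
mini-batches of 100.  A temporal ablation (1x3 convolutions, 1x2 pooling)
treats the image as stacked 1-D series.

Everything is plain numpy with analytic backpropagation; forward, loss
and gradients are verified in the test suite against hand-computed
values and finite differences.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

# Default architecture configuration.  The per-layer feature-map counts are
# deliberately configuration, not logic: (32, 64, 64) with 3x3 kernels,
# fl1 width 1024 and task-dependent output width.
DEFAULT_FEATURE_MAPS = (32, 64, 64)
DEFAULT_KERNEL = (3, 3)
DEFAULT_POOL = (2, 2)
DEFAULT_FL1 = 1024


class ConfigurationError(ValueError):
    """Raised when a layer stack produces a non-positive dimension."""


@dataclass
class CnnSpec:
    """Architecture hyperparameters of the classifier.

    ``conv_layers`` lists ``(kernel_h, kernel_w, feature_maps)``;
    ``pool_positions`` says after which conv layers (1-based) a max-pooling
    layer sits.  ``n_conv`` counts the convolution layers; with a single
    one the second pooling layer is removed.
    """

    input_height: int = 32
    input_width: int = 64
    input_channels: int = 2
    conv_layers: tuple = tuple(
        (DEFAULT_KERNEL[0], DEFAULT_KERNEL[1], m) for m in DEFAULT_FEATURE_MAPS
    )
    pool_positions: tuple = (1, 3)
    pool_size: tuple = DEFAULT_POOL
    fc1_width: int = DEFAULT_FL1
    output_classes: int = 2

    @property
    def n_conv(self) -> int:
        return len(self.conv_layers)

    @classmethod
    def for_task(
        cls,
        output_classes: int,
        input_channels: int = 2,
        feature_maps: tuple = DEFAULT_FEATURE_MAPS,
        fc1_width: int = DEFAULT_FL1,
        n_conv: int | None = None,
        kernel: tuple = DEFAULT_KERNEL,
        pool: tuple = DEFAULT_POOL,
        input_height: int = 32,
        input_width: int = 64,
    ) -> "CnnSpec":
        """Spec for authentication (2 classes) or labeling (K classes).

        ``n_conv`` keeps conv1/mp1 fixed and varies the number of conv
        layers before the second pooling layer; with ``n_conv = 1`` that
        pooling layer is removed.
        """
        if n_conv is None:
            n_conv = len(feature_maps)
        maps = tuple(feature_maps[:n_conv])
        if len(maps) < n_conv:
            maps = maps + (feature_maps[-1],) * (n_conv - len(maps))
        pools = (1,) if n_conv == 1 else (1, n_conv)
        return cls(
            input_height=input_height,
            input_width=input_width,
            input_channels=input_channels,
            conv_layers=tuple((kernel[0], kernel[1], m) for m in maps),
            pool_positions=pools,
            pool_size=pool,
            fc1_width=fc1_width,
            output_classes=output_classes,
        )


@dataclass
class TrainSpec:
    """Training regime: 50 epochs of Adam (lr 0.001) on mini-batches of
    100 with drop probability 0.5 before each fully connected layer."""

    epochs: int = 50
    batch_size: int = 100
    learning_rate: float = 0.001
    dropout: float = 0.5
    seed: int = 0


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def orthogonal_init(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    """Random (semi-)orthogonal matrix reshaped to ``shape``.

    The tensor is flattened to ``(rows, fan)``; the smaller dimension ends
    up orthonormal (``W W^T = I`` for wide matrices, ``W^T W = I`` for
    tall ones).
    """
    rows = shape[0]
    fan = int(np.prod(shape[1:]))
    flat = rng.normal(size=(rows, fan))
    if rows <= fan:
        q, r = np.linalg.qr(flat.T)
        q = q * np.sign(np.diag(r))
        w = q.T[:rows]
    else:
        q, r = np.linalg.qr(flat)
        q = q * np.sign(np.diag(r))
        w = q[:, :fan]
    return np.ascontiguousarray(w.reshape(shape), dtype=np.float64)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def out_shape(self, in_shape):  # (C, H, W) or (D,)
        raise NotImplementedError


class Conv2D(Layer):
    """Valid (no zero padding) 2-D convolution with per-map bias and ReLU."""

    def __init__(self, in_channels, out_channels, kernel, rng, name="conv"):
        super().__init__()
        self.kh, self.kw = kernel
        self.name = name
        self.w = orthogonal_init(
            rng, (out_channels, in_channels, self.kh, self.kw)
        )
        self.b = np.zeros(out_channels)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def out_shape(self, in_shape):
        c, h, w = in_shape
        ho, wo = h - self.kh + 1, w - self.kw + 1
        if ho <= 0 or wo <= 0:
            raise ConfigurationError(
                f"layer {self.name}: kernel {self.kh}x{self.kw} exceeds input {h}x{w}"
            )
        return (self.w.shape[0], ho, wo)

    def forward(self, x, train=False, rng=None):
        b, c, h, w = x.shape
        ho, wo = h - self.kh + 1, w - self.kw + 1
        cols = sliding_window_view(x, (self.kh, self.kw), axis=(2, 3))
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho, wo, -1)
        wmat = self.w.reshape(self.w.shape[0], -1)
        z = cols @ wmat.T + self.b
        z = z.transpose(0, 3, 1, 2)
        self._cache = (cols, z > 0, x.shape)
        return np.maximum(z, 0.0)

    def backward(self, grad):
        cols, mask, in_shape = self._cache
        b, c, h, w = in_shape
        ho, wo = h - self.kh + 1, w - self.kw + 1
        f = self.w.shape[0]
        gz = grad * mask                       # ReLU gate
        gz_mat = gz.transpose(0, 2, 3, 1).reshape(-1, f)
        cols_mat = cols.reshape(-1, cols.shape[-1])
        self.grads[0][...] = (gz_mat.T @ cols_mat).reshape(self.w.shape)
        self.grads[1][...] = gz_mat.sum(axis=0)
        dcols = (gz_mat @ self.w.reshape(f, -1)).reshape(
            b, ho, wo, c, self.kh, self.kw
        )
        dx = np.zeros(in_shape)
        for p in range(self.kh):
            for q in range(self.kw):
                dx[:, :, p : p + ho, q : q + wo] += dcols[:, :, :, :, p, q].transpose(
                    0, 3, 1, 2
                )
        return dx


class MaxPool(Layer):
    """Non-overlapping max pooling with floor on odd dimensions."""

    def __init__(self, size=(2, 2), name="mp"):
        super().__init__()
        self.ph, self.pw = size
        self.name = name

    def out_shape(self, in_shape):
        c, h, w = in_shape
        ho, wo = h // self.ph, w // self.pw
        if ho <= 0 or wo <= 0:
            raise ConfigurationError(f"layer {self.name}: input {h}x{w} too small")
        return (c, ho, wo)

    def forward(self, x, train=False, rng=None):
        b, c, h, w = x.shape
        ho, wo = h // self.ph, w // self.pw
        crop = x[:, :, : ho * self.ph, : wo * self.pw]
        win = crop.reshape(b, c, ho, self.ph, wo, self.pw)
        win = win.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho, wo, -1)
        idx = win.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        idx, in_shape = self._cache
        b, c, h, w = in_shape
        ho, wo = h // self.ph, w // self.pw
        dwin = np.zeros((b, c, ho, wo, self.ph * self.pw))
        np.put_along_axis(dwin, idx[..., None], grad[..., None], axis=-1)
        dwin = dwin.reshape(b, c, ho, wo, self.ph, self.pw).transpose(
            0, 1, 2, 4, 3, 5
        )
        dx = np.zeros(in_shape)
        dx[:, :, : ho * self.ph, : wo * self.pw] = dwin.reshape(
            b, c, ho * self.ph, wo * self.pw
        )
        return dx


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p=0.5):
        super().__init__()
        self.p = p

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False, rng=None):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng, relu=False, name="fl"):
        super().__init__()
        self.w = orthogonal_init(rng, (in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.relu = relu
        self.name = name
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def out_shape(self, in_shape):
        return (self.w.shape[1],)

    def forward(self, x, train=False, rng=None):
        z = x @ self.w + self.b
        if self.relu:
            self._cache = (x, z > 0)
            return np.maximum(z, 0.0)
        self._cache = (x, None)
        return z

    def backward(self, grad):
        x, mask = self._cache
        if mask is not None:
            grad = grad * mask
        self.grads[0][...] = x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class Model:
    spec: CnnSpec
    layers: list
    shapes: list  # per-layer output shapes, input first

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]


def build_cnn(spec: CnnSpec, seed: int = 0) -> Model:
    """Assemble the layer stack and validate every intermediate shape.

    Raises :class:`ConfigurationError` naming the first layer whose output
    dimension would be non-positive.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 71]))
    layers: list[Layer] = []
    shapes = [(spec.input_channels, spec.input_height, spec.input_width)]
    shape = shapes[0]
    in_c = spec.input_channels
    for i, (kh, kw, maps) in enumerate(spec.conv_layers, start=1):
        conv = Conv2D(in_c, maps, (kh, kw), rng, name=f"conv{i}")
        shape = conv.out_shape(shape)
        layers.append(conv)
        shapes.append(shape)
        if i in spec.pool_positions:
            pool = MaxPool(spec.pool_size, name=f"mp{len([l for l in layers if isinstance(l, MaxPool)]) + 1}")
            shape = pool.out_shape(shape)
            layers.append(pool)
            shapes.append(shape)
        in_c = maps
    flat = Flatten()
    shape = flat.out_shape(shape)
    layers.append(flat)
    shapes.append(shape)
    layers.append(Dropout())
    fl1 = Dense(shape[0], spec.fc1_width, rng, relu=True, name="fl1")
    layers.append(fl1)
    shapes.append((spec.fc1_width,))
    layers.append(Dropout())
    fl2 = Dense(spec.fc1_width, spec.output_classes, rng, relu=False, name="fl2")
    layers.append(fl2)
    shapes.append((spec.output_classes,))
    return Model(spec=spec, layers=layers, shapes=shapes)


def build_tcnn(spec: CnnSpec, seed: int = 0) -> Model:
    """Temporal ablation: 1xk convolutions and 1x2 pooling.

    The height (time-delay axis) passes through unchanged; only the time
    axis is convolved and pooled, treating the image as stacked 1-D
    series.
    """
    tspec = CnnSpec(
        input_height=spec.input_height,
        input_width=spec.input_width,
        input_channels=spec.input_channels,
        conv_layers=tuple((1, kw, m) for (_, kw, m) in spec.conv_layers),
        pool_positions=spec.pool_positions,
        pool_size=(1, spec.pool_size[1]),
        fc1_width=spec.fc1_width,
        output_classes=spec.output_classes,
    )
    return build_cnn(tspec, seed=seed)


def count_parameters(model: Model) -> int:
    """Total size of all kernels, biases and fully connected weights."""
    return int(sum(p.size for p in model.params))


def conv_shapes(model: Model) -> list[tuple]:
    """Spatial output shapes (H, W) after each conv/pool layer, in order."""
    return [s[1:] for s in model.shapes[1:] if len(s) == 3]


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


@dataclass
class TrainedClassifier:
    """Fitted model plus its architecture/training metadata."""

    model: Model
    trainspec: TrainSpec
    history: list = field(default_factory=list)
    classes: np.ndarray | None = None

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return predict(self.model, x, batch_size=self.trainspec.batch_size)

    def predict_label(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def train(
    model: Model,
    gdis: np.ndarray,
    labels: np.ndarray,
    trainspec: TrainSpec | None = None,
) -> TrainedClassifier:
    """Fit the network with seeded, reproducible mini-batch Adam.

    ``gdis`` has shape ``(n, Nl, Nh, Nw)``; ``labels`` are integers in
    ``[0, output_classes)``.  Trailing mini-batches smaller than the batch
    size are used, not dropped.  Dropout noise and shuffling flow from
    ``trainspec.seed``, so the same seed reproduces the same final loss.
    """
    trainspec = trainspec or TrainSpec()
    x = np.asarray(gdis, dtype=float)
    y = np.asarray(labels, dtype=int)
    no = model.spec.output_classes
    if y.min(initial=0) < 0 or y.max(initial=0) >= no:
        raise ValueError(f"labels must lie in [0, {no})")
    present = np.unique(y)
    if present.size < no:
        warnings.warn(
            f"only {present.size} of {no} classes present in training data",
            stacklevel=2,
        )
    for layer in model.layers:
        if isinstance(layer, Dropout):
            layer.p = trainspec.dropout
    rng = np.random.default_rng(np.random.SeedSequence([int(trainspec.seed), 9180]))
    opt = _Adam(model.params, trainspec.learning_rate)
    onehot = np.eye(no)
    history = []
    for epoch in range(trainspec.epochs):
        order = rng.permutation(len(x))
        losses = []
        for lo in range(0, len(x), trainspec.batch_size):
            idx = order[lo : lo + trainspec.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, train=True, rng=rng)
            probs = _softmax(logits)
            eps = 1e-12
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + eps))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {lo // trainspec.batch_size}"
                )
            model.backward((probs - onehot[yb]) / len(yb))
            opt.step(model.params, model.grads)
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        logger.info("epoch %d: loss %.5f", epoch + 1, epoch_loss)
    return TrainedClassifier(model=model, trainspec=trainspec, history=history)


def predict(model: Model, gdis: np.ndarray, batch_size: int = 100) -> np.ndarray:
    """Per-sample class probability vectors (dropout disabled)."""
    x = np.asarray(gdis, dtype=float)
    expected = (model.spec.input_channels, model.spec.input_height, model.spec.input_width)
    if x.shape[1:] != expected:
        raise ValueError(f"input shape {x.shape[1:]} does not match spec {expected}")
    out = []
    for lo in range(0, len(x), batch_size):
        out.append(_softmax(model.forward(x[lo : lo + batch_size], train=False)))
    return np.concatenate(out) if out else np.zeros((0, model.spec.output_classes))


def aggregate_cycles(probabilities, method: str = "mean") -> int:
    """Fuse the predictions of N consecutive-cycle AE-GDIs into one label.

    ``mean`` takes the argmax of the mean probability vector; ``vote``
    takes the majority of per-cycle argmaxes.  Ties resolve to the lowest
    class index (argmax semantics).
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 2 or probs.shape[0] == 0:
        raise ValueError("need a non-empty list of probability vectors")
    if method == "mean":
        return int(probs.mean(axis=0).argmax())
    if method == "vote":
        votes = probs.argmax(axis=1)
        counts = np.bincount(votes, minlength=probs.shape[1])
        return int(counts.argmax())
    raise ValueError(f"unknown aggregation method {method!r}")


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(directory, clf: TrainedClassifier) -> None:
    """Write weights (npz) plus a JSON sidecar with spec and count."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", *clf.model.params)
    sidecar = {
        "cnn_spec": asdict(clf.model.spec),
        "train_spec": asdict(clf.trainspec),
        "parameter_count": count_parameters(clf.model),
        "history": clf.history,
        "classes": None if clf.classes is None else clf.classes.tolist(),
    }
    (directory / "model.json").write_text(json.dumps(sidecar, indent=2, default=list))


def load_model(directory) -> TrainedClassifier:
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    raw = sidecar["cnn_spec"]
    raw["conv_layers"] = tuple(tuple(c) for c in raw["conv_layers"])
    raw["pool_positions"] = tuple(raw["pool_positions"])
    raw["pool_size"] = tuple(raw["pool_size"])
    spec = CnnSpec(**raw)
    model = build_cnn(spec)
    with np.load(directory / "weights.npz") as data:
        weights = [data[k] for k in sorted(data.files, key=lambda s: int(s.split("_")[1]))]
    for p, w in zip(model.params, weights):
        p[...] = w
    clf = TrainedClassifier(
        model=model,
        trainspec=TrainSpec(**sidecar["train_spec"]),
        history=sidecar["history"],
        classes=None if sidecar["classes"] is None else np.asarray(sidecar["classes"]),
    )
    return clf
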