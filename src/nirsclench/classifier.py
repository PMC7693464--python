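"""CNN classifier for the Hb frames.

A small, self-contained convolutional network engine (im2col convolution,
overlapping max pooling, fully connected layers, softmax cross-entropy,
SGD with momentum and step decay) written on numpy. The default topology
is the classic five-convolution / three-pool / three-FC stack with a
two-way output; a ``tiny`` preset (64-pixel input, reduced filter counts,
same layer census) trains in minutes on one CPU core and is what the
tests and the scaled-down experiments use.

Everything is float32 and seeded: the same seed and data yield identical
parameters, loss history and predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import HbImage, resize_squash

LABELS = ("rest", "clench")  # index 0 = negative, 1 = positive


class SpecError(ValueError):
    pass


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class ConvStage:
    filters: int
    kernel: int
    stride: int = 1
    pad: int = 0


@dataclass(frozen=True)
class NetworkSpec:
    """Topology: 5 conv stages, 3 max-pool placements, 3 FC widths (last = 2)."""

    input_side: int = 256
    in_channels: int = 1
    conv: tuple[ConvStage, ...] = (
        ConvStage(96, 11, 4, 0),
        ConvStage(256, 5, 1, 2),
        ConvStage(384, 3, 1, 1),
        ConvStage(384, 3, 1, 1),
        ConvStage(256, 3, 1, 1),
    )
    pool_after: tuple[int, ...] = (0, 1, 4)  # conv indices followed by a pool
    pool_kernel: int = 3
    pool_stride: int = 2
    fc: tuple[int, ...] = (4096, 4096, 2)

    def __post_init__(self) -> None:
        if len(self.conv) != 5:
            raise SpecError("expected exactly 5 convolutional stages")
        if len(self.pool_after) != 3:
            raise SpecError("expected exactly 3 max-pooling placements")
        if len(self.fc) != 3:
            raise SpecError("expected exactly 3 fully connected layers")
        if self.fc[-1] != 2:
            raise SpecError("output layer must have 2 class scores")
        if any(i not in range(5) for i in self.pool_after):
            raise SpecError("pool placements must follow conv stages 0..4")
        if self.feature_side() < 1:
            raise SpecError("input side too small for this topology")

    def feature_side(self) -> int:
        side = self.input_side
        for i, st in enumerate(self.conv):
            side = (side + 2 * st.pad - st.kernel) // st.stride + 1
            if i in self.pool_after:
                side = (side - self.pool_kernel) // self.pool_stride + 1
        return side

    @classmethod
    def tiny(cls) -> "NetworkSpec":
        """Desk-scale preset: same layer census, 64-px input, few filters."""
        return cls(
            input_side=64,
            conv=(
                ConvStage(8, 5, 2, 2),
                ConvStage(12, 3, 1, 1),
                ConvStage(12, 3, 1, 1),
                ConvStage(12, 3, 1, 1),
                ConvStage(8, 3, 1, 1),
            ),
            pool_after=(0, 1, 4),
            pool_kernel=2,
            pool_stride=2,
            fc=(32, 16, 2),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Classic SGD defaults: momentum 0.9, step decay x0.1 every 1/3 epochs."""

    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 0.01
    momentum: float = 0.9
    decay_factor: float = 0.1
    decay_steps: int = 3
    seed: int = 0
    mean_subtract: bool = False  # optional mean-image subtraction

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise SpecError("epochs must be >= 1")

    def lr_at(self, epoch: int) -> float:
        step = (epoch * self.decay_steps) // self.epochs
        return self.learning_rate * self.decay_factor ** min(step, self.decay_steps - 1)


# --------------------------------------------------------------------------
# layer machinery

def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int]:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, oh, oh), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i:i + stride * oh:stride, j:j + stride * oh:stride]
    return cols, oh


def _col2im(cols: np.ndarray, shape: tuple[int, ...], k: int, stride: int,
            pad: int, oh: int) -> np.ndarray:
    n, c, h, w = shape
    x = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            x[:, :, i:i + stride * oh:stride, j:j + stride * oh:stride] += cols[:, :, i, j]
    if pad:
        x = x[:, :, pad:-pad, pad:-pad]
    return x


class _Conv:
    def __init__(self, stage: ConvStage, in_ch: int, rng: np.random.Generator):
        fan_in = in_ch * stage.kernel ** 2
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in),
                            (stage.filters, in_ch, stage.kernel, stage.kernel)
                            ).astype(np.float32)
        self.b = np.zeros(stage.filters, dtype=np.float32)
        self.stage = stage
        self.params = [("w", self.w), ("b", self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        st = self.stage
        cols, oh = _im2col(x, st.kernel, st.stride, st.pad)
        n = x.shape[0]
        mat = cols.reshape(n, -1, oh * oh)  # (N, C*K*K, OH*OW)
        wm = self.w.reshape(st.filters, -1)
        out = np.einsum("fk,nkp->nfp", wm, mat) + self.b[None, :, None]
        self._cache = (x.shape, mat, oh)
        return out.reshape(n, st.filters, oh, oh)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        st = self.stage
        x_shape, mat, oh = self._cache
        n = grad.shape[0]
        g = grad.reshape(n, st.filters, oh * oh)
        self.db = g.sum(axis=(0, 2))
        self.dw = np.einsum("nfp,nkp->fk", g, mat).reshape(self.w.shape)
        wm = self.w.reshape(st.filters, -1)
        dmat = np.einsum("fk,nfp->nkp", wm, g)
        in_ch = x_shape[1]
        cols = dmat.reshape(n, in_ch, st.kernel, st.kernel, oh, oh)
        return _col2im(cols, x_shape, st.kernel, st.stride, st.pad, oh)

    def grads(self):
        return [("w", self.dw), ("b", self.db)]


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def grads(self):
        return []


class _MaxPool:
    params: list = []

    def __init__(self, kernel: int, stride: int):
        self.k, self.s = kernel, stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, oh = _im2col(x, self.k, self.s, 0)
        n, c = x.shape[:2]
        flat = cols.reshape(n, c, self.k * self.k, oh, oh)
        self._arg = flat.argmax(axis=2)
        self._cache = (x.shape, oh)
        return flat.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, oh = self._cache
        n, c = x_shape[:2]
        flat = np.zeros((n, c, self.k * self.k, oh, oh), dtype=grad.dtype)
        np.put_along_axis(flat, self._arg[:, :, None], grad[:, :, None], axis=2)
        cols = flat.reshape(n, c, self.k, self.k, oh, oh)
        return _col2im(cols, x_shape, self.k, self.s, 0, oh)

    def grads(self):
        return []


class _Flatten:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    def grads(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [("w", self.w), ("b", self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def grads(self):
        return [("w", self.dw), ("b", self.db)]


class Model:
    """Sequential CNN assembled from a NetworkSpec."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list = []
        in_ch = spec.in_channels
        side = spec.input_side
        for i, st in enumerate(spec.conv):
            layers.append(_Conv(st, in_ch, rng))
            layers.append(_ReLU())
            side = (side + 2 * st.pad - st.kernel) // st.stride + 1
            in_ch = st.filters
            if i in spec.pool_after:
                layers.append(_MaxPool(spec.pool_kernel, spec.pool_stride))
                side = (side - spec.pool_kernel) // spec.pool_stride + 1
        layers.append(_Flatten())
        n_in = in_ch * side * side
        for j, width in enumerate(spec.fc):
            layers.append(_Dense(n_in, width, rng))
            if j < len(spec.fc) - 1:
                layers.append(_ReLU())
            n_in = width
        self.layers = layers
        self.mean_image: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self):
        for layer in self.layers:
            if layer.params:
                yield layer

    def layer_census(self) -> dict[str, int]:
        return {
            "conv": sum(isinstance(l, _Conv) for l in self.layers),
            "pool": sum(isinstance(l, _MaxPool) for l in self.layers),
            "fc": sum(isinstance(l, _Dense) for l in self.layers),
        }


def build_network(spec: NetworkSpec, seed: int = 0) -> Model:
    """Randomly initialised model; the same seed gives identical weights."""
    return Model(spec, seed)


def _spec_to_dict(spec: NetworkSpec) -> dict:
    return {
        "input_side": spec.input_side, "in_channels": spec.in_channels,
        "conv": [[s.filters, s.kernel, s.stride, s.pad] for s in spec.conv],
        "pool_after": list(spec.pool_after), "pool_kernel": spec.pool_kernel,
        "pool_stride": spec.pool_stride, "fc": list(spec.fc),
    }


def _spec_from_dict(d: dict) -> NetworkSpec:
    return NetworkSpec(
        input_side=d["input_side"], in_channels=d["in_channels"],
        conv=tuple(ConvStage(*row) for row in d["conv"]),
        pool_after=tuple(d["pool_after"]), pool_kernel=d["pool_kernel"],
        pool_stride=d["pool_stride"], fc=tuple(d["fc"]),
    )


def save_checkpoint(model: Model, path) -> None:
    """Persist topology and weights (compressed npz with embedded spec)."""
    import json

    arrays = {"spec_json": np.frombuffer(
        json.dumps(_spec_to_dict(model.spec)).encode(), dtype=np.uint8)}
    for li, layer in enumerate(model.parameters()):
        for name, param in layer.params:
            arrays[f"p_{li}_{name}"] = param
    if model.mean_image is not None:
        arrays["mean_image"] = model.mean_image
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> Model:
    import json

    with np.load(path) as z:
        spec = _spec_from_dict(json.loads(bytes(z["spec_json"]).decode()))
        model = Model(spec, seed=0)
        for li, layer in enumerate(model.parameters()):
            for name, param in layer.params:
                param[...] = z[f"p_{li}_{name}"]
        if "mean_image" in z.files:
            model.mean_image = z["mean_image"]
    return model


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def images_to_array(images: list[HbImage], side: int) -> np.ndarray:
    """Squash-resize frames and scale pixel codes to roughly [-0.5, 0.5]."""
    out = np.empty((len(images), 1, side, side), dtype=np.float32)
    for i, im in enumerate(images):
        out[i, 0] = resize_squash(im, side).astype(np.float32)
    return out / 255.0 - 0.5


def labels_to_array(images: list[HbImage]) -> np.ndarray:
    return np.array([LABELS.index(im.label) for im in images], dtype=np.int64)


def train(model: Model, images: list[HbImage], config: TrainConfig,
          x: np.ndarray | None = None,
          y: np.ndarray | None = None) -> pd.DataFrame:
    """SGD training with cross-entropy loss; returns the per-epoch log.

    ``x``/``y`` may be passed to reuse pre-rendered arrays; otherwise they
    are built from ``images``.
    """
    if x is None:
        if not images:
            raise TrainingError("training set is empty")
        x = images_to_array(images, model.spec.input_side)
        y = labels_to_array(images)
    if x.shape[0] == 0:
        raise TrainingError("training set is empty")
    if config.mean_subtract:
        model.mean_image = x.mean(axis=0)
        x = x - model.mean_image

    rng = np.random.default_rng(config.seed)
    velocity: dict[tuple[int, str], np.ndarray] = {}
    history = []
    n = x.shape[0]
    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb)
            probs = softmax(logits)
            eps = 1e-12
            losses.append(float(-np.log(probs[np.arange(len(yb)), yb] + eps).mean()))
            correct += int((probs.argmax(axis=1) == yb).sum())
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            model.backward(grad.astype(np.float32))
            for li, layer in enumerate(model.parameters()):
                for (name, param), (_, g) in zip(layer.params, layer.grads()):
                    key = (li, name)
                    v = velocity.get(key)
                    if v is None:
                        v = np.zeros_like(param)
                    v *= config.momentum
                    v -= lr * g
                    param += v
                    velocity[key] = v
        history.append({
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "train_acc": correct / n,
            "lr": lr,
        })
    return pd.DataFrame(history)


@dataclass
class PredictionSet:
    """Per-image truth, prediction and clench probability."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["subject", "modality", "fold", "label", "pred", "score"]))

    def __post_init__(self) -> None:
        if len(self.frame) and not self.frame["score"].between(0, 1).all():
            raise ValueError("scores must lie in [0, 1]")

    @classmethod
    def concat(cls, parts: list["PredictionSet"]) -> "PredictionSet":
        return cls(pd.concat([p.frame for p in parts], ignore_index=True))

    @property
    def accuracy(self) -> float:
        return float((self.frame["label"] == self.frame["pred"]).mean())


def predict(model: Model, images: list[HbImage], *, fold: int = -1,
            modality: str = "", x: np.ndarray | None = None,
            batch_size: int = 256, threshold: float = 0.5) -> PredictionSet:
    """Clench-class softmax scores and thresholded labels for test images."""
    if x is None:
        x = images_to_array(images, model.spec.input_side)
    if model.mean_image is not None:
        x = x - model.mean_image
    scores = np.empty(x.shape[0], dtype=float)
    for start in range(0, x.shape[0], batch_size):
        logits = model.forward(x[start:start + batch_size])
        scores[start:start + batch_size] = softmax(logits)[:, 1]
    rows = pd.DataFrame({
        "subject": [im.subject_id for im in images],
        "modality": modality or (images[0].modality if images else ""),
        "fold": fold,
        "label": [im.label for im in images],
        "pred": np.where(scores >= threshold, "clench", "rest"),
        "score": scores,
    })
    return PredictionSet(rows)
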