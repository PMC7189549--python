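"""Multilabel convolutional classifier and sliding-window heatmap inference.

The classifier takes a 256 x 256 RGB tile and emits three independent
sigmoid probabilities, one per amyloid morphology (cored plaque, diffuse
plaque, CAA); a tile may contain several pathologies at once, so the heads
are not mutually exclusive.  The architecture is six 3x3 convolution blocks,
each followed by 2x2 max pooling (256 -> 4 spatially), then dense layers of
512 and 100 units and a 3-unit sigmoid output.

The network, its backward pass and the Adam optimizer are implemented
directly on numpy arrays (im2col convolutions, reshape-based pooling), which
keeps the package dependency-light and is entirely adequate at the desk
scale this pipeline targets: thousands of tiles, a few epochs, CPU only.
Confidence heatmaps are produced by sliding the classifier window across the
slide at a fixed stride and recording the three probabilities per position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 256
    in_channels: int = 3
    conv_channels: tuple = (8, 16, 32, 32, 32, 32)
    kernel_size: int = 3
    dense_units: tuple = (512, 100)
    n_classes: int = 3
    seed: int = 0

    def __post_init__(self):
        size = self.input_size
        for _ in self.conv_channels:
            if size % 2 != 0:
                raise ValueError("input size not divisible through pooling stages")
            size //= 2
        if size < 1:
            raise ValueError("too many pooling stages for input size")

    @property
    def spatial_after_conv(self) -> int:
        return self.input_size // (2 ** len(self.conv_channels))

    @property
    def flat_features(self) -> int:
        return self.spatial_after_conv**2 * self.conv_channels[-1]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 2
    optimizer: str = "adam"
    loss: str = "bce"
    seed: int = 0
    train_fraction: float = 0.8
    val_fraction: float = 0.2

    def __post_init__(self):
        if not (0 < self.train_fraction < 1 and 0 < self.val_fraction < 1):
            raise ValueError("split fractions must be in (0, 1)")
        if self.train_fraction + self.val_fraction > 1 + 1e-9:
            raise ValueError("split fractions must sum to at most 1")


# --------------------------------------------------------------------------
# layers (channels-last, float32)


class _Conv3x3:
    """3x3 same-padding convolution via im2col."""

    def __init__(self, c_in, c_out, rng):
        k = 3
        scale = np.sqrt(2.0 / (k * k * c_in))  # He init
        self.W = (rng.standard_normal((k * k * c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._col = None
        self._in_shape = None

    def forward(self, x, train):
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        col = sliding_window_view(xp, (3, 3), axis=(1, 2))  # b,h,w,c,3,3
        col = np.ascontiguousarray(col.transpose(0, 1, 2, 4, 5, 3)).reshape(
            b * h * w, 9 * c
        )
        if train:
            self._col, self._in_shape = col, x.shape
        return (col @ self.W + self.b).reshape(b, h, w, -1)

    def backward(self, dout):
        b, h, w, c_out = dout.shape
        _, _, _, c_in = self._in_shape
        dflat = dout.reshape(b * h * w, c_out)
        self.dW = self._col.T @ dflat
        self.db = dflat.sum(axis=0)
        # dx: accumulate one kernel offset at a time (contiguous GEMM per
        # offset, strided add into the padded gradient)
        Wk = self.W.reshape(3, 3, c_in, c_out)
        dxp = np.zeros((b, h + 2, w + 2, c_in), dtype=np.float32)
        for dy in range(3):
            for dx in range(3):
                dxp[:, dy : dy + h, dx : dx + w] += (
                    dflat @ Wk[dy, dx].T
                ).reshape(b, h, w, c_in)
        self._col = None
        return dxp[:, 1 : 1 + h, 1 : 1 + w]

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x, train):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x, train):
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if train:
            # distribute gradient equally among tied maxima
            mask = xr == out[:, :, None, :, None, :]
            self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
            self._in_shape = x.shape
        return out

    def backward(self, dout):
        b, h, w, c = self._in_shape
        d = dout[:, :, None, :, None, :] * self._mask
        return d.reshape(b, h, w, c).astype(np.float32)

    def params(self):
        return []


class _Flatten:
    def forward(self, x, train):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SmallCNN:
    """The six-conv-block multilabel classifier."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers = []
        c_in = config.in_channels
        for c_out in config.conv_channels:
            layers += [_Conv3x3(c_in, c_out, rng), _ReLU(), _MaxPool2()]
            c_in = c_out
        layers.append(_Flatten())
        n_in = config.flat_features
        for units in config.dense_units:
            layers += [_Dense(n_in, units, rng), _ReLU()]
            n_in = units
        layers.append(_Dense(n_in, config.n_classes, rng))
        self.layers = layers

    # -- inference ---------------------------------------------------------
    def _prep(self, x):
        # map to [0,1] then center: zero-mean inputs condition the first
        # conv layer far better than all-positive ones
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None]
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        else:
            x = x.astype(np.float32)
        return x - np.float32(0.5)

    def forward_logits(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x):
        """Probabilities in [0,1], shape (N, n_classes) (or (n_classes,) for
        a single tile)."""
        xb = self._prep(x)
        out = _sigmoid(self.forward_logits(xb))
        return out[0] if np.asarray(x).ndim == 3 else out

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self):
        out = []
        for layer in self.layers:
            for name, owner in layer.params():
                out.append((name, owner))
        return out

    def state_dict(self):
        return {
            f"{i}.{name}": getattr(owner, name).copy()
            for i, layer in enumerate(self.layers)
            for name, owner in layer.params()
        }

    def load_state_dict(self, state):
        for i, layer in enumerate(self.layers):
            for name, owner in layer.params():
                setattr(owner, name, state[f"{i}.{name}"].copy())

    def save(self, path):
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, config: ModelConfig):
        model = cls(config)
        with np.load(path) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


def build_model(config: ModelConfig | None = None) -> SmallCNN:
    """Instantiate the classifier with seeded-deterministic initial weights."""
    return SmallCNN(config or ModelConfig())


class _Adam:
    def __init__(self, params, lr):
        self.params = params
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(getattr(o, n)) for n, o in params]
        self.v = [np.zeros_like(getattr(o, n)) for n, o in params]

    def step(self):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (name, owner) in enumerate(self.params):
            g = getattr(owner, "d" + name)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p = getattr(owner, name)
            p -= (self.lr * mhat / (np.sqrt(vhat) + eps)).astype(p.dtype)


def _bce(probs, y):
    eps = 1e-7
    p = np.clip(probs, eps, 1 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def train_model(model: SmallCNN, tiles, labels, config: TrainingConfig | None = None):
    """Train with multilabel binary cross-entropy; returns a history dict.

    ``tiles``: (N, S, S, 3) uint8 or float array; ``labels``: (N, n_classes)
    in {0,1}.  The data are split into train/validation per the config
    fractions (deterministically, by seeded shuffle).  History records the
    per-epoch mean training loss and per-class validation AUROC.
    """
    from sklearn.metrics import roc_auc_score

    config = config or TrainingConfig()
    tiles = np.asarray(tiles)
    labels = np.asarray(labels, dtype=np.float32)
    n = len(tiles)
    if n == 0:
        raise ValueError("empty dataset")
    if np.all(labels == labels[0]):
        raise ValueError("training labels are all identical; need >= 2 classes")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    n_train = int(round(n * config.train_fraction))
    n_val = min(n - n_train, int(round(n * config.val_fraction))) or (n - n_train)
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]

    history = {"loss": [], "val_auroc": []}
    if config.epochs == 0:
        return history

    opt = _Adam(model.parameters(), config.learning_rate)
    for _epoch in range(config.epochs):
        perm = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, config.batch_size):
            bidx = idx_train[perm[start : start + config.batch_size]]
            xb = model._prep(tiles[bidx])
            yb = labels[bidx]
            logits = model.forward_logits(xb, train=True)
            probs = _sigmoid(logits)
            losses.append(_bce(probs, yb))
            model.backward((probs - yb).astype(np.float32) / len(bidx))
            opt.step()
        history["loss"].append(float(np.mean(losses)))

        val_probs = predict_in_batches(model, tiles[idx_val], config.batch_size)
        yv = labels[idx_val]
        aurocs = []
        for k in range(labels.shape[1]):
            col = yv[:, k]
            if col.min() == col.max():
                aurocs.append(float("nan"))
            else:
                aurocs.append(float(roc_auc_score(col, val_probs[:, k])))
        history["val_auroc"].append(aurocs)
    return history


def predict_in_batches(model, tiles, batch_size=64):
    out = []
    for start in range(0, len(tiles), batch_size):
        out.append(model.predict_proba(tiles[start : start + batch_size]))
    return np.concatenate(out, axis=0) if out else np.empty((0, model.config.n_classes))


def evaluate_model(model: SmallCNN, tiles, labels, batch_size=64):
    """Per-class AUROC and average precision on a labeled tile set.

    Classes with a single outcome in ``labels`` are reported as NaN
    (undefined).
    """
    from sklearn.metrics import average_precision_score, roc_auc_score

    labels = np.asarray(labels)
    probs = predict_in_batches(model, np.asarray(tiles), batch_size)
    result = {}
    for k in range(labels.shape[1]):
        col = labels[:, k]
        if col.min() == col.max():
            result[k] = {"auroc": float("nan"), "average_precision": float("nan")}
        else:
            result[k] = {
                "auroc": float(roc_auc_score(col, probs[:, k])),
                "average_precision": float(average_precision_score(col, probs[:, k])),
            }
    return result


def heatmap_shape(image_shape, window=256, stride=16):
    """(rows, cols) of the heatmap for a given slide shape."""
    h, w = image_shape[:2]
    if h < window or w < window:
        raise ValueError("image smaller than the classifier window")
    return (h - window) // stride + 1, (w - window) // stride + 1


def sliding_window_heatmap(
    model,
    image,
    tissue_mask=None,
    stride: int = 16,
    window: int = 256,
    min_tissue_fraction: float = 0.5,
    batch_size: int = 128,
):
    """Slide the classifier across the image and collect per-class probabilities.

    Heatmap pixel (i, j) holds the probabilities for the window whose
    top-left slide pixel is (i*stride, j*stride).  Windows whose tissue-mask
    coverage is below ``min_tissue_fraction`` are skipped and left at 0.
    ``model`` may be any object with ``predict_proba(batch) -> (N, C)``.
    Returns a float32 raster of shape (Hh, Wh, C).
    """
    img = np.asarray(image)
    hh, wh = heatmap_shape(img.shape, window, stride)
    n_classes = getattr(getattr(model, "config", None), "n_classes", 3)
    heatmap = np.zeros((hh, wh, n_classes), dtype=np.float32)

    if tissue_mask is not None:
        # integral image -> per-window tissue coverage in O(1) per window
        ii = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.int64)
        ii[1:, 1:] = np.cumsum(np.cumsum(tissue_mask.astype(np.int64), 0), 1)
        r = np.arange(hh) * stride
        c = np.arange(wh) * stride
        cov = (
            ii[np.ix_(r + window, c + window)]
            - ii[np.ix_(r + window, c)]
            - ii[np.ix_(r, c + window)]
            + ii[np.ix_(r, c)]
        ) / float(window * window)
        keep = cov >= min_tissue_fraction
    else:
        keep = np.ones((hh, wh), dtype=bool)

    rows, cols = np.nonzero(keep)
    if rows.size == 0:
        return heatmap
    # strided view over all window origins; gather per batch (copies batch only)
    view = sliding_window_view(img, (window, window), axis=(0, 1))
    for start in range(0, rows.size, batch_size):
        rr = rows[start : start + batch_size]
        cc = cols[start : start + batch_size]
        batch = view[rr * stride, cc * stride]  # (B, C, win, win) or (B, win, win)
        if batch.ndim == 4:
            batch = batch.transpose(0, 2, 3, 1)
        probs = np.asarray(model.predict_proba(batch))
        heatmap[rr, cc] = probs.astype(np.float32)
    return heatmap


def save_heatmap(path, heatmap, stride: int = 16):
    """Write a heatmap as a float32 TIFF with the stride in the description."""
    import json

    import tifffile

    tifffile.imwrite(
        path,
        np.asarray(heatmap, dtype=np.float32),
        description=json.dumps({"stride": int(stride)}),
    )


def load_heatmap(path):
    """Read a heatmap TIFF; returns ``(array, stride)`` (stride None if absent)."""
    import json

    import tifffile

    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        stride = None
        desc = tf.pages[0].description
        if desc:
            try:
                stride = json.loads(desc).get("stride")
            except (ValueError, AttributeError):
                stride = None
    return arr, stride


class ConstantModel:
    """Stub emitting fixed probabilities; useful for geometry checks."""

    def __init__(self, probs=(0.5, 0.5, 0.5)):
        self.probs = np.asarray(probs, dtype=np.float32)

    def predict_proba(self, x):
        x = np.asarray(x)
        n = 1 if x.ndim == 3 else x.shape[0]
        return np.tile(self.probs, (n, 1))


class BrownPixelModel:
    """Stub scoring windows by their fraction of brown (DAB-like) pixels.

    Emits the same value on all three channels; intended for tests that
    need the heatmap hotspot to land on a planted deposit without training.
    """

    def __init__(self, gain=50.0):
        self.gain = gain

    def predict_proba(self, x):
        x = np.asarray(x)
        single = x.ndim == 3
        if single:
            x = x[None]
        x = x.astype(np.float32)
        if x.max() > 1.5:
            x = x / 255.0
        r, g, b = x[..., 0], x[..., 1], x[..., 2]
        brown = (r > g + 0.05) & (g > b + 0.05) & (r < 0.75)
        frac = brown.mean(axis=(1, 2))
        out = np.clip(frac * self.gain, 0.0, 1.0)
        out = np.repeat(out[:, None], 3, axis=1)
        return out[0] if single else out
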