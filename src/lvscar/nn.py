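"""Minimal CNN framework: VGG-style classifiers, focal loss, SGD with momentum.

Everything is plain numpy.  Convolutions are 3x3/pad-1 via im2col + BLAS
matmul; the only other layers needed are ReLU, 2x2 max pooling, average-pool
downsampling, dropout and dense layers.  Two architectures are provided:

* ``vgg16`` — the full 13-conv VGG16 topology adapted to a single-channel
  256x256 input and a single sigmoid logit.
* ``vgg_small`` — same topology class (four blocks of two 3x3 convs with
  ReLU and 2x2 max pooling, then a dense head) at reduced width behind an
  8x average-pool stem, sized to train in minutes on one CPU core.

The loss is the focal loss FL(p_t) = -alpha (1 - p_t)^gamma log(p_t), the
cross-entropy variant that down-weights easy examples; gamma is the
focusing parameter and alpha the class weight.  During training alpha is
applied per class (alpha for positives, 1-alpha for negatives), which is
how a single scalar can counteract class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FocalLossParams",
    "NetworkSpec",
    "Network",
    "SGD",
    "focal_loss",
    "focal_loss_and_grad",
    "build_network",
    "sigmoid",
]

EPS = 1e-7  # probability clamp before any log


@dataclass
class FocalLossParams:
    """Focusing parameter gamma >= 0 and class weight alpha in (0, 1]."""

    gamma: float = 1.560
    alpha: float = 0.6

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class NetworkSpec:
    architecture: str = "vgg_small"
    in_channels: int = 1
    input_size: int = 256


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def focal_loss(p_true, params: FocalLossParams):
    """FL(p_t) = -alpha (1 - p_t)^gamma log(p_t); batch reduction is the mean.

    ``p_true`` is the probability assigned to the true class of each sample,
    clamped to [EPS, 1] before the log.
    """
    p = np.clip(np.asarray(p_true, dtype=np.float64), EPS, 1.0)
    per = -params.alpha * (1.0 - p) ** params.gamma * np.log(p)
    return float(np.mean(per))


def focal_loss_and_grad(logits: np.ndarray, y: np.ndarray, params: FocalLossParams):
    """Mean focal loss over a batch and its gradient w.r.t. the logits.

    Class-dependent weighting: alpha for y=1, (1 - alpha) for y=0.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    p = sigmoid(z)
    p_t = np.clip(y * p + (1.0 - y) * (1.0 - p), EPS, 1.0 - EPS)
    a_t = y * params.alpha + (1.0 - y) * (1.0 - params.alpha)
    g = params.gamma
    one_m = 1.0 - p_t
    loss = float(np.mean(-a_t * one_m**g * np.log(p_t)))
    # dL/dp_t then chain through dp_t/dz = (2y - 1) p (1 - p)
    dL_dpt = -a_t * (-g * one_m ** max(g - 1.0, 0.0) * np.log(p_t) + one_m**g / p_t)
    if g == 0.0:
        dL_dpt = -a_t / p_t
    dpt_dz = (2.0 * y - 1.0) * p * (1.0 - p)
    grad = dL_dpt * dpt_dz / len(z)
    return loss, grad


# ---------------------------------------------------------------------------
# layers


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (spatial size preserved)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        std = np.sqrt(2.0 / (c_in * 9))  # He initialization
        self.W = rng.normal(0.0, std, size=(c_in * 9, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.c_in, self.c_out = c_in, c_out
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x):
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # (B, C, H, W, 3, 3) -> (B, H, W, C, 3, 3) -> (B*H*W, C*9)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * 9)
        return np.ascontiguousarray(cols)

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        self._shape = (B, C, H, W)
        cols = self._im2col(x)
        if train:
            self._cols = cols
        out = cols @ self.W + self.b
        return out.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        B, C, H, W = self._shape
        d2 = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(B * H * W, self.c_out)
        self.grads[0][...] = self._cols.T @ d2
        self.grads[1][...] = d2.sum(axis=0)
        # dx as a convolution of dout with the spatially-flipped kernels
        w_flip = self.W.reshape(C, 3, 3, self.c_out)[:, ::-1, ::-1, :]
        w_flip = np.ascontiguousarray(w_flip.transpose(3, 1, 2, 0)).reshape(self.c_out * 9, C)
        dcols = self._im2col(dout)
        dx2 = dcols @ w_flip  # (B*H*W, C)
        self._cols = None
        return dx2.reshape(B, H, W, C).transpose(0, 3, 1, 2)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        h2, w2 = H // 2, W // 2
        xr = x.reshape(B, C, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, h2, w2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = (B, C, H, W)
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        B, C, H, W = self._shape
        h2, w2 = H // 2, W // 2
        dxr = np.zeros((B, C, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        return dxr.reshape(B, C, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)


class AvgPoolK(Layer):
    """(kh x kw) average pooling at stride (kh, kw); the downsampling stem.

    Anisotropic by design: on polar masks the rows (radius) carry wall
    thickness at 1 mm/pixel while columns (angle) are heavily oversampled,
    so the stem can pool angle much harder than radius.
    """

    def __init__(self, k):
        super().__init__()
        self.kh, self.kw = (k, k) if np.isscalar(k) else k

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        self._shape = (B, C, H, W)
        return x.reshape(B, C, H // self.kh, self.kh, W // self.kw, self.kw).mean(axis=(3, 5))

    def backward(self, dout):
        B, C, H, W = self._shape
        out = np.repeat(np.repeat(dout, self.kh, axis=2), self.kw, axis=3)
        return out / (self.kh * self.kw)


class CropRows(Layer):
    """Keep the first ``n`` rows (small radii); the far field of a polar
    mask is empty, so nothing informative is discarded."""

    def __init__(self, n: int):
        super().__init__()
        self.n = n

    def forward(self, x, train=False):
        self._rows = x.shape[2]
        return x[:, :, : self.n, :]

    def backward(self, dout):
        B, C, _, W = dout.shape
        dx = np.zeros((B, C, self._rows, W), dtype=dout.dtype)
        dx[:, :, : self.n, :] = dout
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        std = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, std, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        return dout * self._mask.astype(dout.dtype)


class Network:
    """A sequential stack ending in a single logit; probability via sigmoid."""

    def __init__(self, layers: list, spec: NetworkSpec):
        self.layers = layers
        self.spec = spec

    @property
    def params(self):
        return [p for lay in self.layers for p in lay.params]

    @property
    def grads(self):
        return [g for lay in self.layers for g in lay.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of masks (B, H, W) or (B, 1, H, W)."""
        if x.ndim == 3:
            x = x[:, None, :, :]
        h = np.ascontiguousarray(x, dtype=self.layers_dtype)
        for lay in self.layers:
            h = lay.forward(h, train=train)
        return h[:, 0].astype(np.float64)

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits[:, None].astype(self.layers_dtype)
        for lay in reversed(self.layers):
            g = lay.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(sigmoid(self.forward(x[i : i + batch_size])))
        return np.concatenate(out) if out else np.empty(0)

    @property
    def layers_dtype(self):
        for lay in self.layers:
            if lay.params:
                return lay.params[0].dtype
        return np.float32


_VGG16_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M", 512, 512, 512, "M"]
_VGG_SMALL_WIDTHS = [8, 8, "M", 16, 16, "M", 32, 32, "M", 64, 64, "M"]


def build_network(spec: NetworkSpec, seed: int, dtype=np.float32) -> Network:
    """Seeded construction of the requested architecture."""
    rng = np.random.default_rng(seed)
    layers: list = []
    if spec.architecture == "vgg16":
        c = spec.in_channels
        size = spec.input_size
        for item in _VGG16_CFG:
            if item == "M":
                layers.append(MaxPool2())
                size //= 2
            else:
                layers.append(Conv3x3(c, item, rng, dtype))
                layers.append(ReLU())
                c = item
        layers.append(Flatten())
        layers.append(Dense(c * size * size, 4096, rng, dtype))
        layers.append(ReLU())
        layers.append(Dropout(0.5, rng))
        layers.append(Dense(4096, 4096, rng, dtype))
        layers.append(ReLU())
        layers.append(Dropout(0.5, rng))
        layers.append(Dense(4096, 1, rng, dtype))
    elif spec.architecture == "vgg_small":
        # stem: drop the empty far-radius field, keep radius at full 1 mm
        # resolution (wall thickness is the signal), pool angle 16x
        crop, stem = 64, (1, 16)
        layers.append(CropRows(crop))
        layers.append(AvgPoolK(stem))
        c = spec.in_channels
        h, w = crop // stem[0], spec.input_size // stem[1]
        for item in _VGG_SMALL_WIDTHS:
            if item == "M":
                layers.append(MaxPool2())
                h //= 2
                w //= 2
            else:
                layers.append(Conv3x3(c, item, rng, dtype))
                layers.append(ReLU())
                c = item
        layers.append(Flatten())
        layers.append(Dense(c * h * w, 64, rng, dtype))
        layers.append(ReLU())
        layers.append(Dense(64, 1, rng, dtype))
    else:
        raise ValueError(f"unknown architecture {spec.architecture!r}")
    return Network(layers, spec)


def save_network(path, model: Network, metadata: dict | None = None) -> None:
    """Checkpoint as a compressed array archive with a JSON sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(model.params)}
    np.savez_compressed(path, **arrays)
    side = {
        "architecture": model.spec.architecture,
        "in_channels": model.spec.in_channels,
        "input_size": model.spec.input_size,
        "n_parameters": model.n_parameters(),
    }
    side.update(metadata or {})
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(side, fh, indent=2)


def load_network(path) -> Network:
    import json
    from pathlib import Path

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        side = json.load(fh)
    spec = NetworkSpec(
        architecture=side["architecture"],
        in_channels=side["in_channels"],
        input_size=side["input_size"],
    )
    model = build_network(spec, seed=0)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        for i, p in enumerate(model.params):
            p[...] = z[f"p{i}"]
    return model


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list, learning_rate: float, momentum: float = 0.0):
        self.params = params
        self.lr = learning_rate
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list) -> None:
        for p, g, v in zip(self.params, grads, self.velocity):
            v *= self.momentum
            v -= self.lr * g.astype(v.dtype)
            p += v
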