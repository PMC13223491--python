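"""Desk-scale DnCNN: denoise-then-segment conv/BN/ReLU stack.

The network is the classic residual denoiser pattern — first layer
conv+ReLU, middle layers conv+BN+ReLU, last layer a plain conv — with two
heads: ``denoise`` (predicts the noise map; the clean estimate is input
minus prediction) and ``segment`` (1-channel sigmoid lesion-probability
map, thresholded to a binary mask).  Training runs in host float64 with
Adam and manual backpropagation; inference can be routed through the
emulated CUTIN floating-point backends layer by layer, matching a
deployment where only the forward datapath runs on the accelerator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_closing
from skimage.morphology import disk

from .quantized_conv import ConvLayerSpec, conv2d

__all__ = [
    "NetworkSpec", "TrainConfig", "Network", "build", "train",
    "denoise", "segment", "postprocess", "dice_bce_loss",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkSpec:
    depth: int = 5
    width: int = 16
    kernel: int = 3
    in_channels: int = 1
    residual: bool = True
    head: str = "denoise"

    def __post_init__(self) -> None:
        if self.depth < 3:
            raise ValueError("depth must be at least 3")
        if self.head not in ("denoise", "segment"):
            raise ValueError("head must be 'denoise' or 'segment'")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 4
    seed: int = 0
    mask_threshold: float = 0.5
    dice_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")
        if not 0 < self.mask_threshold < 1:
            raise ValueError("mask threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# layers (batched NHWC tensors, float64)
# ---------------------------------------------------------------------------

class _Conv:
    def __init__(self, k: int, cin: int, cout: int, rng: np.random.Generator):
        # He initialization for ReLU stacks
        std = math.sqrt(2.0 / (k * k * cin))
        self.w = rng.normal(0.0, std, size=(k, k, cin, cout))
        self.b = np.zeros(cout)
        self.k, self.cin, self.cout = k, cin, cout
        self.pad = k // 2

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win: (n, h, w, cin, k, k) -> cols (n*h*w, k*k*cin) in (k,k,cin) order
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * self.cin)
        out = cols @ self.w.reshape(-1, self.cout) + self.b
        if training:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, h, w, self.cout)

    def backward(self, grad: np.ndarray):
        n, h, w, _ = self._xshape
        k, p = self.k, self.pad
        g = grad.reshape(n * h * w, self.cout)
        self.gw = (self._cols.T @ g).reshape(self.w.shape)
        self.gb = g.sum(axis=0)
        # input gradient: scatter the patch gradients back (col2im)
        gcols = (g @ self.w.reshape(-1, self.cout).T) \
            .reshape(n, h, w, k, k, self.cin)
        gx = np.zeros((n, h + 2 * p, w + 2 * p, self.cin))
        for di in range(k):
            for dj in range(k):
                gx[:, di:di + h, dj:dj + w, :] += gcols[:, :, :, di, dj, :]
        return gx[:, p:p + h, p:p + w, :]

    def grads(self):
        return [self.gw, self.gb]


class _BatchNorm:
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            axes = (0, 1, 2)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            self._xhat = (x - mean) / np.sqrt(var + self.eps)
            self._istd = 1.0 / np.sqrt(var + self.eps)
            self._m = x.shape[0] * x.shape[1] * x.shape[2]
            return self._xhat * self.gamma + self.beta
        return (x - self.run_mean) / np.sqrt(self.run_var + self.eps) \
            * self.gamma + self.beta

    def backward(self, grad: np.ndarray):
        xhat, istd, m = self._xhat, self._istd, self._m
        axes = (0, 1, 2)
        self.ggamma = np.sum(grad * xhat, axis=axes)
        self.gbeta = np.sum(grad, axis=axes)
        gxhat = grad * self.gamma
        return istd / m * (m * gxhat - np.sum(gxhat, axis=axes)
                           - xhat * np.sum(gxhat * xhat, axis=axes))

    def grads(self):
        return [self.ggamma, self.gbeta]


class _ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray):
        return grad * self._mask

    def grads(self):
        return []


class _Sigmoid:
    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if training:
            self._out = out
        return out

    def backward(self, grad: np.ndarray):
        return grad * self._out * (1.0 - self._out)

    def grads(self):
        return []


class Network:
    """A DnCNN layer stack with its structural spec."""

    def __init__(self, spec: NetworkSpec, layers: list):
        self.spec = spec
        self.layers = layers

    def parameter_count(self) -> int:
        return sum(p.size for lay in self.layers for p in lay.params())

    def forward(self, x: np.ndarray, training: bool = False,
                backend: str = "exact") -> np.ndarray:
        """Forward pass; ``backend`` routes conv layers through the emulated
        arithmetic (single image or batch; emulated backends run per-sample)."""
        if backend == "exact":
            for lay in self.layers:
                x = lay.forward(x, training)
            return x
        if training:
            raise ValueError("emulated backends are inference-only")
        for lay in self.layers:
            if isinstance(lay, _Conv):
                spec = ConvLayerSpec(lay.k, lay.cin, lay.cout,
                                     padding=lay.pad, backend=backend)
                x = np.stack([conv2d(xi, lay.w, spec, bias=lay.b)
                              for xi in x])
            else:
                x = lay.forward(x, False)
        return x

    def predict(self, image: np.ndarray, backend: str = "exact") -> np.ndarray:
        """Single-image H×W (or H×W×C) forward; returns H×W map."""
        x = np.asarray(image, dtype=np.float64)
        if x.ndim == 2:
            x = x[:, :, None]
        out = self.forward(x[None], training=False, backend=backend)[0]
        if self.spec.head == "denoise" and self.spec.residual:
            out = x - out
        return out[:, :, 0]


def build(spec: NetworkSpec, seed: int = 0) -> Network:
    """Assemble the layer stack: conv+ReLU, (depth-2)×[conv+BN+ReLU], conv
    (+sigmoid for the segment head)."""
    rng = np.random.default_rng(seed)
    k, w, cin = spec.kernel, spec.width, spec.in_channels
    layers: list = [_Conv(k, cin, w, rng), _ReLU()]
    for _ in range(spec.depth - 2):
        layers += [_Conv(k, w, w, rng), _BatchNorm(w), _ReLU()]
    layers.append(_Conv(k, w, 1, rng))
    if spec.head == "segment":
        layers.append(_Sigmoid())
    return Network(spec, layers)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    return 0.5 * float(np.mean(diff * diff)), diff / diff.size


def dice_bce_loss(p: np.ndarray, t: np.ndarray, dice_weight: float = 0.5,
                  eps: float = 1e-7, smooth: float = 1.0):
    """Weighted Dice + binary cross-entropy on probabilities; returns
    (loss, dL/dp)."""
    p = np.clip(p, eps, 1.0 - eps)
    n = p.size
    bce = -float(np.mean(t * np.log(p) + (1 - t) * np.log(1 - p)))
    gbce = (p - t) / (p * (1 - p)) / n
    inter = float(np.sum(p * t))
    denom = float(np.sum(p) + np.sum(t)) + smooth
    dice = 1.0 - (2 * inter + smooth) / denom
    gdice = -(2 * t * denom - (2 * inter + smooth)) / denom**2
    w = dice_weight
    return (1 - w) * bce + w * dice, (1 - w) * gbce + w * gdice


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def train(net: Network, dataset: list[tuple[np.ndarray, np.ndarray]],
          cfg: TrainConfig) -> list[float]:
    """Train in host arithmetic; returns the per-epoch mean loss trace.

    ``dataset`` holds (input image, target) pairs: target is the clean image
    for the denoise head (residual networks learn input − clean internally)
    or the binary mask for the segment head.  Fully deterministic under
    ``cfg.seed``; a NaN loss aborts with a diagnostic.
    """
    rng = np.random.default_rng(cfg.seed)
    xs = np.stack([np.asarray(x, dtype=np.float64)[:, :, None]
                   if np.asarray(x).ndim == 2 else np.asarray(x)
                   for x, _ in dataset])
    ts = np.stack([np.asarray(t, dtype=np.float64)[:, :, None]
                   if np.asarray(t).ndim == 2 else np.asarray(t)
                   for _, t in dataset])
    if net.spec.head == "denoise" and net.spec.residual:
        ts = xs - ts            # residual target: the noise map
    params = [p for lay in net.layers for p in lay.params()]
    opt = _Adam(params, cfg.learning_rate)
    trace: list[float] = []
    n = len(dataset)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, tb = xs[idx], ts[idx]
            out = net.forward(xb, training=True)
            if net.spec.head == "segment":
                loss, grad = dice_bce_loss(out, tb, cfg.dice_weight)
            else:
                loss, grad = _mse_loss(out, tb)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss {loss!r} at epoch "
                    f"{_epoch} (lr={cfg.learning_rate})")
            for lay in reversed(net.layers):
                grad = lay.backward(grad)
            opt.step([g for lay in net.layers for g in lay.grads()])
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return trace


def denoise(net: Network, image: np.ndarray,
            backend: str = "exact") -> np.ndarray:
    """Clean-image estimate from a denoise-head network."""
    if net.spec.head != "denoise":
        raise ValueError("network does not have a denoise head")
    return np.clip(net.predict(image, backend=backend), 0.0, 1.0)


def segment(net: Network, image: np.ndarray, threshold: float = 0.5,
            backend: str = "exact") -> np.ndarray:
    """Binary lesion mask: sigmoid probability map thresholded at
    ``threshold`` (inclusive)."""
    if net.spec.head != "segment":
        raise ValueError("network does not have a segment head")
    prob = net.predict(image, backend=backend)
    return (prob >= threshold).astype(np.uint8)


def save_checkpoint(net: Network, path) -> None:
    """Self-describing archive: structural spec plus every parameter array."""
    import json

    arrays: dict[str, np.ndarray] = {}
    for i, lay in enumerate(net.layers):
        for j, p in enumerate(lay.params()):
            arrays[f"layer{i}_p{j}"] = p
        if isinstance(lay, _BatchNorm):
            arrays[f"layer{i}_rmean"] = lay.run_mean
            arrays[f"layer{i}_rvar"] = lay.run_var
    spec = net.spec
    meta = json.dumps({
        "depth": spec.depth, "width": spec.width, "kernel": spec.kernel,
        "in_channels": spec.in_channels, "residual": spec.residual,
        "head": spec.head,
    })
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> Network:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        spec = NetworkSpec(**meta)
        net = build(spec, seed=0)
        for i, lay in enumerate(net.layers):
            for j, p in enumerate(lay.params()):
                p[...] = z[f"layer{i}_p{j}"]
            if isinstance(lay, _BatchNorm):
                lay.run_mean = z[f"layer{i}_rmean"]
                lay.run_var = z[f"layer{i}_rvar"]
    return net


def postprocess(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological closing (dilate then erode) with a disk element.

    Fills pinholes and smooths the lesion border; radius 0 is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    m = np.asarray(mask).astype(bool)
    if radius == 0:
        return m.astype(np.uint8)
    return binary_closing(m, structure=disk(radius)).astype(np.uint8)
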