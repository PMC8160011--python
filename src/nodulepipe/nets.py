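"""2D U-Net and Res-U-Net built on a small numpy autodiff core.

The segmentation networks are encoder-decoder graphs: each encoder
level applies two 3x3 same-padded convolutions with LeakyReLU
(negative-side slope alpha, default 0.3) and halves the spatial dims by
2x2 max-pooling; the decoder mirrors this with 2x2 transposed
convolutions and fuses encoder features by channel concatenation (not
addition).  The residual variant wraps each level's convolution pair in
a residual block: branch output plus an identity shortcut, with a 1x1
projection when channel counts differ.  Weights use He initialization
(std sqrt(2 / fan_in)) from a caller-supplied seed; the terminal
nonlinearity is a per-channel sigmoid, so the channels of a hybrid
two-channel head are independent.

Everything here is plain numpy with hand-written forward/backward
passes and an Adam optimizer, sized for CPU-scale experiments.  Arrays
are (N, C, H, W) float32; forward passes are deterministic, and two
builds from one seed are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SegModelSpec", "ModelHandle", "build_unet", "build_res_unet", "Adam"]


# ---------------------------------------------------------------------------
# primitives

def _conv2d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 same-padded 2D convolution; x (N,C,H,W), w (O,C,k,k)."""
    k = w.shape[2]
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    view = sliding_window_view(x, (k, k), axis=(2, 3))
    return np.einsum("nchwij,ocij->nohw", view, w, optimize=True)


class _Conv(object):
    """3x3 (or 1x1) same-padded convolution layer with bias."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 zero_init: bool = False):
        fan_in = in_ch * k * k
        std = np.sqrt(2.0 / fan_in)
        if zero_init:
            self.w = np.zeros((out_ch, in_ch, k, k), dtype=np.float32)
        else:
            self.w = rng.normal(0.0, std, (out_ch, in_ch, k, k)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return _conv2d_same(x, self.w) + self.b[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, w = self._x, self.w
        k = w.shape[2]
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        view = sliding_window_view(xp, (k, k), axis=(2, 3))
        self.gw += np.einsum("nchwij,nohw->ocij", view, g, optimize=True)
        self.gb += g.sum(axis=(0, 2, 3))
        # input gradient = correlation with the flipped, transposed kernel
        w_flip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return _conv2d_same(g, w_flip)

    def params(self):
        return [("w", self), ("b", self)]


class _LeakyReLU:
    def __init__(self, alpha: float):
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, self.alpha * g)


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(out, self._idx[..., None], g[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class _UpConv2:
    """2x2 stride-2 transposed convolution; doubles the spatial dims."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / in_ch)  # fan_in = in_ch * 1 * 1 per output position
        self.w = rng.normal(0.0, std, (in_ch, out_ch, 2, 2)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        o = self.w.shape[1]
        t = np.einsum("ncij,coab->noiajb", x, self.w, optimize=True)
        return t.reshape(n, o, 2 * h, 2 * w) + self.b[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        o = self.w.shape[1]
        gr = g.reshape(n, o, h, 2, w, 2)
        self.gw += np.einsum("ncij,noiajb->coab", x, gr, optimize=True)
        self.gb += g.sum(axis=(0, 2, 3))
        return np.einsum("noiajb,coab->ncij", gr, self.w, optimize=True)


class _ConvBlock:
    """Two conv+LeakyReLU stages, optionally wrapped as a residual block.

    Residual form: branch(x) + shortcut(x), identity shortcut when the
    channel counts match, 1x1 projection otherwise; no activation after
    the addition so a zero branch reduces to the shortcut exactly.
    """

    def __init__(self, in_ch: int, out_ch: int, alpha: float, residual: bool,
                 rng: np.random.Generator):
        self.residual = residual
        self.conv1 = _Conv(in_ch, out_ch, 3, rng)
        self.act1 = _LeakyReLU(alpha)
        self.conv2 = _Conv(out_ch, out_ch, 3, rng)
        self.act2 = _LeakyReLU(alpha)
        self.proj = None
        if residual and in_ch != out_ch:
            self.proj = _Conv(in_ch, out_ch, 1, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.act2.forward(self.conv2.forward(self.act1.forward(self.conv1.forward(x))))
        if not self.residual:
            return y
        short = self.proj.forward(x) if self.proj is not None else x
        return y + short

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx = self.conv1.backward(self.act1.backward(
            self.conv2.backward(self.act2.backward(g))))
        if self.residual:
            gx = gx + (self.proj.backward(g) if self.proj is not None else g)
        return gx

    def layers(self):
        out = [self.conv1, self.conv2]
        if self.proj is not None:
            out.append(self.proj)
        return out


# ---------------------------------------------------------------------------
# model spec and graph

@dataclass(frozen=True)
class SegModelSpec:
    """Declarative architecture description for U-Net / Res-U-Net."""

    depth: int = 2
    base_channels: int = 8
    channel_growth: int = 2
    in_channels: int = 1
    out_channels: int = 1
    activation_slope: float = 0.3
    residual: bool = False
    init_scheme: str = "he"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.out_channels not in (1, 2):
            raise ValueError("out_channels must be 1 (mono) or 2 (hybrid)")
        if self.init_scheme != "he":
            raise ValueError(f"unknown init scheme {self.init_scheme!r}")


class _UNetGraph:
    """Hand-wired forward/backward for the (Res-)U-Net topology."""

    def __init__(self, spec: SegModelSpec, seed: int):
        rng = np.random.default_rng(seed)
        self.spec = spec
        d, g = spec.depth, spec.channel_growth
        chans = [spec.base_channels * g ** i for i in range(d + 1)]

        self.enc_blocks = []
        self.pools = []
        in_ch = spec.in_channels
        for i in range(d):
            self.enc_blocks.append(_ConvBlock(in_ch, chans[i], spec.activation_slope,
                                              spec.residual, rng))
            self.pools.append(_MaxPool2())
            in_ch = chans[i]
        self.bottleneck = _ConvBlock(in_ch, chans[d], spec.activation_slope,
                                     spec.residual, rng)

        self.upconvs = []
        self.dec_blocks = []
        up_in = chans[d]
        for i in reversed(range(d)):
            self.upconvs.append(_UpConv2(up_in, chans[i], rng))
            self.dec_blocks.append(_ConvBlock(2 * chans[i], chans[i],
                                              spec.activation_slope, spec.residual, rng))
            up_in = chans[i]
        self.head = _Conv(up_in, spec.out_channels, 1, rng)

    # -- graph traversal ----------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        d = self.spec.depth
        div = 2 ** d
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"input spatial dims {x.shape[2:]} must be divisible by 2^depth = {div}"
            )
        skips = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        for up, blk, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            h = up.forward(h)
            h = blk.forward(np.concatenate([skip, h], axis=1))
        z = self.head.forward(h)
        # numerically stable logistic
        self._y = np.where(z >= 0,
                           1.0 / (1.0 + np.exp(-np.abs(z))),
                           np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z)))
                           ).astype(np.float32)
        return self._y

    def backward(self, gy: np.ndarray) -> None:
        g = (gy * self._y * (1.0 - self._y)).astype(np.float32)
        g = self.head.backward(g)
        skip_grads = []
        for up, blk in zip(reversed(self.upconvs), reversed(self.dec_blocks)):
            g = blk.backward(g)
            c = g.shape[1] // 2
            skip_grads.append(g[:, :c])
            g = up.backward(g[:, c:])
        g = self.bottleneck.backward(g)
        # skip_grads were collected shallowest-first; encoder unwinds deepest-first
        for blk, pool, gskip in zip(reversed(self.enc_blocks), reversed(self.pools),
                                    reversed(skip_grads)):
            g = pool.backward(g)
            g = blk.backward(g + gskip)

    # -- parameters ----------------------------------------------------------
    def param_layers(self):
        layers = []
        for blk in self.enc_blocks:
            layers.extend(blk.layers())
        layers.extend(self.bottleneck.layers())
        for up, blk in zip(self.upconvs, self.dec_blocks):
            layers.append(up)
            layers.extend(blk.layers())
        layers.append(self.head)
        return layers

    def param_arrays(self):
        out = []
        for lyr in self.param_layers():
            out.append(lyr.w)
            out.append(lyr.b)
        return out

    def grad_arrays(self):
        out = []
        for lyr in self.param_layers():
            out.append(lyr.gw)
            out.append(lyr.gb)
        return out

    def zero_grads(self) -> None:
        for g in self.grad_arrays():
            g[...] = 0.0


class Adam:
    """Adam optimizer over a graph's parameter arrays (in-place updates)."""

    def __init__(self, graph: _UNetGraph, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.graph = graph
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in graph.param_arrays()]
        self.v = [np.zeros_like(p) for p in graph.param_arrays()]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.graph.param_arrays(), self.graph.grad_arrays(),
                              self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class ModelHandle:
    """A built (possibly trained) network plus its spec and seed."""

    graph: _UNetGraph
    spec: SegModelSpec
    seed: int

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.graph.param_arrays()))

    def predict(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Forward pass; x is (N, C, H, W) or (C, H, W); output in [0, 1]."""
        x = np.asarray(x, dtype=np.float32)
        single = x.ndim == 3
        if single:
            x = x[None]
        outs = [self.graph.forward(x[i:i + batch_size])
                for i in range(0, x.shape[0], batch_size)]
        y = np.concatenate(outs, axis=0)
        return y[0] if single else y

    def save(self, path: str | Path) -> Path:
        """Checkpoint: npz weights + JSON spec sidecar (self-describing)."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.graph.param_arrays())}
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {"spec": asdict(self.spec), "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "ModelHandle":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        spec = SegModelSpec(**sidecar["spec"])
        handle = build_model(spec, seed=sidecar["seed"])
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(handle.graph.param_arrays()):
                p[...] = data[f"p{i}"]
        return handle


def build_unet(spec: SegModelSpec, seed: int = 0) -> ModelHandle:
    """Build a plain U-Net (spec.residual must be False)."""
    if spec.residual:
        raise ValueError("build_unet requires residual=False; use build_res_unet")
    return ModelHandle(graph=_UNetGraph(spec, seed), spec=spec, seed=seed)


def build_res_unet(spec: SegModelSpec, seed: int = 0) -> ModelHandle:
    """Build a Res-U-Net (spec.residual must be True)."""
    if not spec.residual:
        raise ValueError("build_res_unet requires residual=True")
    return ModelHandle(graph=_UNetGraph(spec, seed), spec=spec, seed=seed)


def build_model(spec: SegModelSpec, seed: int = 0) -> ModelHandle:
    return build_res_unet(spec, seed) if spec.residual else build_unet(spec, seed)


# ---------------------------------------------------------------------------
# training-side loss gradient (soft dice over (sample, channel) pairs)

def dice_loss_and_grad(pred: np.ndarray, target: np.ndarray,
                       eps: float = 1e-6) -> tuple[float, np.ndarray]:
    """Soft dice loss averaged over (sample, channel) pairs, with gradient.

    For each sample n and channel c, L = 1 - (2 S_pt + eps)/(S_p + S_t + eps)
    with sums over the spatial dims; the batch loss is the mean over all
    (n, c), which for a hybrid head equals the mean of the per-channel
    dice losses.  Returns (loss, dL/dpred).
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    s_pt = np.sum(pred * target, axis=(2, 3))
    s_p = np.sum(pred, axis=(2, 3))
    s_t = np.sum(target, axis=(2, 3))
    num = 2.0 * s_pt + eps
    den = s_p + s_t + eps
    loss = float(np.mean(1.0 - num / den))
    n_terms = pred.shape[0] * pred.shape[1]
    grad = -(2.0 * target * den[..., None, None] - num[..., None, None]) \
        / den[..., None, None] ** 2 / n_terms
    return loss, grad.astype(np.float32)
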