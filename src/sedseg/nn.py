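"""A compact NumPy neural-network engine for the segmentation models.

Implements exactly the layer vocabulary the two cascade stages need —
3x3/1x1 convolutions, 2x2 max pooling, transposed convolutions, batch
normalization, ReLU/sigmoid, dropout, channel concatenation and dense
blocks — with hand-derived reverse-mode gradients and an Adam optimizer.

Tensors are ``float32`` in channel-last ``(batch, height, width,
channels)`` layout; a KxK convolution is computed as K*K shifted
matrix products ``x[:, u:u+H, v:v+W, :] @ W[u, v]``, which lowers
straight onto BLAS without materializing an im2col buffer.

The engine is deliberately small and deterministic: given a seed, weight
initialization, dropout masks and therefore whole training runs are
reproducible on a single thread.

:class:`GraphModel` compiles a :class:`~sedseg.netgraph.LayerGraph` into
an executable network, so the same declarative topology that is verified
symbolically is the one that runs.
"""

from __future__ import annotations

import pickle
from typing import Sequence

import numpy as np
from numba import njit

from .netgraph import GraphError, LayerGraph, propagate_shapes

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "Sequential",
    "DenseBlock",
    "GraphModel",
    "Adam",
    "soft_dice_batch",
    "dice_loss_and_grad",
]

F32 = np.float32


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


# ---------------------------------------------------------------------------
# stride-1 correlation primitive (shared by Conv2d / ConvTranspose2d)
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, lo: int, hi: int | None = None) -> np.ndarray:
    hi = lo if hi is None else hi
    if lo == 0 and hi == 0:
        return x
    return np.pad(x, ((0, 0), (lo, hi), (lo, hi), (0, 0)))


def _corr(xp: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Correlate padded ``xp`` (B,Hp,Wp,C) with ``w`` (k,k,C,O) -> (B,H,W,O)."""
    k = w.shape[0]
    h = xp.shape[1] - k + 1
    wd = xp.shape[2] - k + 1
    y = xp[:, 0:h, 0:wd, :] @ w[0, 0]
    for u in range(k):
        for v in range(k):
            if u == 0 and v == 0:
                continue
            y += xp[:, u : u + h, v : v + wd, :] @ w[u, v]
    return y


def _corr_dw(xp: np.ndarray, dy: np.ndarray, k: int) -> np.ndarray:
    """Weight gradient of :func:`_corr`: (k,k,C,O)."""
    h, wd = dy.shape[1], dy.shape[2]
    dw = np.empty((k, k, xp.shape[3], dy.shape[3]), dtype=F32)
    for u in range(k):
        for v in range(k):
            dw[u, v] = np.tensordot(xp[:, u : u + h, v : v + wd, :], dy,
                                    axes=([0, 1, 2], [0, 1, 2]))
    return dw


def _corr_dxp(dy: np.ndarray, w: np.ndarray, xp_shape: tuple) -> np.ndarray:
    """Gradient w.r.t. the *padded* input of :func:`_corr`."""
    k = w.shape[0]
    h, wd = dy.shape[1], dy.shape[2]
    dxp = np.zeros(xp_shape, dtype=F32)
    for u in range(k):
        for v in range(k):
            dxp[:, u : u + h, v : v + wd, :] += dy @ w[u, v].T
    return dxp


# ---------------------------------------------------------------------------
# fused elementwise kernels (single memory pass; large channel-last tensors)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _bn_stats(x2):
    n, c = x2.shape
    s = np.zeros(c, np.float64)
    ss = np.zeros(c, np.float64)
    for i in range(n):
        for j in range(c):
            v = x2[i, j]
            s[j] += v
            ss[j] += v * v
    mean = np.empty(c, np.float32)
    var = np.empty(c, np.float32)
    for j in range(c):
        m = s[j] / n
        mean[j] = m
        v = ss[j] / n - m * m
        var[j] = v if v > 0.0 else 0.0
    return mean, var


@njit(cache=True)
def _bn_affine(x2, mean, istd, gamma, beta, out2):
    n, c = x2.shape
    for i in range(n):
        for j in range(c):
            out2[i, j] = (x2[i, j] - mean[j]) * istd[j] * gamma[j] + beta[j]


@njit(cache=True)
def _bn_bwd_stats(x2, dy2, mean, istd):
    n, c = x2.shape
    s1 = np.zeros(c, np.float64)
    s2 = np.zeros(c, np.float64)
    for i in range(n):
        for j in range(c):
            d = dy2[i, j]
            s1[j] += d
            s2[j] += d * (x2[i, j] - mean[j]) * istd[j]
    return s1.astype(np.float32), s2.astype(np.float32)


@njit(cache=True)
def _bn_bwd_dx(x2, dy2, mean, istd, gamma, s1n, s2n, out2):
    n, c = x2.shape
    for i in range(n):
        for j in range(c):
            xhat = (x2[i, j] - mean[j]) * istd[j]
            out2[i, j] = gamma[j] * istd[j] * (dy2[i, j] - s1n[j] - xhat * s2n[j])


@njit(cache=True)
def _relu_bwd(y2, dy2, out2):
    n, c = y2.shape
    for i in range(n):
        for j in range(c):
            out2[i, j] = dy2[i, j] if y2[i, j] > 0.0 else 0.0


def _flat2(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x).reshape(-1, x.shape[-1])


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    train_mode = True

    def params(self) -> list:
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 "same"-padded convolution with bias (odd kernel size)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator) -> None:
        if k % 2 != 1:
            raise ValueError("Conv2d supports odd kernel sizes only")
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, std, size=(k, k, cin, cout)))
        self.b = Param(np.zeros(cout))
        self.k, self.p = k, k // 2
        self._xp = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._xp = _pad_hw(x, self.p)
        return _corr(self._xp, self.w.value) + self.b.value

    def backward(self, dy):
        self.w.grad += _corr_dw(self._xp, dy, self.k)
        self.b.grad += dy.sum(axis=(0, 1, 2))
        dxp = _corr_dxp(dy, self.w.value, self._xp.shape)
        p = self.p
        if p == 0:
            return dxp
        return np.ascontiguousarray(dxp[:, p:-p, p:-p, :])


class ConvTranspose2d(Layer):
    """Stride-2 transposed convolution that exactly doubles H and W.

    Supported kernels: k=2 (non-overlapping, the classic U-Net up step)
    and k=3 with padding 1 / output padding 1 (the dense-path transition
    up).  Lowered to zero-dilation followed by a stride-1 correlation
    with the flipped kernel.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator) -> None:
        if k not in (2, 3):
            raise ValueError("ConvTranspose2d supports k=2 or k=3 only")
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, std, size=(k, k, cin, cout)))
        self.b = Param(np.zeros(cout))
        self.k = k
        # output = (H-1)*2 - 2p + k + op == 2H for (k=2, p=0, op=0) and
        # (k=3, p=1, op=1)
        self.p_lo = k - 1 - (0 if k == 2 else 1)
        self.p_hi = self.p_lo + (0 if k == 2 else 1)

    def params(self):
        return [self.w, self.b]

    def _dilate(self, x):
        b, h, w, c = x.shape
        lo, hi = self.p_lo, self.p_hi
        xd = np.zeros((b, 2 * h - 1 + lo + hi, 2 * w - 1 + lo + hi, c), dtype=F32)
        xd[:, lo : lo + 2 * h - 1 : 2, lo : lo + 2 * w - 1 : 2, :] = x
        return xd

    def forward(self, x):
        self._in_shape = x.shape
        self._xd = self._dilate(x)
        wf = self.w.value[::-1, ::-1]  # flipped: transposed conv == correlation
        return _corr(self._xd, wf) + self.b.value

    def backward(self, dy):
        dwf = _corr_dw(self._xd, dy, self.k)
        self.w.grad += dwf[::-1, ::-1]
        self.b.grad += dy.sum(axis=(0, 1, 2))
        dxd = _corr_dxp(dy, self.w.value[::-1, ::-1], self._xd.shape)
        h, w = self._in_shape[1:3]
        lo = self.p_lo
        return np.ascontiguousarray(
            dxd[:, lo : lo + 2 * h - 1 : 2, lo : lo + 2 * w - 1 : 2, :]
        )


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; ties route the gradient to one winner."""

    def forward(self, x):
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d: odd spatial size {(h, w)}")
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = np.ascontiguousarray(xr).reshape(b, h // 2, w // 2, c, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        b, h, w, c = self._shape
        dflat = np.zeros((b, h // 2, w // 2, c, 4), dtype=F32)
        np.put_along_axis(dflat, self._idx[..., None], dy[..., None], axis=-1)
        return np.ascontiguousarray(
            dflat.reshape(b, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(b, h, w, c)
        )


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        x2 = _flat2(x)
        if self.train_mode:
            mean, var = _bn_stats(x2)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._mean = np.asarray(mean, dtype=F32)
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        self._x2 = x2
        out = np.empty_like(x2)
        _bn_affine(x2, self._mean, self._istd, self.gamma.value, self.beta.value, out)
        return out.reshape(x.shape)

    def backward(self, dy):
        dy2 = _flat2(dy)
        s1, s2 = _bn_bwd_stats(self._x2, dy2, self._mean, self._istd)
        self.gamma.grad += s2
        self.beta.grad += s1
        if not self.train_mode:
            return dy * (self.gamma.value * self._istd)
        n = F32(dy2.shape[0])
        out = np.empty_like(dy2)
        _bn_bwd_dx(self._x2, dy2, self._mean, self._istd, self.gamma.value,
                   s1 / n, s2 / n, out)
        return out.reshape(dy.shape)


class ReLU(Layer):
    def forward(self, x):
        self._y = np.maximum(x, F32(0.0))
        return self._y

    def backward(self, dy):
        y2, dy2 = _flat2(self._y), _flat2(dy)
        out = np.empty_like(dy2)
        _relu_bwd(y2, dy2, out)
        return out.reshape(dy.shape)


class Sigmoid(Layer):
    def forward(self, x):
        x = np.clip(x, -60.0, 60.0)
        self._y = (1.0 / (1.0 + np.exp(-x))).astype(F32)
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator) -> None:
        self.p, self.rng = float(p), rng

    def forward(self, x):
        if not self.train_mode or self.p == 0.0:
            self._mask = None
            return x
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u >= self.p).astype(F32) / F32(1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class DenseBlock(Layer):
    """``n_layers`` dense layers, each BN -> ReLU -> 3x3 conv (growth_rate
    maps) -> dropout, concatenated onto the running feature stack.

    ``concat_with_input`` mode emits the input plus all new features
    (encoder blocks); ``new_features_only`` emits just the new features
    (decoder blocks).  In both modes the *new* features occupy the
    trailing ``n_layers * growth_rate`` channels of the output, which is
    what a following transition-up consumes.
    """

    def __init__(self, cin: int, n_layers: int, growth_rate: int, mode: str,
                 dropout: float, rng: np.random.Generator) -> None:
        if mode not in ("concat_with_input", "new_features_only"):
            raise ValueError(f"unknown dense-block mode {mode!r}")
        if n_layers == 0 and mode == "new_features_only":
            raise ValueError("a 0-layer dense block in new_features_only mode is empty")
        self.cin, self.n, self.k, self.mode = cin, n_layers, growth_rate, mode
        self.sublayers = [
            Sequential(
                BatchNorm2d(cin + i * growth_rate),
                ReLU(),
                Conv2d(cin + i * growth_rate, growth_rate, 3, rng),
                Dropout(dropout, rng),
            )
            for i in range(n_layers)
        ]

    def params(self):
        return [p for l in self.sublayers for p in l.params()]

    def forward(self, x):
        feats = [x]
        for layer in self.sublayers:
            feats.append(layer.forward(np.concatenate(feats, axis=-1)))
        self._widths = [f.shape[-1] for f in feats]
        if self.mode == "concat_with_input":
            return np.concatenate(feats, axis=-1)
        return np.concatenate(feats[1:], axis=-1)

    def backward(self, dy):
        k = self.k
        if self.mode == "concat_with_input":
            offs = np.cumsum([0] + self._widths)
            grads = [np.ascontiguousarray(dy[..., offs[i] : offs[i + 1]])
                     for i in range(self.n + 1)]
        else:
            grads = [np.zeros(dy.shape[:-1] + (self.cin,), dtype=F32)]
            grads += [np.ascontiguousarray(dy[..., i * k : (i + 1) * k])
                      for i in range(self.n)]
        for i in range(self.n - 1, -1, -1):
            dcat = self.sublayers[i].backward(grads[i + 1])
            off = 0
            for j, w in enumerate(self._widths[: i + 1]):
                grads[j] = grads[j] + dcat[..., off : off + w]
                off += w
        return grads[0]


# ---------------------------------------------------------------------------
# graph compiler
# ---------------------------------------------------------------------------

class _Slice(Layer):
    """Pass through the trailing ``n`` channels (transition-up feed)."""

    def __init__(self, n: int) -> None:
        self.n = n

    def forward(self, x):
        self._cin = x.shape[-1]
        return np.ascontiguousarray(x[..., -self.n :])

    def backward(self, dy):
        dx = np.zeros(dy.shape[:-1] + (self._cin,), dtype=F32)
        dx[..., -self.n :] = dy
        return dx


class GraphModel:
    """Executable network compiled from a :class:`LayerGraph`.

    The compiler walks the graph in topological order, asks the symbolic
    shape engine for every node's input width, and instantiates the layer
    stack for each node kind.  Forward and backward traverse the same
    order, accumulating gradients at fan-out points.  Inputs and outputs
    are ``(batch, H, W, channels)`` arrays.
    """

    def __init__(self, graph: LayerGraph, input_size: tuple, seed: int = 0,
                 dropout: float = 0.2) -> None:
        self.graph = graph
        self.input_size = tuple(input_size)
        self.rng = np.random.default_rng(seed)
        shapes = propagate_shapes(graph, input_size)
        self._shapes = shapes
        self.layers: dict[str, Layer] = {}
        self.output_name = graph.names[-1]
        rng = self.rng
        for node in graph:
            cin = shapes[node.inputs[0]].channels if node.inputs else input_size[2]
            cout = shapes[node.name].channels
            if node.kind == "input":
                continue
            if node.kind == "conv":
                self.layers[node.name] = Conv2d(cin, cout, 3, rng)
            elif node.kind == "conv_block":
                self.layers[node.name] = Sequential(
                    Conv2d(cin, cout, 3, rng), ReLU(),
                    Conv2d(cout, cout, 3, rng), ReLU(),
                )
            elif node.kind == "pool":
                self.layers[node.name] = MaxPool2d()
            elif node.kind == "up":
                self.layers[node.name] = ConvTranspose2d(cin, cout, 2, rng)
            elif node.kind == "dense_block":
                self.layers[node.name] = DenseBlock(
                    cin, node.params["n_layers"], node.params["growth_rate"],
                    node.params.get("mode", "concat_with_input"), dropout, rng,
                )
            elif node.kind == "transition_down":
                self.layers[node.name] = Sequential(
                    BatchNorm2d(cin), ReLU(), Conv2d(cin, cin, 1, rng),
                    Dropout(dropout, rng), MaxPool2d(),
                )
            elif node.kind == "transition_up":
                self.layers[node.name] = Sequential(
                    _Slice(cout), ConvTranspose2d(cout, cout, 3, rng)
                )
            elif node.kind == "concat":
                self.layers[node.name] = None  # handled inline
            elif node.kind == "conv1x1_out":
                self.layers[node.name] = Sequential(Conv2d(cin, cout, 1, rng), Sigmoid())
            else:  # pragma: no cover
                raise GraphError(f"cannot compile node kind {node.kind!r}")

    # -- parameter access ----------------------------------------------
    def params(self) -> list:
        out = []
        for name in self.graph.names:
            layer = self.layers.get(name)
            if layer is not None:
                out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def set_train(self, mode: bool) -> None:
        def _set(layer):
            layer.train_mode = mode
            for sub in getattr(layer, "layers", []):
                _set(sub)
            for sub in getattr(layer, "sublayers", []):
                _set(sub)
        for layer in self.layers.values():
            if layer is not None:
                _set(layer)

    # -- execution -------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError("expected a (batch, H, W, channel) array")
        if x.shape[1:] != (self.input_size[0], self.input_size[1], self.input_size[2]):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match configured "
                f"{self.input_size}"
            )
        self.set_train(train)
        x = np.ascontiguousarray(x, dtype=F32)
        self._cache: dict[str, np.ndarray] = {}
        for node in self.graph:
            if node.kind == "input":
                self._cache[node.name] = x
            elif node.kind == "concat":
                self._cache[node.name] = np.concatenate(
                    [self._cache[i] for i in node.inputs], axis=-1
                )
            else:
                self._cache[node.name] = self.layers[node.name].forward(
                    self._cache[node.inputs[0]]
                )
        return self._cache[self.output_name]

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)

    def backward(self, dy: np.ndarray):
        grads: dict[str, np.ndarray] = {self.output_name: np.asarray(dy, dtype=F32)}
        for node in reversed(list(self.graph)):
            g = grads.pop(node.name, None)
            if node.kind == "input":
                return g
            if g is None:
                continue
            if node.kind == "concat":
                off = 0
                for src in node.inputs:
                    w = self._cache[src].shape[-1]
                    piece = np.ascontiguousarray(g[..., off : off + w])
                    grads[src] = grads[src] + piece if src in grads else piece
                    off += w
            else:
                dx = self.layers[node.name].backward(g)
                src = node.inputs[0]
                grads[src] = grads[src] + dx if src in grads else dx
        return None  # pragma: no cover

    # -- checkpointing ----------------------------------------------------
    def state_dict(self) -> dict:
        state = {"params": [p.value.copy() for p in self.params()], "bn": []}
        for name in self.graph.names:
            layer = self.layers.get(name)
            if layer is None:
                continue
            for bn in _iter_bn(layer):
                state["bn"].append((bn.running_mean.copy(), bn.running_var.copy()))
        return state

    def load_state_dict(self, state: dict) -> None:
        params = self.params()
        if len(params) != len(state["params"]):
            raise ValueError("checkpoint does not match model")
        for p, v in zip(params, state["params"]):
            p.value[...] = v
        bns = [bn for name in self.graph.names if self.layers.get(name) is not None
               for bn in _iter_bn(self.layers[name])]
        for bn, (m, v) in zip(bns, state["bn"]):
            bn.running_mean[...] = m
            bn.running_var[...] = v

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"graph": self.graph.to_dict(),
                         "input_size": self.input_size,
                         "state": self.state_dict()}, fh)

    @classmethod
    def load(cls, path) -> "GraphModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        model = cls(LayerGraph.from_dict(blob["graph"]), tuple(blob["input_size"]))
        model.load_state_dict(blob["state"])
        return model


def _iter_bn(layer):
    if isinstance(layer, BatchNorm2d):
        yield layer
    for sub in getattr(layer, "layers", []):
        yield from _iter_bn(sub)
    for sub in getattr(layer, "sublayers", []):
        yield from _iter_bn(sub)


# ---------------------------------------------------------------------------
# optimizer and loss
# ---------------------------------------------------------------------------

class Adam:
    """Adam with framework-default moments (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def soft_dice_batch(a: np.ndarray, b: np.ndarray, eps: float = 1.0) -> np.ndarray:
    """Per-sample soft Dice 2*sum(ab)/(sum(a^2)+sum(b^2)) with smoothing.

    ``a`` and ``b`` are (B, H, W, 1) (any trailing dims); returns a
    length-B vector.
    """
    axes = tuple(range(1, a.ndim))
    num = 2.0 * (a * b).sum(axis=axes) + eps
    den = (a * a).sum(axis=axes) + (b * b).sum(axis=axes) + eps
    return num / den


def dice_loss_and_grad(a: np.ndarray, b: np.ndarray, eps: float = 1.0):
    """Mean (over batch) soft-Dice loss and its gradient w.r.t. ``a``."""
    a = np.asarray(a, dtype=F32)
    b = np.asarray(b, dtype=F32)
    axes = tuple(range(1, a.ndim))
    num = 2.0 * (a * b).sum(axis=axes) + eps
    den = (a * a).sum(axis=axes) + (b * b).sum(axis=axes) + eps
    loss = float(np.mean(1.0 - num / den))
    shape = (-1,) + (1,) * (a.ndim - 1)
    numb = num.reshape(shape)
    denb = den.reshape(shape)
    # d/da_i [ -(2*sum(ab)+eps)/(sum(a^2)+sum(b^2)+eps) ]
    grad = (-(2.0 * b * denb - numb * 2.0 * a) / (denb * denb)) / a.shape[0]
    return loss, grad.astype(F32)
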