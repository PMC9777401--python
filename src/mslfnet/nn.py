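"""Minimal CPU neural-network layer library used by the segmentation model.

Layers operate on float32 arrays in NCHW layout and implement explicit
forward/backward passes; there is no autograd tape.  Convolutions are
evaluated as sums of shifted channel-mixing matmuls, which keeps peak
memory proportional to one feature map rather than to an im2col buffer —
necessary for full-resolution (1440x960) fundus inputs on a CPU.

Every layer takes ``train`` in ``forward``; with ``train=False`` nothing is
cached, so inference on large inputs stays memory-lean.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "ReLU",
    "BilinearUpsample",
    "CategoryGroupedConv1x1",
    "SGD",
    "softmax",
]


class Param:
    """A learnable array together with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: a layer with parameters and an explicit backward pass."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """k x k same-padded convolution, stride 1, with bias and He init."""

    def __init__(self, cin: int, cout: int, k: int = 3, *, rng: np.random.Generator,
                 name: str = "conv") -> None:
        if k % 2 != 1:
            raise ValueError("same-padded Conv2d requires odd kernel size")
        self.cin, self.cout, self.k = cin, cout, k
        self.w = Param(_he_init(rng, (cout, cin, k, k), cin * k * k), f"{name}.w")
        self.b = Param(np.zeros(cout, np.float32), f"{name}.b")
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.cin:
            raise ValueError(f"expected (N,{self.cin},H,W) input, got {x.shape}")
        n, _, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x.astype(np.float32, copy=False), ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.zeros((n, self.cout, h * w), np.float32)
        wv = self.w.value
        for di in range(self.k):
            for dj in range(self.k):
                xs = np.ascontiguousarray(xp[:, :, di:di + h, dj:dj + w])
                xs = xs.reshape(n, self.cin, h * w)
                out += np.matmul(wv[:, :, di, dj][None], xs)
        out += self.b.value[None, :, None]
        out = out.reshape(n, self.cout, h, w)
        self._cache = (xp, (n, h, w)) if train else None
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a cached forward (train=True)")
        xp, (n, h, w) = self._cache
        p = self.k // 2
        dyf = dy.reshape(n, self.cout, h * w).astype(np.float32, copy=False)
        dxp = np.zeros_like(xp)
        wv = self.w.value
        for di in range(self.k):
            for dj in range(self.k):
                xs = np.ascontiguousarray(xp[:, :, di:di + h, dj:dj + w])
                xs = xs.reshape(n, self.cin, h * w)
                self.w.grad[:, :, di, dj] += np.einsum("noh,nch->oc", dyf, xs,
                                                       optimize=True)
                dxs = np.matmul(wv[:, :, di, dj].T[None], dyf)
                dxp[:, :, di:di + h, dj:dj + w] += dxs.reshape(n, self.cin, h, w)
        self.b.grad += dyf.sum(axis=(0, 2))
        self._cache = None
        if p == 0:
            return dxp
        return dxp[:, :, p:p + h, p:p + w]


class ConvTranspose2d(Module):
    """2x2, stride-2 transposed convolution (exact 2x upsampling, no overlap)."""

    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator,
                 name: str = "upconv") -> None:
        self.cin, self.cout = cin, cout
        self.w = Param(_he_init(rng, (cin, cout, 2, 2), cin), f"{name}.w")
        self.b = Param(np.zeros(cout, np.float32), f"{name}.b")
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        xf = x.reshape(n, c, h * w).astype(np.float32, copy=False)
        out = np.empty((n, self.cout, 2 * h, 2 * w), np.float32)
        for di in range(2):
            for dj in range(2):
                sub = np.matmul(self.w.value[:, :, di, dj].T[None], xf)
                out[:, :, di::2, dj::2] = sub.reshape(n, self.cout, h, w)
        out += self.b.value[None, :, None, None]
        self._cache = (xf, (n, h, w)) if train else None
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a cached forward (train=True)")
        xf, (n, h, w) = self._cache
        dx = np.zeros((n, self.cin, h * w), np.float32)
        for di in range(2):
            for dj in range(2):
                sub = np.ascontiguousarray(dy[:, :, di::2, dj::2])
                sub = sub.reshape(n, self.cout, h * w)
                self.w.grad[:, :, di, dj] += np.einsum("nch,noh->co", xf, sub,
                                                       optimize=True)
                self.b.grad += sub.sum(axis=(0, 2))
                dx += np.matmul(self.w.value[:, :, di, dj][None], sub)
        self._cache = None
        return dx.reshape(n, self.cin, h, w)


class MaxPool2d(Module):
    """2x2 max pooling with stride 2; ties route the gradient to the first max."""

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {h}x{w}")
        ho, wo = h // 2, w // 2
        xc = x.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
        xc = np.ascontiguousarray(xc).reshape(n, c, ho, wo, 4)
        idx = xc.argmax(axis=-1)
        y = np.take_along_axis(xc, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, c, h, w)) if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a cached forward (train=True)")
        idx, (n, c, h, w) = self._cache
        ho, wo = h // 2, w // 2
        dxc = np.zeros((n, c, ho, wo, 4), np.float32)
        np.put_along_axis(dxc, idx[..., None], dy[..., None].astype(np.float32), axis=-1)
        dx = dxc.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


class ReLU(Module):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        self._mask = (x > 0.0) if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward called without a cached forward (train=True)")
        dx = dy * self._mask
        self._mask = None
        return dx


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel centre alignment)."""
    m = np.zeros((n_out, n_in), np.float32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0.0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = (src - i0).astype(np.float32)
    m[np.arange(n_out), i0] += 1.0 - t
    m[np.arange(n_out), i1] += t
    return m


class BilinearUpsample(Module):
    """Bilinear resize to a fixed output size, as a separable linear map."""

    def __init__(self, out_hw: tuple[int, int]) -> None:
        self.out_hw = out_hw
        self._mats: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._in_hw: tuple[int, int] | None = None

    def _matrices(self, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
        key = (h, w)
        if key not in self._mats:
            self._mats[key] = (_interp_matrix(self.out_hw[0], h),
                               _interp_matrix(self.out_hw[1], w))
        return self._mats[key]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        _, _, h, w = x.shape
        r, c = self._matrices(h, w)
        y = np.matmul(np.matmul(r, x.astype(np.float32, copy=False)),
                      c.T)
        self._in_hw = (h, w) if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._in_hw is None:
            raise RuntimeError("backward called without a cached forward (train=True)")
        r, c = self._matrices(*self._in_hw)
        self._in_hw = None
        return np.matmul(np.matmul(r.T, dy.astype(np.float32, copy=False)), c)


class CategoryGroupedConv1x1(Module):
    """Grouped 1x1 convolution over category-major channels.

    Input has ``n_classes * n_blocks`` channels ordered category-major
    (all blocks of category 0, then category 1, ...).  Group ``g`` sees only
    the ``n_blocks`` channels of category ``g`` and emits one channel, so
    evidence never leaks between categories.
    """

    def __init__(self, n_classes: int, n_blocks: int, *, rng: np.random.Generator,
                 name: str = "fuse") -> None:
        self.n_classes, self.n_blocks = n_classes, n_blocks
        self.w = Param(_he_init(rng, (n_classes, n_blocks), n_blocks), f"{name}.w")
        self.b = Param(np.zeros(n_classes, np.float32), f"{name}.b")
        self._cache: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.n_classes * self.n_blocks:
            raise ValueError(
                f"expected {self.n_classes * self.n_blocks} channels "
                f"({self.n_classes} categories x {self.n_blocks} blocks), got {c}")
        xg = x.reshape(n, self.n_classes, self.n_blocks, h, w)
        y = np.einsum("mk,nmkhw->nmhw", self.w.value, xg, optimize=True)
        y += self.b.value[None, :, None, None]
        self._cache = xg if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a cached forward (train=True)")
        xg = self._cache
        n, m, k, h, w = xg.shape
        self.w.grad += np.einsum("nmhw,nmkhw->mk", dy, xg, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("mk,nmhw->nmkhw", self.w.value, dy, optimize=True)
        self._cache = None
        return dx.reshape(n, m * k, h, w)


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay.

    Update (per parameter): v <- mu*v + (g + wd*w); w <- w - lr*v.
    """

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0) -> None:
        self.parameters = params
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._vel = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.parameters, self._vel):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v
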