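"""Minimal NumPy neural-network engine with explicit backpropagation.

Implements exactly the pieces the segmentation models need: 2D and 1D
convolutions (including dilated causal 1D), ReLU, max pooling, nearest
upsampling, channel softmax, and Adam.  Every layer caches its forward
inputs and exposes ``backward(grad_out) -> grad_in``; parameters accumulate
gradients in ``Parameter.grad``.  Arrays are channel-first:
images ``(N, C, H, W)``, sequences ``(N, C, L)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "Conv1d",
    "ReLU",
    "MaxPool2d",
    "MaxPool1d",
    "Upsample2d",
    "Softmax",
    "Sequential",
    "Adam",
    "he_init",
]


# Compute dtype for the whole engine.  float32 halves memory traffic (the
# bottleneck for voxelwise temporal batches); gradient-accuracy tests may set
# float64 before building a model.
DEFAULT_DTYPE = np.float32


class Parameter:
    """A learnable array with its gradient accumulator."""

    def __init__(self, value: np.ndarray, decay: bool = True) -> None:
        self.value = np.asarray(value, dtype=DEFAULT_DTYPE)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # participates in L2 kernel regularization

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Layer):
    """2D convolution; ``pad='same'`` keeps the spatial shape (odd kernels)."""

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int,
        rng: np.random.Generator,
        pad: str | int = "same",
    ) -> None:
        self.k = kernel
        if pad == "same":
            if kernel % 2 == 0:
                raise ValueError("'same' padding requires an odd kernel")
            self.pad = kernel // 2
        else:
            self.pad = int(pad)
        fan_in = cin * kernel * kernel
        self.w = Parameter(he_init(rng, (cout, cin, kernel, kernel), fan_in))
        self.b = Parameter(np.zeros(cout), decay=False)
        self._x_pad: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        x = np.asarray(x, dtype=self.w.value.dtype)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        N, C, H, W = xp.shape
        Ho, Wo = H - self.k + 1, W - self.k + 1
        out = np.zeros((N, self.w.shape[0], Ho * Wo), dtype=self.w.value.dtype)
        # convolution as k*k shifted (O,C)@(N,C,HW) matmuls (BLAS-backed);
        # contiguous patch copies are kept for the backward pass
        self._shape = (N, C, H, W, Ho, Wo)
        self._patches = {}
        for i in range(self.k):
            for j in range(self.k):
                patch = np.ascontiguousarray(
                    xp[:, :, i: i + Ho, j: j + Wo]
                ).reshape(N, C, Ho * Wo)
                self._patches[i, j] = patch
                out += np.matmul(self.w.value[:, :, i, j], patch)
        out = out.reshape(N, -1, Ho, Wo)
        return out + self.b.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W, Ho, Wo = self._shape
        self.b.grad += grad.sum(axis=(0, 2, 3))
        g2 = np.ascontiguousarray(grad).reshape(N, -1, Ho * Wo)
        dxp = np.zeros((N, C, H, W), dtype=grad.dtype)
        for i in range(self.k):
            for j in range(self.k):
                patch = self._patches[i, j]
                self.w.grad[:, :, i, j] += np.matmul(
                    g2, patch.transpose(0, 2, 1)
                ).sum(axis=0)
                dxp[:, :, i: i + Ho, j: j + Wo] += np.matmul(
                    self.w.value[:, :, i, j].T, g2
                ).reshape(N, C, Ho, Wo)
        p = self.pad
        return dxp[:, :, p: H - p, p: W - p] if p else dxp


class Conv1d(Layer):
    """1D convolution.

    ``causal=True`` left-pads by ``(kernel-1)*dilation`` so the output has
    the input's length and element *t* depends only on inputs at times <= t;
    otherwise the convolution is unpadded (valid) and shortens the sequence.

    ``layout`` is ``"ncl"`` (batch, channel, length) or ``"lcn"``
    (length, channel, batch).  The computation always runs time-major
    (lcn), where every kernel tap is a batched GEMM over contiguous
    time-slice views — no padding or gather copies even for the very large
    voxel batches produced by per-voxel temporal processing; ncl converts
    at the boundaries.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int,
        rng: np.random.Generator,
        dilation: int = 1,
        causal: bool = False,
        layout: str = "ncl",
    ) -> None:
        self.k = kernel
        self.d = dilation
        self.causal = causal
        if layout not in ("ncl", "lcn"):
            raise ValueError("layout must be 'ncl' or 'lcn'")
        self.layout = layout
        self.w = Parameter(he_init(rng, (cout, cin, kernel), cin * kernel))
        self.b = Parameter(np.zeros(cout), decay=False)
        self._xt: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        dtype = self.w.value.dtype
        if self.layout == "ncl":
            xt = np.ascontiguousarray(x.transpose(2, 1, 0), dtype=dtype)
        else:
            xt = np.ascontiguousarray(x, dtype=dtype)
        L, C, N = xt.shape
        self._xt = xt
        O = self.w.shape[0]
        if self.causal:
            # implicit left padding: tap i reaches x[t - (k-1-i)*d] and is
            # applied only where that index exists
            out = np.empty((L, O, N), dtype=dtype)
            np.matmul(self.w.value[:, :, self.k - 1], xt, out=out)
            for i in range(self.k - 1):
                s = (self.k - 1 - i) * self.d
                out[s:] += np.matmul(self.w.value[:, :, i], xt[: L - s])
            Lo = L
        else:
            Lo = L - (self.k - 1) * self.d
            if Lo < 1:
                raise ValueError(
                    f"sequence of length {L} too short for kernel "
                    f"{self.k} with dilation {self.d}"
                )
            out = np.matmul(self.w.value[:, :, 0], xt[:Lo])
            for i in range(1, self.k):
                out += np.matmul(
                    self.w.value[:, :, i], xt[i * self.d: i * self.d + Lo]
                )
        out += self.b.value[None, :, None]
        return out.transpose(2, 1, 0) if self.layout == "ncl" else out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xt = self._xt
        L, C, N = xt.shape
        if self.layout == "ncl":
            g = np.ascontiguousarray(grad.transpose(2, 1, 0))
        else:
            g = np.ascontiguousarray(grad)
        Lo = g.shape[0]
        self.b.grad += g.sum(axis=(0, 2))
        dxt = np.zeros_like(xt)
        for i in range(self.k):
            if self.causal:
                s = (self.k - 1 - i) * self.d
                gi, xi, dsl = g[s:], xt[: L - s], dxt[: L - s]
            else:
                s = i * self.d
                gi, xi, dsl = g, xt[s: s + Lo], dxt[s: s + Lo]
            self.w.grad[:, :, i] += np.matmul(gi, xi.transpose(0, 2, 1)).sum(axis=0)
            dsl += np.matmul(self.w.value[:, :, i].T, gi)
        return dxt.transpose(2, 1, 0) if self.layout == "ncl" else dxt


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"max pool requires even spatial dims, got {H}x{W}")
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(N, C, H // 2, W // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return xr.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W = self._in_shape
        onehot = np.eye(4, dtype=grad.dtype)[self._argmax]  # (N,C,H/2,W/2,4)
        g = grad[..., None] * onehot
        g = g.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return g.reshape(N, C, H, W)


class MaxPool1d(Layer):
    """Factor-2 max pooling along the sequence axis (length must be even).

    Supports the same two layouts as :class:`Conv1d`.
    """

    def __init__(self, layout: str = "ncl") -> None:
        if layout not in ("ncl", "lcn"):
            raise ValueError("layout must be 'ncl' or 'lcn'")
        self.axis = 2 if layout == "ncl" else 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        L = x.shape[self.axis]
        if L % 2:
            raise ValueError(f"max pool requires an even length, got {L}")
        shape = list(x.shape)
        shape[self.axis: self.axis + 1] = [L // 2, 2]
        xr = x.reshape(shape)
        self._argmax = xr.argmax(axis=self.axis + 1)
        self._in_shape = x.shape
        return xr.max(axis=self.axis + 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = np.expand_dims(grad, self.axis + 1) * np.moveaxis(
            np.eye(2, dtype=grad.dtype)[self._argmax], -1, self.axis + 1
        )
        return g.reshape(self._in_shape)


class Upsample2d(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W = grad.shape
        return grad.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Softmax(Layer):
    """Softmax over the channel axis of ``(N, C, ...)``."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, grad: np.ndarray) -> np.ndarray:
        p = self._p
        inner = (grad * p).sum(axis=1, keepdims=True)
        return p * (grad - inner)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimizer; ``l2`` adds a kernel weight-decay term to the gradient
    of every parameter flagged ``decay`` (biases are exempt)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 0.0005,
        beta1: float = 0.975,
        beta2: float = 0.999,
        eps: float = 0.08,
        l2: float = 0.5e-4,
    ) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if p.decay and self.l2:
                g = g + 2.0 * self.l2 * p.value
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
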