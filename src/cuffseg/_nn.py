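"""Minimal CPU neural-network layers with hand-derived backpropagation.

Everything operates on float32 arrays shaped ``(N, C, *spatial)`` with 2 or 3
spatial axes.  Layers cache what their backward pass needs; ``backward``
returns the gradient w.r.t. the input and accumulates parameter gradients in
place.  Convolution is computed as a sum over kernel offsets of batched
matrix products, which keeps memory at one padded copy of the input and
dispatches the arithmetic to BLAS.

The scope is deliberately narrow: exactly the pieces a small encoder–decoder
segmentation network needs (3^d convolutions with same padding, instance
normalization, leaky ReLU, max pooling, nearest-neighbour upsampling,
channel concatenation) plus SGD with momentum.  Gradient correctness is
established by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

# float32 throughout; tests may switch to float64 for tight gradient checks
DTYPE = np.float32

__all__ = [
    "Param",
    "ConvNd",
    "InstanceNorm",
    "LeakyReLU",
    "MaxPool",
    "Upsample",
    "SGD",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []


class ConvNd(Layer):
    """Same-padded convolution with odd kernel size, stride 1, 2-D or 3-D."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, ndim: int,
                 rng: np.random.Generator):
        self.ndim = ndim
        self.kernel = (kernel,) * ndim
        fan_in = in_ch * kernel**ndim
        # He initialization, appropriate for leaky-ReLU activations
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, *self.kernel))
        self.W = Param(w)
        self.b = Param(np.zeros(out_ch))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def _pad(self, x):
        p = [(0, 0), (0, 0)] + [(k // 2, k // 2) for k in self.kernel]
        return np.pad(x, p)

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, Cin = x.shape[:2]
        spatial = x.shape[2:]
        sf = int(np.prod(spatial))
        xp = self._pad(x)
        Cout = self.W.value.shape[0]
        out = np.zeros((N, Cout, sf), dtype=DTYPE)
        for idx in np.ndindex(*self.kernel):
            sl = (slice(None), slice(None)) + tuple(
                slice(i, i + s) for i, s in zip(idx, spatial)
            )
            xs = np.ascontiguousarray(xp[sl]).reshape(N, Cin, sf)
            Wj = self.W.value[(slice(None), slice(None)) + idx]  # (Cout, Cin)
            out += np.matmul(Wj[None], xs)
        out += self.b.value.reshape(1, -1, 1)
        self._cache = (xp, x.shape)
        return out.reshape(N, Cout, *spatial)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp, xshape = self._cache
        N, Cin = xshape[:2]
        spatial = xshape[2:]
        sf = int(np.prod(spatial))
        gf = np.ascontiguousarray(g).reshape(N, -1, sf)
        self.b.grad += gf.sum(axis=(0, 2))
        gxp = np.zeros_like(xp)
        for idx in np.ndindex(*self.kernel):
            sl = (slice(None), slice(None)) + tuple(
                slice(i, i + s) for i, s in zip(idx, spatial)
            )
            xs = np.ascontiguousarray(xp[sl]).reshape(N, Cin, sf)
            # dL/dW_j = sum_n g_n @ x_n^T (batched gemm, summed over batch)
            self.W.grad[(slice(None), slice(None)) + idx] += np.matmul(
                gf, xs.transpose(0, 2, 1)
            ).sum(axis=0)
            Wj = self.W.value[(slice(None), slice(None)) + idx]
            gxs = np.matmul(Wj.T[None], gf)  # (N, Cin, sf)
            gxp[sl] += gxs.reshape(N, Cin, *spatial)
        crop = (slice(None), slice(None)) + tuple(
            slice(k // 2, k // 2 + s) for k, s in zip(self.kernel, spatial)
        )
        return gxp[crop]


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization over spatial axes, with affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        ax = tuple(range(2, x.ndim))
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        shape = (1, -1) + (1,) * (x.ndim - 2)
        self._cache = (xhat, ivar, ax, shape)
        return (self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)).astype(DTYPE)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, ivar, ax, shape = self._cache
        self.gamma.grad += (g * xhat).sum(axis=(0, *ax))
        self.beta.grad += g.sum(axis=(0, *ax))
        m = np.prod([xhat.shape[a] for a in ax])
        gxhat = g * self.gamma.value.reshape(shape)
        # standard normalization backward over the spatial axes
        return (
            ivar
            / m
            * (
                m * gxhat
                - gxhat.sum(axis=ax, keepdims=True)
                - xhat * (gxhat * xhat).sum(axis=ax, keepdims=True)
            )
        ).astype(DTYPE)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, self.slope * g)


class MaxPool(Layer):
    """Max pooling with per-axis integer factors; input sizes must divide."""

    def __init__(self, factors: tuple[int, ...]):
        self.factors = tuple(int(f) for f in factors)
        self._cache = None

    def _blocked(self, x):
        N, C = x.shape[:2]
        shape = [N, C]
        for s, f in zip(x.shape[2:], self.factors):
            if s % f:
                raise ValueError(f"spatial size {s} not divisible by pool factor {f}")
            shape += [s // f, f]
        return x.reshape(shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        xb = self._blocked(x)
        ax = tuple(range(3, xb.ndim, 2))
        out = xb.max(axis=ax)
        # expand out back to block shape for the tie mask
        expand = out.reshape(
            out.shape[:2] + tuple(v for s in out.shape[2:] for v in (s, 1))
        )
        mask = xb == expand
        counts = mask.sum(axis=ax, keepdims=True)
        self._cache = (mask, counts, ax, x.shape)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        mask, counts, ax, xshape = self._cache
        gb = g.reshape(g.shape[:2] + tuple(v for s in g.shape[2:] for v in (s, 1)))
        # ties share the gradient equally
        gx = mask * (gb / counts)
        return gx.reshape(xshape).astype(DTYPE)


class Upsample(Layer):
    """Nearest-neighbour upsampling by per-axis integer factors."""

    def __init__(self, factors: tuple[int, ...]):
        self.factors = tuple(int(f) for f in factors)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x
        for ax, f in enumerate(self.factors):
            if f > 1:
                out = np.repeat(out, f, axis=ax + 2)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        N, C = g.shape[:2]
        shape = [N, C]
        for s, f in zip(g.shape[2:], self.factors):
            shape += [s // f, f]
        ax = tuple(range(3, len(shape), 2))
        return g.reshape(shape).sum(axis=ax)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
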