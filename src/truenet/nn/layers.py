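"""Minimal CNN layer library with explicit forward/backward passes.

Layers operate on float32 arrays of shape ``(N, C, *spatial)`` and work for
both 2D and 3D spatial grids (``ndim`` spatial dimensions).  Each layer
caches what it needs during ``forward`` and returns the input gradient from
``backward``; trainable arrays are exposed as :class:`Param` objects that an
optimiser updates in place.  Convolutions use 'same' padding with odd
kernels; the input gradient is computed as a convolution with the
channel-swapped, spatially flipped kernel, which keeps everything on the
same fast ``tensordot`` path.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv", "ConvTranspose", "BatchNorm", "ReLU", "MaxPool"]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []


def _im2col(x: np.ndarray, kernel: tuple[int, ...], ndim: int) -> np.ndarray:
    """Contiguous patch matrix ``(prod(k) * Cin, N * prod(S))`` for 'same' conv.

    The input is transposed once to channel-major and then each kernel
    offset contributes one contiguous block copy, which is far cheaper than
    reshaping a strided sliding-window view.
    """
    n, cin = x.shape[0], x.shape[1]
    spatial = x.shape[2:]
    pad = [(0, 0), (0, 0)] + [(k // 2, k // 2) for k in kernel]
    xp = np.pad(x, pad)
    xp = np.ascontiguousarray(xp.swapaxes(0, 1))  # (Cin, N, *Spad)
    n_off = int(np.prod(kernel))
    cols = np.empty((n_off, cin, n, *spatial), dtype=np.float32)
    for kidx, offset in enumerate(np.ndindex(*kernel)):
        sl = tuple(slice(o, o + s) for o, s in zip(offset, spatial))
        cols[kidx] = xp[(slice(None), slice(None), *sl)]
    return cols.reshape(n_off * cin, n * int(np.prod(spatial)))


def _weight_matrix(weight: np.ndarray, ndim: int) -> np.ndarray:
    """(Cout, Cin, *k) -> (Cout, prod(k) * Cin) matching the im2col layout."""
    cout = weight.shape[0]
    perm = (0,) + tuple(range(2, 2 + ndim)) + (1,)
    return np.ascontiguousarray(weight.transpose(perm)).reshape(cout, -1)


def _conv_nd(
    x: np.ndarray,
    weight: np.ndarray,
    bias: np.ndarray | None,
    ndim: int,
) -> tuple[np.ndarray, np.ndarray]:
    """'same' N-D correlation; returns (output, patch matrix)."""
    kernel = weight.shape[2:]
    n, spatial = x.shape[0], x.shape[2:]
    cols = _im2col(x, kernel, ndim)
    out = _weight_matrix(weight, ndim) @ cols  # (Cout, N * prod(S))
    out = out.reshape(weight.shape[0], n, *spatial).swapaxes(0, 1)
    if bias is not None:
        out += bias.reshape((1, -1) + (1,) * ndim)
    return np.ascontiguousarray(out, dtype=np.float32), cols


class Conv(Layer):
    """N-D convolution ('same' padding, stride 1, odd kernel)."""

    def __init__(self, cin: int, cout: int, kernel: int | tuple[int, ...], ndim: int,
                 rng: np.random.Generator):
        if isinstance(kernel, int):
            kernel = (kernel,) * ndim
        if any(k % 2 == 0 for k in kernel):
            raise ValueError("conv kernels must be odd for 'same' padding")
        self.ndim = ndim
        fan_in = cin * int(np.prod(kernel))
        std = float(np.sqrt(2.0 / fan_in))  # He init for ReLU nets
        self.w = Param("weight", rng.normal(0.0, std, size=(cout, cin, *kernel)))
        self.b = Param("bias", np.zeros(cout))
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out, cols = _conv_nd(x, self.w.value, self.b.value, self.ndim)
        self._cols = cols if train else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        ndim = self.ndim
        spatial = list(range(2, 2 + ndim))
        cout = dout.shape[1]
        dout_mat = np.ascontiguousarray(dout.swapaxes(0, 1)).reshape(cout, -1)
        kernel = self.w.value.shape[2:]
        cin = self.w.value.shape[1]
        dw = (dout_mat @ self._cols.T).reshape(cout, *kernel, cin)
        inv_perm = (0, 1 + ndim) + tuple(range(1, 1 + ndim))
        self.w.grad += dw.transpose(inv_perm)
        self.b.grad += dout_mat.sum(axis=1, dtype=np.float32)
        w_back = np.ascontiguousarray(
            np.flip(self.w.value, axis=tuple(range(2, 2 + ndim))).swapaxes(0, 1)
        )
        dx, _ = _conv_nd(dout, w_back, None, ndim)
        return dx

    def params(self) -> list[Param]:
        return [self.w, self.b]


class ConvTranspose(Layer):
    """Up-convolution: kernel 2, stride 2 (no output overlap)."""

    def __init__(self, cin: int, cout: int, ndim: int, rng: np.random.Generator):
        self.ndim = ndim
        kernel = (2,) * ndim
        fan_in = cin * int(np.prod(kernel))
        std = float(np.sqrt(2.0 / fan_in))
        self.w = Param("weight", rng.normal(0.0, std, size=(cin, cout, *kernel)))
        self.b = Param("bias", np.zeros(cout))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        d = self.ndim
        t = np.tensordot(x, self.w.value, axes=([1], [0]))  # (N, *S, Cout, *2)
        perm = [0, 1 + d]
        for i in range(d):
            perm += [1 + i, 2 + d + i]
        t = t.transpose(perm)  # (N, Cout, S1, 2, S2, 2, ...)
        n, cout = t.shape[0], t.shape[1]
        out_spatial = [t.shape[2 + 2 * i] * 2 for i in range(d)]
        out = t.reshape(n, cout, *out_spatial)
        out += self.b.value.reshape((1, -1) + (1,) * d)
        return np.ascontiguousarray(out, dtype=np.float32)

    def _blocks(self, dout: np.ndarray) -> np.ndarray:
        """Reshape ``(N, Cout, *2S)`` into ``(N, *S, Cout, *2)`` blocks."""
        d = self.ndim
        n, cout = dout.shape[0], dout.shape[1]
        spatial = [s // 2 for s in dout.shape[2:]]
        shape = [n, cout]
        for s in spatial:
            shape += [s, 2]
        t = dout.reshape(shape)
        perm = [0] + [2 + 2 * i for i in range(d)] + [1] + [3 + 2 * i for i in range(d)]
        return t.transpose(perm)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.ndim
        blocks = self._blocks(dout)  # (N, *S, Cout, *2)
        k_axes = list(range(1 + d, 1 + 2 * d + 1))  # cout + kernel axes of blocks
        dx = np.tensordot(blocks, self.w.value, axes=(k_axes, list(range(1, 2 + d))))
        dx = np.moveaxis(dx, -1, 1)
        x = self._x
        contract = [0] + list(range(2, 2 + d))  # N and spatial axes of x
        b_contract = [0] + list(range(1, 1 + d))
        self.w.grad += np.tensordot(x, blocks, axes=(contract, b_contract)).astype(np.float32)
        self.b.grad += dout.sum(axis=tuple([0] + list(range(2, 2 + d))), dtype=np.float32)
        return np.ascontiguousarray(dx, dtype=np.float32)

    def params(self) -> list[Param]:
        return [self.w, self.b]


class BatchNorm(Layer):
    """Batch normalisation over batch and spatial axes, per channel."""

    def __init__(self, channels: int, ndim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.ndim = ndim
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param("gamma", np.ones(channels))
        self.beta = Param("beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def _shape(self, v: np.ndarray) -> np.ndarray:
        return v.reshape((1, -1) + (1,) * self.ndim)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = tuple([0] + list(range(2, 2 + self.ndim)))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(mean)) * self._shape(inv_std)
        xhat = xhat.astype(np.float32)
        if train:
            m = x.size // x.shape[1]
            self._cache = (xhat, inv_std.astype(np.float32), m, axes)
        return self._shape(self.gamma.value) * xhat + self._shape(self.beta.value)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, m, axes = self._cache
        self.beta.grad += dout.sum(axis=axes, dtype=np.float32)
        self.gamma.grad += (dout * xhat).sum(axis=axes, dtype=np.float32)
        dxhat = dout * self._shape(self.gamma.value)
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        dx = (dxhat - s1 / m - xhat * s2 / m) * self._shape(inv_std)
        return dx.astype(np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool(Layer):
    """2x downsampling max pool; spatial dims must be even."""

    def __init__(self, ndim: int):
        self.ndim = ndim
        self._cache = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        d = self.ndim
        n, c = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        if any(s % 2 for s in spatial):
            raise ValueError(f"spatial dims {spatial} not divisible by 2 for max-pool")
        shape = [n, c]
        for s in spatial:
            shape += [s // 2, 2]
        t = x.reshape(shape)
        perm = [0, 1] + [2 + 2 * i for i in range(d)] + [3 + 2 * i for i in range(d)]
        t = t.transpose(perm)
        lead = t.shape[: 2 + d]
        return t.reshape(*lead, -1)  # (..., 2^d)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        t = self._split(x)
        idx = t.argmax(axis=-1)
        if train:
            self._cache = (idx, x.shape)
        return np.take_along_axis(t, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, in_shape = self._cache
        d = self.ndim
        g = np.zeros((*dout.shape, 2**d), dtype=np.float32)
        np.put_along_axis(g, idx[..., None], dout[..., None].astype(np.float32), axis=-1)
        n, c = in_shape[0], in_shape[1]
        half = [s // 2 for s in in_shape[2:]]
        g = g.reshape(n, c, *half, *([2] * d))
        inv = [0, 1]
        for i in range(d):
            inv += [2 + i, 2 + d + i]
        g = g.transpose(inv)
        return np.ascontiguousarray(g.reshape(in_shape), dtype=np.float32)
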