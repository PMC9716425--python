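"""Layers operating on NHWC float arrays.

Convolution uses an im2col + matmul formulation; the column tensor is cached
on the layer during a training forward pass so the backward pass can form
weight gradients with a single matmul and scatter input gradients per kernel
offset (col2im).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: stateless layers override forward/backward only."""

    def params(self):  # list of (array, grad) pairs, same shapes
        return []

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, zero 'same' padding, optional stride.

    Weights are stored as (k*k*in_ch, out_ch) with column order matching the
    (ky, kx, channel) layout produced by im2col. Glorot-uniform init.
    """

    def __init__(self, in_ch, out_ch, kernel_size, stride=1, rng=None, dtype=np.float32):
        if rng is None:
            rng = np.random.default_rng(0)
        k = int(kernel_size)
        fan_in = k * k * in_ch
        fan_out = k * k * out_ch
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.k = k
        self.stride = int(stride)
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.W = rng.uniform(-limit, limit, size=(fan_in, out_ch)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols = None
        self._in_shape = None

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def _im2col(self, x):
        k, s = self.k, self.stride
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # windows: (N, Hp-k+1, Wp-k+1, C, k, k) -> stride-sliced
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        n, ho, wo = win.shape[:3]
        # reorder to (ky, kx, C) per column to match weight layout
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        return cols.reshape(n, ho, wo, k * k * self.in_ch)

    def forward(self, x, train=False):
        cols = self._im2col(np.ascontiguousarray(x))
        out = cols @ self.W + self.b
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return out

    def backward(self, grad):
        n, ho, wo, _ = grad.shape
        cols2d = self._cols.reshape(-1, self.W.shape[0])
        g2d = grad.reshape(-1, self.out_ch)
        self.gW[...] = cols2d.T @ g2d
        self.gb[...] = g2d.sum(axis=0)
        # col2im: scatter grad @ W.T back onto the padded input grid
        gcols = (g2d @ self.W.T).reshape(n, ho, wo, self.k, self.k, self.in_ch)
        _, h, w, _ = self._in_shape
        k, s, p = self.k, self.stride, self.k // 2
        gxp = np.zeros((n, h + 2 * p, w + 2 * p, self.in_ch), dtype=grad.dtype)
        for ky in range(k):
            for kx in range(k):
                gxp[:, ky:ky + s * ho:s, kx:kx + s * wo:s, :] += gcols[:, :, :, ky, kx, :]
        self._cols = None
        if p:
            return gxp[:, p:-p, p:-p, :]
        return gxp

    @property
    def n_params(self):
        return self.W.size + self.b.size


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling; backward sums 2x2 blocks."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad):
        n, h, w, c = grad.shape
        return grad.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for lyr in self.layers:
            out.extend(lyr.params())
        return out

    def forward(self, x, train=False):
        for lyr in self.layers:
            x = lyr.forward(x, train=train)
        return x

    def forward_to(self, x, n_layers):
        """Inference-only forward through the first n_layers layers."""
        for lyr in self.layers[:n_layers]:
            x = lyr.forward(x, train=False)
        return x

    def backward(self, grad):
        for lyr in reversed(self.layers):
            grad = lyr.backward(grad)
        return grad

    @property
    def n_params(self):
        return int(sum(p.size for p, _ in self.params()))

    def state(self):
        return [p.copy() for p, _ in self.params()]

    def load_state(self, state):
        for (p, _), s in zip(self.params(), state):
            p[...] = s

    def checksum(self):
        """Bitwise checksum of all parameters (frozen-weights assertions)."""
        import hashlib

        h = hashlib.sha256()
        for p, _ in self.params():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()
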