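"""Minimal convolutional network primitives on numpy.

Forward and backward passes are expressed as GEMMs via im2col so the work
lands in BLAS.  Tensors follow the ``(N, C, H, W)`` float32 convention.
Every layer caches what its backward pass needs; a layer instance is used
at exactly one position in the network graph.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable tensor with its gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patch matrix for 3x3 same-padding conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3) -> (N*H*W, C*9)
    return np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)


class Conv2d:
    """k x k convolution (k in {1, 3}), stride 1, same padding, He init."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.cin, self.cout, self.k = cin, cout, k
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Param(rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32))
        self.bias = Param(np.zeros(cout, dtype=np.float32))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        if self.k == 3:
            cols = _im2col3(x)
        else:
            cols = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(n * h * w, c)
        self._cols = cols
        wm = self.weight.value.reshape(self.cout, -1).T       # (C*k*k, cout)
        y = cols @ wm + self.bias.value
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        gy_flat = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(n * h * w, self.cout)
        self.bias.grad = gy_flat.sum(axis=0)
        gwm = self._cols.T @ gy_flat                          # (C*k*k, cout)
        self.weight.grad = gwm.T.reshape(self.weight.value.shape)
        if self.k == 3:
            gcols = _im2col3(gy)                              # (N*H*W, cout*9)
            wflip = self.weight.value[:, :, ::-1, ::-1].transpose(0, 2, 3, 1)
            gx_flat = gcols @ wflip.reshape(self.cout * 9, self.cin)
        else:
            gx_flat = gy_flat @ self.weight.value.reshape(self.cout, self.cin)
        gx = gx_flat.reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)
        self._cols = None
        return np.ascontiguousarray(gx)


class ReLU:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, x.dtype.type(0))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, gy.dtype.type(0))


class MaxPool2:
    """2x2 max pooling, stride 2; gradient routed to the argmax element."""

    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        gflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(gflat, self._idx[..., None], gy[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(gx).reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbor 2x upsampling; backward sums each 2x2 block."""

    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = gy.shape
        return gy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
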