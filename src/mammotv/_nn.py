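"""Minimal numpy inference engine for frozen convolutional feature extractors.

Only what the backbone definitions need: 2-D convolution (im2col + one BLAS
matmul per layer), ReLU, max/average pooling, residual blocks, parallel
branch concatenation, global average pooling and fully-connected layers.
Everything runs in float32, image by image, so outputs are bit-identical
regardless of how callers batch their inputs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d", "ReLU", "MaxPool2d", "AvgPool2d", "GlobalAvgPool", "Flatten",
    "Linear", "Sequential", "Parallel", "Residual", "conv_init", "linear_init",
]


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(C, H, W) -> (C, OH, OW, k, k) sliding windows with the given stride."""
    v = sliding_window_view(x, (k, k), axis=(1, 2))
    return v[:, ::stride, ::stride]


class Conv2d:
    def __init__(self, weight: np.ndarray, bias: np.ndarray, stride: int = 1, pad: int = 0):
        self.weight = np.ascontiguousarray(weight, dtype=np.float32)  # (O, C, k, k)
        self.bias = np.ascontiguousarray(bias, dtype=np.float32)
        self.stride = stride
        self.pad = pad
        o, c, kh, kw = weight.shape
        self._wmat = self.weight.reshape(o, c * kh * kw)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        o, c, kh, kw = self.weight.shape
        v = _windows(x, kh, self.stride)  # (C, OH, OW, k, k)
        _, oh, ow = v.shape[0], v.shape[1], v.shape[2]
        cols = np.ascontiguousarray(v.transpose(0, 3, 4, 1, 2)).reshape(c * kh * kw, oh * ow)
        out = self._wmat @ cols
        out += self.bias[:, None]
        return out.reshape(o, oh, ow)


class ReLU:
    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(x, 0.0)


class MaxPool2d:
    def __init__(self, k: int, stride: int, pad: int = 0):
        self.k, self.stride, self.pad = k, stride, pad

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            x = np.pad(
                x, ((0, 0), (self.pad, self.pad), (self.pad, self.pad)),
                constant_values=-np.inf,
            )
        v = _windows(x, self.k, self.stride)
        return v.max(axis=(3, 4))


class AvgPool2d:
    """Average pooling; zero padding is counted in the divisor (k*k)."""

    def __init__(self, k: int, stride: int, pad: int = 0):
        self.k, self.stride, self.pad = k, stride, pad

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        v = _windows(x, self.k, self.stride)
        return v.mean(axis=(3, 4), dtype=np.float32)


class GlobalAvgPool:
    def __call__(self, x: np.ndarray) -> np.ndarray:
        return x.mean(axis=(1, 2), dtype=np.float32)


class Flatten:
    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(x).reshape(-1)


class Linear:
    def __init__(self, weight: np.ndarray, bias: np.ndarray):
        self.weight = np.ascontiguousarray(weight, dtype=np.float32)  # (O, I)
        self.bias = np.ascontiguousarray(bias, dtype=np.float32)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.weight @ x + self.bias


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x


class Parallel:
    """Run branches on the same input and concatenate along the channel axis."""

    def __init__(self, branches):
        self.branches = [Sequential(b) if isinstance(b, (list, tuple)) else b for b in branches]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([b(x) for b in self.branches], axis=0)


class Residual:
    """main(x) + shortcut(x) followed by ReLU; identity shortcut when None."""

    def __init__(self, main, shortcut=None):
        self.main = Sequential(main) if isinstance(main, (list, tuple)) else main
        if isinstance(shortcut, (list, tuple)):
            shortcut = Sequential(shortcut)
        self.shortcut = shortcut

    def __call__(self, x: np.ndarray) -> np.ndarray:
        s = x if self.shortcut is None else self.shortcut(x)
        return np.maximum(self.main(x) + s, 0.0)


def conv_init(rng: np.random.Generator, out_ch: int, in_ch: int, k: int,
              stride: int = 1, pad: int = 0) -> Conv2d:
    """He-normal initialised convolution (frozen random weights)."""
    fan_in = in_ch * k * k
    w = (rng.standard_normal((out_ch, in_ch, k, k)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
    b = np.zeros(out_ch, dtype=np.float32)
    return Conv2d(w, b, stride=stride, pad=pad)


def linear_init(rng: np.random.Generator, out_dim: int, in_dim: int) -> Linear:
    w = (rng.standard_normal((out_dim, in_dim)) * np.sqrt(2.0 / in_dim)).astype(np.float32)
    b = np.zeros(out_dim, dtype=np.float32)
    return Linear(w, b)
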