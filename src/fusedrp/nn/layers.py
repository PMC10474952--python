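"""NumPy layers with explicit forward/backward passes.

Each layer caches what its backward pass needs during forward; ``backward``
consumes the upstream gradient and accumulates parameter gradients into
``grads``.  All layers support float32 (training speed) and float64
(numerical gradient checks).
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "Conv2d",
    "GlobalMaxPool2d",
    "ResidualBlock2d",
    "Sequential",
    "MLP",
]


class Layer:
    """Base class: parameter store plus state (de)serialization."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def zero_grad(self) -> None:
        for lyr in self.layers():
            for name, p in lyr.params.items():
                lyr.grads[name] = np.zeros_like(p)

    def layers(self) -> Iterator["Layer"]:
        """All parameterized leaf layers, depth-first (self included)."""
        yield self

    def n_params(self) -> int:
        return sum(p.size for lyr in self.layers() for p in lyr.params.values())

    def state(self) -> list[np.ndarray]:
        return [p.copy() for lyr in self.layers() for p in
                (lyr.params[k] for k in sorted(lyr.params))]

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        it = iter(arrays)
        for lyr in self.layers():
            for k in sorted(lyr.params):
                lyr.params[k] = next(it).copy()


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...],
                  fan_in: int, dtype) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Dense(Layer):
    """Affine (or pure linear) map y = x W [+ b]."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float64) -> None:
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.params["W"] = _uniform_init(rng, (in_dim, out_dim), in_dim, dtype)
        if bias:
            self.params["b"] = _uniform_init(rng, (out_dim,), in_dim, dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.in_dim:
            raise ValueError(
                f"Dense expected input width {self.in_dim}, got {x.shape[-1]}"
            )
        self._x = x
        y = x @ self.params["W"]
        if "b" in self.params:
            y = y + self.params["b"]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        if "b" in self.params:
            self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Conv2d(Layer):
    """2-D convolution, stride 1, 'same' zero padding, odd kernel size.

    Input (B, C_in, H, W) -> output (B, C_out, H, W).  Both passes run as a
    single im2col matrix product (BLAS), with a 9-offset scatter-add for the
    input gradient (col2im).
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int,
                 rng: np.random.Generator, dtype=np.float64) -> None:
        super().__init__()
        if ksize % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, ksize
        fan_in = in_ch * ksize * ksize
        self.params["W"] = _uniform_init(rng, (out_ch, in_ch, ksize, ksize),
                                         fan_in, dtype)
        self.params["b"] = _uniform_init(rng, (out_ch,), fan_in, dtype)
        self.zero_grad()

    @staticmethod
    def _im2col(x: np.ndarray, k: int, p: int) -> np.ndarray:
        """(B, C, H, W) -> (B*H*W, C*k*k) patch rows under same padding."""
        B, C, H, W = x.shape
        if k == 1:
            return x.transpose(0, 2, 3, 1).reshape(B * H * W, C)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)) \
            .reshape(B * H * W, C * k * k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"Conv2d expected {self.in_ch} channels, got {C}")
        k, p = self.ksize, self.ksize // 2
        if H < k or W < k:
            raise ValueError(f"spatial size {(H, W)} smaller than kernel {k}")
        cols = self._im2col(x, k, p)
        self._cols, self._shape = cols, (B, C, H, W)
        Wmat = self.params["W"].reshape(self.out_ch, -1).T  # (C*k*k, F)
        y = cols @ Wmat + self.params["b"]
        return np.ascontiguousarray(
            y.reshape(B, H, W, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        k, p = self.ksize, self.ksize // 2
        dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)) \
            .reshape(B * H * W, self.out_ch)
        self.grads["W"] += (dy_flat.T @ self._cols).reshape(
            self.out_ch, C, k, k)
        self.grads["b"] += dy_flat.sum(axis=0)
        # input gradient as a gather: correlate dy with the spatially
        # rotated kernel, channels swapped (transposed convolution)
        W_rot = self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dy_cols = self._im2col(dy, k, p)          # (B*H*W, F*k*k)
        dx = dy_cols @ W_rot.reshape(C, -1).T     # (B*H*W, C)
        return np.ascontiguousarray(
            dx.reshape(B, H, W, C).transpose(0, 3, 1, 2))


class GlobalMaxPool2d(Layer):
    """(B, C, H, W) -> (B, C) max over spatial positions.

    Gradient is routed to the (first) argmax position per (batch, channel).
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        flat = x.reshape(B, C, H * W)
        self._idx = flat.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[:, :, None], axis=2)[:, :, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        dflat = np.zeros((B, C, H * W), dtype=dy.dtype)
        np.put_along_axis(dflat, self._idx[:, :, None], dy[:, :, None], axis=2)
        return dflat.reshape(B, C, H, W)


class Sequential(Layer):
    def __init__(self, *mods: Layer) -> None:
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.mods:
            x = m.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for m in reversed(self.mods):
            dy = m.backward(dy)
        return dy

    def layers(self) -> Iterator[Layer]:
        for m in self.mods:
            yield from m.layers()


class ResidualBlock2d(Layer):
    """x -> shortcut(x) + conv2(relu(conv1(x))).

    The shortcut is the identity when channel counts match, else a 1x1
    convolution.  With the residual branch's weights at zero the block is
    exactly the identity map (or the bare shortcut projection).
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int,
                 rng: np.random.Generator, dtype=np.float64) -> None:
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, ksize, rng, dtype=dtype)
        self.relu = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, ksize, rng, dtype=dtype)
        self.shortcut = (None if in_ch == out_ch
                         else Conv2d(in_ch, out_ch, 1, rng, dtype=dtype))

    def zero_residual_(self) -> None:
        """Zero the residual branch (conv2): the block becomes h(x) alone."""
        self.conv2.params["W"][...] = 0.0
        self.conv2.params["b"][...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        r = self.conv2.forward(self.relu.forward(self.conv1.forward(x)))
        h = x if self.shortcut is None else self.shortcut.forward(x)
        return h + r

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dr = self.conv1.backward(self.relu.backward(self.conv2.backward(dy)))
        dh = dy if self.shortcut is None else self.shortcut.backward(dy)
        return dh + dr

    def layers(self) -> Iterator[Layer]:
        yield from self.conv1.layers()
        yield from self.conv2.layers()
        if self.shortcut is not None:
            yield from self.shortcut.layers()


class MLP(Layer):
    """Fully connected stack with ReLU between layers.

    ``relu_last`` controls whether the final layer is followed by a ReLU
    (hidden-embedding MLPs) or left linear (heads).
    """

    def __init__(self, in_dim: int, sizes: Sequence[int],
                 rng: np.random.Generator, relu_last: bool = False,
                 dtype=np.float64) -> None:
        super().__init__()
        mods: list[Layer] = []
        prev = in_dim
        for i, w in enumerate(sizes):
            mods.append(Dense(prev, w, rng, dtype=dtype))
            if i < len(sizes) - 1 or relu_last:
                mods.append(ReLU())
            prev = w
        self.seq = Sequential(*mods)
        self.out_dim = prev

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.seq.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.seq.backward(dy)

    def layers(self) -> Iterator[Layer]:
        yield from self.seq.layers()
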