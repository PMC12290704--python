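"""Minimal 3D convolutional network primitives with explicit backprop.

Everything operates on single samples shaped ``(C, D, H, W)`` in float32.
Convolutions are evaluated by im2col + BLAS matmul; the gradient with
respect to the input of a stride-1 same-padding convolution is itself a
convolution with the spatially flipped, channel-transposed kernel, so no
scatter-add is ever needed.  Layers cache what their backward pass needs;
a forward must precede each backward.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3d",
    "InstanceNorm",
    "LeakyReLU",
    "ConvBlock",
    "UNet3D",
    "avgpool2",
    "avgpool2_backward",
    "upsample2",
    "upsample2_backward",
    "Adam",
]

_DT = np.float32


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(C, D, H, W) -> (D*H*W, C*27) patch matrix with zero padding of 1."""
    c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))  # (C,D,H,W,3,3,3)
    cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(d * h * w, c * 27)
    return np.ascontiguousarray(cols, dtype=_DT)


class Conv3d:
    """3x3x3 (or 1x1x1) convolution, stride 1, same padding."""

    def __init__(
        self,
        cin: int,
        cout: int,
        rng: np.random.Generator,
        kernel: int = 3,
        zero_init: bool = False,
    ):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.cin, self.cout, self.kernel = cin, cout, kernel
        fan_in = cin * kernel**3
        std = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((cout, cin, kernel, kernel, kernel)) * std).astype(_DT)
        self.b = np.zeros(cout, dtype=_DT)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._x: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        _, d, h, w = x.shape
        if self.kernel == 1:
            self._x = x
            y = np.tensordot(self.W[:, :, 0, 0, 0], x, axes=([1], [0]))
        else:
            cols = _im2col3(x)
            self._cols = cols
            y = (cols @ self.W.reshape(self.cout, -1).T).T.reshape(self.cout, d, h, w)
        return y + self.b[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        _, d, h, w = self._shape
        self.db += dy.sum(axis=(1, 2, 3))
        if self.kernel == 1:
            self.dW[:, :, 0, 0, 0] += np.tensordot(dy, self._x, axes=([1, 2, 3], [1, 2, 3]))
            return np.tensordot(self.W[:, :, 0, 0, 0].T, dy, axes=([1], [0]))
        dym = dy.reshape(self.cout, -1).T  # (N, cout)
        self.dW += (dym.T @ self._cols).reshape(self.W.shape)
        # grad wrt input: convolve dy with flipped, transposed kernel
        w_t = np.ascontiguousarray(
            self.W.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        )
        cols_dy = _im2col3(dy.astype(_DT))
        dx = (cols_dy @ w_t.reshape(self.cin, -1).T).T.reshape(self.cin, d, h, w)
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class InstanceNorm:
    """Per-channel normalization over the spatial volume, learned affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=_DT)
        self.beta = np.zeros(channels, dtype=_DT)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._xhat, self._inv_std = xhat, inv_std
        return self.gamma[:, None, None, None] * xhat + self.beta[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.dgamma += (dy * xhat).sum(axis=(1, 2, 3))
        self.dbeta += dy.sum(axis=(1, 2, 3))
        g = dy * self.gamma[:, None, None, None]
        g_mean = g.mean(axis=(1, 2, 3), keepdims=True)
        gx_mean = (g * xhat).mean(axis=(1, 2, 3), keepdims=True)
        return inv_std * (g - g_mean - xhat * gx_mean)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class LeakyReLU:
    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)

    def params(self):
        return []


def avgpool2(x: np.ndarray) -> np.ndarray:
    c, d, h, w = x.shape
    return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))


def avgpool2_backward(dy: np.ndarray) -> np.ndarray:
    c, d, h, w = dy.shape
    out = np.empty((c, d, 2, h, 2, w, 2), dtype=dy.dtype)
    out[...] = (dy / 8.0)[:, :, None, :, None, :, None]
    return out.reshape(c, 2 * d, 2 * h, 2 * w)


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour x2 upsampling along the three spatial axes."""
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    c, d, h, w = dy.shape
    return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


class ConvBlock:
    """Conv -> InstanceNorm -> LeakyReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, kernel: int = 3):
        self.conv = Conv3d(cin, cout, rng, kernel=kernel)
        self.norm = InstanceNorm(cout)
        self.act = LeakyReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.act.forward(self.norm.forward(self.conv.forward(x)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.norm.backward(self.act.backward(dy)))

    def params(self):
        return self.conv.params() + self.norm.params()


class UNet3D:
    """Compact 3D U-Net emitting per-voxel logits.

    ``depth`` encoder levels with channel widths base * 2^level, average
    pooling between levels, nearest-neighbour upsampling with skip
    concatenation on the way back up.  Each decoder stage first collapses
    the concatenated channels with a 1x1 projection block, then applies a
    3x3x3 block.  The 1x1 output head is zero-initialised so an untrained
    network emits uniform class probabilities, which keeps the temperature
    SoftMax unsaturated at the start of training.
    """

    def __init__(
        self,
        in_channels: int = 2,
        out_channels: int = 3,
        depth: int = 3,
        base_channels: int = 8,
        seed: int = 0,
    ):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.in_channels = in_channels
        self.out_channels = out_channels
        chans = [base_channels * 2**i for i in range(depth)]
        self.enc = [
            ConvBlock(in_channels if i == 0 else chans[i - 1], chans[i], rng)
            for i in range(depth)
        ]
        self.reduce: list[ConvBlock] = []
        self.dec: list[ConvBlock] = []
        for i in reversed(range(depth - 1)):
            self.reduce.append(ConvBlock(chans[i] + chans[i + 1], chans[i], rng, kernel=1))
            self.dec.append(ConvBlock(chans[i], chans[i], rng))
        self.head = Conv3d(chans[0], out_channels, rng, kernel=1, zero_init=True)
        self._chans = chans

    # -- execution -------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        factor = 2 ** (self.depth - 1)
        if any(s % factor for s in x.shape[1:]):
            raise ValueError(
                f"spatial shape {x.shape[1:]} not divisible by {factor}"
            )
        x = np.ascontiguousarray(x, dtype=_DT)
        skips = []
        h = x
        for i, blk in enumerate(self.enc):
            if i > 0:
                h = avgpool2(h)
            h = blk.forward(h)
            skips.append(h)
        self._skip_channels = [s.shape[0] for s in skips]
        h = skips[-1]
        for k in range(self.depth - 1):
            i = self.depth - 2 - k
            h = upsample2(h)
            h = np.concatenate([skips[i], h], axis=0)
            h = self.reduce[k].forward(h)
            h = self.dec[k].forward(h)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.head.backward(np.ascontiguousarray(dlogits, dtype=_DT))
        dskips: list[np.ndarray | None] = [None] * self.depth
        for k in reversed(range(self.depth - 1)):
            i = self.depth - 2 - k
            dh = self.reduce[k].backward(self.dec[k].backward(dh))
            c_skip = self._chans[i]
            dskips[i] = dh[:c_skip]
            dh = upsample2_backward(dh[c_skip:])
        if dskips[self.depth - 1] is None:
            dskips[self.depth - 1] = dh
        else:  # depth == 1 never reaches decoder loop
            dskips[self.depth - 1] = dskips[self.depth - 1] + dh
        grad = dskips[self.depth - 1]
        for i in reversed(range(self.depth)):
            if i < self.depth - 1:
                grad = dskips[i] + avgpool2_backward(grad)
            grad = self.enc[i].backward(grad)
        return grad

    # -- parameters ------------------------------------------------------
    def _layers(self):
        yield from self.enc
        yield from self.reduce
        yield from self.dec
        yield self.head

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.copy() for i, (p, _) in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for i, (p, _) in enumerate(params):
            src = state[f"param_{i}"]
            if src.shape != p.shape:
                raise ValueError(f"parameter {i} shape mismatch: {src.shape} vs {p.shape}")
            p[...] = src


class Adam:
    """Adam optimizer over a list of (param, grad) array pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
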