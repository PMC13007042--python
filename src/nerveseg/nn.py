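"""A small NumPy engine for 3D encoder-decoder segmentation networks.

Implements exactly the building blocks the segmentation U-Net needs — 3D
convolution with same padding and per-axis strides, instance normalization,
leaky ReLU, nearest-neighbour upsampling, skip concatenation — each with an
explicit, hand-derived backward pass, plus SGD with Nesterov momentum and
global gradient-norm clipping. Everything is float32 and fully deterministic
given a seeded ``numpy.random.Generator``.

Convolutions run through numba-compiled direct loops when numba is present
(the default environment), with a pure-NumPy im2col/GEMM path as fallback
and as an independent reference implementation in the tests.

Tensors are channel-first: activations ``(C, Z, Y, X)``.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from . import _conv_kernels as _ck

__all__ = ["Conv3d", "InstanceNorm3d", "LeakyReLU", "Upsample", "UNet3D", "SGDNesterov"]

_F32 = np.float32


class Conv3d:
    """3D convolution, cubic odd kernel, same padding, per-axis stride."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3,
                 stride: tuple[int, int, int] = (1, 1, 1),
                 rng: np.random.Generator | None = None):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = c_in * kernel ** 3
        std = math.sqrt(2.0 / fan_in)  # He init for leaky-ReLU networks
        self.W = rng.normal(0.0, std, (c_out, c_in, kernel, kernel, kernel)).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.kernel = kernel
        self.stride = tuple(stride)
        self._xp: np.ndarray | None = None
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None
        #: first layer of a network: input gradient is never consumed
        self.needs_input_grad = True

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def _out_shape(self) -> tuple[int, int, int]:
        _, z, y, x = self._in_shape
        sz, sy, sx = self.stride
        return (z + sz - 1) // sz, (y + sy - 1) // sy, (x + sx - 1) // sx

    def _offset_view(self, arr: np.ndarray, a: int, b: int, c: int,
                     out: tuple[int, int, int]) -> np.ndarray:
        sz, sy, sx = self.stride
        zo, yo, xo = out
        return arr[:, a:a + sz * zo:sz, b:b + sy * yo:sy, c:c + sx * xo:sx]

    #: im2col buffers above this size fall back to offset-wise GEMMs
    _IM2COL_LIMIT_BYTES = 1 << 30

    def _wmat(self) -> np.ndarray:
        # (C_out, k^3 * C_in) with offset-major row blocks, matching _cols
        return self.W.transpose(0, 2, 3, 4, 1).reshape(self.W.shape[0], -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        self._in_shape = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p))) if p else x
        self._xp = xp
        k = self.kernel
        zo, yo, xo = out_sp = self._out_shape()
        n = zo * yo * xo
        c_in = xp.shape[0]
        c_out = self.W.shape[0]
        if _ck.HAVE_NUMBA and xp.dtype == np.float32:
            self._cols = None
            out = np.empty((c_out, zo, yo, xo), dtype=_F32)
            _ck.conv3d_forward(xp, self.W, self.b, *self.stride, out)
            return out
        cols_bytes = k ** 3 * c_in * n * 4
        if cols_bytes <= self._IM2COL_LIMIT_BYTES:
            # im2col: one gather into a column buffer, one large GEMM
            cols = np.empty((k ** 3 * c_in, n), dtype=_F32)
            for o, (a, b, c) in enumerate(product(range(k), repeat=3)):
                cols[o * c_in:(o + 1) * c_in] = (
                    self._offset_view(xp, a, b, c, out_sp).reshape(c_in, n)
                )
            self._cols = cols
            out = self._wmat() @ cols
        else:
            # offset-wise shifted GEMMs: slower but O(input) memory
            self._cols = None
            out = np.zeros((c_out, n), dtype=_F32)
            for a, b, c in product(range(k), repeat=3):
                xs = self._offset_view(xp, a, b, c, out_sp).reshape(c_in, n)
                out += self.W[:, :, a, b, c] @ xs
        out = out.reshape(c_out, zo, yo, xo)
        return out + self.b[:, None, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xp = self._xp
        k = self.kernel
        p = k // 2
        c_in = xp.shape[0]
        out_sp = gout.shape[1:]
        n = int(np.prod(out_sp))
        if _ck.HAVE_NUMBA and xp.dtype == np.float32:
            gout32 = np.ascontiguousarray(gout, dtype=_F32)
            gxp = np.zeros_like(xp)
            _ck.conv3d_backward(xp, self.W, gout32, *self.stride,
                                self.gW, self.gb, gxp,
                                self.needs_input_grad)
            if p:
                _, z, y, x = self._in_shape
                gxp = gxp[:, p:p + z, p:p + y, p:p + x]
            self._xp = None
            return gxp
        gflat = np.ascontiguousarray(gout.reshape(gout.shape[0], -1))
        gxp = np.zeros_like(xp)
        if self._cols is not None:
            gwmat = gflat @ self._cols.T  # (C_out, k^3 * C_in)
            self.gW += gwmat.reshape(
                self.W.shape[0], k, k, k, c_in
            ).transpose(0, 4, 1, 2, 3)
            gcols = self._wmat().T @ gflat  # (k^3 * C_in, N)
            for o, (a, b, c) in enumerate(product(range(k), repeat=3)):
                gview = self._offset_view(gxp, a, b, c, out_sp)
                gview += gcols[o * c_in:(o + 1) * c_in].reshape(gview.shape)
            self._cols = None
        else:
            for a, b, c in product(range(k), repeat=3):
                xs = self._offset_view(xp, a, b, c, out_sp).reshape(c_in, n)
                self.gW[:, :, a, b, c] += gflat @ xs.T
                gview = self._offset_view(gxp, a, b, c, out_sp)
                gview += (self.W[:, :, a, b, c].T @ gflat).reshape(gview.shape)
        self.gb += gflat.sum(axis=1)
        if p:
            _, z, y, x = self._in_shape
            gxp = gxp[:, p:p + z, p:p + y, p:p + x]
        self._xp = None
        return gxp


class InstanceNorm3d:
    """Per-channel normalization over the spatial axes, with affine scale/shift."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=_F32)
        self.beta = np.zeros(c, dtype=_F32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._xhat, self._inv_std = xhat, inv_std
        return (self.gamma[:, None, None, None] * xhat + self.beta[:, None, None, None]).astype(_F32, copy=False)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.ggamma += (gout * xhat).sum(axis=(1, 2, 3))
        self.gbeta += gout.sum(axis=(1, 2, 3))
        gxhat = gout * self.gamma[:, None, None, None]
        m1 = gxhat.mean(axis=(1, 2, 3), keepdims=True)
        m2 = (gxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
        gx = inv_std * (gxhat - m1 - xhat * m2)
        self._xhat = self._inv_std = None
        return gx.astype(_F32, copy=False)


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(_F32, copy=False)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gx = np.where(self._mask, gout, self.slope * gout)
        self._mask = None
        return gx.astype(_F32, copy=False)


class Upsample:
    """Nearest-neighbour upsampling by integer per-axis factors."""

    def __init__(self, factors: tuple[int, int, int]):
        self.factors = tuple(factors)

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        fz, fy, fx = self.factors
        out = x
        if fz > 1:
            out = np.repeat(out, fz, axis=1)
        if fy > 1:
            out = np.repeat(out, fy, axis=2)
        if fx > 1:
            out = np.repeat(out, fx, axis=3)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        fz, fy, fx = self.factors
        c, z, y, x = gout.shape
        g = gout.reshape(c, z // fz, fz, y // fy, fy, x // fx, fx)
        return g.sum(axis=(2, 4, 6)).astype(_F32, copy=False)


class _ConvBlock:
    """Conv -> InstanceNorm -> LeakyReLU."""

    def __init__(self, c_in, c_out, stride, rng, kernel=3):
        self.layers = [
            Conv3d(c_in, c_out, kernel=kernel, stride=stride, rng=rng),
            InstanceNorm3d(c_out),
            LeakyReLU(),
        ]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g

    def params(self):
        return [p for lay in self.layers for p in lay.params()]


class UNet3D:
    """Encoder-decoder segmentation network with skip connections.

    Each encoder stage applies two 3x3x3 convolutions (the first carries the
    stage's downsampling stride) with instance normalization and leaky ReLU.
    The decoder mirrors the encoder: nearest-neighbour upsampling by the
    corresponding stage stride, concatenation with the skip feature map, and
    two convolutions. A 1x1x1 convolution produces per-class scores.
    """

    def __init__(
        self,
        features: tuple[int, ...],
        strides: tuple[tuple[int, int, int], ...],
        n_classes: int = 3,
        in_channels: int = 1,
        rng: np.random.Generator | None = None,
    ):
        if len(features) != len(strides):
            raise ValueError("features and strides must have equal length")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.features = tuple(features)
        self.strides = tuple(tuple(s) for s in strides)
        self.n_classes = n_classes
        self.in_channels = in_channels

        self.enc: list[list[_ConvBlock]] = []
        c_prev = in_channels
        for f, s in zip(self.features, self.strides):
            self.enc.append([
                _ConvBlock(c_prev, f, s, rng),
                _ConvBlock(f, f, (1, 1, 1), rng),
            ])
            c_prev = f

        self.dec: list[dict] = []
        for i in range(len(self.features) - 2, -1, -1):
            f_skip = self.features[i]
            f_deep = self.features[i + 1]
            self.dec.append({
                "up": Upsample(self.strides[i + 1]),
                "blocks": [
                    _ConvBlock(f_deep + f_skip, f_skip, (1, 1, 1), rng),
                    _ConvBlock(f_skip, f_skip, (1, 1, 1), rng),
                ],
                "skip_index": i,
            })
        self.head = Conv3d(self.features[0], n_classes, kernel=1, rng=rng)
        self.enc[0][0].layers[0].needs_input_grad = False
        self._skips: list[np.ndarray] | None = None

    # ---- shape bookkeeping -------------------------------------------
    def stage_shapes(self, input_shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        """Spatial shape after each encoder stage; raises on indivisibility."""
        shapes = []
        cur = tuple(input_shape)
        for s in self.strides:
            for dim, st in zip(cur, s):
                if dim % st:
                    raise ValueError(
                        f"input shape {input_shape} not divisible by cumulative "
                        f"strides (failing at stride {s} on extent {dim})"
                    )
            cur = tuple(d // st for d, st in zip(cur, s))
            shapes.append(cur)
        return shapes

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for p, _ in self.parameters())

    # ---- forward / backward ------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map (in_channels, Z, Y, X) to class scores (n_classes, Z, Y, X)."""
        if x.ndim != 4 or x.shape[0] != self.in_channels:
            raise ValueError(f"expected ({self.in_channels}, Z, Y, X), got {x.shape}")
        self.stage_shapes(x.shape[1:])
        x = x.astype(_F32, copy=False)
        skips = []
        for blocks in self.enc:
            for blk in blocks:
                x = blk.forward(x)
            skips.append(x)
        self._skips = skips
        for step in self.dec:
            x = step["up"].forward(x)
            skip = skips[step["skip_index"]]
            x = np.concatenate([x, skip], axis=0)
            for blk in step["blocks"]:
                x = blk.forward(x)
        return self.head.forward(x)

    def backward(self, glogits: np.ndarray) -> None:
        g = self.head.backward(glogits)
        skip_grads: dict[int, np.ndarray] = {}
        for step in reversed(self.dec):
            for blk in reversed(step["blocks"]):
                g = blk.backward(g)
            f_deep = self.features[step["skip_index"] + 1]
            g_deep, g_skip = g[:f_deep], g[f_deep:]
            skip_grads[step["skip_index"]] = g_skip
            g = step["up"].backward(g_deep)
        for i in range(len(self.enc) - 1, -1, -1):
            if i in skip_grads:
                g = g + skip_grads[i] if i < len(self.enc) - 1 else skip_grads[i]
            for blk in reversed(self.enc[i]):
                g = blk.backward(g)
        self._skips = None

    def parameters(self):
        out = []
        for blocks in self.enc:
            for blk in blocks:
                out.extend(blk.params())
        for step in self.dec:
            for blk in step["blocks"]:
                out.extend(blk.params())
        out.extend(self.head.params())
        return out

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0

    # ---- weight (de)serialization ------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match architecture")
        for (p, _), w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape {w.shape} != parameter {p.shape}")
            p[...] = w


class SGDNesterov:
    """SGD with Nesterov momentum and global gradient-norm clipping."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.99,
                 clip_norm: float | None = 12.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((g * g).sum()) for _, g in self.params))
            if total > self.clip_norm and total > 0:
                scale = _F32(self.clip_norm / total)
                for _, g in self.params:
                    g *= scale
        mu = _F32(self.momentum)
        lr = _F32(self.lr)
        for (p, g), v in zip(self.params, self.velocity):
            v *= mu
            v += g
            p -= lr * (g + mu * v)
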