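"""Numba JIT kernels for 3D convolution.

Direct convolution loops (channels-first, same padding handled by the
caller) that keep the working set in cache instead of materializing an
im2col buffer. Inner loops are specialized for unit x-stride so they
vectorize. Used by :class:`nerveseg.nn.Conv3d` when numba is available; the
pure-NumPy GEMM path remains as fallback and as the reference in tests.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco


@njit(fastmath=True, cache=False)
def conv3d_forward(xp, W, b, sz, sy, sx, out):
    c_out, c_in, k, _, _ = W.shape
    _, zo_n, yo_n, xo_n = out.shape
    for o in range(c_out):
        for zo in range(zo_n):
            for yo in range(yo_n):
                orow = out[o, zo, yo]
                for xo in range(xo_n):
                    orow[xo] = b[o]
                for i in range(c_in):
                    for a in range(k):
                        xpl = xp[i, zo * sz + a]
                        for bb in range(k):
                            xin = xpl[yo * sy + bb]
                            for cc in range(k):
                                w = W[o, i, a, bb, cc]
                                if sx == 1:
                                    for xo in range(xo_n):
                                        orow[xo] += w * xin[cc + xo]
                                else:
                                    for xo in range(xo_n):
                                        orow[xo] += w * xin[cc + xo * sx]


@njit(fastmath=True, cache=False)
def conv3d_backward(xp, W, gout, sz, sy, sx, gW, gb, gxp, need_gx):
    c_out, c_in, k, _, _ = W.shape
    _, zo_n, yo_n, xo_n = gout.shape
    # bias gradient
    for o in range(c_out):
        s = 0.0
        for zo in range(zo_n):
            for yo in range(yo_n):
                grow = gout[o, zo, yo]
                for xo in range(xo_n):
                    s += grow[xo]
        gb[o] += s
    # weight gradient: scalar reductions over cache-resident rows
    for o in range(c_out):
        for i in range(c_in):
            for a in range(k):
                for bb in range(k):
                    for cc in range(k):
                        acc = 0.0
                        for zo in range(zo_n):
                            xpl = xp[i, zo * sz + a]
                            for yo in range(yo_n):
                                xin = xpl[yo * sy + bb]
                                grow = gout[o, zo, yo]
                                if sx == 1:
                                    for xo in range(xo_n):
                                        acc += grow[xo] * xin[cc + xo]
                                else:
                                    for xo in range(xo_n):
                                        acc += grow[xo] * xin[cc + xo * sx]
                        gW[o, i, a, bb, cc] += acc
    # input gradient: scatter into padded-input rows
    if not need_gx:
        return
    for i in range(c_in):
        for o in range(c_out):
            for zo in range(zo_n):
                for a in range(k):
                    gxl = gxp[i, zo * sz + a]
                    for yo in range(yo_n):
                        grow = gout[o, zo, yo]
                        for bb in range(k):
                            gxrow = gxl[yo * sy + bb]
                            for cc in range(k):
                                w = W[o, i, a, bb, cc]
                                if sx == 1:
                                    for xo in range(xo_n):
                                        gxrow[cc + xo] += w * grow[xo]
                                else:
                                    for xo in range(xo_n):
                                        gxrow[cc + xo * sx] += w * grow[xo]
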