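"""Minimal NumPy layers (forward + backward) for the Siamese CNN.

Valid-mode stride-1 convolution (cross-correlation convention), 2x2/
stride-2 max pooling with first-maximum tie routing, ReLU and a dense
layer.  Convolutions switch between an FFT path (large spatial extents)
and direct per-offset accumulation (small ones); both are exact
convolutions and fully deterministic.  All arithmetic is float32.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

DTYPE = np.float32

#: direct-accumulation cost (C * k * k * OH * OW) above which the FFT path is used
_FFT_THRESHOLD = 150_000


def _conv_cost(C: int, k: int, OH: int, OW: int) -> int:
    return C * k * k * OH * OW


def conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x: (B, C, H, W); W: (Cout, C, kh, kw) -> (out, cache)."""
    B, C, H, Wd = x.shape
    Cout, _, kh, kw = W.shape
    OH, OW = H - kh + 1, Wd - kw + 1
    if _conv_cost(C, kh, OH, OW) > _FFT_THRESHOLD:
        out = fftconvolve(
            x[:, None], W[None, :, :, ::-1, ::-1], mode="valid", axes=(3, 4)
        ).sum(axis=2)
        out = out.astype(DTYPE, copy=False) + b[None, :, None, None]
    else:
        acc = np.zeros((B, Cout, OH, OW), dtype=DTYPE)
        for u in range(kh):
            for v in range(kw):
                t = np.tensordot(W[:, :, u, v], x[:, :, u:u + OH, v:v + OW], axes=(1, 1))
                acc += t.transpose(1, 0, 2, 3)
        out = acc + b[None, :, None, None]
    return out, x


def conv2d_backward(dout: np.ndarray, x: np.ndarray, W: np.ndarray, x_shape):
    B, C, H, Wd = x_shape
    Cout, _, kh, kw = W.shape
    OH, OW = H - kh + 1, Wd - kw + 1
    P = OH * OW
    # hoist the (Cout, B*P) layout once; per-offset work is then pure GEMM
    doutm = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(Cout, B * P)
    dW = np.empty_like(W)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    for u in range(kh):
        for v in range(kw):
            xs = np.ascontiguousarray(x[:, :, u:u + OH, v:v + OW]).reshape(B, C, P)
            xsm = xs.transpose(0, 2, 1).reshape(B * P, C)
            dW[:, :, u, v] = doutm @ xsm
            t = (W[:, :, u, v].T @ doutm).reshape(C, B, OH, OW)
            dx[:, :, u:u + OH, v:v + OW] += t.transpose(1, 0, 2, 3)
    db = dout.sum(axis=(0, 2, 3))
    return dx, dW, db


def maxpool2_forward(x: np.ndarray):
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped."""
    B, C, H, W = x.shape
    H2, W2 = H // 2, W // 2
    xw = np.ascontiguousarray(
        x[:, :, : H2 * 2, : W2 * 2]
        .reshape(B, C, H2, 2, W2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
    ).reshape(B, C, H2, W2, 4)
    idx = xw.argmax(axis=-1)                                 # first max wins ties
    out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2_backward(dout: np.ndarray, cache):
    idx, x_shape = cache
    B, C, H, W = x_shape
    H2, W2 = idx.shape[2], idx.shape[3]
    dxw = np.zeros((B, C, H2, W2, 4), dtype=dout.dtype)
    np.put_along_axis(dxw, idx[..., None], dout[..., None], axis=-1)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, :, : H2 * 2, : W2 * 2] = (
        dxw.reshape(B, C, H2, W2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(B, C, H2 * 2, W2 * 2)
    )
    return dx


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable in both tails
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce(p: np.ndarray, t: np.ndarray, eps: float = 1e-7) -> float:
    pc = np.clip(p, eps, 1.0 - eps)
    return float(-(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)).mean())
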