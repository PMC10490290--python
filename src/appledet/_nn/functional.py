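"""Structured ops (convolution, pooling, normalization) with custom backward passes.

Convolution uses an im2col + GEMM formulation; the column gradient is
scattered back with a k*k loop of strided adds (col2im).  All ops follow the
"same" padding convention pad = k // 2.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    # xp: padded (N, C, Hp, Wp) -> (N, Ho, Wo, C, k, k)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    return win.transpose(0, 2, 3, 1, 4, 5)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int | None = None) -> Tensor:
    """2-D convolution, NCHW, square kernel, pad = k//2 unless given."""
    co, ci, k, _ = weight.shape
    n, c, h, w = x.shape
    if c != ci:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    pad = k // 2 if padding is None else padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = np.ascontiguousarray(_im2col(xp, k, stride)).reshape(n * ho * wo, ci * k * k)
    wmat = weight.data.reshape(co, ci * k * k)
    out = cols @ wmat.T
    if bias is not None:
        out += bias.data
    out_data = out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    out_data = np.ascontiguousarray(out_data)

    def bwd(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        if weight.requires_grad:
            weight._accumulate((gm.T @ cols).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gm.sum(axis=0))
        if x.requires_grad:
            dcols = (gm @ wmat).reshape(n, ho, wo, ci, k, k)
            dxp = np.zeros_like(xp)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] += \
                        dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            if pad:
                dxp = dxp[:, :, pad:-pad or None, pad:-pad or None]
            x._accumulate(dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out_data, parents=parents, backward=bwd)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.03, eps: float = 1e-3) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    Running statistics are updated in place in training mode (exponential
    moving average with the given momentum, the YOLOv5 convention).
    """
    n, c, h, w = x.shape
    axes = (0, 2, 3)
    if training:
        m = x.data.mean(axis=axes)
        v = x.data.var(axis=axes)
        cnt = n * h * w
        running_mean += momentum * (m - running_mean)
        # unbiased estimate into the running buffer
        running_var += momentum * (v * cnt / max(cnt - 1, 1) - running_var)
    else:
        m, v = running_mean, running_var
    inv_std = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data[None, :, None, None]
            if training:
                cnt = n * h * w
                t1 = dxhat.sum(axis=axes, keepdims=True)
                t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                dx = (dxhat - t1 / cnt - xhat * t2 / cnt) * inv_std[None, :, None, None]
            else:
                dx = dxhat * inv_std[None, :, None, None]
            x._accumulate(dx.astype(np.float32))

    return Tensor(out_data.astype(np.float32), parents=(x, gamma, beta), backward=bwd)


def max_pool2d(x: Tensor, k: int, stride: int = 1) -> Tensor:
    """Max pooling with same padding (k odd), default stride 1 (SPPF style)."""
    if k % 2 == 0:
        raise ValueError("max_pool2d requires odd kernel for same padding")
    n, c, h, w = x.shape
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, k * k)
    amax = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, amax[..., None], axis=-1)[..., 0]

    def bwd(g):
        dxp = np.zeros_like(xp)
        ii, jj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        src_i = ii[None, None] * stride + amax // k
        src_j = jj[None, None] * stride + amax % k
        nn, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        np.add.at(dxp, (nn[:, :, None, None], cc[:, :, None, None], src_i, src_j), g)
        x._accumulate(dxp[:, :, pad:-pad, pad:-pad])

    return Tensor(np.ascontiguousarray(out_data), parents=(x,), backward=bwd)


def upsample_nearest2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor(out_data, parents=(x,), backward=bwd)


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on logits (numerically stable)."""
    z = logits.data
    t = np.asarray(target, dtype=np.float32)
    out_data = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))

    def bwd(g):
        sig = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate(g * (sig - t))

    return Tensor(out_data.astype(np.float32), parents=(logits,), backward=bwd)
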