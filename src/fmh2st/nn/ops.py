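"""Differentiable building blocks on numpy arrays.

All ops are pure functions of ``(params, inputs)`` written with
``autograd.numpy`` so the whole dual-branch forward pass can be differentiated
with reverse-mode AD. Parameters live in nested dicts of plain numpy arrays.

Batch norm keeps non-trainable running statistics in a separate mutable
``state`` dict; updates are stripped of autograd boxes via ``getval`` so the
side effect is never traced. In eval mode the running statistics are used,
which makes inference deterministic.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval

# ---------------------------------------------------------------------------
# initializers


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def conv_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    # shape (out_c, in_c, kh, kw); He-style fan-in scaling
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------------
# activations


def relu(x):
    return anp.maximum(x, 0.0)


def leaky_relu(x, slope: float = 0.2):
    return anp.where(x >= 0, x, slope * x)


def elu(x, alpha: float = 1.0):
    # clip the exp argument: ELU is ~-alpha below -30 anyway and this keeps
    # the untaken branch of `where` from overflowing
    return anp.where(x >= 0, x, alpha * (anp.exp(anp.minimum(x, 0.0)) - 1.0))


def tanh(x):
    # clip keeps the cosh^2 in the tanh gradient from overflowing; tanh is
    # saturated to machine precision well before |x| = 30
    return anp.tanh(anp.clip(x, -30.0, 30.0))


def gelu(x):
    return 0.5 * x * (1.0 + tanh(np.sqrt(2.0 / np.pi) * (x + 0.044715 * x**3)))


def sigmoid(x):
    return 0.5 * (tanh(0.5 * x) + 1.0)


def softmax(x, axis: int = -1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# dense layers


def linear_init(rng, d_in: int, d_out: int) -> dict:
    return {"W": glorot(rng, (d_in, d_out)), "b": np.zeros(d_out)}


def linear(params: dict, x):
    return anp.dot(x, params["W"]) + params["b"]


def mlp2_init(rng, d_in: int, d_hidden: int, d_out: int) -> dict:
    return {"l1": linear_init(rng, d_in, d_hidden), "l2": linear_init(rng, d_hidden, d_out)}


def mlp2(params: dict, x, act=elu):
    return linear(params["l2"], act(linear(params["l1"], x)))


# ---------------------------------------------------------------------------
# batch norm


def batchnorm_init(n_channels: int) -> tuple[dict, dict]:
    params = {"gamma": np.ones(n_channels), "beta": np.zeros(n_channels)}
    state = {"mean": np.zeros(n_channels), "var": np.ones(n_channels)}
    return params, state


def batchnorm(params: dict, state: dict, x, train: bool, eps: float = 1e-5,
              momentum: float = 0.1):
    """Normalize over all axes except the channel axis (axis 1 for 4-D maps,
    last axis for 2-D)."""
    if x.ndim == 4:
        axes, shape = (0, 2, 3), (1, -1, 1, 1)
    else:
        axes, shape = (0,), (1, -1)
    if train:
        mean = anp.mean(x, axis=axes)
        var = anp.var(x, axis=axes)
        state["mean"] = (1 - momentum) * state["mean"] + momentum * getval(mean)
        state["var"] = (1 - momentum) * state["var"] + momentum * getval(var)
    else:
        mean, var = state["mean"], state["var"]
    xn = (x - anp.reshape(mean, shape)) / anp.sqrt(anp.reshape(var, shape) + eps)
    return xn * anp.reshape(params["gamma"], shape) + anp.reshape(params["beta"], shape)


# ---------------------------------------------------------------------------
# convolutions (im2col; inputs are N x C x H x W)


def _pad_same(x, kh: int, kw: int, mode: str = "constant"):
    ph0, ph1 = (kh - 1) // 2, kh // 2
    pw0, pw1 = (kw - 1) // 2, kw // 2
    return anp.pad(x, ((0, 0), (0, 0), (ph0, ph1), (pw0, pw1)), mode=mode)


def _im2col(x, kh: int, kw: int, stride: int = 1):
    """(N, C, H, W) -> (N, C, kh*kw, out_h*out_w) patch matrix."""
    n, c, h, w = x.shape
    out_h = (h - kh) // stride + 1
    out_w = (w - kw) // stride + 1
    i0 = np.repeat(np.arange(kh), kw)
    j0 = np.tile(np.arange(kw), kh)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    rows = i0[:, None] + i1[None, :]  # (kh*kw, P)
    cols = j0[:, None] + j1[None, :]
    cols_mat = x[:, :, rows, cols]  # (N, C, kh*kw, P)
    return cols_mat, out_h, out_w


def conv2d(params: dict, x, stride: int = 1, same: bool = True):
    """Standard convolution; params: W (O, C, kh, kw), b (O,)."""
    W, b = params["W"], params["b"]
    o, c, kh, kw = W.shape
    if same:
        x = _pad_same(x, kh, kw)
    cols, out_h, out_w = _im2col(x, kh, kw, stride)
    Wm = anp.reshape(W, (o, c * kh * kw))
    colsm = anp.reshape(cols, (x.shape[0], c * kh * kw, out_h * out_w))
    out = anp.einsum("ok,nkp->nop", Wm, colsm) + anp.reshape(b, (1, o, 1))
    return anp.reshape(out, (x.shape[0], o, out_h, out_w))


def depthwise_conv2d(params: dict, x, same: bool = True):
    """Per-channel convolution; params: W (C, kh, kw), b (C,)."""
    W, b = params["W"], params["b"]
    c, kh, kw = W.shape
    if same:
        x = _pad_same(x, kh, kw)
    cols, out_h, out_w = _im2col(x, kh, kw, 1)  # (N, C, kh*kw, P)
    Wm = anp.reshape(W, (c, kh * kw))
    out = anp.einsum("nckp,ck->ncp", cols, Wm) + anp.reshape(b, (1, c, 1))
    return anp.reshape(out, (x.shape[0], c, out_h, out_w))


def conv2d_init(rng, out_c: int, in_c: int, k: int) -> dict:
    return {"W": conv_init(rng, (out_c, in_c, k, k)), "b": np.zeros(out_c)}


def depthwise_init(rng, channels: int, k: int) -> dict:
    return {"W": conv_init(rng, (channels, 1, k, k))[:, 0], "b": np.zeros(channels)}
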