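"""Spot-specific branch: fine-grained features straight from patch pixels.

Pipeline per section: multiscale convolutions (kernels 3/5/7) each refined by
a CBAM (channel then spatial attention), fused by a 1x1 conv + batch norm;
``L`` ConvMixer blocks (depthwise + pointwise convs with a residual path);
a strided downsampling conv + flatten to one vector per spot; a transformer
with learned x/y positional embeddings attending across all spots of the
section; and finally a GAT over the spatial graph.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from .foundation_branch import gat_encode, gat_init
from .nn import (
    batchnorm,
    batchnorm_init,
    conv2d,
    conv2d_init,
    depthwise_conv2d,
    depthwise_init,
    gelu,
    glorot,
    linear,
    linear_init,
    relu,
    sigmoid,
    softmax,
)

__all__ = [
    "init_spot_params",
    "patches_to_float",
    "multiscale_extract",
    "convmixer_refine",
    "transformer_contextualize",
    "gat_contextualize",
    "spot_forward",
]

SCALES = (3, 5, 7)


def patches_to_float(patches: np.ndarray) -> np.ndarray:
    """uint8 H&E patches (N, H, W, 3) -> float (N, 3, H, W) in [0, 1]."""
    return np.transpose(patches.astype(float) / 255.0, (0, 3, 1, 2))


# ---------------------------------------------------------------------------
# CBAM


def _cbam_init(rng, channels: int, reduction: int = 2, spatial_kernel: int = 7) -> dict:
    hidden = max(1, channels // reduction)
    return {
        "mlp1": linear_init(rng, channels, hidden),
        "mlp2": linear_init(rng, hidden, channels),
        "spatial": conv2d_init(rng, 1, 2, spatial_kernel),
    }


def cbam(params: dict, x):
    """Channel attention (shared MLP on avg-/max-pooled descriptors) then
    spatial attention (conv over channel-wise avg/max maps)."""
    avg = anp.mean(x, axis=(2, 3))
    mx = anp.max(anp.reshape(x, x.shape[:2] + (-1,)), axis=2)

    def shared_mlp(v):
        return linear(params["mlp2"], relu(linear(params["mlp1"], v)))

    m_c = sigmoid(shared_mlp(avg) + shared_mlp(mx))  # (N, C)
    x = x * m_c[:, :, None, None]

    avg_map = anp.mean(x, axis=1, keepdims=True)
    max_map = anp.max(x, axis=1, keepdims=True)
    m_s = sigmoid(conv2d(params["spatial"], anp.concatenate([avg_map, max_map], axis=1)))
    return x * m_s


# ---------------------------------------------------------------------------
# parameter initialization


def init_spot_params(
    rng: np.random.Generator,
    patch_size: int,
    scale_channels: int = 32,
    n_blocks: int = 4,
    dw_kernel: int = 7,
    down_spatial: int = 4,
    down_channels: int = 32,
    n_heads: int = 8,
    d_out: int = 256,
    gat_heads: int = 4,
    pos_vocab: int = 64,
) -> tuple[dict, dict]:
    """Returns (params, batch-norm state). ``flat_dim = down_channels * down_spatial**2``."""
    if patch_size % down_spatial != 0:
        raise ValueError("patch_size must be divisible by down_spatial")
    fused_c = 2 * scale_channels
    flat_dim = down_channels * down_spatial**2
    if flat_dim % n_heads != 0:
        raise ValueError("flat feature length must be divisible by the head count")
    d_k = flat_dim // n_heads

    params: dict = {"scales": {}, "cbam": {}}
    state: dict = {}
    for n in SCALES:
        params["scales"][f"k{n}"] = conv2d_init(rng, scale_channels, 3, n)
        params["cbam"][f"k{n}"] = _cbam_init(rng, scale_channels)
    params["fuse1x1"] = conv2d_init(rng, fused_c, 3 * scale_channels, 1)
    params["fuse_bn"], state["fuse_bn"] = batchnorm_init(fused_c)

    params["mixer"] = []
    state["mixer"] = []
    for _ in range(n_blocks):
        blk = {
            "dw": depthwise_init(rng, fused_c, dw_kernel),
            "pw": conv2d_init(rng, fused_c, fused_c, 1),
        }
        st = {}
        blk["dw_bn"], st["dw_bn"] = batchnorm_init(fused_c)
        blk["pw_bn"], st["pw_bn"] = batchnorm_init(fused_c)
        params["mixer"].append(blk)
        state["mixer"].append(st)

    stride = patch_size // down_spatial
    params["down"] = conv2d_init(rng, down_channels, fused_c, stride)
    state["down_stride"] = stride  # static config; kept out of the trained params

    params["pos_x"] = rng.normal(0, 0.02, (pos_vocab, flat_dim))
    params["pos_y"] = rng.normal(0, 0.02, (pos_vocab, flat_dim))
    params["attn_heads"] = [
        {
            "Wq": glorot(rng, (flat_dim, d_k)),
            "Wk": glorot(rng, (flat_dim, d_k)),
            "Wv": glorot(rng, (flat_dim, d_k)),
        }
        for _ in range(n_heads)
    ]
    params["Wt"] = glorot(rng, (n_heads * d_k, flat_dim))
    params["gat"] = gat_init(rng, flat_dim, d_out, gat_heads)
    return params, state


# ---------------------------------------------------------------------------
# forward ops


def multiscale_extract(params: dict, state: dict, x, train: bool):
    """Hierarchical stage: per-scale conv + CBAM, then 1x1 fusion conv + BN."""
    if x.shape[2] < max(SCALES) or x.shape[3] < max(SCALES):
        raise ValueError(f"patch smaller than the largest kernel ({max(SCALES)})")
    feats = []
    for n in SCALES:
        g = conv2d(params["scales"][f"k{n}"], x)
        feats.append(cbam(params["cbam"][f"k{n}"], g))
    cat = anp.concatenate(feats, axis=1)
    return batchnorm(params["fuse_bn"], state["fuse_bn"], conv2d(params["fuse1x1"], cat), train)


def convmixer_refine(params: dict, state: dict, g0, train: bool):
    """L residual depthwise/pointwise blocks, then strided conv + flatten."""
    g = g0
    for blk, st in zip(params["mixer"], state["mixer"]):
        dw = batchnorm(blk["dw_bn"], st["dw_bn"], gelu(depthwise_conv2d(blk["dw"], g)), train)
        g = batchnorm(blk["pw_bn"], st["pw_bn"], gelu(conv2d(blk["pw"], dw + g)), train)
    s = state["down_stride"]
    down = conv2d(params["down"], g, stride=s, same=False)
    return anp.reshape(down, (down.shape[0], -1))


def transformer_contextualize(params: dict, g, array_coords: np.ndarray,
                              return_attention: bool = False):
    """Positional lookup + multi-head self-attention across the section's spots."""
    vocab = params["pos_x"].shape[0]
    ax, ay = array_coords[:, 0], array_coords[:, 1]
    if np.any(ax < 0) or np.any(ay < 0) or np.any(ax >= vocab) or np.any(ay >= vocab):
        raise ValueError("array coordinate outside the positional-embedding table")
    gt = g + params["pos_x"][ax] + params["pos_y"][ay]

    heads, attns = [], []
    for hp in params["attn_heads"]:
        q = anp.dot(gt, hp["Wq"])
        k = anp.dot(gt, hp["Wk"])
        v = anp.dot(gt, hp["Wv"])
        a = softmax(anp.dot(q, k.T) / np.sqrt(q.shape[1]), axis=1)
        heads.append(anp.dot(a, v))
        attns.append(a)
    out = anp.dot(anp.concatenate(heads, axis=1), params["Wt"])
    if return_attention:
        return out, attns
    return out


def gat_contextualize(params: dict, g_t, spatial_neighbors):
    """Same GAT mechanics as the foundation branch, on the spatial graph."""
    return gat_encode(params, g_t, spatial_neighbors)


def spot_forward(params: dict, state: dict, patches_f, array_coords, spatial_neighbors,
                 train: bool):
    g0 = multiscale_extract(params, state, patches_f, train)
    g = convmixer_refine(params, state, g0, train)
    g_t = transformer_contextualize(params, g, array_coords)
    return gat_contextualize(params["gat"], g_t, spatial_neighbors)
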