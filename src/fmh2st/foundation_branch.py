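"""Foundation-model branch: slice-aware, dual-graph-contextualized spot features.

A pretrained pathology image encoder is consumed only through a contract: any
callable mapping an RGB raster to a fixed-length vector. Spot patches and the
whole slice image are embedded by the same encoder (the backbone stays
frozen; embeddings are precomputed and cacheable), concatenated per spot and
fused by a two-layer MLP into ``h``. Two graph-attention encoders — one on the
spatial KNN graph, one on the semantic feature graph — then produce ``z_s``
and ``z_f``, which an attention aggregation layer combines into the branch
output ``z_F``.

The GAT encoder follows the standard multi-head formulation: per head,
edge logits ``e_ij = LeakyReLU(a^T [W h_i || W h_j])`` softmax-normalized over
each node's neighbor set, neighbor features averaged with those weights and
passed through ELU; head outputs are concatenated and a second single-head
attention layer reduces to the output width.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Callable, Protocol, runtime_checkable

import autograd.numpy as anp
import numpy as np

from .nn import elu, glorot, leaky_relu, mlp2, mlp2_init, softmax
from .nn.ops import tanh

__all__ = [
    "BackboneContract",
    "embed_spots",
    "embed_slice",
    "fuse_multilevel",
    "gat_init",
    "gat_encode",
    "attention_aggregate_init",
    "attention_aggregate",
    "init_foundation_params",
    "foundation_forward",
]


@runtime_checkable
class BackboneContract(Protocol):
    """Image -> fixed-length feature vector; deterministic; constant length."""

    name: str

    def __call__(self, image: np.ndarray) -> np.ndarray: ...


# registry so external pretrained adapters can be plugged in by name
BACKBONES: dict[str, Callable[[], BackboneContract]] = {}


def register_backbone(name: str, ctor: Callable[[], BackboneContract]) -> None:
    BACKBONES[name] = ctor


def get_backbone(name: str) -> BackboneContract:
    if name not in BACKBONES:
        raise KeyError(f"unknown backbone {name!r}; registered: {sorted(BACKBONES)}")
    return BACKBONES[name]()


def _cache_key(backbone: BackboneContract, section_id: str, data: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(getattr(backbone, "name", "anon").encode())
    h.update(section_id.encode())
    h.update(np.ascontiguousarray(data).tobytes())
    return h.hexdigest()[:16]


def embed_spots(
    backbone: BackboneContract,
    patches: np.ndarray,
    section_id: str = "",
    cache_dir: str | Path | None = None,
) -> np.ndarray:
    """Embed every spot patch; rows follow patch order.

    With ``cache_dir`` set, embeddings are persisted keyed by
    (backbone id, section, patch-stack hash) and reloaded bitwise-identical.
    """
    if cache_dir is not None:
        key = _cache_key(backbone, section_id, patches)
        f = Path(cache_dir) / f"spots_{key}.npz"
        if f.exists():
            return np.load(f)["h_sp"]
    rows = [np.asarray(backbone(p), dtype=float) for p in patches]
    lengths = {r.shape for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"backbone output length varies: {lengths}")
    h_sp = np.stack(rows)
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        np.savez(f, h_sp=h_sp)
    return h_sp


def embed_slice(backbone: BackboneContract, image: np.ndarray) -> np.ndarray:
    """One global embedding per section, broadcast to its spots downstream.

    The whole-slide image is passed to the backbone as-is; backbones that
    need a fixed input size are expected to resize internally.
    """
    return np.asarray(backbone(image), dtype=float)


# ---------------------------------------------------------------------------
# multilevel fusion


def fuse_multilevel(params: dict, h_sp, h_sl):
    """h_i = MLP([h_i^sp || h_i^sl]); two linear layers with ELU between."""
    n = h_sp.shape[0]
    h_sl_b = anp.broadcast_to(anp.reshape(h_sl, (1, -1)), (n, h_sl.shape[-1]))
    return mlp2(params, anp.concatenate([h_sp, h_sl_b], axis=1), act=elu)


# ---------------------------------------------------------------------------
# GAT encoder (used on both graphs here and on the spatial graph in the
# spot-specific branch)


def gat_init(rng: np.random.Generator, d_in: int, d_out: int, n_heads: int = 4,
             d_head: int | None = None) -> dict:
    if d_head is None:
        d_head = max(1, d_out // n_heads)
    heads = []
    for _ in range(n_heads):
        heads.append({
            "W": glorot(rng, (d_in, d_head)),
            "a_src": rng.normal(0, 0.1, d_head),
            "a_dst": rng.normal(0, 0.1, d_head),
        })
    return {
        "heads": heads,
        "out": {
            "W": glorot(rng, (n_heads * d_head, d_out)),
            "a_src": rng.normal(0, 0.1, d_out),
            "a_dst": rng.normal(0, 0.1, d_out),
        },
    }


def _attention_layer(p: dict, h, neighbors, return_alpha: bool = False):
    """One graph-attention head: softmax over each node's neighbor set."""
    Wh = anp.dot(h, p["W"])  # (n, d)
    logits = anp.dot(Wh, p["a_src"])[:, None] + anp.dot(Wh, p["a_dst"])[neighbors]
    e = leaky_relu(logits, 0.2)  # (n, k)
    alpha = softmax(e, axis=1)
    out = anp.sum(alpha[:, :, None] * Wh[neighbors], axis=1)
    if return_alpha:
        return elu(out), alpha
    return elu(out)


def gat_encode(params: dict, h, neighbors, return_alpha: bool = False):
    """Multi-head attention + single-head reduction over one spot graph.

    ``neighbors`` is the n x k out-neighbor array of a :class:`SpotGraph`.
    """
    outs, alphas = [], []
    for p in params["heads"]:
        if return_alpha:
            o, a = _attention_layer(p, h, neighbors, return_alpha=True)
            alphas.append(a)
        else:
            o = _attention_layer(p, h, neighbors)
        outs.append(o)
    g = anp.concatenate(outs, axis=1)
    if return_alpha:
        z, beta = _attention_layer(params["out"], g, neighbors, return_alpha=True)
        return z, alphas, beta
    return _attention_layer(params["out"], g, neighbors)


# ---------------------------------------------------------------------------
# attention aggregation of the two graph views


def attention_aggregate_init(rng: np.random.Generator, d: int, d_att: int | None = None) -> dict:
    d_att = d_att or d
    return {"W": glorot(rng, (d, d_att)), "b": np.zeros(d_att), "q": rng.normal(0, 0.1, d_att)}


def attention_aggregate(params: dict, z_s, z_f, return_weights: bool = False):
    """Per-spot convex combination of the two graph views.

    Scores ``e_i^m = q^T tanh(W z_i^m + b)`` are softmax-normalized over the
    pair (spatial, feature); the output is the weighted sum.
    """
    def score(z):
        return anp.dot(tanh(anp.dot(z, params["W"]) + params["b"]), params["q"])

    e = anp.stack([score(z_s), score(z_f)], axis=1)  # (n, 2)
    w = softmax(e, axis=1)
    out = w[:, 0:1] * z_s + w[:, 1:2] * z_f
    if return_weights:
        return out, w
    return out


# ---------------------------------------------------------------------------
# full branch


def init_foundation_params(rng: np.random.Generator, d_fm: int, d_h: int = 256,
                           d_out: int = 256, n_heads: int = 4) -> dict:
    return {
        "fuse": mlp2_init(rng, 2 * d_fm, d_h, d_h),
        "gat_s": gat_init(rng, d_h, d_out, n_heads),
        "gat_f": gat_init(rng, d_h, d_out, n_heads),
        "agg": attention_aggregate_init(rng, d_out),
    }


def foundation_forward(params: dict, h_sp, h_sl, spatial_neighbors, feature_neighbors):
    """Full branch: fuse multilevel features, encode both graphs, aggregate.

    Returns ``(z_F, h)`` — the branch output and the fused features ``h`` the
    learnable feature graph is rebuilt from.
    """
    h = fuse_multilevel(params["fuse"], h_sp, h_sl)
    z_s = gat_encode(params["gat_s"], h, spatial_neighbors)
    z_f = gat_encode(params["gat_f"], h, feature_neighbors)
    z_F = attention_aggregate(params["agg"], z_s, z_f)
    return z_F, h
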