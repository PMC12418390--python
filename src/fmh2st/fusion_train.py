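"""Branch fusion, the three prediction heads, the collaborative loss, and the
training / inference loops.

The two branch outputs are projected to a shared fusion width, combined by
the same attention-aggregation mechanism used inside the foundation branch,
and mapped to the gene dimension by a linear head. Two further single-layer
heads predict expression from each branch alone; their losses mix a
ground-truth MSE term with a distillation term toward the fused prediction:

    L_B = (1 - alpha) * mean((y_B - y)^2) + alpha * mean((y_B - y_U)^2)
    L_U = mean((y_U - y)^2)
    L   = L_U + L_F + L_S

Squared errors are averaged over spots *and* genes so the loss magnitude does
not scale with the gene-vocabulary size. Training is Adam with one step per
training section per epoch; the semantic feature graph is rebuilt from the
current fused features every ``rebuild_every`` epochs.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.tracer import getval

from . import foundation_branch as fb
from . import spot_branch as sb
from .graphs import build_feature_graph, build_spatial_graph
from .nn import Adam, linear, linear_init
from .st_data import CVSplit, STDataset, Section, extract_patches

__all__ = [
    "TrainingConfig",
    "PredictionTriple",
    "LossBreakdown",
    "Checkpoint",
    "fuse_branches",
    "predict_heads",
    "compute_losses",
    "train",
    "predict_section",
    "save_predictions",
]


@dataclass
class TrainingConfig:
    """All tunable knobs; defaults target real Visium-scale data. Use
    :meth:`tiny` for desk-scale synthetic runs."""

    # optimization
    alpha: float = 0.3          # distillation weight in [0, 1]
    lr: float = 1e-4
    lr_decay: float = 1.0       # per-epoch multiplicative decay
    epochs: int = 100
    seed: int = 0
    clip_norm: float = 5.0
    adam_betas: tuple = (0.9, 0.999)
    # graphs
    k_s: int = 4
    k_f: int = 8
    pca_dim: int = 50
    rebuild_every: int = 1      # epochs between feature-graph rebuilds
    # foundation branch
    d_h: int = 256
    d_out_f: int = 256
    gat_heads_f: int = 4
    # spot branch
    patch_size: int = 112
    scale_channels: int = 32
    n_blocks: int = 4
    dw_kernel: int = 7
    down_spatial: int = 4
    down_channels: int = 32
    attn_heads: int = 8
    d_out_s: int = 256
    gat_heads_s: int = 4
    pos_vocab: int = 64
    # fusion
    fusion_width: int = 256

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def tiny(cls, **overrides) -> "TrainingConfig":
        """Small widths + higher learning rate for the synthetic desk-scale scenario."""
        base = dict(
            lr=5e-3, lr_decay=0.99, adam_betas=(0.9, 0.95),
            epochs=100, d_h=32, d_out_f=32, gat_heads_f=2,
            patch_size=16, scale_channels=4, n_blocks=2, dw_kernel=3,
            down_spatial=4, down_channels=8, attn_heads=2, d_out_s=32,
            gat_heads_s=2, pos_vocab=16, fusion_width=32, pca_dim=8,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class PredictionTriple:
    """The three per-spot expression predictions (normalized-log units)."""

    y_U: np.ndarray  # fused head
    y_F: np.ndarray  # foundation-branch head
    y_S: np.ndarray  # spot-branch head

    def __post_init__(self) -> None:
        if not (np.shape(self.y_U) == np.shape(self.y_F) == np.shape(self.y_S)):
            raise ValueError("head predictions must share one shape")


@dataclass
class LossBreakdown:
    L_U: float
    L_F: float
    L_S: float
    L: float


@dataclass
class Checkpoint:
    params: dict
    state: dict
    config: TrainingConfig
    gene_vocabulary: list[str]
    backbone_name: str
    log: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with open(path, "rb") as fh:
            ckpt = pickle.load(fh)
        if not isinstance(ckpt, cls):
            raise TypeError(f"{path} is not a checkpoint file")
        return ckpt


# ---------------------------------------------------------------------------
# fusion + heads


def init_fusion_params(rng: np.random.Generator, cfg: TrainingConfig, d_fm: int,
                       n_genes: int) -> tuple[dict, dict]:
    fw = cfg.fusion_width
    params = {
        "foundation": fb.init_foundation_params(
            rng, d_fm, d_h=cfg.d_h, d_out=cfg.d_out_f, n_heads=cfg.gat_heads_f
        ),
        "proj_F": linear_init(rng, cfg.d_out_f, fw),
        "proj_S": linear_init(rng, cfg.d_out_s, fw),
        "fuse_att": fb.attention_aggregate_init(rng, fw),
        "head_U": linear_init(rng, fw, n_genes),
        "head_F": linear_init(rng, fw, n_genes),
        "head_S": linear_init(rng, fw, n_genes),
    }
    params["spot"], spot_state = sb.init_spot_params(
        rng,
        patch_size=cfg.patch_size,
        scale_channels=cfg.scale_channels,
        n_blocks=cfg.n_blocks,
        dw_kernel=cfg.dw_kernel,
        down_spatial=cfg.down_spatial,
        down_channels=cfg.down_channels,
        n_heads=cfg.attn_heads,
        d_out=cfg.d_out_s,
        gat_heads=cfg.gat_heads_s,
        pos_vocab=cfg.pos_vocab,
    )
    return params, {"spot": spot_state}


def fuse_branches(params: dict, z_F, z_S, return_weights: bool = False):
    """Project both branch outputs to the fusion width, then attention-fuse.

    Returns ``(z_U, z_F_proj, z_S_proj [, weights])``; the projected branch
    features also feed the two branch heads.
    """
    zf = linear(params["proj_F"], z_F)
    zs = linear(params["proj_S"], z_S)
    out = fb.attention_aggregate(params["fuse_att"], zf, zs, return_weights=return_weights)
    if return_weights:
        z_U, w = out
        return z_U, zf, zs, w
    return out, zf, zs


def predict_heads(params: dict, z_U, z_F, z_S) -> PredictionTriple:
    return PredictionTriple(
        y_U=linear(params["head_U"], z_U),
        y_F=linear(params["head_F"], z_F),
        y_S=linear(params["head_S"], z_S),
    )


def compute_losses(triple: PredictionTriple, y_true, alpha: float) -> LossBreakdown:
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if np.shape(getval(triple.y_U)) != np.shape(getval(np.asarray(y_true))):
        raise ValueError("prediction / truth shape mismatch")

    def mse(a, b):
        return anp.mean((a - b) ** 2)

    L_U = mse(triple.y_U, y_true)
    L_F = (1 - alpha) * mse(triple.y_F, y_true) + alpha * mse(triple.y_F, triple.y_U)
    L_S = (1 - alpha) * mse(triple.y_S, y_true) + alpha * mse(triple.y_S, triple.y_U)
    return LossBreakdown(L_U=L_U, L_F=L_F, L_S=L_S, L=L_U + L_F + L_S)


# ---------------------------------------------------------------------------
# per-section batches


@dataclass
class SectionBatch:
    section_id: str
    spot_ids: list[str]
    patches_f: np.ndarray          # (n, 3, ps, ps) float in [0, 1]
    h_sp: np.ndarray               # (n, d_fm)
    h_sl: np.ndarray               # (d_fm,)
    array_coords: np.ndarray       # (n, 2) int
    spatial_neighbors: np.ndarray  # (n, k_s)
    feature_neighbors: np.ndarray | None  # (n, k_f); rebuilt during training
    y: np.ndarray | None           # (n, G) normalized log expression


def prepare_section(section: Section, backbone, cfg: TrainingConfig,
                    cache_dir: str | Path | None = None) -> SectionBatch:
    patches = extract_patches(section, cfg.patch_size).patches
    h_sp = fb.embed_spots(backbone, patches, section.section_id, cache_dir)
    h_sl = fb.embed_slice(backbone, section.image)
    spatial = build_spatial_graph(section.coords, cfg.k_s)
    return SectionBatch(
        section_id=section.section_id,
        spot_ids=section.spots["spot_id"].astype(str).tolist(),
        patches_f=sb.patches_to_float(patches),
        h_sp=h_sp,
        h_sl=h_sl,
        array_coords=section.array_coords(n_bins=cfg.pos_vocab),
        spatial_neighbors=spatial.neighbors,
        feature_neighbors=None,
        y=section.expression,
    )


def rebuild_feature_graph(params: dict, batch: SectionBatch, cfg: TrainingConfig) -> None:
    """Recompute the semantic KNN graph from the current fused features h."""
    h = fb.fuse_multilevel(params["foundation"]["fuse"], batch.h_sp, batch.h_sl)
    g = build_feature_graph(np.asarray(h), k_f=cfg.k_f, pca_dim=cfg.pca_dim)
    batch.feature_neighbors = g.neighbors


def forward_section(params: dict, state: dict, batch: SectionBatch, train: bool):
    """Full dual-branch forward for one section. Returns (triple, fused h)."""
    z_F, h = fb.foundation_forward(
        params["foundation"], batch.h_sp, batch.h_sl,
        batch.spatial_neighbors, batch.feature_neighbors,
    )
    z_S = sb.spot_forward(
        params["spot"], state["spot"], batch.patches_f, batch.array_coords,
        batch.spatial_neighbors, train,
    )
    z_U, zf, zs = fuse_branches(params, z_F, z_S)
    return predict_heads(params, z_U, zf, zs), h


# ---------------------------------------------------------------------------
# training


def train(dataset: STDataset, split: CVSplit | None, config: TrainingConfig,
          backbone, cache_dir: str | Path | None = None,
          verbose: bool = False) -> Checkpoint:
    """Fit the dual-branch model on the split's training sections.

    One Adam step per training section per epoch; deterministic given
    (config.seed, backbone, data). Aborts with diagnostics on NaN loss.
    """
    train_ids = split.train_section_ids if split is not None else dataset.section_ids
    sections = [dataset.get_section(sid) for sid in train_ids]
    for s in sections:
        if s.expression is None:
            raise ValueError(f"section {s.section_id} is not preprocessed")

    rng = np.random.default_rng(config.seed)
    batches = [prepare_section(s, backbone, config, cache_dir) for s in sections]
    d_fm = batches[0].h_sp.shape[1]
    n_genes = len(dataset.gene_vocabulary)
    params, state = init_fusion_params(rng, config, d_fm, n_genes)
    # start every head at the training-set gene means: the heads then learn
    # deviations, which removes the long initial phase of rescaling outputs
    y_mean = np.vstack([b.y for b in batches]).mean(axis=0)
    for head in ("head_U", "head_F", "head_S"):
        params[head]["b"] = y_mean.copy()
    opt = Adam(params, lr=config.lr, betas=config.adam_betas, clip_norm=config.clip_norm)

    log: list[dict] = []
    for epoch in range(config.epochs):
        opt.lr = config.lr * config.lr_decay**epoch
        if epoch % config.rebuild_every == 0:
            for b in batches:
                rebuild_feature_graph(params, b, config)
        parts = np.zeros(4)
        for b in batches:
            holder: dict[str, float] = {}

            def loss_fn(p):
                triple, _ = forward_section(p, state, b, train=True)
                lb = compute_losses(triple, b.y, config.alpha)
                holder.update(
                    L_U=float(getval(lb.L_U)), L_F=float(getval(lb.L_F)),
                    L_S=float(getval(lb.L_S)),
                )
                return lb.L

            loss_val, grads = value_and_grad(loss_fn)(params)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, section {b.section_id}: "
                    f"{holder} — try a lower learning rate"
                )
            params = opt.step(params, grads)
            parts += [holder["L_U"], holder["L_F"], holder["L_S"], float(loss_val)]
        parts /= len(batches)
        entry = {"epoch": epoch, "L_U": parts[0], "L_F": parts[1],
                 "L_S": parts[2], "L": parts[3]}
        log.append(entry)
        if verbose:
            print("epoch {epoch:4d}  L_U={L_U:.5f}  L_F={L_F:.5f}  "
                  "L_S={L_S:.5f}  L={L:.5f}".format(**entry))

    return Checkpoint(
        params=params, state=state, config=config,
        gene_vocabulary=list(dataset.gene_vocabulary),
        backbone_name=getattr(backbone, "name", "custom"), log=log,
    )


def predict_section(checkpoint: Checkpoint, section: Section, backbone=None,
                    cache_dir: str | Path | None = None) -> PredictionTriple:
    """Inference on one section; graphs are built from the section itself, so
    predictions never depend on other sections."""
    if backbone is None:
        backbone = fb.get_backbone(checkpoint.backbone_name)
    if section.gene_ids != checkpoint.gene_vocabulary:
        raise ValueError(
            f"section {section.section_id} gene vocabulary does not match the checkpoint"
        )
    cfg = checkpoint.config
    batch = prepare_section(section, backbone, cfg, cache_dir)
    rebuild_feature_graph(checkpoint.params, batch, cfg)
    triple, _ = forward_section(checkpoint.params, checkpoint.state, batch, train=False)
    return PredictionTriple(
        y_U=np.asarray(triple.y_U), y_F=np.asarray(triple.y_F), y_S=np.asarray(triple.y_S)
    )


def save_predictions(triple: PredictionTriple, spot_ids: list[str], gene_ids: list[str],
                     out_prefix: str | Path) -> None:
    """Main head to ``<prefix>.tsv``; branch heads to companion files."""
    import pandas as pd

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    for name, mat in [("", triple.y_U), (".foundation", triple.y_F), (".spot", triple.y_S)]:
        pd.DataFrame(mat, index=spot_ids, columns=gene_ids).to_csv(
            Path(str(out_prefix) + name + ".tsv"), sep="\t"
        )
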