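"""Model/Results facade over the dual-branch pipeline.

``DualBranchModel`` is constructed from a preprocessed :class:`STDataset`
(plus a backbone and a :class:`TrainingConfig`); ``fit()`` runs the
collaborative training loop and returns a ``DualBranchResults`` carrying the
fitted parameters, the loss trajectory, prediction and evaluation methods,
and a ``summary()`` table. ``fit_loocv()`` runs the full
leave-one-section-out protocol and aggregates held-out metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import evaluation as ev
from .fusion_train import (
    Checkpoint,
    PredictionTriple,
    TrainingConfig,
    predict_section,
    train,
)
from .st_data import CVSplit, STDataset, Section, load_processed, make_loocv_splits

__all__ = ["DualBranchModel", "DualBranchResults", "CrossValidationResults"]


class DualBranchModel:
    """Spot-level expression-from-histology model over a multi-section dataset.

    Parameters
    ----------
    dataset
        Preprocessed dataset (sections carry normalized log expression).
    backbone
        Image->vector encoder satisfying the backbone contract.
    config
        Training configuration; defaults to :meth:`TrainingConfig.tiny` when
        the dataset is small (< 200 spots per section), else full defaults.
    """

    def __init__(self, dataset: STDataset, backbone, config: TrainingConfig | None = None,
                 cache_dir: str | Path | None = None):
        if config is None:
            small = max(s.n_spots for s in dataset.sections) < 200
            config = TrainingConfig.tiny() if small else TrainingConfig()
        self.dataset = dataset
        self.backbone = backbone
        self.config = config
        self.cache_dir = cache_dir

    @classmethod
    def from_directory(cls, path: str | Path, backbone,
                       config: TrainingConfig | None = None) -> "DualBranchModel":
        return cls(load_processed(path), backbone, config)

    def fit(self, split: CVSplit | None = None, verbose: bool = False) -> "DualBranchResults":
        ckpt = train(self.dataset, split, self.config, self.backbone,
                     cache_dir=self.cache_dir, verbose=verbose)
        return DualBranchResults(model=self, checkpoint=ckpt, split=split)

    def fit_loocv(self, verbose: bool = False) -> "CrossValidationResults":
        folds = []
        for split in make_loocv_splits(self.dataset):
            res = self.fit(split, verbose=verbose)
            folds.append(res)
        return CrossValidationResults(folds=folds)


@dataclass
class DualBranchResults:
    model: DualBranchModel
    checkpoint: Checkpoint
    split: CVSplit | None
    _pred_cache: dict = field(default_factory=dict, repr=False)

    @property
    def training_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.checkpoint.log)

    @property
    def final_losses(self) -> dict:
        return {k: v for k, v in self.checkpoint.log[-1].items() if k != "epoch"}

    def predict(self, section: Section) -> PredictionTriple:
        if section.section_id not in self._pred_cache:
            self._pred_cache[section.section_id] = predict_section(
                self.checkpoint, section, self.model.backbone,
                cache_dir=self.model.cache_dir,
            )
        return self._pred_cache[section.section_id]

    def evaluate(self, section: Section, head: str = "y_U") -> pd.DataFrame:
        """Per-gene metrics of one head's prediction against the section truth."""
        triple = self.predict(section)
        pred = getattr(triple, head)
        return ev.per_gene_metrics(pred, section.expression,
                                   gene_ids=self.checkpoint.gene_vocabulary)

    def evaluate_heads(self, section: Section) -> dict[str, pd.DataFrame]:
        triple = self.predict(section)
        return {
            head: ev.per_gene_metrics(getattr(triple, head), section.expression,
                                      gene_ids=self.checkpoint.gene_vocabulary)
            for head in ("y_U", "y_F", "y_S")
        }

    def summary(self) -> str:
        cfg = self.checkpoint.config
        lines = [
            "Dual-branch expression-from-histology model",
            "=" * 52,
            f"backbone:            {self.checkpoint.backbone_name}",
            f"genes:               {len(self.checkpoint.gene_vocabulary)}",
            f"training sections:   {len(self.split.train_section_ids) if self.split else len(self.model.dataset.sections)}",
            f"held-out section:    {self.split.test_section_id if self.split else '-'}",
            f"epochs:              {cfg.epochs}   lr: {cfg.lr}   alpha: {cfg.alpha}",
            f"graphs:              k_s={cfg.k_s}  k_f={cfg.k_f}  rebuild_every={cfg.rebuild_every}",
            "-" * 52,
            "final losses:",
        ]
        for k, v in self.final_losses.items():
            lines.append(f"  {k:4s} = {v:.5f}")
        if self.split is not None:
            test = self.model.dataset.get_section(self.split.test_section_id)
            metrics = self.evaluate(test)
            lines += [
                "-" * 52,
                f"held-out ({test.section_id}) mean over genes:",
                f"  PCC      = {metrics['pcc'].mean():.4f}",
                f"  Spearman = {metrics['spearman'].mean():.4f}",
                f"  MSE      = {metrics['mse'].mean():.4f}",
                f"  MAE      = {metrics['mae'].mean():.4f}",
            ]
        return "\n".join(lines)


@dataclass
class CrossValidationResults:
    folds: list[DualBranchResults]

    def held_out_metrics(self, head: str = "y_U") -> pd.DataFrame:
        """Long table of per-gene metrics on every fold's held-out section."""
        frames = []
        for res in self.folds:
            test = res.model.dataset.get_section(res.split.test_section_id)
            m = res.evaluate(test, head=head)
            m.insert(0, "section", test.section_id)
            frames.append(m)
        return pd.concat(frames, ignore_index=True)

    def mean_pcc(self, head: str = "y_U") -> float:
        """Mean over genes within each held-out section, then over sections."""
        m = self.held_out_metrics(head)
        return float(m.groupby("section")["pcc"].mean().mean())

    def mean_metric(self, metric: str, head: str = "y_U") -> float:
        m = self.held_out_metrics(head)
        return float(m.groupby("section")[metric].mean().mean())

    def summary(self) -> str:
        lines = ["Leave-one-section-out cross-validation", "=" * 52,
                 f"folds: {len(self.folds)}"]
        for head, label in [("y_U", "fused head"), ("y_F", "foundation branch"),
                            ("y_S", "spot branch")]:
            lines.append(f"  {label:18s} mean PCC = {self.mean_pcc(head):.4f}")
        lines.append(f"  fused head         mean MSE = {self.mean_metric('mse'):.4f}")
        return "\n".join(lines)
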