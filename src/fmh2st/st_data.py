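"""Reading, validation, preprocessing and CV splitting of multi-section ST data.

A *section* is one tissue slice: an H&E image, a table of spot coordinates
(pixel space, 0-based, ``px`` = column, ``py`` = row), and a spots-by-genes
raw count matrix. Sections are grouped into a :class:`STDataset` sharing a
gene vocabulary after filtering.

Counts are accepted either as a dense TSV/CSV (spots x genes, header row of
gene ids, first column the spot id) or as a MatrixMarket triplet directory in
the Space Ranger layout (``matrix.mtx`` genes x barcodes + ``genes.tsv`` /
``features.tsv`` + ``barcodes.tsv``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.stats
from PIL import Image

__all__ = [
    "Section",
    "STDataset",
    "PatchSet",
    "CVSplit",
    "load_section",
    "extract_patches",
    "filter_genes",
    "normalize_expression",
    "make_loocv_splits",
    "preprocess_dataset",
    "save_processed",
    "load_processed",
]

SPOT_COLUMNS = ["spot_id", "px", "py", "ax", "ay", "annotation"]


@dataclass
class Section:
    """One tissue slice: image + spot table + raw counts (+ optional annotations)."""

    section_id: str
    patient_id: str
    image: np.ndarray  # H x W x 3 uint8
    spots: pd.DataFrame  # columns spot_id, px, py [, ax, ay, annotation]
    counts: np.ndarray  # n_spots x n_genes, non-negative integers
    gene_ids: list[str]
    expression: np.ndarray | None = None  # normalized log expression, set by preprocessing

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        self.counts = np.asarray(self.counts)
        n_spots = len(self.spots)
        if self.counts.shape != (n_spots, len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{n_spots} spots x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        h, w = self.image.shape[:2]
        px = self.spots["px"].to_numpy()
        py = self.spots["py"].to_numpy()
        bad = (px < 0) | (px >= w) | (py < 0) | (py >= h)
        if np.any(bad):
            offenders = self.spots["spot_id"].to_numpy()[bad].tolist()
            raise ValueError(f"spot centers outside image bounds: {offenders}")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def coords(self) -> np.ndarray:
        """n x 2 array of (px, py) pixel coordinates."""
        return self.spots[["px", "py"]].to_numpy(dtype=float)

    def array_coords(self, n_bins: int = 64) -> np.ndarray:
        """Integer (ax, ay) array coordinates; rank-discretized from pixels if absent.

        Positional-embedding tables in the spot branch are indexed by these
        integers, so they must be small and non-negative.
        """
        if "ax" in self.spots.columns and self.spots["ax"].notna().all():
            ax = self.spots["ax"].to_numpy(dtype=int)
            ay = self.spots["ay"].to_numpy(dtype=int)
            return np.stack([ax, ay], axis=1)
        out = np.zeros((self.n_spots, 2), dtype=int)
        for j, col in enumerate(["px", "py"]):
            v = self.spots[col].to_numpy(dtype=float)
            ranks = scipy.stats.rankdata(v, method="dense").astype(int) - 1
            out[:, j] = np.minimum(ranks, n_bins - 1)
        return out



@dataclass
class STDataset:
    sections: list[Section]
    gene_vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_vocabulary and self.sections:
            self.gene_vocabulary = list(self.sections[0].gene_ids)

    @property
    def section_ids(self) -> list[str]:
        return [s.section_id for s in self.sections]

    def get_section(self, section_id: str) -> Section:
        for s in self.sections:
            if s.section_id == section_id:
                return s
        raise KeyError(section_id)


@dataclass
class PatchSet:
    section_id: str
    patches: np.ndarray  # n_spots x ps x ps x 3 uint8
    patch_size: int


@dataclass
class CVSplit:
    fold_id: int
    train_section_ids: list[str]
    test_section_id: str

    def __post_init__(self) -> None:
        if self.test_section_id in self.train_section_ids:
            raise ValueError("test section present in train set")


def _read_image(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "RGB":
        img = img.convert("RGB")
    return np.asarray(img, dtype=np.uint8)


def _read_counts_dense(path: Path) -> tuple[pd.Index, list[str], np.ndarray]:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.index.astype(str), [str(g) for g in df.columns], df.to_numpy()


def _read_counts_mtx(path: Path) -> tuple[pd.Index, list[str], np.ndarray]:
    """Space Ranger triplet layout: matrix.mtx is genes x barcodes."""
    d = path if path.is_dir() else path.parent
    mtx = d / "matrix.mtx" if path.is_dir() else path
    genes_file = next((d / n for n in ("genes.tsv", "features.tsv") if (d / n).exists()), None)
    barcodes_file = d / "barcodes.tsv"
    if genes_file is None or not barcodes_file.exists():
        raise FileNotFoundError(f"MTX layout needs genes/features.tsv and barcodes.tsv in {d}")
    mat = scipy.io.mmread(str(mtx)).toarray().T  # -> spots x genes
    genes_df = pd.read_csv(genes_file, sep="\t", header=None)
    gene_ids = genes_df.iloc[:, 0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_file, sep="\t", header=None).iloc[:, 0].astype(str)
    return pd.Index(barcodes), gene_ids, mat


def load_section(
    image_path: str | Path,
    counts_path: str | Path,
    coords_path: str | Path,
    section_id: str | None = None,
    patient_id: str | None = None,
) -> Section:
    """Load one section from disk, aligning counts rows to the coordinate order.

    Spot order is the coordinate-file order. Spots present in one file but
    not the other are rejected with the list of offending ids.
    """
    image_path, counts_path, coords_path = Path(image_path), Path(counts_path), Path(coords_path)
    image = _read_image(image_path)

    coords = pd.read_csv(coords_path)
    if "spot_id" not in coords.columns:
        raise ValueError("coordinates file must have a spot_id column")
    coords["spot_id"] = coords["spot_id"].astype(str)

    if counts_path.is_dir() or counts_path.suffix == ".mtx":
        spot_index, gene_ids, mat = _read_counts_mtx(counts_path)
    else:
        spot_index, gene_ids, mat = _read_counts_dense(counts_path)

    missing = [s for s in coords["spot_id"] if s not in set(spot_index)]
    extra = [s for s in spot_index if s not in set(coords["spot_id"])]
    if missing or extra:
        raise ValueError(
            f"spot id mismatch between counts and coordinates; "
            f"missing from counts: {missing}; missing from coordinates: {extra}"
        )

    order = pd.Index(spot_index).get_indexer(coords["spot_id"])
    mat = mat[order]
    if not np.allclose(mat, np.round(mat)):
        raise ValueError("counts matrix contains non-integer values")
    mat = np.round(mat).astype(np.int64)

    sid = section_id or image_path.stem
    return Section(
        section_id=sid,
        patient_id=patient_id or sid,
        image=image,
        spots=coords,
        counts=mat,
        gene_ids=gene_ids,
    )


def extract_patches(section: Section, patch_size: int = 112) -> PatchSet:
    """Crop one square patch of side ``patch_size`` per spot, centered on (px, py).

    Half-open convention: the crop covers rows/cols ``[c - size//2, c + size - size//2)``.
    Out-of-bounds pixels are filled by reflection padding so boundary spots keep
    a full-size patch and the patch count stays equal to the spot count.
    """
    ps = int(patch_size)
    half = ps // 2
    img = np.pad(section.image, ((ps, ps), (ps, ps), (0, 0)), mode="reflect")
    patches = np.empty((section.n_spots, ps, ps, 3), dtype=np.uint8)
    for i, (px, py) in enumerate(section.coords.astype(int)):
        r0 = py - half + ps
        c0 = px - half + ps
        patches[i] = img[r0 : r0 + ps, c0 : c0 + ps]
    return PatchSet(section.section_id, patches, ps)


def normalize_expression(counts: np.ndarray, scale: float = 1e6) -> np.ndarray:
    """Per-spot counts-per-million followed by a natural log transform.

    value(i, g) = ln(1 + count(i, g) / total(i) * scale). The log1p form keeps
    zero counts defined (they map to exactly 0). Spots whose total count is
    zero are left as all-zero rows with a warning; callers that preprocess a
    dataset drop them.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    totals = counts.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} spot(s) with zero total count left as zero rows")
        totals = np.where(totals == 0, 1.0, totals)
    return np.log1p(counts / totals * scale)


def _hvg_scores(dataset: STDataset, genes_mask: np.ndarray) -> np.ndarray:
    """Variability score per gene: variance of log-normalized expression pooled
    over all spots of all sections. Normalization totals use the full raw gene
    set (scoring happens before the vocabulary is reduced)."""
    mats = [normalize_expression(s.counts) for s in dataset.sections]
    pooled = np.vstack(mats)
    scores = pooled.var(axis=0)
    scores[~genes_mask] = -np.inf
    return scores


def filter_genes(dataset: STDataset, n_hvg: int = 1000, min_spots: int = 1000) -> STDataset:
    """Min-spot filter then highly-variable-gene selection, shared across sections.

    Genes expressed (raw count > 0) in fewer than ``min_spots`` spots pooled over
    all sections are removed first; of the survivors the ``n_hvg`` with highest
    variability score are kept (ties broken by gene id, lexicographic). The
    resulting vocabulary is applied to every section, preserving score order.
    """
    gene_ids = dataset.sections[0].gene_ids
    for s in dataset.sections:
        if s.gene_ids != gene_ids:
            raise ValueError("sections disagree on raw gene ids")

    n_expressed = np.zeros(len(gene_ids), dtype=int)
    for s in dataset.sections:
        n_expressed += (s.counts > 0).sum(axis=0)
    survives = n_expressed >= min_spots
    if survives.sum() < n_hvg:
        warnings.warn(
            f"only {int(survives.sum())} genes pass the min-spot filter; keeping all of them"
        )
        n_keep = int(survives.sum())
    else:
        n_keep = n_hvg
    if n_keep == 0:
        raise ValueError("no genes pass the min-spot filter")

    scores = _hvg_scores(dataset, survives)
    order = sorted(np.where(survives)[0], key=lambda j: (-scores[j], gene_ids[j]))
    keep = sorted(order[:n_keep])  # stable original order within the kept set
    vocab = [gene_ids[j] for j in keep]

    new_sections = []
    for s in dataset.sections:
        new_sections.append(
            Section(
                section_id=s.section_id,
                patient_id=s.patient_id,
                image=s.image,
                spots=s.spots,
                counts=s.counts[:, keep],
                gene_ids=vocab,
            )
        )
    return STDataset(sections=new_sections, gene_vocabulary=vocab)


def preprocess_dataset(
    dataset: STDataset, n_hvg: int = 1000, min_spots: int = 1000
) -> STDataset:
    """Filter genes, drop zero-total spots, and attach normalized log expression."""
    ds = filter_genes(dataset, n_hvg=n_hvg, min_spots=min_spots)
    for s in ds.sections:
        totals = s.counts.sum(axis=1)
        keep = totals > 0
        if not np.all(keep):
            warnings.warn(
                f"section {s.section_id}: dropping {int((~keep).sum())} zero-total spot(s)"
            )
            s.spots = s.spots.loc[keep].reset_index(drop=True)
            s.counts = s.counts[keep]
        s.expression = normalize_expression(s.counts)
    return ds


def make_loocv_splits(dataset: STDataset) -> list[CVSplit]:
    """Leave-one-section-out folds: fold k holds out section k."""
    ids = dataset.section_ids
    if len(ids) < 2:
        raise ValueError("leave-one-out CV needs at least 2 sections")
    return [
        CVSplit(fold_id=k, train_section_ids=[i for i in ids if i != sid], test_section_id=sid)
        for k, sid in enumerate(ids)
    ]


def save_processed(dataset: STDataset, outdir: str | Path, patch_size: int = 112) -> None:
    """One directory per section: normalized matrix TSV, patch stack (.npz), metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "gene_vocabulary.txt").write_text("\n".join(dataset.gene_vocabulary) + "\n")
    for s in dataset.sections:
        d = outdir / s.section_id
        d.mkdir(exist_ok=True)
        expr = s.expression if s.expression is not None else normalize_expression(s.counts)
        pd.DataFrame(expr, index=s.spots["spot_id"], columns=s.gene_ids).to_csv(
            d / "expression.tsv", sep="\t"
        )
        pd.DataFrame(s.counts, index=s.spots["spot_id"], columns=s.gene_ids).to_csv(
            d / "counts.tsv", sep="\t"
        )
        s.spots.to_csv(d / "spots.csv", index=False)
        patches = extract_patches(s, patch_size).patches
        np.savez_compressed(d / "patches.npz", patches=patches, image=s.image)
        meta = {"section_id": s.section_id, "patient_id": s.patient_id, "patch_size": patch_size}
        (d / "meta.json").write_text(json.dumps(meta))


def load_processed(indir: str | Path) -> STDataset:
    indir = Path(indir)
    vocab = (indir / "gene_vocabulary.txt").read_text().split()
    sections = []
    for d in sorted(p for p in indir.iterdir() if p.is_dir()):
        meta = json.loads((d / "meta.json").read_text())
        arr = np.load(d / "patches.npz")
        spots = pd.read_csv(d / "spots.csv")
        spots["spot_id"] = spots["spot_id"].astype(str)
        counts_df = pd.read_csv(d / "counts.tsv", sep="\t", index_col=0)
        expr_df = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
        sec = Section(
            section_id=meta["section_id"],
            patient_id=meta["patient_id"],
            image=arr["image"],
            spots=spots,
            counts=counts_df.to_numpy().astype(np.int64),
            gene_ids=[str(g) for g in counts_df.columns],
        )
        sec.expression = expr_df.to_numpy()
        sections.append(sec)
    return STDataset(sections=sections, gene_vocabulary=vocab)
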