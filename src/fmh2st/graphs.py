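"""Spot-neighborhood graphs.

Two directed KNN graphs per section drive neighbor aggregation:

* the **spatial graph** connects each spot to its ``k_s`` nearest neighbors by
  Euclidean distance in pixel coordinates (default ``k_s = 4``);
* the **feature graph** connects each spot to its ``k_f`` most cosine-similar
  neighbors in a PCA embedding of the fused features (default ``k_f = 8``).
  Its edges carry no trainable weights — "learnability" comes from rebuilding
  it as the fused features evolve during training.

Every node has out-degree exactly ``min(k, n-1)`` and no self-loop. Distance /
similarity ties are broken by ascending node index so graph construction is
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

__all__ = ["SpotGraph", "build_spatial_graph", "build_feature_graph"]


@dataclass
class SpotGraph:
    kind: str  # "spatial" | "feature"
    n_nodes: int
    k: int  # effective out-degree, min(requested k, n-1)
    neighbors: np.ndarray  # n_nodes x k int array; row i lists the out-neighbors of i

    def __post_init__(self) -> None:
        self.neighbors = np.asarray(self.neighbors, dtype=int)
        if self.neighbors.shape != (self.n_nodes, self.k):
            raise ValueError("neighbor array shape mismatch")
        if np.any(self.neighbors < 0) or np.any(self.neighbors >= self.n_nodes):
            raise ValueError("neighbor index out of range")
        rows = np.arange(self.n_nodes)[:, None]
        if np.any(self.neighbors == rows):
            raise ValueError("self-loop in graph")

    @property
    def edges(self) -> np.ndarray:
        """Directed edge list (i -> j means j is a neighbor of i)."""
        src = np.repeat(np.arange(self.n_nodes), self.k)
        return np.stack([src, self.neighbors.ravel()], axis=1)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.edges, fmt="%d", delimiter="\t")
        header = {"kind": self.kind, "k": int(self.k), "n_nodes": int(self.n_nodes)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))

    @classmethod
    def load(cls, path: str | Path) -> "SpotGraph":
        path = Path(path)
        header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        edges = np.loadtxt(path, dtype=int, delimiter="\t").reshape(-1, 2)
        nbrs = edges[:, 1].reshape(header["n_nodes"], header["k"])
        return cls(header["kind"], header["n_nodes"], header["k"], nbrs)


def _knn_from_scores(scores: np.ndarray, k: int, largest: bool) -> np.ndarray:
    """Top-k per row with self excluded; ties broken by ascending index.

    ``scores[i, j]`` is distance (largest=False) or similarity (largest=True).
    """
    n = scores.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    k_eff = min(k, n - 1)
    s = scores.copy().astype(float)
    diag = np.arange(n)
    s[diag, diag] = np.inf if not largest else -np.inf
    key = -s if largest else s
    # stable sort on the score leaves equal scores in index order
    order = np.argsort(key, axis=1, kind="stable")
    return order[:, :k_eff]


def build_spatial_graph(coords: np.ndarray, k_s: int = 4) -> SpotGraph:
    """Directed KNN graph over pixel coordinates by Euclidean distance."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be n x 2")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("spatial graph needs at least 2 spots")
    dist = cdist(coords, coords)
    nbrs = _knn_from_scores(dist, k_s, largest=False)
    return SpotGraph("spatial", n, nbrs.shape[1], nbrs)


def build_feature_graph(
    features: np.ndarray, k_f: int = 8, pca_dim: int = 50
) -> SpotGraph:
    """Directed KNN graph by cosine similarity of PCA-reduced features.

    ``pca_dim`` is clipped to ``min(n - 1, d)``; the PCA is refit on every call
    (the graph is rebuilt from current features during training). Zero-norm
    embedding rows get similarity −inf to everyone, so their neighbors fall
    back to the lowest-index tie-break.
    """
    x = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features")
    n, d = x.shape
    if n < 2:
        raise ValueError("feature graph needs at least 2 spots")
    dim = max(1, min(pca_dim, n - 1, d))
    emb = PCA(n_components=dim, svd_solver="full").fit_transform(x)
    norms = np.linalg.norm(emb, axis=1)
    nonzero = norms > 0
    unit = np.zeros_like(emb)
    unit[nonzero] = emb[nonzero] / norms[nonzero, None]
    sim = unit @ unit.T
    # zero-norm rows: similarity undefined -> strictly below any cosine so the
    # index tie-break decides; the self-diagonal is set even lower downstream
    sim[~nonzero, :] = -2.0
    sim[:, ~nonzero] = -2.0
    nbrs = _knn_from_scores(sim, k_f, largest=True)
    return SpotGraph("feature", n, nbrs.shape[1], nbrs)
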