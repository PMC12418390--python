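"""Evaluation and downstream analyses.

Per-gene agreement metrics (PCC / Spearman / MSE / MAE with correlation
p-values), gene ranking across CV folds, spatial-domain clustering scored by
the adjusted Rand index, gene co-expression matrices, Wilcoxon + BH
differential expression, and network-property statistics (power-law fit of
the degree distribution, clustering coefficient, TF out-degree ranking) for
gene-regulatory-network edge lists produced by an external inference tool.

Aggregation conventions: "per-section PCC" is the distribution over genes
within one section; "mean PCC" averages over genes first, then over sections.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import comb
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneMetrics",
    "NetworkStats",
    "per_gene_metrics",
    "rank_predicted_genes",
    "adjusted_rand_index",
    "cluster_domains",
    "coexpression_matrix",
    "differential_expression",
    "network_properties",
    "tf_outdegree_ranking",
]


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    r2_powerlaw: float  # R^2 of the OLS fit on (log degree, log count)
    clustering_coefficient: float  # mean local clustering over all nodes


GeneMetrics = pd.DataFrame  # columns: gene, pcc, spearman, mse, mae, p_value


def per_gene_metrics(y_pred: np.ndarray, y_true: np.ndarray,
                     gene_ids: list[str] | None = None) -> GeneMetrics:
    """Column-wise agreement between predicted and observed expression.

    Correlation p-values come from the standard t test on the Pearson r.
    Constant columns (in either matrix) have undefined correlations and are
    recorded as NaN.
    """
    y_pred, y_true = np.asarray(y_pred, float), np.asarray(y_true, float)
    if y_pred.shape != y_true.shape:
        raise ValueError("shape mismatch")
    n, g = y_pred.shape
    if n < 3:
        raise ValueError("need at least 3 spots")
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(g)]

    rows = []
    for j in range(g):
        p, t = y_pred[:, j], y_true[:, j]
        mse = float(np.mean((p - t) ** 2))
        mae = float(np.mean(np.abs(p - t)))
        if np.ptp(p) == 0 or np.ptp(t) == 0:
            pcc, pval, rho = np.nan, np.nan, np.nan
        else:
            pcc, pval = scipy.stats.pearsonr(p, t)
            rho = scipy.stats.spearmanr(p, t).statistic
        rows.append(
            {"gene": gene_ids[j], "pcc": pcc, "spearman": rho, "mse": mse,
             "mae": mae, "p_value": pval}
        )
    return pd.DataFrame(rows)


def rank_predicted_genes(
    fold_metrics: list[GeneMetrics], top_n: int = 50, p_threshold: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-fold gene ranking.

    Returns ``(by_logp, top_by_pcc)``: all genes sorted by mean −log10 p
    (descending), and the genes with mean p below ``p_threshold`` sorted by
    mean PCC and truncated to ``top_n``.
    """
    long = pd.concat(fold_metrics, ignore_index=True)
    agg = long.groupby("gene").agg(
        mean_pcc=("pcc", "mean"),
        mean_p=("p_value", "mean"),
        mean_neglog10_p=("p_value", lambda p: np.mean(-np.log10(np.maximum(p, 1e-300)))),
    ).reset_index()
    by_logp = agg.sort_values(
        ["mean_neglog10_p", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    top = agg[agg["mean_p"] < p_threshold].sort_values(
        ["mean_pcc", "gene"], ascending=[False, True]
    ).head(top_n).reset_index(drop=True)
    return by_logp, top


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement, from the contingency table.

    Evaluates the pair-counting definition directly: with n_ij the table
    entries and a_i / b_j its margins,

        ARI = (Σ C(n_ij,2) − Σ C(a_i,2) Σ C(b_j,2) / C(n,2))
              / (½[Σ C(a_i,2) + Σ C(b_j,2)] − Σ C(a_i,2) Σ C(b_j,2) / C(n,2))

    Ranges over [−1, 1]; 1 means identical partitions, 0 the chance level.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 items")
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial -> define as 1
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def cluster_domains(
    y_pred: np.ndarray, k: int, seed: int = 0, n_init: int = 10,
    annotation=None,
) -> tuple[np.ndarray, float | None]:
    """k-means spatial-domain clustering of predicted expression rows.

    ``k`` is meant to match the number of annotated domains. Returns the
    labels and, when an annotation vector is given, the ARI against it.
    """
    y_pred = np.asarray(y_pred, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > y_pred.shape[0]:
        raise ValueError("k exceeds the number of spots")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(y_pred)
    ari = adjusted_rand_index(labels, annotation) if annotation is not None else None
    return labels, ari


def coexpression_matrix(
    y: np.ndarray, gene_ids: list[str], top_n: int = 50
) -> pd.DataFrame:
    """Pairwise PCC among the ``top_n`` genes by mean expression in a section.

    Constant genes among the selected set get NaN rows/columns (their
    correlation is undefined); the diagonal of non-constant genes is exactly 1.
    """
    y = np.asarray(y, float)
    if y.shape[1] < top_n:
        raise ValueError(f"need at least {top_n} genes, have {y.shape[1]}")
    means = y.mean(axis=0)
    # descending mean, ties by gene id for determinism
    order = sorted(range(y.shape[1]), key=lambda j: (-means[j], gene_ids[j]))[:top_n]
    sub = y[:, order]
    ids = [gene_ids[j] for j in order]
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(sub, rowvar=False)
    mat = 0.5 * (mat + mat.T)  # corrcoef is symmetric only to rounding
    const = np.ptp(sub, axis=0) == 0
    mat[const, :] = np.nan
    mat[:, const] = np.nan
    np.fill_diagonal(mat, np.where(const, np.nan, 1.0))
    return pd.DataFrame(mat, index=ids, columns=ids)


def differential_expression(
    y: np.ndarray, group_labels, gene_ids: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group Wilcoxon rank-sum per gene with Benjamini–Hochberg adjustment."""
    y = np.asarray(y, float)
    groups = np.asarray(group_labels)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(uniq)}")
    in_a = groups == uniq[0]
    if in_a.sum() < 3 or (~in_a).sum() < 3:
        raise ValueError("each group needs at least 3 spots")
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(y.shape[1])]

    stats, pvals = [], []
    for j in range(y.shape[1]):
        res = scipy.stats.ranksums(y[in_a, j], y[~in_a, j])
        stats.append(res.statistic)
        pvals.append(res.pvalue)
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {"gene": gene_ids, "statistic": stats, "p_value": pvals,
         "p_adjusted": p_adj, "significant": reject}
    )


def _top_edges(edges: pd.DataFrame, top_k: int | None) -> pd.DataFrame:
    cols = list(edges.columns[:3])
    e = edges.rename(columns=dict(zip(cols, ["regulator", "target", "confidence"])))
    if top_k is not None:
        if "confidence" not in e.columns or e["confidence"].isna().all():
            raise ValueError("top-k filtering needs confidence scores")
        e = e.sort_values(
            ["confidence", "regulator", "target"], ascending=[False, True, True]
        ).head(top_k)
    return e.reset_index(drop=True)


def network_properties(edges: pd.DataFrame, top_k: int | None = 3000) -> NetworkStats:
    """Degree-distribution power-law R^2 and mean local clustering coefficient.

    ``edges`` has columns (regulator, target, confidence); the ``top_k``
    highest-confidence edges are kept, then the graph is treated as an
    undirected simple graph. The power-law fit is OLS on
    (log degree, log frequency) over degrees with nonzero frequency.
    Nodes of degree < 2 contribute 0 to the clustering coefficient.
    """
    e = _top_edges(edges, top_k)
    if len(e) == 0:
        raise ValueError("empty edge list")
    g = nx.Graph()
    g.add_edges_from(zip(e["regulator"], e["target"]))
    degrees = np.array([d for _, d in g.degree()])
    values, counts = np.unique(degrees[degrees > 0], return_counts=True)
    if len(values) < 2:
        r2 = np.nan
    else:
        fit = scipy.stats.linregress(np.log(values), np.log(counts))
        r2 = float(fit.rvalue**2)
    return NetworkStats(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        r2_powerlaw=r2,
        clustering_coefficient=float(nx.average_clustering(g)),
    )


def tf_outdegree_ranking(edges: pd.DataFrame, tf_list: list[str]) -> pd.DataFrame:
    """Transcription factors sorted by out-degree (descending, ties by name)."""
    e = _top_edges(edges, None)
    counts = e[e["regulator"].isin(tf_list)].groupby("regulator").size()
    rows = [{"tf": tf, "outdegree": int(counts.get(tf, 0))} for tf in set(tf_list)]
    return (
        pd.DataFrame(rows, columns=["tf", "outdegree"])
        .sort_values(["outdegree", "tf"], ascending=[False, True])
        .reset_index(drop=True)
    )
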