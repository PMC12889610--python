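"""Hybrid cluster-level cell typing and permeabilized-cell filtering.

Clusters are derived purely from the proteome: PCA of the highly variable
proteins, a shared-nearest-neighbor (SNN) graph whose edge weights are the
Jaccard overlap of k-nearest-neighbor sets, and Louvain community detection.
Each cluster is then annotated by asking which reference-predicted cell type
is over-represented among the cluster's high-confidence cells, using the
hypergeometric tail probability

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

with N the number of high-confidence cells, K those predicted as the type,
n those in the cluster, and k their overlap. After multiple-testing
adjustment across the cluster × type grid the best significant type is
propagated to *all* cells of the cluster (including low-confidence ones);
clusters with no significant type are labeled "unknown".

Cells damaged before isolation leak cytosolic protein ("unintentional
permeabilization") and show up as a duplicate, lower-input cluster of an
existing cell type. :func:`flag_permeabilized` detects such same-label
cluster pairs by (1) a sufficiently low median input ratio and rank-sum
separation of the estimated per-cell peptide input and (2) rank-sum
separation of per-cell protein identification counts; prediction-score
distributions are reported as a non-gating diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .label_transfer import PredictionScores
from .quant_io import QuantMatrix

__all__ = [
    "ClusterAssignment",
    "EnrichmentTable",
    "PermeabilizationReport",
    "pca_embed",
    "snn_graph",
    "louvain_cluster",
    "cluster_enrichment",
    "flag_permeabilized",
]


@dataclass
class ClusterAssignment:
    clusters: pd.Series  # per cell: dense integer cluster id
    graph: nx.Graph
    embedding: pd.DataFrame  # cells × PCs
    resolution: float
    seed: int

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.clusters.unique())


@dataclass
class EnrichmentTable:
    """Per-(cluster, type) hypergeometric enrichment and final labels."""

    table: pd.DataFrame  # cluster, type, N, K, n, k, p, p_adj
    cluster_labels: dict[int, str]
    cell_labels: pd.Series  # propagated to every cell


@dataclass
class PermeabilizationReport:
    pairs: pd.DataFrame
    flagged_clusters: list[int]
    flagged_cells: pd.Index


def pca_embed(
    qm: QuantMatrix, features: list[str], n_pcs: int = 30, seed: int = 0
) -> pd.DataFrame:
    """PCA embedding of cells on the selected features (complete log2 data).

    Features are centered and unit-scaled; component signs are fixed so each
    component's largest-magnitude loading is positive.
    """
    if n_pcs <= 0:
        raise ValueError("n_pcs must be positive")
    vals = qm.values.loc[features].to_numpy(dtype=float).T  # cells × features
    if np.isnan(vals).any():
        raise ValueError("pca_embed requires a complete (imputed) matrix")
    n_pcs_eff = min(n_pcs, *vals.shape)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd
    pca = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=seed)
    emb = pca.fit_transform(z)
    # deterministic sign convention
    flip = np.sign(pca.components_[np.arange(n_pcs_eff), np.abs(pca.components_).argmax(axis=1)])
    emb *= flip
    return pd.DataFrame(
        emb, index=qm.sample_ids, columns=[f"PC{i + 1}" for i in range(n_pcs_eff)]
    )


def snn_graph(embedding: pd.DataFrame, k_neighbors: int = 20, prune: float = 1 / 15) -> nx.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Neighbor sets are the k nearest cells by Euclidean distance, self
    excluded. For every ordered kNN pair an undirected edge carries weight
    |N(i) ∩ N(j)| / |N(i) ∪ N(j)|; edges with weight < ``prune`` are removed
    (so ``prune=0`` keeps every kNN edge, including weight-zero ones).
    """
    n = embedding.shape[0]
    if k_neighbors <= 0:
        raise ValueError("k_neighbors must be positive")
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of cells {n}")
    X = embedding.to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = [set(row[1:]) for row in idx]  # drop self

    G = nx.Graph()
    G.add_nodes_from(embedding.index)
    names = embedding.index.to_numpy()
    seen: set[tuple[int, int]] = set()
    for i in range(n):
        for j in neigh[i]:
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(neigh[a] & neigh[b])
            union = len(neigh[a] | neigh[b])
            w = inter / union if union else 0.0
            if w >= prune:
                G.add_edge(names[a], names[b], weight=w)
    return G


def louvain_cluster(
    graph: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> pd.Series:
    """Louvain community detection; isolated nodes become singleton clusters.

    Returns dense integer cluster ids per node, numbered by decreasing
    cluster size (ties by smallest member name) for determinism.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), sorted(map(str, c))[0]))
    labels = {}
    for cid, members in enumerate(comms):
        for node in members:
            labels[node] = cid
    return pd.Series(labels, name="cluster").loc[list(graph.nodes)]


def hypergeom_enrichment_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def cluster_enrichment(
    clusters: pd.Series,
    scores: PredictionScores,
    alpha: float = 0.05,
    mt_method: str = "fdr_bh",
) -> EnrichmentTable:
    """Annotate clusters by hypergeometric enrichment of predicted types.

    Only high-confidence cells enter the test; the winning label (smallest
    adjusted p below ``alpha``, ties broken by larger overlap then type name)
    is propagated to every cell of the cluster. Clusters without any
    significant type — including clusters with no high-confidence cell — are
    labeled ``"unknown"``.
    """
    clusters = clusters.astype(int)
    hc = scores.high_confidence.reindex(clusters.index)
    if hc.isna().any():
        raise ValueError("prediction scores missing for some clustered cells")
    predicted = scores.predicted.reindex(clusters.index)
    hc_cells = clusters.index[hc.to_numpy(dtype=bool)]
    N = len(hc_cells)
    if N == 0:
        raise ValueError("no high-confidence cells available for enrichment")

    types = sorted(predicted.loc[hc_cells].unique())
    K = {t: int((predicted.loc[hc_cells] == t).sum()) for t in types}
    rows = []
    for cid in sorted(clusters.unique()):
        members = clusters.index[clusters == cid]
        hc_members = [c for c in members if hc[c]]
        n = len(hc_members)
        if n == 0:
            warnings.warn(f"cluster {cid} has no high-confidence cells; labeled unknown")
        for t in types:
            k = int((predicted.loc[hc_members] == t).sum()) if n else 0
            rows.append(
                {
                    "cluster": cid,
                    "type": t,
                    "N": N,
                    "K": K[t],
                    "n": n,
                    "k": k,
                    "p": hypergeom_enrichment_p(N, K[t], n, k),
                }
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"].to_numpy(), method=mt_method)[1]

    cluster_labels: dict[int, str] = {}
    for cid, sub in table.groupby("cluster"):
        sig = sub[sub["p_adj"] < alpha]
        if sig.empty:
            cluster_labels[int(cid)] = "unknown"
        else:
            best = sig.sort_values(
                ["p_adj", "k", "type"], ascending=[True, False, True], kind="stable"
            ).iloc[0]
            cluster_labels[int(cid)] = str(best["type"])
    cell_labels = clusters.map(cluster_labels).rename("label")
    return EnrichmentTable(table=table, cluster_labels=cluster_labels, cell_labels=cell_labels)


def flag_permeabilized(
    clusters: pd.Series,
    labels: pd.Series,
    input_pg: pd.Series,
    n_proteins: pd.Series,
    scores: PredictionScores | None = None,
    max_input_ratio: float = 0.67,
    p_threshold: float = 0.01,
) -> PermeabilizationReport:
    """Flag lower-input duplicate clusters of the same cell type.

    For every pair of clusters sharing a (non-"unknown") label, the
    lower-median-input cluster is flagged iff the median input ratio
    (low/high) is at most ``max_input_ratio`` AND two-sided rank-sum tests
    separate the clusters at ``p_threshold`` on both the estimated per-cell
    input and the per-cell protein identification counts. Prediction-score
    distributions are summarized as a diagnostic only.
    """
    clusters = clusters.astype(int)
    rows = []
    flagged: set[int] = set()
    by_label: dict[str, list[int]] = {}
    for cid in sorted(clusters.unique()):
        members = clusters.index[clusters == cid]
        lab = labels.loc[members].iloc[0]
        if lab != "unknown":
            by_label.setdefault(lab, []).append(cid)

    for lab, cids in by_label.items():
        for i in range(len(cids)):
            for j in range(i + 1, len(cids)):
                a, b = cids[i], cids[j]
                cells_a = clusters.index[clusters == a]
                cells_b = clusters.index[clusters == b]
                in_a, in_b = input_pg.loc[cells_a].dropna(), input_pg.loc[cells_b].dropna()
                lo, hi = (a, b) if in_a.median() <= in_b.median() else (b, a)
                in_lo, in_hi = (in_a, in_b) if lo == a else (in_b, in_a)
                np_lo = n_proteins.loc[clusters.index[clusters == lo]].dropna()
                np_hi = n_proteins.loc[clusters.index[clusters == hi]].dropna()
                ratio = float(in_lo.median() / in_hi.median()) if in_hi.median() > 0 else np.nan
                p_input = float(stats.mannwhitneyu(in_lo, in_hi, alternative="two-sided").pvalue)
                p_nprot = float(stats.mannwhitneyu(np_lo, np_hi, alternative="two-sided").pvalue)
                flag = (
                    np.isfinite(ratio)
                    and ratio <= max_input_ratio
                    and p_input < p_threshold
                    and p_nprot < p_threshold
                )
                row = {
                    "label": lab,
                    "cluster_low": lo,
                    "cluster_high": hi,
                    "median_input_low": float(in_lo.median()),
                    "median_input_high": float(in_hi.median()),
                    "input_ratio": ratio,
                    "median_nprot_low": float(np_lo.median()),
                    "median_nprot_high": float(np_hi.median()),
                    "p_input": p_input,
                    "p_nprot": p_nprot,
                    "flagged": bool(flag),
                }
                if scores is not None:
                    ms = scores.max_score
                    row["median_max_score_low"] = float(
                        ms.loc[clusters.index[clusters == lo]].median()
                    )
                    row["median_max_score_high"] = float(
                        ms.loc[clusters.index[clusters == hi]].median()
                    )
                rows.append(row)
                if flag:
                    flagged.add(lo)

    pairs = pd.DataFrame(rows)
    flagged_cells = clusters.index[clusters.isin(flagged)]
    return PermeabilizationReport(
        pairs=pairs, flagged_clusters=sorted(flagged), flagged_cells=flagged_cells
    )
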