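"""Reference label transfer with per-cell prediction scores.

Cell types are transferred from a labeled reference expression atlas (e.g. a
single-cell transcriptome) to the proteome query through the features the two
modalities share. Both datasets are restricted to the shared features and
z-scaled per feature; a PCA basis is fitted on the reference and the query is
projected into it; each query cell's k nearest reference cells then vote for
its type with Gaussian distance-decay weights (bandwidth = distance to the
k-th neighbor). The per-cell score vector over types sums to one, and the
maximum score is thresholded at a data-driven confidence cutoff:

    cutoff = mean(max scores) - 1 * SD(max scores)   (sample SD, n-1)

Cells at or above the cutoff are "high-confidence" and drive the cluster
annotation downstream; low-confidence cells inherit labels only through
their cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .quant_io import QuantMatrix
from .synthetic import ReferenceExpression

__all__ = ["PredictionScores", "select_hvf", "feature_overlap", "transfer_labels"]


@dataclass
class PredictionScores:
    """Per-cell type scores from reference mapping.

    ``scores`` rows (cells) sum to one; ``predicted`` is the argmax type;
    ``high_confidence`` flags cells whose max score reaches the cutoff.
    """

    scores: pd.DataFrame  # cells × types
    cutoff: float

    @property
    def predicted(self) -> pd.Series:
        return self.scores.idxmax(axis=1).rename("predicted_type")

    @property
    def max_score(self) -> pd.Series:
        return self.scores.max(axis=1).rename("max_score")

    @property
    def high_confidence(self) -> pd.Series:
        return (self.max_score >= self.cutoff).rename("high_confidence")

    def table(self) -> pd.DataFrame:
        out = self.scores.copy()
        out["predicted_type"] = self.predicted
        out["max_score"] = self.max_score
        out["high_confidence"] = self.high_confidence
        return out


def confidence_cutoff(max_scores: np.ndarray | pd.Series) -> float:
    """Mean minus one sample standard deviation of the per-cell max scores."""
    arr = np.asarray(max_scores, dtype=float)
    if arr.size < 2:
        return float(arr.mean())
    return float(arr.mean() - arr.std(ddof=1))


def select_hvf(qm: QuantMatrix, n: int) -> list[str]:
    """Top-``n`` features by variance over observed values.

    Ties break lexicographically by feature id; features with fewer than two
    observations count as zero variance. Expects log2 scale.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > qm.values.shape[0]:
        raise ValueError(f"n={n} exceeds feature count {qm.values.shape[0]}")
    var = qm.values.var(axis=1, skipna=True).fillna(0.0)
    order = var.sort_index().sort_values(ascending=False, kind="stable")
    return list(order.index[:n])


def feature_overlap(hvp: list[str], hvg: list[str]) -> tuple[list[str], int]:
    """Shared ids between two feature lists, case-normalized, sorted."""
    a = {str(x).upper(): x for x in hvp}
    b = {str(x).upper() for x in hvg}
    shared = sorted(a[k] for k in set(a) & b)
    return shared, len(shared)


def transfer_labels(
    query: QuantMatrix,
    reference: ReferenceExpression,
    shared_features: list[str] | None = None,
    k: int = 20,
    n_pcs: int = 30,
    seed: int = 0,
) -> PredictionScores:
    """Score each query cell against the reference types via weighted kNN.

    ``query`` must be a complete log2 matrix (features × cells). When
    ``shared_features`` is omitted the full id intersection is used.
    """
    if shared_features is None:
        shared_features, _ = feature_overlap(
            list(query.feature_ids), list(reference.values.index)
        )
    if len(shared_features) == 0:
        raise ValueError("no shared features between query and reference")
    n_ref = reference.values.shape[1]
    if k > n_ref:
        raise ValueError(f"k={k} exceeds reference size {n_ref}")

    q = query.values.loc[shared_features].to_numpy(dtype=float).T  # cells × features
    r = reference.values.loc[shared_features].to_numpy(dtype=float).T
    if np.isnan(q).any():
        raise ValueError("query matrix must be complete (imputed) for label transfer")

    def _zscale(mat: np.ndarray) -> np.ndarray:
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0)
        sd[sd == 0] = 1.0
        return (mat - mu) / sd

    qz, rz = _zscale(q), _zscale(r)
    n_pcs_eff = min(n_pcs, rz.shape[0], rz.shape[1])
    pca = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=seed)
    r_emb = pca.fit_transform(rz)
    q_emb = pca.transform(qz)

    nn = NearestNeighbors(n_neighbors=k).fit(r_emb)
    dist, idx = nn.kneighbors(q_emb)
    bandwidth = dist[:, -1].copy()
    bandwidth[bandwidth == 0] = 1.0
    w = np.exp(-0.5 * (dist / bandwidth[:, None]) ** 2)

    types = sorted(reference.labels.unique())
    labels = reference.labels.to_numpy()
    t_index = {t: j for j, t in enumerate(types)}
    neigh_types = np.vectorize(t_index.get)(labels[idx])
    scores = np.zeros((q.shape[0], len(types)))
    for j in range(len(types)):
        scores[:, j] = np.where(neigh_types == j, w, 0.0).sum(axis=1)
    scores /= scores.sum(axis=1, keepdims=True)

    score_df = pd.DataFrame(scores, index=query.sample_ids, columns=types)
    cutoff = confidence_cutoff(score_df.max(axis=1))
    return PredictionScores(scores=score_df, cutoff=cutoff)
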