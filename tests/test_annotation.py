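import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from scplex.annotation import (
    cluster_enrichment,
    flag_permeabilized,
    hypergeom_enrichment_p,
    louvain_cluster,
    pca_embed,
    snn_graph,
)
from scplex.label_transfer import PredictionScores
from scplex.quant_io import QuantMatrix


def _qm(arr, index=None, columns=None):
    arr = np.asarray(arr, dtype=float)
    df = pd.DataFrame(
        arr,
        index=index or [f"f{i}" for i in range(arr.shape[0])],
        columns=columns or [f"c{j}" for j in range(arr.shape[1])],
    )
    return QuantMatrix(values=df, scale="log2")


class TestPCAEmbed:
    def test_collinear_data_single_component(self):
        x = np.linspace(0, 1, 10)
        qm = _qm(np.vstack([x, 2 * x]))
        emb = pca_embed(qm, ["f0", "f1"], n_pcs=2)
        assert emb["PC1"].var() > 0
        assert np.allclose(emb["PC2"], 0.0, atol=1e-9)

    def test_zero_pcs_rejected(self):
        qm = _qm(np.eye(3))
        with pytest.raises(ValueError):
            pca_embed(qm, ["f0"], n_pcs=0)

    def test_reproducible(self, rng):
        arr = rng.normal(size=(20, 30))
        qm = _qm(arr)
        a = pca_embed(qm, list(qm.feature_ids), n_pcs=5, seed=3)
        b = pca_embed(qm, list(qm.feature_ids), n_pcs=5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_incomplete_matrix_rejected(self):
        arr = np.ones((3, 3))
        arr[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            pca_embed(_qm(arr), ["f0", "f1", "f2"])


class TestSNNGraph:
    def test_two_points_k1_edge_pruned(self):
        """Each point's neighbor set is the other point, the sets are
        disjoint, Jaccard = 0, and the default prune removes the edge."""
        emb = pd.DataFrame([[0.0], [1.0]], index=["a", "b"], columns=["PC1"])
        g = snn_graph(emb, k_neighbors=1)
        assert g.number_of_edges() == 0
        g0 = snn_graph(emb, k_neighbors=1, prune=0.0)
        assert g0.number_of_edges() == 1
        assert g0["a"]["b"]["weight"] == 0.0

    def test_separated_blobs_have_no_cross_edges(self, rng):
        a = rng.normal(0, 0.1, size=(10, 2))
        b = rng.normal(50, 0.1, size=(10, 2))
        emb = pd.DataFrame(
            np.vstack([a, b]),
            index=[f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)],
            columns=["PC1", "PC2"],
        )
        g = snn_graph(emb, k_neighbors=3, prune=0.0)
        for u, v in g.edges:
            assert u[0] == v[0]

    def test_invalid_k(self):
        emb = pd.DataFrame(np.zeros((3, 1)), index=list("abc"), columns=["PC1"])
        with pytest.raises(ValueError):
            snn_graph(emb, k_neighbors=0)
        with pytest.raises(ValueError):
            snn_graph(emb, k_neighbors=3)


def _bridged_cliques():
    g = nx.Graph()
    left, right = list(range(4)), list(range(4, 8))
    for grp in (left, right):
        g.add_edges_from(itertools.combinations(grp, 2))
    g.add_edge(3, 4)
    for u, v in g.edges:
        g[u][v]["weight"] = 1.0
    return g, left, right


def _brute_force_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _brute_force_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


class TestLouvain:
    def test_bridged_cliques_match_brute_force_modularity(self):
        """Louvain on two 4-cliques joined by one edge recovers the global
        modularity optimum found by exhaustive enumeration."""
        g, left, right = _bridged_cliques()
        best_q, best_part = -np.inf, None
        for part in _brute_force_partitions(list(g.nodes)):
            q = nx.community.modularity(g, [set(p) for p in part])
            if q > best_q:
                best_q, best_part = q, part
        best_sets = {frozenset(p) for p in best_part}
        assert best_sets == {frozenset(left), frozenset(right)}

        clusters = louvain_cluster(g, resolution=1.0, seed=0)
        assert clusters.nunique() == 2
        assert len(set(clusters.loc[left])) == 1
        assert len(set(clusters.loc[right])) == 1
        q_louvain = nx.community.modularity(
            g, [set(clusters.index[clusters == c]) for c in clusters.unique()]
        )
        assert q_louvain == pytest.approx(best_q)

    def test_complete_graph_single_community(self):
        g = nx.complete_graph(6)
        clusters = louvain_cluster(g, resolution=1.0, seed=1)
        assert clusters.nunique() == 1

    def test_isolated_nodes_become_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        g.add_edge("a", "b", weight=1.0)
        clusters = louvain_cluster(g, seed=0)
        assert clusters.loc["x"] != clusters.loc["y"]

    def test_deterministic_given_seed(self, rng):
        g = nx.gnp_random_graph(60, 0.1, seed=7)
        a = louvain_cluster(g, seed=5)
        b = louvain_cluster(g, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain_cluster(nx.Graph())


def _exact_hypergeom_tail(N, K, n, k):
    num = sum(math.comb(K, j) * math.comb(N - K, n - j)
              for j in range(k, min(K, n) + 1))
    return num / math.comb(N, n)


class TestHypergeom:
    def test_worked_example(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        assert hypergeom_enrichment_p(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_k_zero_gives_one(self):
        assert hypergeom_enrichment_p(10, 5, 4, 0) == 1.0

    def test_saturated_type_gives_one(self):
        # every high-confidence cell has the type: no enrichment possible
        assert hypergeom_enrichment_p(10, 10, 4, 4) == pytest.approx(1.0)

    def test_matches_enumeration_up_to_N12(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        assert hypergeom_enrichment_p(N, K, n, k) == pytest.approx(
                            _exact_hypergeom_tail(N, K, n, k), abs=1e-12
                        )


def _scores(predicted: dict[str, str], high_conf: dict[str, bool], types=None):
    types = types or sorted(set(predicted.values()))
    cells = list(predicted)
    mat = pd.DataFrame(0.0, index=cells, columns=types)
    for c, t in predicted.items():
        mat.loc[c, t] = 1.0 if high_conf[c] else 0.4
        rest = (1.0 - mat.loc[c, t]) / max(len(types) - 1, 1)
        for o in types:
            if o != t:
                mat.loc[c, o] = rest
    cut = 0.9
    return PredictionScores(scores=mat, cutoff=cut)


class TestClusterEnrichment:
    def test_enriched_type_propagates_to_low_confidence_members(self):
        predicted = {f"c{i}": ("A" if i < 6 else "B") for i in range(12)}
        high_conf = {c: True for c in predicted}
        high_conf["c0"] = False  # low confidence, cluster 0 member
        clusters = pd.Series([0] * 6 + [1] * 6, index=list(predicted))
        scores = _scores(predicted, high_conf)
        enr = cluster_enrichment(clusters, scores, alpha=0.05)
        assert enr.cluster_labels == {0: "A", 1: "B"}
        assert enr.cell_labels.loc["c0"] == "A"

    def test_cluster_without_signal_labeled_unknown(self):
        predicted = {f"c{i}": "A" for i in range(8)}
        high_conf = {c: True for c in predicted}
        clusters = pd.Series([0] * 4 + [1] * 4, index=list(predicted))
        scores = _scores(predicted, high_conf, types=["A", "B"])
        enr = cluster_enrichment(clusters, scores, alpha=0.05)
        # K = N for type A: p = 1 everywhere, nothing is enriched
        assert set(enr.cluster_labels.values()) == {"unknown"}

    def test_cluster_with_no_high_confidence_cells_warns_unknown(self):
        predicted = {f"c{i}": ("A" if i < 4 else "B") for i in range(8)}
        high_conf = {c: i < 4 for i, c in enumerate(predicted)}
        clusters = pd.Series([0] * 4 + [1] * 4, index=list(predicted))
        scores = _scores(predicted, high_conf)
        with pytest.warns(UserWarning, match="no high-confidence"):
            enr = cluster_enrichment(clusters, scores, alpha=0.05)
        assert enr.cluster_labels[1] == "unknown"

    def test_table_invariants(self):
        predicted = {f"c{i}": ("A" if i % 3 else "B") for i in range(12)}
        high_conf = {c: True for c in predicted}
        clusters = pd.Series([0] * 6 + [1] * 6, index=list(predicted))
        enr = cluster_enrichment(clusters, _scores(predicted, high_conf), alpha=0.05)
        t = enr.table
        assert (t["k"] <= np.minimum(t["K"], t["n"])).all()
        assert ((t["p"] > 0) & (t["p"] <= 1)).all()
        assert (t["p_adj"] >= t["p"] - 1e-12).all()


class TestFlagPermeabilized:
    def _inputs(self, clusters, labels, inputs, nprot):
        idx = clusters.index
        return (
            clusters,
            labels.reindex(idx),
            pd.Series(inputs, index=idx, dtype=float),
            pd.Series(nprot, index=idx, dtype=float),
        )

    def test_single_cluster_per_label_nothing_flagged(self, rng):
        idx = [f"c{i}" for i in range(20)]
        clusters = pd.Series([0] * 10 + [1] * 10, index=idx)
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=idx)
        rep = flag_permeabilized(
            clusters, labels,
            pd.Series(rng.uniform(10, 20, 20), index=idx),
            pd.Series(rng.integers(500, 700, 20), index=idx),
        )
        assert rep.flagged_clusters == []

    def test_identical_distributions_not_flagged(self, rng):
        idx = [f"c{i}" for i in range(100)]
        clusters = pd.Series([0] * 50 + [1] * 50, index=idx)
        labels = pd.Series("A", index=idx)
        inputs = pd.Series(rng.lognormal(np.log(14), 0.4, 100), index=idx)
        nprot = pd.Series(rng.integers(600, 700, 100), index=idx)
        rep = flag_permeabilized(clusters, labels, inputs, nprot)
        assert rep.flagged_clusters == []

    def test_lower_input_duplicate_cluster_flagged(self, rng):
        idx = [f"c{i}" for i in range(200)]
        clusters = pd.Series([0] * 100 + [1] * 100, index=idx)
        labels = pd.Series("A", index=idx)
        hi = rng.lognormal(np.log(14), 0.3, 100)
        lo = rng.lognormal(np.log(14 * 0.5), 0.3, 100)
        inputs = pd.Series(np.concatenate([hi, lo]), index=idx)
        nprot = pd.Series(
            np.concatenate([rng.normal(650, 30, 100), rng.normal(450, 30, 100)]),
            index=idx,
        )
        rep = flag_permeabilized(clusters, labels, inputs, nprot)
        assert rep.flagged_clusters == [1]
        assert set(rep.flagged_cells) == set(idx[100:])
        # flags only ever land on the lower-input member
        assert (rep.pairs.loc[rep.pairs["flagged"], "median_input_low"]
                <= rep.pairs.loc[rep.pairs["flagged"], "median_input_high"]).all()
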