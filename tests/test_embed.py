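"""Feature assembly, hypergraph convolution, contrastive training,
clustering and validation comparison."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from asdnet import embed as emb
from asdnet import hypergraph as hgm
from asdnet import topology as topo
from asdnet.embed import (
    HUB_INDEPENDENT5,
    TOPOLOGY7,
    ContrastiveConfig,
    TrainConfig,
    contrastive_loss,
)


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

class TestFeatureMatrix:
    @pytest.fixture(scope="class")
    def parts(self, synth200, synth200_mldpp):
        cent = topo.centrality_profile(synth200["network"])
        return cent, synth200_mldpp["metrics"].to_frame(), synth200["gene_table"]

    def test_standardization_contract(self, synth200, parts):
        cent, mdf, gt = parts
        fm = emb.build_feature_matrix(
            cent, mdf, gt, "topology7", static_scores=synth200["scores"]
        )
        means = fm.X.mean(axis=0)
        sds = fm.X.std(axis=0)
        assert np.all(np.abs(means) < 1e-9)
        assert np.all(np.abs(sds[~fm.zero_variance] - 1) < 1e-9)

    def test_topology7_columns_in_order(self, synth200, parts):
        cent, mdf, gt = parts
        fm = emb.build_feature_matrix(
            cent, mdf, gt, "topology7", static_scores=synth200["scores"]
        )
        assert fm.feature_names == TOPOLOGY7
        assert fm.X.shape[1] == 7

    def test_hub_independent5_excludes_centralities(self, parts):
        cent, mdf, gt = parts
        fm = emb.build_feature_matrix(cent, None, gt, "hub_independent5")
        assert fm.feature_names == HUB_INDEPENDENT5
        centrality_names = {
            "degree", "degree_centrality", "betweenness", "closeness",
            "eigenvector", "clustering_coef",
        }
        assert not set(fm.feature_names) & centrality_names

    def test_hub_independent3_variant(self, parts):
        cent, mdf, gt = parts
        fm = emb.build_feature_matrix(cent, None, gt, "hub_independent3")
        assert fm.feature_names == ("clustering_coef", "sfari_member", "log_degree")

    def test_unknown_variant_rejected(self, parts):
        cent, mdf, gt = parts
        with pytest.raises(ValueError):
            emb.build_feature_matrix(cent, mdf, gt, "everything")


# ---------------------------------------------------------------------------
# forward pass vs dense oracle
# ---------------------------------------------------------------------------

def dense_forward_oracle(hg, X, thetas, relu_hidden=True):
    """Straight dense computation of the layer stack (no BN, no dropout)."""
    P = hg.propagation_operator()
    Z = X
    pre = []
    for i, theta in enumerate(thetas):
        A = P @ Z @ theta
        pre.append(A)
        Z = np.maximum(A, 0) if (relu_hidden and i < len(thetas) - 1) else A
    return Z, pre


class TestForward:
    def _tiny_hypergraph(self):
        src = [hgm.Hyperedge(("A", "B", "C"), 1.0, "clique")]
        return hgm.assemble_hypergraph([src], ["A", "B", "C"])

    def test_single_hyperedge_identity_theta(self):
        hg = self._tiny_hypergraph()
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        params = emb.init_params(dims=(2, 2), dropout=0.0,
                                 use_batchnorm=False, seed=0)
        params.thetas[0] = np.eye(2)
        out = emb.hgnn_forward(hg, X, params)
        P = hg.propagation_operator()
        assert np.allclose(out, P @ X)

    @pytest.mark.parametrize("seed", range(5))
    def test_multilayer_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(8)]
        edges = {}
        for _ in range(6):
            members = tuple(sorted(rng.choice(genes, size=3, replace=False)))
            edges[members] = hgm.Hyperedge(members, float(rng.uniform(0.5, 2)),
                                           "clique")
        hg = hgm.assemble_hypergraph([list(edges.values())], genes)
        X = rng.normal(size=(8, 4))
        params = emb.init_params(dims=(4, 5, 3), dropout=0.0,
                                 use_batchnorm=False, seed=seed)
        out, layers = emb.hgnn_forward(hg, X, params, return_layers=True)
        expected, pre = dense_forward_oracle(hg, X, params.thetas)
        for got, want in zip(layers, pre):
            assert np.allclose(got, want, atol=1e-12)
        assert np.allclose(out, expected, atol=1e-12)

    def test_evaluation_mode_deterministic(self, two_class_hypergraph):
        hg, X, labels = two_class_hypergraph
        params = emb.init_params(dims=(7, 8, 4), seed=1)
        a = emb.hgnn_forward(hg, X, params, training=False)
        b = emb.hgnn_forward(hg, X, params, training=False)
        assert np.array_equal(a, b)

    def test_zero_dropout_training_equals_evaluation(self, two_class_hypergraph):
        hg, X, labels = two_class_hypergraph
        params = emb.init_params(dims=(7, 8, 4), dropout=0.0, seed=1)
        train_out = emb.hgnn_forward(
            hg, X, params, training=True, rng=np.random.default_rng(0)
        )
        eval_out = emb.hgnn_forward(hg, X, params, training=False)
        assert np.allclose(train_out, eval_out)

    def test_shape_mismatch_rejected(self, two_class_hypergraph):
        hg, X, _ = two_class_hypergraph
        params = emb.init_params(dims=(5, 4), seed=0)
        with pytest.raises(ValueError):
            emb.hgnn_forward(hg, X, params)


# ---------------------------------------------------------------------------
# contrastive loss
# ---------------------------------------------------------------------------

class TestContrastiveLoss:
    def test_zero_when_margins_satisfied(self):
        E = np.array([[0.0, 0.0], [0.3, 0.0], [5.0, 0.0], [5.3, 0.0]])
        labels = [True, True, False, False]
        assert contrastive_loss(E, labels) == 0.0

    def test_hub_pair_violation_hand_value(self):
        # one hub pair at distance 1.0; cross pairs far beyond the margin
        E = np.array([[0.0, 0.0], [1.0, 0.0], [100.0, 0.0]])
        labels = [True, True, False]
        assert contrastive_loss(E, labels) == pytest.approx(0.25)

    def test_cross_pair_violation_hand_value(self):
        # hub pair coincident (satisfied); one of two cross pairs at 1.0
        E = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        labels = [True, True, False]
        # both cross pairs violate at d=1.0: mean of two (0.5)^2 terms
        assert contrastive_loss(E, labels) == pytest.approx(0.25)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss(np.zeros((3, 2)), [True, True, True])

    @pytest.mark.parametrize("seed", range(5))
    def test_zero_iff_margins_hold(self, seed):
        rng = np.random.default_rng(seed)
        E = rng.normal(size=(10, 3))
        labels = np.arange(10) < 4
        cfg = ContrastiveConfig()
        loss = contrastive_loss(E, labels, cfg)
        D = np.sqrt(((E[:, None] - E[None]) ** 2).sum(-1))
        hh = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        hn = [(i, j) for i in range(4) for j in range(4, 10)]
        satisfied = all(D[i, j] <= cfg.m_pos for i, j in hh) and all(
            D[i, j] >= cfg.m_neg for i, j in hn
        )
        assert (loss == 0.0) == satisfied


class TestGradientCheck:
    def test_backprop_matches_finite_differences(self, two_class_hypergraph):
        # 5-node toy, full loss wrt every transform matrix, training-mode
        # batch norm, no dropout
        genes = ["a", "b", "c", "d", "e"]
        src = [
            hgm.Hyperedge(("a", "b", "c"), 1.0, "clique"),
            hgm.Hyperedge(("c", "d", "e"), 1.0, "clique"),
        ]
        hg = hgm.assemble_hypergraph([src], genes)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        labels = np.array([True, True, False, False, False])
        params = emb.init_params(dims=(3, 4, 2), dropout=0.0, seed=1)
        P = hg.propagation_operator()
        cfg = ContrastiveConfig()

        def loss_of(params_):
            Z, _ = emb._forward(P, X, params_, training=True, rng=None)
            return emb._loss_and_grad(Z, labels, cfg, need_grad=False)[0]

        Z, cache = emb._forward(P, X, params, training=True, rng=None)
        _, dZ = emb._loss_and_grad(Z, labels, cfg)
        d_thetas, d_gammas, d_betas = emb._backward(P, params, cache, dZ,
                                                    training=True)
        eps = 1e-6
        for kind, grads, values in (
            ("theta", d_thetas, params.thetas),
            ("gamma", d_gammas, params.gammas),
            ("beta", d_betas, params.betas),
        ):
            for layer in range(len(values)):
                arr = values[layer]
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    up = loss_of(params)
                    arr[idx] = orig - eps
                    down = loss_of(params)
                    arr[idx] = orig
                    numeric = (up - down) / (2 * eps)
                    analytic = grads[layer][idx]
                    denom = max(abs(numeric), abs(analytic), 1e-8)
                    # absolute floor covers finite-difference roundoff on
                    # near-zero gradient entries
                    assert (
                        abs(numeric - analytic) / denom < 1e-5
                        or abs(numeric - analytic) < 1e-9
                    ), f"{kind} layer {layer} index {idx}"


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class TestTraining:
    def test_two_epoch_determinism(self, two_class_hypergraph):
        hg, X, labels = two_class_hypergraph
        cfg = TrainConfig(max_epochs=16, patience=15, seed=3)
        _, h1 = emb.train_hgnn(hg, X, labels, cfg)
        _, h2 = emb.train_hgnn(hg, X, labels, cfg)
        pd.testing.assert_frame_equal(h1, h2)

    def test_separation_grows_and_loss_drops(self, two_class_hypergraph):
        hg, X, labels = two_class_hypergraph
        cfg = TrainConfig(max_epochs=100, seed=1)
        params, hist = emb.train_hgnn(hg, X, labels, cfg)
        best = int(hist.attrs["best_epoch"])
        row = hist[hist["epoch"] == best].iloc[0]
        assert row["intergroup_distance"] > hist["intergroup_distance"].iloc[0]
        assert row["train_loss"] < hist["train_loss"].iloc[0]

    def test_label_alignment_validated(self, two_class_hypergraph):
        hg, X, labels = two_class_hypergraph
        with pytest.raises(ValueError):
            emb.train_hgnn(hg, X, labels[:-1])


# ---------------------------------------------------------------------------
# clustering and quality
# ---------------------------------------------------------------------------

class TestKMeans:
    def test_two_separated_pairs(self):
        pts = np.array([[0.0], [0.0], [10.0], [10.0]])
        labels = emb.kmeans_clusters(pts, k=2, n_init=5, seed=0)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_k_equals_n_zero_inertia(self):
        pts = np.arange(6, dtype=float).reshape(-1, 1) * 10
        labels = emb.kmeans_clusters(pts, k=6, n_init=2, seed=0)
        assert len(set(labels)) == 6

    def test_k_validation(self):
        pts = np.zeros((4, 2))
        with pytest.raises(ValueError):
            emb.kmeans_clusters(pts, k=1)
        with pytest.raises(ValueError):
            emb.kmeans_clusters(pts, k=5)

    def test_planted_five_blobs_exact(self):
        rng = np.random.default_rng(0)
        centers = rng.normal(size=(5, 4)) * 100
        pts = np.vstack([c + rng.normal(size=(30, 4)) for c in centers])
        truth = np.repeat(np.arange(5), 30)
        labels = emb.kmeans_clusters(pts, k=5, n_init=20, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0


def silhouette_textbook(X, labels):
    n = len(labels)
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            vals.append(0.0)
            continue
        a = D[i, own & (np.arange(n) != i)].mean()
        b = min(
            D[i, labels == c].mean() for c in set(labels) if c != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def calinski_textbook(X, labels):
    n, k = len(labels), len(set(labels))
    overall = X.mean(axis=0)
    between = sum(
        (labels == c).sum() * ((X[labels == c].mean(0) - overall) ** 2).sum()
        for c in set(labels)
    )
    within = sum(
        ((X[labels == c] - X[labels == c].mean(0)) ** 2).sum()
        for c in set(labels)
    )
    return float((between / (k - 1)) / (within / (n - k)))


def davies_bouldin_textbook(X, labels):
    cls = sorted(set(labels))
    cents = [X[labels == c].mean(0) for c in cls]
    scatter = [
        np.mean(np.linalg.norm(X[labels == c] - cents[i], axis=1))
        for i, c in enumerate(cls)
    ]
    k = len(cls)
    total = 0.0
    for i in range(k):
        worst = max(
            (scatter[i] + scatter[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in range(k) if j != i
        )
        total += worst
    return float(total / k)


class TestClusterQuality:
    def test_two_pair_clusters_hand_silhouette(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels = np.array([0, 0, 1, 1])
        q = emb.cluster_quality(X, labels)
        assert q["silhouette"] == pytest.approx(0.900, abs=5e-4)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            emb.cluster_quality(np.zeros((4, 2)), np.zeros(4))

    def test_zero_scatter_davies_bouldin_limit(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        q = emb.cluster_quality(X, np.array([0, 0, 1, 1]))
        assert q["davies_bouldin"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_textbook_formulas(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 3)) + np.repeat(
            rng.normal(size=(4, 3)) * 3, 10, axis=0
        )
        labels = np.repeat(np.arange(4), 10)
        q = emb.cluster_quality(X, labels)
        assert q["silhouette"] == pytest.approx(
            silhouette_textbook(X, labels), abs=1e-9
        )
        assert q["calinski_harabasz"] == pytest.approx(
            calinski_textbook(X, labels), rel=1e-9
        )
        assert q["davies_bouldin"] == pytest.approx(
            davies_bouldin_textbook(X, labels), rel=1e-9
        )


class TestProject2D:
    def test_line_explained_by_first_component(self):
        t = np.linspace(0, 1, 20)
        X = np.outer(t, np.array([1.0, 2.0, -1.0]))
        coords, evr = emb.project_2d(X, "pca")
        assert evr[0] == pytest.approx(1.0)
        assert evr.sum() <= 1 + 1e-12

    def test_pca_sign_convention_reproducible(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        c1, e1 = emb.project_2d(X, "pca")
        c2, e2 = emb.project_2d(X, "pca")
        assert np.array_equal(c1, c2)

    def test_tsne_perplexity_validated(self):
        X = np.random.default_rng(0).normal(size=(30, 4))
        with pytest.raises(ValueError):
            emb.project_2d(X, "tsne", perplexity=10.0)

    def test_tsne_runs_on_valid_input(self):
        X = np.random.default_rng(0).normal(size=(60, 4))
        coords, extra = emb.project_2d(X, "tsne", perplexity=10.0, n_iter=250)
        assert coords.shape == (60, 2)
        assert extra is None


class TestCompareClusterings:
    def _assignments(self):
        genes = [f"g{i:03d}" for i in range(40)]
        a = pd.Series([0] * 10 + [1] * 30, index=genes)
        return genes, a

    def test_identical_assignments(self):
        genes, a = self._assignments()
        res = emb.compare_clusterings(a, a.copy(), set(genes[:10]),
                                      n_perm=100, seed=0)
        assert res["jaccard"] == 1.0
        assert res["adjusted_rand"] == 1.0

    def test_partial_overlap_jaccard(self):
        genes = [f"g{i:03d}" for i in range(60)]
        # focus clusters of 10 sharing 8 members -> jaccard 8/12
        a = pd.Series(
            [0] * 10 + [1] * 50, index=genes
        )
        b_labels = [9] * 8 + [5] * 2 + [9] * 2 + [5] * 48
        b = pd.Series(b_labels, index=genes)
        res = emb.compare_clusterings(a, b, set(genes[:10]), n_perm=100, seed=0)
        assert res["jaccard"] == pytest.approx(8 / 12)

    def test_random_vs_structured_ari_near_zero(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:04d}" for i in range(1000)]
        a = pd.Series(np.repeat(np.arange(5), 200), index=genes)
        b = pd.Series(rng.integers(0, 5, size=1000), index=genes)
        res = emb.compare_clusterings(a, b, set(genes[:10]), n_perm=50, seed=0)
        assert abs(res["adjusted_rand"]) < 0.05

    def test_empty_focus_rejected(self):
        genes, a = self._assignments()
        with pytest.raises(ValueError):
            emb.compare_clusterings(a, a, set(), n_perm=10, seed=0)
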