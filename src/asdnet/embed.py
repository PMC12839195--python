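"""Hypergraph-convolution embeddings with contrastive training.

A three-layer hypergraph convolutional network (7 -> 64 -> 32 -> 16)
propagates node features through the hypergraph operator
Theta = Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2}, with batch normalization,
rectifier nonlinearities on the hidden layers and dropout during training.
Training minimizes a contrastive margin loss that pulls hub-hub embedding
distances below m_pos and pushes hub/non-hub distances above m_neg, using
full-batch Adam with exponential learning-rate decay and early stopping.

The network is implemented directly on numpy arrays with hand-written
backpropagation; gradients are verified against finite differences in the
test suite.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .hypergraph import Hypergraph
from .stats import fisher_exact_2x2, jaccard_index

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "HGNNParams",
    "ContrastiveConfig",
    "TrainConfig",
    "build_feature_matrix",
    "init_params",
    "hgnn_forward",
    "contrastive_loss",
    "train_hgnn",
    "kmeans_clusters",
    "cluster_quality",
    "project_2d",
    "compare_clusterings",
]

TOPOLOGY7 = (
    "degree_centrality",
    "betweenness",
    "closeness",
    "clustering_coef",
    "static_perturbation",
    "mldpp_final",
    "stability",
)
HUB_INDEPENDENT5 = (
    "sfari_score",
    "gene_length_kb",
    "constraint",
    "brain_expression",
    "pathway_count",
)
HUB_INDEPENDENT3 = ("clustering_coef", "sfari_member", "log_degree")

# category evidence strength, descending from category 1
_SFARI_SCORE = {"1": 4.0, "2": 3.0, "3": 2.0, "S": 1.0, "unknown": 0.0}

_BN_EPS = 1e-5


@dataclass
class FeatureMatrix:
    X: np.ndarray
    feature_names: tuple[str, ...]
    genes: list[str]
    variant: str
    means: np.ndarray
    sds: np.ndarray
    zero_variance: np.ndarray


@dataclass(frozen=True)
class ContrastiveConfig:
    m_pos: float = 0.5
    m_neg: float = 1.5

    def __post_init__(self):
        if not 0 < self.m_pos < self.m_neg:
            raise ValueError("margins must satisfy 0 < m_pos < m_neg")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    decay_factor: float = 0.95
    decay_every: int = 10
    weight_decay: float = 1e-5
    max_epochs: int = 100
    patience: int = 15
    test_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be below max_epochs")
        if min(self.lr, self.beta1, self.beta2, self.eps) <= 0:
            raise ValueError("optimizer hyperparameters must be positive")


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def build_feature_matrix(
    centralities: pd.DataFrame,
    mldpp_metrics: pd.DataFrame | None,
    gene_table: pd.DataFrame | None,
    variant: str = "topology7",
    static_scores: pd.Series | None = None,
) -> FeatureMatrix:
    """Assemble and z-score one of the documented feature variants.

    ``topology7`` needs the centrality profile, the static perturbation
    scores, and the propagation metrics frame (mldpp_final, stability);
    ``hub_independent5`` uses annotation features only; ``hub_independent3``
    uses clustering coefficient, a curated-membership indicator, and log
    degree.  Constant columns are kept but flagged and only centered.
    """
    genes = list(centralities.index)
    cols: dict[str, np.ndarray] = {}
    if variant == "topology7":
        if mldpp_metrics is None or static_scores is None:
            raise ValueError("topology7 needs mldpp metrics and static scores")
        for c in ("degree_centrality", "betweenness", "closeness", "clustering_coef"):
            cols[c] = centralities[c].to_numpy(dtype=float)
        cols["static_perturbation"] = static_scores.reindex(genes).to_numpy(dtype=float)
        cols["mldpp_final"] = mldpp_metrics["mldpp_final"].reindex(genes).to_numpy(dtype=float)
        cols["stability"] = mldpp_metrics["stability"].reindex(genes).to_numpy(dtype=float)
        names = TOPOLOGY7
    elif variant == "hub_independent5":
        if gene_table is None:
            raise ValueError("hub_independent5 needs the gene table")
        gt = gene_table.reindex(genes)
        cols["sfari_score"] = gt["category"].map(_SFARI_SCORE).to_numpy(dtype=float)
        cols["gene_length_kb"] = gt["gene_length_kb"].to_numpy(dtype=float)
        cols["constraint"] = gt["constraint"].to_numpy(dtype=float)
        cols["brain_expression"] = gt["brain_expression"].to_numpy(dtype=float)
        cols["pathway_count"] = gt["pathway_count"].to_numpy(dtype=float)
        names = HUB_INDEPENDENT5
    elif variant == "hub_independent3":
        if gene_table is None:
            raise ValueError("hub_independent3 needs the gene table")
        gt = gene_table.reindex(genes)
        cols["clustering_coef"] = centralities["clustering_coef"].to_numpy(dtype=float)
        cols["sfari_member"] = (gt["category"] != "unknown").to_numpy(dtype=float)
        cols["log_degree"] = np.log1p(centralities["degree"].to_numpy(dtype=float))
        names = HUB_INDEPENDENT3
    else:
        raise ValueError(f"unknown feature variant {variant!r}")

    X = np.column_stack([cols[c] for c in names]).astype(float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    zero_var = sds == 0
    X = X - means
    X[:, ~zero_var] = X[:, ~zero_var] / sds[~zero_var]
    return FeatureMatrix(X, tuple(names), genes, variant, means, sds, zero_var)


# ---------------------------------------------------------------------------
# network parameters and forward pass
# ---------------------------------------------------------------------------

@dataclass
class HGNNParams:
    """Learnable state: per-layer transform plus batch-norm moments."""

    thetas: list[np.ndarray]
    gammas: list[np.ndarray]
    betas: list[np.ndarray]
    running_means: list[np.ndarray]
    running_vars: list[np.ndarray]
    dropout: float = 0.2
    use_batchnorm: bool = True
    bn_momentum: float = 0.9
    bn_initialized: bool = False
    dims: tuple[int, ...] = (7, 64, 32, 16)
    seed: int = 0

    def copy(self) -> "HGNNParams":
        return copy.deepcopy(self)


def init_params(
    dims: tuple[int, ...] = (7, 64, 32, 16),
    dropout: float = 0.2,
    use_batchnorm: bool = True,
    seed: int = 0,
) -> HGNNParams:
    """Glorot-uniform transforms; unit batch-norm scale on hidden layers.

    The final layer's batch-norm scale starts at 0.1 so initial embeddings
    are compact relative to the contrastive margins; training then grows
    inter-group separation instead of having to shrink an initially
    scattered embedding cloud.
    """
    rng = np.random.default_rng(seed)
    thetas, gammas, betas, rmeans, rvars = [], [], [], [], []
    n_layers = len(dims) - 1
    for layer, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
        limit = np.sqrt(6.0 / (d_in + d_out))
        thetas.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
        gammas.append(np.full(d_out, 0.1) if layer == n_layers - 1
                      else np.ones(d_out))
        betas.append(np.zeros(d_out))
        rmeans.append(np.zeros(d_out))
        rvars.append(np.ones(d_out))
    return HGNNParams(thetas, gammas, betas, rmeans, rvars, dropout,
                      use_batchnorm, dims=tuple(dims), seed=seed)


def _forward(
    P: np.ndarray,
    X: np.ndarray,
    params: HGNNParams,
    training: bool,
    rng: np.random.Generator | None,
    update_running: bool = False,
):
    """Forward pass returning the embedding and a cache for backprop."""
    n_layers = len(params.thetas)
    Z = X
    cache = []
    for layer in range(n_layers):
        M = P @ Z
        A = M @ params.thetas[layer]
        if params.use_batchnorm:
            if training:
                mu = A.mean(axis=0)
                var = A.var(axis=0, ddof=0)
                if update_running:
                    if not params.bn_initialized:
                        # warm start: first batch stats seed the running
                        # moments so early evaluation passes are usable
                        params.running_means[layer] = mu.copy()
                        params.running_vars[layer] = var.copy()
                    else:
                        m = params.bn_momentum
                        params.running_means[layer] = (
                            m * params.running_means[layer] + (1 - m) * mu
                        )
                        params.running_vars[layer] = (
                            m * params.running_vars[layer] + (1 - m) * var
                        )
            else:
                mu = params.running_means[layer]
                var = params.running_vars[layer]
            std = np.sqrt(var + _BN_EPS)
            xhat = (A - mu) / std
            B = params.gammas[layer] * xhat + params.betas[layer]
        else:
            xhat, std, B = None, None, A
        hidden = layer < n_layers - 1
        C = np.maximum(B, 0.0) if hidden else B
        if training and params.dropout > 0:
            assert rng is not None, "training with dropout needs an rng"
            mask = (rng.uniform(size=C.shape) >= params.dropout) / (1 - params.dropout)
            Znew = C * mask
        else:
            mask = None
            Znew = C
        cache.append(dict(Z_in=Z, M=M, A=A, xhat=xhat, std=std, B=B,
                          mask=mask, hidden=hidden))
        Z = Znew
    if update_running and params.use_batchnorm:
        params.bn_initialized = True
    return Z, cache


def hgnn_forward(
    hg: Hypergraph,
    X: np.ndarray,
    params: HGNNParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
    return_layers: bool = False,
):
    """Embed nodes; evaluation mode is deterministic.

    Returns the final embedding, or with ``return_layers`` a list of
    pre-nonlinearity layer outputs plus the embedding (for the dense-oracle
    equivalence checks).
    """
    if X.shape[0] != len(hg.nodes):
        raise ValueError("feature rows must match hypergraph nodes")
    if X.shape[1] != params.dims[0]:
        raise ValueError(
            f"feature width {X.shape[1]} != input dim {params.dims[0]}"
        )
    P = hg.propagation_operator()
    Z, cache = _forward(P, X, params, training, rng, update_running=training)
    if return_layers:
        return Z, [c["A"] for c in cache]
    return Z


def _backward(P, params, cache, dZ, training: bool):
    """Backprop through the cached forward pass; returns parameter grads."""
    n = dZ.shape[0]
    d_thetas = [None] * len(params.thetas)
    d_gammas = [None] * len(params.thetas)
    d_betas = [None] * len(params.thetas)
    for layer in reversed(range(len(params.thetas))):
        c = cache[layer]
        dC = dZ * c["mask"] if c["mask"] is not None else dZ
        dB = dC * (c["B"] > 0) if c["hidden"] else dC
        if params.use_batchnorm:
            xhat, std = c["xhat"], c["std"]
            d_gammas[layer] = (dB * xhat).sum(axis=0)
            d_betas[layer] = dB.sum(axis=0)
            g = params.gammas[layer]
            if training:
                dA = (g / std) * (
                    dB
                    - dB.mean(axis=0)
                    - xhat * (dB * xhat).mean(axis=0)
                )
            else:
                dA = dB * g / std
        else:
            d_gammas[layer] = np.zeros_like(params.gammas[layer])
            d_betas[layer] = np.zeros_like(params.betas[layer])
            dA = dB
        d_thetas[layer] = c["M"].T @ dA
        dZ = P.T @ (dA @ params.thetas[layer].T)
    return d_thetas, d_gammas, d_betas


# ---------------------------------------------------------------------------
# contrastive loss
# ---------------------------------------------------------------------------

def _pair_masks(hub_labels: np.ndarray):
    h = hub_labels.astype(bool)
    if h.all() or not h.any():
        raise ValueError("need at least one hub and one non-hub gene")
    same = np.outer(h, h)
    cross = np.outer(h, ~h) | np.outer(~h, h)
    upper = np.triu(np.ones_like(same, dtype=bool), k=1)
    return same & upper, cross & upper


def _distances(E: np.ndarray) -> np.ndarray:
    sq = np.sum(E**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * E @ E.T, 0.0)
    return np.sqrt(d2)


def contrastive_loss(
    embeddings: np.ndarray,
    hub_labels,
    config: ContrastiveConfig = ContrastiveConfig(),
) -> float:
    """Margin loss: mean squared hinge over hub-hub and hub/non-hub pairs."""
    loss, _ = _loss_and_grad(np.asarray(embeddings, dtype=float),
                             np.asarray(hub_labels), config, need_grad=False)
    return loss


def _loss_and_grad(E, hub_labels, config, need_grad=True):
    hh, hn = _pair_masks(np.asarray(hub_labels))
    D = _distances(E)
    n_hh, n_hn = int(hh.sum()), int(hn.sum())
    pos_viol = hh & (D > config.m_pos)
    neg_viol = hn & (D < config.m_neg)
    loss = 0.0
    if n_hh:
        loss += float(np.sum((D[pos_viol] - config.m_pos) ** 2)) / n_hh
    if n_hn:
        loss += float(np.sum((config.m_neg - D[neg_viol]) ** 2)) / n_hn
    if not need_grad:
        return loss, None
    K = np.zeros_like(D)
    safe_D = np.where(D > 1e-12, D, 1.0)
    if n_hh:
        K[pos_viol] = 2.0 * (D[pos_viol] - config.m_pos) / safe_D[pos_viol] / n_hh
    if n_hn:
        mask = neg_viol & (D > 1e-12)  # zero-distance cross pairs: subgradient 0
        K[mask] -= 2.0 * (config.m_neg - D[mask]) / safe_D[mask] / n_hn
    K = K + K.T
    grad = E * K.sum(axis=1)[:, None] - K @ E
    return loss, grad


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_hgnn(
    hg: Hypergraph,
    X: np.ndarray,
    hub_labels,
    train_config: TrainConfig = TrainConfig(),
    contrastive_config: ContrastiveConfig = ContrastiveConfig(),
    params: HGNNParams | None = None,
) -> tuple[HGNNParams, pd.DataFrame]:
    """Full-batch Adam training with early stopping on held-out genes.

    A stratified ``test_fraction`` of genes is held out; the validation loss
    is the contrastive loss among held-out genes in evaluation mode.  The
    history records, per epoch, training loss, validation loss and the mean
    hub/non-hub inter-group embedding distance.  The returned parameters
    are the best-validation-loss snapshot.
    """
    hub_labels = np.asarray(hub_labels, dtype=bool)
    if X.shape[0] != len(hub_labels):
        raise ValueError("labels must align with feature rows")
    rng = np.random.default_rng(train_config.seed)
    if params is None:
        params = init_params(
            dims=(X.shape[1], 64, 32, 16), seed=train_config.seed
        )
    P = hg.propagation_operator()

    hub_idx = np.flatnonzero(hub_labels)
    non_idx = np.flatnonzero(~hub_labels)
    n_val_h = int(round(train_config.test_fraction * len(hub_idx)))
    n_val_n = int(round(train_config.test_fraction * len(non_idx)))
    val_idx = np.array([], dtype=int)
    if (
        n_val_h >= 1 and n_val_n >= 1
        and len(hub_idx) - n_val_h >= 1 and len(non_idx) - n_val_n >= 1
    ):
        val_idx = np.concatenate([
            rng.choice(hub_idx, size=n_val_h, replace=False),
            rng.choice(non_idx, size=n_val_n, replace=False),
        ])
    else:
        logger.info("too few genes per class for a validation split; "
                    "validation loss falls back to training loss")
    train_mask = np.ones(X.shape[0], dtype=bool)
    train_mask[val_idx] = False

    m_state = {k: None for k in ("theta", "gamma", "beta")}
    v_state = {k: None for k in ("theta", "gamma", "beta")}

    def adam_step(grads, key, values, lr, step):
        if m_state[key] is None:
            m_state[key] = [np.zeros_like(g) for g in grads]
            v_state[key] = [np.zeros_like(g) for g in grads]
        b1, b2, eps = train_config.beta1, train_config.beta2, train_config.eps
        for i, g in enumerate(grads):
            m_state[key][i] = b1 * m_state[key][i] + (1 - b1) * g
            v_state[key][i] = b2 * v_state[key][i] + (1 - b2) * g**2
            mhat = m_state[key][i] / (1 - b1**step)
            vhat = v_state[key][i] / (1 - b2**step)
            values[i] -= lr * mhat / (np.sqrt(vhat) + eps)

    def intergroup_distance(E):
        D = _distances(E)
        return float(D[np.ix_(hub_labels, ~hub_labels)].mean())

    best_val = np.inf
    best_params = params.copy()
    best_epoch = 0
    since_best = 0
    rows = []
    for epoch in range(1, train_config.max_epochs + 1):
        lr = train_config.lr * train_config.decay_factor ** (
            (epoch - 1) // train_config.decay_every
        )
        Z, cache = _forward(P, X, params, training=True, rng=rng,
                            update_running=True)
        loss_tr, dZ_full = _loss_and_grad(
            Z[train_mask], hub_labels[train_mask], contrastive_config
        )
        if not np.isfinite(loss_tr):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        dZ = np.zeros_like(Z)
        dZ[train_mask] = dZ_full
        d_thetas, d_gammas, d_betas = _backward(P, params, cache, dZ, training=True)
        for i in range(len(d_thetas)):
            d_thetas[i] = d_thetas[i] + train_config.weight_decay * params.thetas[i]
        adam_step(d_thetas, "theta", params.thetas, lr, epoch)
        if params.use_batchnorm:
            adam_step(d_gammas, "gamma", params.gammas, lr, epoch)
            adam_step(d_betas, "beta", params.betas, lr, epoch)

        E_eval, _ = _forward(P, X, params, training=False, rng=None)
        if len(val_idx):
            loss_val, _ = _loss_and_grad(
                E_eval[val_idx], hub_labels[val_idx], contrastive_config,
                need_grad=False,
            )
        else:
            loss_val, _ = _loss_and_grad(
                E_eval[train_mask], hub_labels[train_mask], contrastive_config,
                need_grad=False,
            )
        rows.append((epoch, loss_tr, loss_val, intergroup_distance(E_eval)))
        if loss_val < best_val - 1e-12:
            best_val = loss_val
            best_params = params.copy()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= train_config.patience:
                break
    history = pd.DataFrame(
        rows, columns=["epoch", "train_loss", "val_loss", "intergroup_distance"]
    )
    history.attrs["best_epoch"] = best_epoch
    return best_params, history


# ---------------------------------------------------------------------------
# clustering of embeddings
# ---------------------------------------------------------------------------

def kmeans_clusters(
    embeddings: np.ndarray, k: int = 5, n_init: int = 100, seed: int = 0
) -> np.ndarray:
    """Minimum-inertia K-means assignment over ``n_init`` restarts."""
    embeddings = np.asarray(embeddings, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > embeddings.shape[0]:
        raise ValueError("k cannot exceed the number of points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(embeddings)


def cluster_quality(embeddings: np.ndarray, assignment) -> dict:
    """Silhouette, Calinski-Harabasz and Davies-Bouldin (Euclidean)."""
    assignment = np.asarray(assignment)
    if len(np.unique(assignment)) < 2:
        raise ValueError("cluster quality undefined for a single cluster")
    return {
        "silhouette": float(silhouette_score(embeddings, assignment)),
        "calinski_harabasz": float(calinski_harabasz_score(embeddings, assignment)),
        "davies_bouldin": float(davies_bouldin_score(embeddings, assignment)),
    }


def project_2d(
    embeddings: np.ndarray,
    method: str = "pca",
    perplexity: float = 30.0,
    learning_rate: float = 200.0,
    n_iter: int = 1000,
    seed: int = 0,
):
    """2-D projection for visualization.

    PCA reports explained-variance fractions and fixes component signs by
    making the largest-magnitude loading positive, so repeated runs agree
    exactly.  t-SNE uses the documented perplexity/learning-rate defaults
    and a fixed seed; it is a visualization device only.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    n = embeddings.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to project")
    if method == "pca":
        pca = PCA(n_components=2, random_state=seed)
        coords = pca.fit_transform(embeddings)
        for j in range(coords.shape[1]):
            load = pca.components_[j]
            if load[np.argmax(np.abs(load))] < 0:
                coords[:, j] *= -1
        return coords, pca.explained_variance_ratio_.copy()
    if method == "tsne":
        if perplexity >= n / 3:
            raise ValueError("perplexity must be below n/3")
        tsne = TSNE(
            n_components=2, perplexity=perplexity, learning_rate=learning_rate,
            max_iter=n_iter, random_state=seed, init="pca",
        )
        return tsne.fit_transform(embeddings), None
    raise ValueError(f"unknown projection method {method!r}")


# ---------------------------------------------------------------------------
# clustering comparison (hub-independent validation)
# ---------------------------------------------------------------------------

def _focus_cluster(assignment: pd.Series, focus: set[str]) -> set[str]:
    counts = assignment.loc[assignment.index.isin(focus)].value_counts()
    best = counts.idxmax()
    return set(assignment.index[assignment == best])


def compare_clusterings(
    assignment_a: pd.Series,
    assignment_b: pd.Series,
    focus_set: set[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Agreement between two clusterings around a focus gene set.

    The focus cluster of each assignment is the cluster holding the
    plurality of focus genes; ``jaccard`` is their intersection over union.
    The permutation p randomly reassigns the second clustering's labels.
    ``adjusted_rand`` covers the complete assignments, and Fisher's exact
    test quantifies focus-gene concentration in the second assignment's
    best-overlap cluster.
    """
    if not focus_set:
        raise ValueError("empty focus set")
    if not assignment_a.index.equals(assignment_b.index):
        assignment_b = assignment_b.reindex(assignment_a.index)
        if assignment_b.isna().any():
            raise ValueError("assignments must cover the same gene universe")
    genes = assignment_a.index
    focus = set(focus_set) & set(genes)
    if not focus:
        raise ValueError("focus set disjoint from the gene universe")

    cluster_a = _focus_cluster(assignment_a, focus)
    cluster_b = _focus_cluster(assignment_b, focus)
    jac = jaccard_index(cluster_a, cluster_b)
    ari = float(adjusted_rand_score(assignment_a.to_numpy(), assignment_b.to_numpy()))

    rng = np.random.default_rng(seed)
    labels_b = assignment_b.to_numpy()
    count = 0
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(labels_b), index=genes)
        if jaccard_index(cluster_a, _focus_cluster(perm, focus)) >= jac:
            count += 1
    perm_p = (1 + count) / (1 + n_perm)

    in_b = assignment_b.index.isin(cluster_b)
    in_focus = assignment_b.index.isin(focus)
    a = int((in_b & in_focus).sum())
    b = int((~in_b & in_focus).sum())
    c = int((in_b & ~in_focus).sum())
    d = int((~in_b & ~in_focus).sum())
    fisher = fisher_exact_2x2(a, b, c, d)
    return {
        "jaccard": float(jac),
        "adjusted_rand": ari,
        "perm_p": float(perm_p),
        "fisher_or": fisher.odds_ratio,
        "fisher_ci": fisher.ci95,
        "fisher_p": fisher.p,
    }
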