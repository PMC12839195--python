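"""Centralities, composite perturbation scores, hub classification, and
global topology statistics with robustness validations.

The hub-classification statistic is the *static perturbation score*: a
gene's degree centrality multiplied by the mean confidence of its incident
edges.  Genes strictly above the 80th percentile of that score are hubs.
Robustness of the classification is probed by random edge removal and by
k-fold randomized edge sampling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "HubClassification",
    "PowerLawFit",
    "centrality_profile",
    "score_from_components",
    "perturbation_scores",
    "classify_hubs",
    "fit_power_law",
    "small_world_stats",
    "edge_removal_robustness",
    "edge_cv_stability",
]


@dataclass
class HubClassification:
    """Per-gene perturbation score with the realized percentile cutoff."""

    scores: pd.Series
    is_hub: pd.Series
    threshold_value: float
    percentile: float = 80.0

    @property
    def hubs(self) -> set[str]:
        return set(self.is_hub.index[self.is_hub])

    @property
    def n_hubs(self) -> int:
        return int(self.is_hub.sum())


@dataclass(frozen=True)
class PowerLawFit:
    alpha: float
    xmin: float
    r_squared: float
    gof_p: float
    n_tail: int


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

def centrality_profile(network: nx.Graph) -> pd.DataFrame:
    """Six centrality measures for every node.

    Betweenness is reported raw (unordered-pair counts, not normalized).
    Closeness is the classic inverse mean shortest-path distance on
    connected graphs; on disconnected graphs the normalized harmonic
    variant is substituted and flagged in ``df.attrs['closeness_variant']``.
    """
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("centralities undefined for fewer than 2 nodes")
    nodes = sorted(network.nodes())
    degree = dict(network.degree())
    degree_centrality = nx.degree_centrality(network)
    betweenness = nx.betweenness_centrality(network, normalized=False)
    if nx.is_connected(network):
        closeness = nx.closeness_centrality(network)
        closeness_variant = "standard"
    else:
        harmonic = nx.harmonic_centrality(network)
        closeness = {v: harmonic[v] / (n - 1) for v in network}
        closeness_variant = "harmonic"
    # eigenvector centrality per connected component (solvers reject
    # disconnected graphs); Perron vector of the component adjacency,
    # unit Euclidean norm; singletons score 0
    eigenvector: dict = {}
    for component in nx.connected_components(network):
        members = sorted(component)
        if len(members) == 1:
            eigenvector[members[0]] = 0.0
            continue
        adj = nx.to_numpy_array(network.subgraph(members), nodelist=members)
        vals, vecs = np.linalg.eigh(adj)
        vec = np.abs(vecs[:, -1])
        vec /= np.linalg.norm(vec)
        eigenvector.update(zip(members, vec))
    clustering = nx.clustering(network)
    df = pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "degree_centrality": [degree_centrality[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "eigenvector": [eigenvector[v] for v in nodes],
            "clustering_coef": [clustering[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )
    df.attrs["closeness_variant"] = closeness_variant
    return df


# ---------------------------------------------------------------------------
# perturbation score and hub rule
# ---------------------------------------------------------------------------

def score_from_components(degree_centrality: float, mean_confidence: float) -> float:
    """Composite static score: degree centrality x mean incident confidence."""
    return degree_centrality * mean_confidence


def perturbation_scores(network: nx.Graph, max_normalize: bool = False) -> pd.Series:
    """Static perturbation score per gene; isolated nodes score 0.

    The default is the plain product of degree centrality and the mean
    confidence of incident edges.  ``max_normalize`` rescales by the
    maximum score so the top gene scores exactly 1.
    """
    n = network.number_of_nodes()
    nodes = sorted(network.nodes())
    scores = {}
    for v in nodes:
        deg = network.degree(v)
        if deg == 0 or n < 2:
            scores[v] = 0.0
            continue
        mean_w = float(
            np.mean([network[v][u]["confidence"] for u in network.neighbors(v)])
        )
        scores[v] = score_from_components(deg / (n - 1), mean_w)
    s = pd.Series(scores, name="perturbation_score")
    s.index.name = "gene"
    if max_normalize:
        top = s.max()
        if top > 0:
            s = s / top
    return s


def classify_hubs(scores: pd.Series, percentile: float = 80.0) -> HubClassification:
    """Hub classification at a percentile cutoff (strictly above).

    The threshold is the linear-interpolation percentile over order
    statistics.  An all-equal score vector is degenerate: zero hubs plus a
    logged warning.
    """
    if len(scores) < 5:
        raise ValueError("need at least 5 scores to classify hubs")
    values = scores.to_numpy(dtype=float)
    threshold = float(np.percentile(values, percentile))
    if values.max() == values.min():
        logger.warning("all perturbation scores identical: zero hubs classified")
        is_hub = pd.Series(False, index=scores.index)
        return HubClassification(scores, is_hub, threshold, percentile)
    is_hub = pd.Series(values > threshold, index=scores.index)
    return HubClassification(scores, is_hub, threshold, percentile)


# ---------------------------------------------------------------------------
# power-law fit
# ---------------------------------------------------------------------------

def fit_power_law(
    degrees, xmin: float | None = None, discrete: bool = False
) -> PowerLawFit:
    """Continuous maximum-likelihood power-law fit of a degree sequence.

    alpha = 1 + n / sum(ln(x_i / xmin)) over the tail x >= xmin.  With
    ``discrete=True`` the standard half-shift xmin - 1/2 is used in the
    logarithm, the usual correction when integer counts are fit with the
    continuous estimator.  ``r_squared`` is from least squares on the
    log-log empirical degree distribution; ``gof_p`` is a chi-squared
    goodness-of-fit p-value against the fitted law.
    """
    degrees = np.asarray(degrees, dtype=float)
    degrees = degrees[degrees > 0]
    if xmin is None:
        if degrees.size < 50:
            raise ValueError("need at least 50 positive degrees (or explicit xmin)")
        xmin = float(degrees.min())
    tail = degrees[degrees >= xmin]
    if tail.size < 2:
        raise ValueError("too few degrees at or above xmin")
    if tail.max() == tail.min():
        raise ValueError("all degrees equal: power-law fit undefined")
    shift = 0.5 if discrete else 0.0
    denom = np.log(tail / (xmin - shift)).sum()
    alpha = 1.0 + tail.size / denom

    # log-log least squares on the empirical pmf
    uniq, counts = np.unique(tail, return_counts=True)
    pk = counts / tail.size
    slope, intercept, r, _, _ = sps.linregress(np.log(uniq), np.log(pk))
    r_squared = float(r**2)

    # chi-squared GOF: expected counts under the fitted law over observed
    # support, adjacent bins merged until every expected count is >= 5
    support = np.arange(int(np.floor(xmin)), int(tail.max()) + 1, dtype=float)
    expected_p = support ** (-alpha)
    expected_p /= expected_p.sum()
    obs_counts = np.array(
        [np.sum(tail == k) for k in support], dtype=float
    )
    exp_counts = expected_p * tail.size
    merged_obs, merged_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs_counts, exp_counts):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            merged_obs.append(acc_o)
            merged_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and merged_exp:
        merged_obs[-1] += acc_o
        merged_exp[-1] += acc_e
    if len(merged_exp) > 1:
        merged_obs = np.asarray(merged_obs)
        merged_exp = np.asarray(merged_exp) * merged_obs.sum() / np.sum(merged_exp)
        chi2 = np.sum((merged_obs - merged_exp) ** 2 / merged_exp)
        gof_p = float(sps.chi2.sf(chi2, df=max(len(merged_exp) - 2, 1)))
    else:
        gof_p = float("nan")
    return PowerLawFit(float(alpha), float(xmin), r_squared, gof_p, int(tail.size))


# ---------------------------------------------------------------------------
# small-world statistics
# ---------------------------------------------------------------------------

def _mean_reachable_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length over reachable (connected) node pairs."""
    total = 0.0
    count = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                count += 1
    return total / count if count else float("nan")


def small_world_stats(network: nx.Graph, n_random: int = 20, seed: int = 0) -> dict:
    """Clustering/path-length comparison against matched random graphs.

    C and L are compared with Erdos-Renyi G(n, m) graphs with the same node
    and edge counts, averaged over ``n_random`` draws (path length measured
    over reachable pairs in case a draw is disconnected).  Also reports the
    degree assortativity; graphs with zero degree variance over edges yield
    NaN with a warning.
    """
    if n_random < 1:
        raise ValueError("n_random must be at least 1")
    if not nx.is_connected(network):
        raise ValueError("apply small_world_stats to the giant component")
    n, m = network.number_of_nodes(), network.number_of_edges()
    C = nx.average_clustering(network)
    L = _mean_reachable_path_length(network)
    rng = np.random.default_rng(seed)
    c_rand, l_rand = [], []
    for _ in range(n_random):
        gr = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        c_rand.append(nx.average_clustering(gr))
        l_rand.append(_mean_reachable_path_length(gr))
    C_random = float(np.mean(c_rand))
    L_random = float(np.nanmean(l_rand))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            assort = float(nx.degree_assortativity_coefficient(network))
        except (ZeroDivisionError, ValueError):
            assort = float("nan")
    if np.isnan(assort):
        logger.warning("degree assortativity undefined (zero variance); NaN")
    return {
        "C": float(C),
        "L": float(L),
        "C_random": C_random,
        "L_random": L_random,
        "C_ratio": float(C / C_random) if C_random > 0 else float("inf"),
        "assortativity": assort,
    }


# ---------------------------------------------------------------------------
# robustness validations
# ---------------------------------------------------------------------------

def edge_removal_robustness(
    network: nx.Graph,
    fractions=(0.1, 0.2, 0.3),
    n_iter: int = 100,
    seed: int = 0,
    percentile: float = 80.0,
) -> pd.DataFrame:
    """Hub-classification consistency under random edge removal.

    For each removal fraction and iteration, that fraction of edges is
    removed uniformly at random, hubs are re-classified on the perturbed
    network, and consistency is the percentage of original hubs - restricted
    to genes remaining in the perturbed network's largest component - that
    keep hub status.  Fraction 0 is allowed as a control (exactly 100%).
    """
    for f in fractions:
        if not 0 <= f < 1:
            raise ValueError("removal fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    original = classify_hubs(perturbation_scores(network), percentile)
    orig_hubs = original.hubs
    edges = list(network.edges())
    m = len(edges)
    rows = []
    for f in fractions:
        n_remove = int(round(f * m))
        consistencies = []
        for _ in range(n_iter):
            g = network.copy()
            if n_remove:
                idx = rng.choice(m, size=n_remove, replace=False)
                g.remove_edges_from([edges[i] for i in idx])
            giant = max(nx.connected_components(g), key=len)
            surviving = orig_hubs & giant
            if not surviving:
                continue
            new_hubs = classify_hubs(perturbation_scores(g), percentile).hubs
            consistencies.append(100.0 * len(surviving & new_hubs) / len(surviving))
        rows.append(
            (f, float(np.mean(consistencies)), float(np.std(consistencies, ddof=0)),
             len(consistencies))
        )
    return pd.DataFrame(
        rows, columns=["fraction", "mean_consistency", "sd_consistency", "n_iterations"]
    )


def edge_cv_stability(
    network: nx.Graph,
    k: int = 5,
    sample_frac: float = 0.8,
    seed: int = 0,
    percentile: float = 80.0,
) -> pd.DataFrame:
    """k-fold randomized edge sampling stability of the hub classification.

    Each fold retains ``sample_frac`` of edges at random; consistency is the
    percentage of all genes keeping their full-network hub/non-hub status.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if not 0 < sample_frac <= 1:
        raise ValueError("sample_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    full = classify_hubs(perturbation_scores(network), percentile)
    edges = list(network.edges())
    m = len(edges)
    n_keep = int(round(sample_frac * m))
    rows = []
    for fold in range(k):
        g = nx.Graph()
        g.add_nodes_from(network.nodes())
        if n_keep:
            idx = rng.choice(m, size=n_keep, replace=False)
            for i in idx:
                a, b = edges[i]
                g.add_edge(a, b, confidence=network[a][b]["confidence"])
        fold_cls = classify_hubs(perturbation_scores(g), percentile)
        agree = (fold_cls.is_hub.reindex(full.is_hub.index) == full.is_hub).mean()
        rows.append((fold, fold_cls.n_hubs, 100.0 * float(agree)))
    df = pd.DataFrame(rows, columns=["fold", "n_hubs", "consistency"])
    df.attrs["mean_consistency"] = float(df["consistency"].mean())
    df.attrs["sd_consistency"] = float(df["consistency"].std(ddof=0))
    return df
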