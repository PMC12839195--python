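"""Enrichment statistics and the shared statistical toolbox.

Hypergeometric gene-set enrichment with Benjamini-Hochberg control,
Fisher's exact test for 2x2 tables, Jaccard overlap networks between gene
sets, rank tests (Mann-Whitney, Kruskal-Wallis with Dunn post hoc) and a
generic label-permutation machine.  These are the statistical primitives the
network, propagation, and clustering modules report through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "FisherResult",
    "hypergeom_enrichment",
    "bh_fdr",
    "fisher_exact_2x2",
    "jaccard_index",
    "jaccard_overlap_network",
    "mann_whitney",
    "kruskal_dunn",
    "permutation_pvalue",
    "fold_change",
    "relative_increase",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set hypergeometric enrichment row."""

    set_name: str
    set_size: int
    observed: int
    expected: float
    ratio: float
    p: float
    q: float


@dataclass(frozen=True)
class FisherResult:
    """2x2 Fisher's exact test result with a Woolf log-interval CI.

    ``haldane_corrected`` flags tables where a zero cell required the 0.5
    continuity correction for the sample odds ratio and its interval.
    """

    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    haldane_corrected: bool = False


# ---------------------------------------------------------------------------
# simple effect-size arithmetic shared by reporting code
# ---------------------------------------------------------------------------

def fold_change(value: float, baseline: float) -> float:
    """Ratio of ``value`` to ``baseline`` (e.g. hub mean over non-hub mean)."""
    if baseline == 0:
        raise ValueError("fold change undefined for zero baseline")
    return value / baseline


def relative_increase(value: float, baseline: float) -> float:
    """Fractional increase of ``value`` over ``baseline``: (v - b) / b."""
    if baseline == 0:
        raise ValueError("relative increase undefined for zero baseline")
    return (value - baseline) / baseline


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrichment(
    test_set: set[str] | Sequence[str],
    gene_sets: Mapping[str, set[str]],
    universe: set[str] | Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``test_set`` in each gene set.

    Every set is intersected with the universe before testing; the test set
    must be contained in the universe.  ``p`` is the exact upper tail
    P(X >= observed); ``q`` is Benjamini-Hochberg adjusted across all sets
    tested together.  ``expected`` is set_size * |test| / |universe| and
    ``ratio`` is observed / expected.
    """
    universe = set(universe)
    test = set(test_set)
    if not universe:
        raise ValueError("empty universe")
    if not test:
        raise ValueError("empty test set")
    if not test <= universe:
        raise ValueError("test set must be a subset of the universe")

    N, n = len(universe), len(test)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        K = len(members)
        obs = len(members & test)
        expected = K * n / N
        # P(X >= obs); sf(obs - 1) is exact for the discrete distribution
        p = float(sps.hypergeom.sf(obs - 1, N, K, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        ratio = obs / expected if expected > 0 else np.nan
        rows.append((name, K, obs, expected, ratio, p))
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "set_size", "observed", "expected", "ratio", "p", "q"]
        )
    df = pd.DataFrame(
        rows, columns=["set_name", "set_size", "observed", "expected", "ratio", "p"]
    )
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    The p-value sums hypergeometric point masses no larger than the observed
    table's mass.  The odds ratio is the sample OR a*d / (b*c); when a zero
    cell makes it degenerate, the Haldane-Anscombe 0.5 correction is applied
    and flagged.  The CI is the Woolf log-interval.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be nonnegative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("zero margin: Fisher's exact test undefined")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a_, b_, c_, d_ = (x + 0.5 for x in (a, b, c, d))
    else:
        a_, b_, c_, d_ = float(a), float(b), float(c), float(d)
    odds = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    lo, hi = np.exp(np.log(odds) - 1.959963984540054 * se), np.exp(
        np.log(odds) + 1.959963984540054 * se
    )
    return FisherResult(odds, (float(lo), float(hi)), float(p), corrected)


# ---------------------------------------------------------------------------
# set overlap
# ---------------------------------------------------------------------------

def jaccard_index(a: set, b: set) -> float:
    """|A n B| / |A u B|; zero for two empty sets."""
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def jaccard_overlap_network(
    gene_sets: Mapping[str, set[str]], min_jaccard: float = 0.0
) -> nx.Graph:
    """Weighted pathway-overlap graph: nodes are sets, edges carry Jaccard.

    Edges are kept when the Jaccard index is >= ``min_jaccard`` and positive.
    """
    if len(gene_sets) < 2:
        raise ValueError("need at least two gene sets")
    g = nx.Graph()
    names = list(gene_sets)
    g.add_nodes_from(names)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            j = jaccard_index(set(gene_sets[na]), set(gene_sets[nb]))
            if j > 0 and j >= min_jaccard:
                g.add_edge(na, nb, weight=j)
    return g


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _mw_z(u: float, x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected normal z for the Mann-Whitney U (no continuity corr.)."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return (u - n1 * n2 / 2.0) / np.sqrt(var)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U test: returns (U_x, p, effect_r).

    U is reported for the first sample.  For samples of at most 10 each the
    p-value is exact (full enumeration, ties permitting); otherwise the
    tie-corrected normal approximation without continuity correction is
    used, whose z also drives the rank-biserial style effect size
    r = |z| / sqrt(n_x + n_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    u = float(res.statistic)
    z = _mw_z(u, x, y)
    pooled_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if x.size <= 10 and y.size <= 10 and not pooled_ties:
        p = float(res.pvalue)  # scipy uses exact enumeration here
    else:
        p = float(2 * sps.norm.sf(abs(z)))
    p = min(p, 1.0)
    r = abs(z) / np.sqrt(x.size + y.size)
    return u, p, r


@dataclass
class KruskalDunnResult:
    H: float
    p: float
    eta_squared: float
    pairwise: pd.DataFrame = field(repr=False)


def kruskal_dunn(groups: Sequence[Sequence[float]]) -> KruskalDunnResult:
    """Kruskal-Wallis H with Dunn's pairwise post hoc (Bonferroni adjusted).

    ``eta_squared`` uses the (H - k + 1) / (n - k) convention.  Dunn z
    statistics are computed on pooled mean ranks with the usual tie
    correction of the pooled variance.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two members")
    H, p = sps.kruskal(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    eta2 = (H - k + 1) / (n - k)

    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    idx = np.cumsum([0] + [g.size for g in groups])
    mean_ranks = [ranks[idx[i] : idx[i + 1]].mean() for i in range(k)]
    n_pairs = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_corr)
                * (1.0 / groups[i].size + 1.0 / groups[j].size)
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_unadj = 2 * sps.norm.sf(abs(z))
            rows.append((i, j, z, p_unadj, min(1.0, p_unadj * n_pairs)))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p", "p_adj"])
    return KruskalDunnResult(float(H), float(p), float(eta2), table)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def permutation_pvalue(
    statistic_fn: Callable[[np.ndarray], float],
    labels: Sequence,
    n_perm: int = 10000,
    seed: int | None = None,
) -> float:
    """Empirical upper-tail p from random label permutations.

    ``statistic_fn`` receives a permuted copy of ``labels`` and must be a
    pure function of it.  The add-one estimator
    p = (1 + #{perm >= observed}) / (1 + n_perm) avoids zero p-values.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = statistic_fn(labels)
    count = 0
    for _ in range(n_perm):
        if statistic_fn(rng.permutation(labels)) >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)
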