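"""Multi-evidence hypergraph assembly, spectral communities and cohesion.

Hyperedges (gene sets of size >= 3) come from four evidence sources:
maximal cliques of the interaction network, thresholded co-expression
components, curated disease pathway sets, and broad pathway annotations.
The union is deduplicated by gene-set identity, an incidence structure is
built, and the normalized hypergraph Laplacian

    L = I - Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2}

drives spectral community detection.  Module cohesion multiplies the
normalized mean perturbation score, hub fraction and internal interaction
density of a hyperedge, so only modules strong on all three axes score
high.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.cluster import KMeans

from .topology import HubClassification

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperedge",
    "Hypergraph",
    "ModuleCohesion",
    "clique_hyperedges",
    "coexpression_hyperedges",
    "pathway_hyperedges",
    "assemble_hypergraph",
    "hypergraph_laplacian",
    "spectral_communities",
    "module_cohesion",
    "hypergraph_modularity",
    "multiway_statistics",
]

PROVENANCES = ("clique", "coexpression", "autism_pathway", "reactome_pathway")


@dataclass(frozen=True)
class Hyperedge:
    genes: tuple[str, ...]  # sorted, unique
    weight: float
    provenance: str

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes inside a hyperedge")
        if tuple(sorted(self.genes)) != self.genes:
            raise ValueError("hyperedge genes must be sorted")
        if self.weight <= 0:
            raise ValueError("hyperedge weight must be positive")


@dataclass
class Hypergraph:
    """Incidence structure over a fixed gene universe.

    ``H`` is the n x m binary incidence matrix (genes x hyperedges); ``Dv``
    holds weighted node degrees (sum of incident hyperedge weights), ``De``
    hyperedge cardinalities.
    """

    nodes: list[str]
    hyperedges: list[Hyperedge]
    H: sparse.csr_matrix
    node_index: dict[str, int]

    @property
    def edge_weights(self) -> np.ndarray:
        return np.array([e.weight for e in self.hyperedges])

    @property
    def Dv(self) -> np.ndarray:
        """Weighted node degrees: sum of incident hyperedge weights."""
        return np.asarray(self.H @ self.edge_weights).ravel()

    @property
    def De(self) -> np.ndarray:
        """Hyperedge cardinalities."""
        return np.asarray(self.H.sum(axis=0)).ravel()

    def propagation_operator(self) -> np.ndarray:
        """Theta = Dv^-1/2 H W De^-1 H^T Dv^-1/2 (dense); zero rows for
        nodes in no hyperedge."""
        dv = self.Dv
        with np.errstate(divide="ignore"):
            dvi = np.where(dv > 0, 1.0 / np.sqrt(dv), 0.0)
        de = self.De
        Hd = self.H.toarray().astype(float)
        W = np.diag(self.edge_weights)
        DeI = np.diag(1.0 / de)
        return (dvi[:, None] * Hd) @ W @ DeI @ (Hd.T * dvi[None, :])


@dataclass(frozen=True)
class ModuleCohesion:
    hyperedge_index: int
    size: int
    mean_perturbation: float
    normalized_mean_perturbation: float
    hub_fraction: float
    internal_density: float
    cohesion: float


# ---------------------------------------------------------------------------
# hyperedge sources
# ---------------------------------------------------------------------------

def clique_hyperedges(
    network: nx.Graph, min_size: int = 3, weight: float = 1.0
) -> list[Hyperedge]:
    """All maximal cliques of size >= min_size (Bron-Kerbosch), one each.

    Maximal cliques (not all triangles) are used so tightly coupled groups
    of any size form a single hyperedge.
    """
    out = []
    for clique in nx.find_cliques(network):
        if len(clique) >= min_size:
            out.append(Hyperedge(tuple(sorted(clique)), weight, "clique"))
    out.sort(key=lambda e: e.genes)
    return out


def coexpression_hyperedges(
    expression: pd.DataFrame,
    r_threshold: float = 0.7,
    min_size: int = 3,
    weight: float = 1.0,
) -> list[Hyperedge]:
    """Connected components of the thresholded Pearson-correlation graph.

    Genes with constant expression are excluded with a warning (their
    correlation is undefined).  Edges require r strictly above the
    threshold; components of at least ``min_size`` genes become hyperedges.
    """
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples per gene")
    x = expression.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant-expression genes excluded from "
            "co-expression hyperedges"
        )
    genes = expression.index.to_numpy()[~constant]
    x = x[~constant]
    if len(genes) < min_size:
        return []
    r = np.corrcoef(x)
    np.fill_diagonal(r, 0.0)
    g = nx.Graph()
    g.add_nodes_from(genes)
    ii, jj = np.nonzero(np.triu(r > r_threshold, k=1))
    g.add_edges_from(zip(genes[ii], genes[jj]))
    out = []
    for component in nx.connected_components(g):
        if len(component) >= min_size:
            out.append(Hyperedge(tuple(sorted(component)), weight, "coexpression"))
    out.sort(key=lambda e: e.genes)
    return out


def pathway_hyperedges(
    gene_sets: Mapping[str, set[str]],
    universe: set[str],
    provenance: str = "reactome_pathway",
    min_size: int = 3,
    weight: float = 1.0,
) -> list[Hyperedge]:
    """Pathway gene sets restricted to the analyzed universe, size >= 3."""
    out = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        if len(members) >= min_size:
            out.append(Hyperedge(tuple(sorted(members)), weight, provenance))
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_hypergraph(
    sources: Iterable[Sequence[Hyperedge]],
    nodes: Iterable[str],
    weights_by_provenance: Mapping[str, float] | None = None,
) -> Hypergraph:
    """Set-union of hyperedge sources over a fixed node universe.

    Exact duplicate gene sets are merged: the first provenance is retained
    and weights are summed.  Each hyperedge's weight is its own weight times
    the per-provenance multiplier (default 1.0).  Nodes in no hyperedge stay
    as isolated zero rows; a hyperedge naming an unknown gene is an error.
    """
    nodes = sorted(set(nodes))
    node_set = set(nodes)
    weights_by_provenance = dict(weights_by_provenance or {})
    merged: dict[tuple[str, ...], Hyperedge] = {}
    any_edge = False
    for source in sources:
        for e in source:
            any_edge = True
            unknown = set(e.genes) - node_set
            if unknown:
                raise ValueError(f"hyperedge references unknown genes: {sorted(unknown)}")
            w = e.weight * weights_by_provenance.get(e.provenance, 1.0)
            if e.genes in merged:
                prev = merged[e.genes]
                merged[e.genes] = Hyperedge(e.genes, prev.weight + w, prev.provenance)
            else:
                merged[e.genes] = Hyperedge(e.genes, w, e.provenance)
    if not any_edge:
        raise ValueError("no hyperedges in any source")
    hyperedges = [merged[k] for k in sorted(merged)]
    index = {v: i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for j, e in enumerate(hyperedges):
        for g in e.genes:
            rows.append(index[g])
            cols.append(j)
    H = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(nodes), len(hyperedges))
    )
    return Hypergraph(nodes, hyperedges, H, index)


# ---------------------------------------------------------------------------
# Laplacian and communities
# ---------------------------------------------------------------------------

def hypergraph_laplacian(hg: Hypergraph) -> np.ndarray:
    """Normalized hypergraph Laplacian L = I - Theta (dense, symmetric PSD).

    Nodes in no hyperedge have zero Theta rows, making their Laplacian rows
    identity rows (eigenvalue 1 directions).
    """
    theta = hg.propagation_operator()
    L = np.eye(len(hg.nodes)) - theta
    return (L + L.T) / 2.0  # enforce exact symmetry


def spectral_communities(
    hg: Hypergraph, k: int, seed: int = 0, n_init: int = 10
) -> pd.Series:
    """K-means on the k lowest-eigenvalue eigenvectors of the Laplacian."""
    n = len(hg.nodes)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError("k cannot exceed the node count")
    L = hypergraph_laplacian(hg)
    vals, vecs = np.linalg.eigh(L)
    emb = vecs[:, :k]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(emb)
    return pd.Series(labels, index=pd.Index(hg.nodes, name="gene"), name="community")


# ---------------------------------------------------------------------------
# cohesion and modularity
# ---------------------------------------------------------------------------

def module_cohesion(
    hg: Hypergraph,
    scores: pd.Series,
    hubs: HubClassification,
    ppi_network: nx.Graph,
) -> pd.DataFrame:
    """Composite cohesion per hyperedge.

    normalized mean perturbation (mean member score / global max score)
    x hub fraction x internal interaction density, clipped to [0, 1].
    """
    global_max = float(scores.max())
    hub_set = hubs.hubs
    rows = []
    for j, e in enumerate(hg.hyperedges):
        size = len(e.genes)
        if size < 2:
            raise ValueError("cohesion undefined for hyperedges of size < 2")
        missing = [g for g in e.genes if g not in scores.index or g not in ppi_network]
        if missing:
            raise ValueError(f"hyperedge members missing from scores/network: {missing}")
        mean_score = float(scores.loc[list(e.genes)].mean())
        norm_mean = mean_score / global_max if global_max > 0 else 0.0
        hub_fraction = sum(g in hub_set for g in e.genes) / size
        n_edges = sum(
            ppi_network.has_edge(a, b) for a, b in combinations(e.genes, 2)
        )
        density = n_edges / comb(size, 2)
        cohesion = float(np.clip(norm_mean * hub_fraction * density, 0.0, 1.0))
        rows.append(
            (j, size, mean_score, norm_mean, hub_fraction, density, cohesion)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "hyperedge_index", "size", "mean_perturbation",
            "normalized_mean_perturbation", "hub_fraction",
            "internal_density", "cohesion",
        ],
    )


def clique_expansion(hg: Hypergraph) -> nx.Graph:
    """Weighted pairwise expansion: each hyperedge adds w_e/(|e|-1) to every
    internal pair."""
    g = nx.Graph()
    g.add_nodes_from(hg.nodes)
    for e in hg.hyperedges:
        share = e.weight / (len(e.genes) - 1)
        for a, b in combinations(e.genes, 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += share
            else:
                g.add_edge(a, b, weight=share)
    return g


def hypergraph_modularity(
    hg: Hypergraph, assignment: pd.Series | Mapping[str, int], gamma: float = 1.0
) -> float:
    """Newman-Girvan modularity of the clique expansion at resolution gamma."""
    if isinstance(assignment, pd.Series):
        assignment = assignment.to_dict()
    if not assignment:
        raise ValueError("empty community assignment")
    expansion = clique_expansion(hg)
    communities: dict[int, set[str]] = {}
    for gene in expansion.nodes():
        if gene not in assignment:
            raise ValueError(f"gene {gene!r} missing from assignment")
        communities.setdefault(assignment[gene], set()).add(gene)
    return float(
        nx.community.modularity(
            expansion, communities.values(), weight="weight", resolution=gamma
        )
    )


# ---------------------------------------------------------------------------
# counting contract
# ---------------------------------------------------------------------------

def multiway_statistics(hg: Hypergraph, ppi_network: nx.Graph) -> dict:
    """Raw counts behind the multi-way-relationship statistic.

    ``multiway_relationships`` counts the pair slots induced by hyperedges
    that are not already pairwise interaction edges; the gain over the
    pairwise network is their ratio.
    """
    pair_slots = sum(comb(len(e.genes), 2) for e in hg.hyperedges)
    covered = set()
    for e in hg.hyperedges:
        covered.update(frozenset(p) for p in combinations(e.genes, 2))
    existing = {frozenset((a, b)) for a, b in ppi_network.edges()}
    overlap = len(covered & existing)
    n_pairwise = ppi_network.number_of_edges()
    multiway = pair_slots - overlap
    return {
        "n_hyperedges": len(hg.hyperedges),
        "pair_slots": int(pair_slots),
        "covered_pairs_in_ppi": int(overlap),
        "n_pairwise_edges": int(n_pairwise),
        "multiway_relationships": int(multiway),
        "relative_gain": multiway / n_pairwise if n_pairwise else float("nan"),
    }
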