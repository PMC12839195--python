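import networkx as nx
import numpy as np
import pytest

from asdnet import hypergraph as hgm
from asdnet import mldpp as mp
from asdnet import topology as topo
from asdnet.synthetic import (
    SyntheticConfig,
    generate_expression,
    generate_gene_table,
    generate_pathway_sets,
    generate_ppi_network,
)


def weighted_graph(edges):
    """Graph from (a, b, confidence) triples."""
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, confidence=w)
    return g


@pytest.fixture(scope="session")
def synth200():
    """Shared medium synthetic bundle (network, truth, annotations, hubs)."""
    cfg = SyntheticConfig(n_genes=200, n_pathways=25, seed=11)
    network, truth = generate_ppi_network(cfg)
    gene_table = generate_gene_table(network, truth, cfg)
    expression = generate_expression(truth, 50, cfg)
    gene_sets = generate_pathway_sets(truth, cfg)
    scores = topo.perturbation_scores(network)
    hubs = topo.classify_hubs(scores)
    return dict(
        config=cfg, network=network, truth=truth, gene_table=gene_table,
        expression=expression, gene_sets=gene_sets, scores=scores, hubs=hubs,
    )


@pytest.fixture(scope="session")
def synth200_mldpp(synth200):
    p0 = mp.initialize_perturbation(
        synth200["gene_table"], synth200["hubs"], synth200["network"]
    )
    traj = mp.run_mldpp(synth200["network"], p0)
    metrics = mp.mldpp_metrics(traj, synth200["scores"])
    return dict(p0=p0, trajectory=traj, metrics=metrics)


@pytest.fixture(scope="session")
def two_class_hypergraph():
    """Planted two-class hypergraph: hubs share hyperedges, non-hubs share
    hyperedges, plus a planted feature shift for the hub class."""
    rng = np.random.default_rng(7)
    genes = [f"G{i:03d}" for i in range(60)]
    labels = np.zeros(60, dtype=bool)
    labels[:15] = True
    edges = []
    seen = set()
    for _ in range(12):
        members = tuple(sorted(
            genes[i] for i in rng.choice(np.arange(15), size=4, replace=False)
        ))
        if members not in seen:
            seen.add(members)
            edges.append(hgm.Hyperedge(members, 1.0, "clique"))
    for _ in range(20):
        members = tuple(sorted(
            genes[i] for i in rng.choice(np.arange(15, 60), size=5, replace=False)
        ))
        if members not in seen:
            seen.add(members)
            edges.append(hgm.Hyperedge(members, 1.0, "reactome_pathway"))
    hg = hgm.assemble_hypergraph([edges], genes)
    X = rng.normal(size=(60, 7))
    X[labels] += 1.0
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return hg, X, labels
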