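# asdnet

Integrative network analysis of disease risk genes — built around the kind
of curated autism-gene cohort (SFARI-style categories) embedded in a
confidence-weighted protein–protein interaction network (STRING-style
scores). The package identifies hub genes, models how perturbations
propagate dynamically through the network, captures multi-gene relationships
with a hypergraph, learns contrastive gene embeddings, and ranks druggable
therapeutic targets. A synthetic-data generator reproduces the statistical
structure of those inputs, so the entire pipeline runs and is tested fully
offline.

## Who this is for

Computational biologists studying polygenic disorders who want to move past
static centrality rankings: the question is not only *which genes are well
connected* but *which genes amplify and sustain perturbations* once network
dynamics, interaction confidence, and higher-order (multi-gene) structure
are taken into account.

## The model

**Static hub score.** For gene *i* with degree *k<sub>i</sub>* in a network
of *n* genes and incident edge confidences *w<sub>ij</sub>* ∈ (0, 1]:

    s_i = k_i/(n−1) · mean_j(w_ij)

Genes with *s<sub>i</sub>* strictly above the 80th percentile
(linear-interpolation order statistics) are **hubs** — the top ~20%.

**Dynamic perturbation propagation (MLDPP).** With A = D^(−1/2) W D^(−1/2)
the symmetric degree-normalized confidence-weighted adjacency and p(0) a
stratified seed (1.0 for high-risk hubs, 0.8 hubs, 0.6 high-risk,
degree-scaled 0.1–0.5 otherwise):

    p(t+1) = tanh( α · A · p(t) + (1−α) · p(0) ),   α = 0.85

The tanh saturation keeps states in (−1, 1) so dense regions cannot
accumulate unbounded scores. Convergence requires jointly: mean squared
change < 10⁻⁶, maximum squared per-gene change < 10⁻⁵, and Spearman
correlation between consecutive states > 0.9999. Derived per-gene metrics:
final state, stability (SD over the last five iterations), propagation gain
(final − static score), and integrated risk (final × stability).

**Hypergraph layer.** Hyperedges (gene sets, size ≥ 3) from four evidence
sources — maximal PPI cliques (Bron–Kerbosch), co-expression components
(Pearson r > 0.7), curated disease pathways, and broad pathway sets — are
united into an incidence structure H with normalized Laplacian
L = I − Dv^(−1/2) H W De^(−1) Hᵀ Dv^(−1/2); spectral k-means on its low
eigenvectors yields communities, and each module's *cohesion* is the
product of its normalized mean perturbation score, hub fraction, and
internal interaction density.

**Embeddings.** A three-layer hypergraph convolution network (7→64→32→16,
batch norm, dropout 0.2) trained full-batch with Adam under a contrastive
margin loss (hub–hub pairs pulled below 0.5, hub/non-hub pairs pushed
beyond 1.5), then k-means clustering with quality metrics (silhouette,
Calinski–Harabasz, Davies–Bouldin) and a hub-independent validation
clustering on annotation-only features to rule out topological circularity.

**Prioritization.** priority = 0.2·hub + 0.3·MLDPP + 0.5·druggability,
ranked descending; genes never assessed for druggability are excluded
rather than scored zero.

## Worked example

```python
from asdnet.synthetic import SyntheticConfig, generate_ppi_network, generate_gene_table
from asdnet import topology as topo, mldpp as mp

cfg = SyntheticConfig(n_genes=300, seed=42)
network, truth = generate_ppi_network(cfg)
genes = generate_gene_table(network, truth, cfg)

scores = topo.perturbation_scores(network)
hubs = topo.classify_hubs(scores)
fit = topo.fit_power_law([d for _, d in network.degree()], discrete=True)
print(f"{network.number_of_nodes()} genes, {network.number_of_edges()} interactions")
print(f"hubs: {hubs.n_hubs} (threshold {hubs.threshold_value:.4f})")
print(f"degree-distribution exponent: {fit.alpha:.2f} (R^2 = {fit.r_squared:.2f})")

p0 = mp.initialize_perturbation(genes, hubs, network)
traj = mp.run_mldpp(network, p0)
metrics = mp.mldpp_metrics(traj, scores)
hub_mask = hubs.is_hub.reindex(metrics.final.index)
print(f"converged at iteration {traj.converged_at}")
print(f"mean final state: hubs {metrics.final[hub_mask].mean():.3f}, "
      f"non-hubs {metrics.final[~hub_mask].mean():.3f}")
```

prints

```
300 genes, 852 interactions
hubs: 60 (threshold 0.0215)
degree-distribution exponent: 1.59 (R^2 = 0.83)
converged at iteration 20
mean final state: hubs 0.481, non-hubs 0.165
```

Exactly 20% of genes are classified hubs; the fitted degree exponent
recovers the generator's scale-free target (1.52); and after propagation
hub genes settle at roughly three times the perturbation level of
peripheral genes — connectivity plus interaction confidence translates into
sustained dynamic amplification.

The same stages are available from a shell:

```bash
asdnet simulate --n-genes 300 --seed 42 --out data/
asdnet build-network --edges data/edges.tsv --threshold 0.7 --out graph.json
asdnet topology --graph graph.json --out centralities.tsv --hubs hubs.tsv
asdnet mldpp --graph graph.json --genes data/genes.tsv --out mldpp.tsv
asdnet run --preset desk --seed 1 --out run/        # full pipeline
```

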