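# Methods

This note documents the models, the synthetic data the package is validated
on, the numerical conventions, and the design choices made where the
underlying methodology left genuine freedom. Package surface:
`synthetic`, `network_io`, `topology`, `mldpp`, `hypergraph`, `embed`,
`stats`, `prioritize`, `pipeline` (plus a thin `cli`).

## Network construction

Edge tables follow the STRING convention (two symbols + combined score).
Score dialect is auto-detected: any score above 1 implies the 0–1000
integer scale and is divided by 1000. Filtering keeps edges with confidence
*strictly above* the threshold (default 0.7); symmetric duplicates collapse
to the maximum confidence and self-loops are dropped with a logged count.
Gene identity is the case-sensitive symbol string; identifier aliasing is
assumed resolved upstream.

## Static topology and hub classification

The hub statistic is the product of degree centrality and the mean
confidence of incident edges. The methodology's description mentions an
additional division by the maximum score; the plain product is the default
here because the group means it implies are internally consistent (a hub
degree centrality of 0.104 at mean confidence ≈0.885 reproduces the hub
score mean of 0.092, which max-normalization would not), and a
`max_normalize` flag provides the alternative. Hubs are scores strictly
above the linear-interpolation 80th percentile; for n distinct scores this
gives n − 1 − floor(0.8(n−1)) hubs — exactly 179 of 893. An all-equal score
vector is degenerate and classifies zero hubs with a warning.

Betweenness is reported raw (unordered-pair counts): the reported hub
magnitudes (means near 68) are only consistent with unnormalized values.
Closeness is the classic inverse-mean-distance form on connected graphs and
the normalized harmonic variant on disconnected ones (flagged in the output
attrs). Eigenvector centrality is the per-component Perron vector at unit
Euclidean norm. Effect sizes for rank tests use r = |Z|/√N; the alternative
Z/N convention that appears in one table caption is not a recognized effect
size and is not used.

### Power-law fitting

The continuous maximum-likelihood estimator α = 1 + n / Σ ln(x_i/xmin) is
used, with xmin defaulting to the smallest positive degree (or given
explicitly, which also bypasses the ≥50-sample requirement for toy inputs).
For integer degree data the standard half-shift correction
(xmin − ½ inside the logarithm) is available via `discrete=True` and is
what the synthetic recovery analyses use: on bounded discrete power-law
samples the uncorrected continuous estimator is badly biased upward, while
the corrected one recovers the generating exponent (1.52 ± 0.15 at
n = 2000). Goodness of fit is reported as R² of a log–log least-squares
line through the empirical pmf and as a chi-squared tail probability with
adjacent bins merged to expected counts ≥ 5.

### Robustness validations

Edge-removal robustness removes a fraction of edges uniformly at random
(100 iterations per fraction by default), re-runs scoring and
classification on the perturbed network, and reports the percentage of
original hubs — restricted to genes still in the largest component — that
keep hub status. Fraction 0 is an exact-100% control. Five-fold stability
retains 80% of edges per fold and reports the percentage of all genes
keeping their hub/non-hub status versus the full network.

## Dynamic perturbation propagation

The update p(t+1) = tanh(α·A_sym·p(t) + (1−α)·p(0)) is a reconstruction:
the stated ingredients are damping against the initial state, symmetric
degree normalization of confidence weights, and tanh saturation, and this
is the minimal map with all three. It is a contraction (rate ≈ α times the
mean tanh slope, empirically ≈0.78 per iteration on scale-free graphs), so
a fixed point exists and every run converges.

**Convergence semantics.** The three convergence constants (10⁻⁶, 10⁻⁵,
0.9999) are applied to *squared* per-gene changes: mean squared change
< 10⁻⁶, maximum squared change < 10⁻⁵, plus Spearman rank stability
> 0.9999. Applied literally to the L2 norm of the change vector, a 10⁻⁶
threshold would require ≈65 iterations at the measured contraction rate —
incompatible with the documented behaviour of convergence in ≈17–25
iterations within a 50-iteration cap. The squared-change reading is the
one under which the constants and the reported iteration counts coexist;
with it, a 1000-gene scale-free network converges at ≈20 iterations from
random initializations. Runs always execute at least `stability_window`
iterations so stability metrics are defined; metrics are reported at
min(convergence iteration, horizon = 25).

Propagation gain is final state minus the *static* hub score. The group
arithmetic only closes under this baseline (hub gain ≈ hub final 0.4394 −
static 0.092), whereas seed-based gain would be negative for hubs; the seed
baseline remains available behind `gain_baseline="seed"`.

Comparator propagators use common literature defaults: random walk with
restart r = 0.15 on the column-normalized weight matrix; heat diffusion
exp(−tL)p(0) with t = 1 via eigendecomposition of the combinatorial
Laplacian; and the linear damped update without tanh for standard network
propagation. Steiger's (1980) Z compares dependent correlations sharing one
variable. The damping sweep (0.50–0.95 in 0.05 steps) reruns the full
propagation per α and reports Spearman correlation and top-10 overlap
against the α = 0.85 reference.

## Hypergraph

"Triangle cliques" are implemented as *maximal* cliques of size ≥ 3:
observed hyperedge sizes extend far beyond 3, which rules out pure
triangles. Co-expression hyperedges are connected components of the graph
with edges at Pearson r > 0.7 — the weakest deterministic grouping rule
consistent with "genes exceeding the threshold were grouped"; genes with
constant expression are excluded with a warning. Pathway sets are
restricted to the analyzed universe and to size ≥ 3. Union assembly merges
exact duplicate gene sets, keeping the first provenance and summing
weights; per-provenance weight multipliers default to 1.0 (no stated
values exist) and are configurable.

The normalized Laplacian L = I − Dv^(−1/2) H W De^(−1) Hᵀ Dv^(−1/2) is
symmetric PSD with null eigenvalue(s) on covered components; nodes in no
hyperedge become identity rows. Communities come from k-means (seeded,
multiple restarts) on the k lowest eigenvectors. Modularity is
Newman–Girvan at resolution γ on the clique expansion in which a hyperedge
of size s contributes w/(s−1) to each internal pair. Cohesion normalizes
the module's mean perturbation score by the global maximum score before
multiplying by hub fraction and internal density — the only factor scaling
under which top-module cohesion magnitudes near 0.9 are reachable, since
the raw product of the three stated factors is bounded well below the
reported maximum; this normalization is a reconstruction and is documented
as such.

## Embeddings

Input variants: `topology7` (degree centrality, raw betweenness, closeness,
clustering coefficient, static score, propagated final state, stability);
`hub_independent5` (evidence-category score, gene length, constraint,
brain expression, pathway count — no network-derived feature);
`hub_independent3` (clustering coefficient, curated-membership indicator,
log degree). All are z-scored; constant columns are centered only and
flagged.

The convolution operator is the same Θ as the Laplacian complement. Hidden
layers use batch normalization → rectifier → dropout (0.2, training only);
the final 16-dimensional layer is linear (identity) so the metric structure
the contrastive loss shapes is preserved. Batch-norm running moments are
seeded from the first full-batch statistics and then tracked with momentum
0.9, keeping evaluation mode meaningful from the first epoch. The final
layer's batch-norm scale initializes at 0.1 so that the initial embedding
cloud is compact relative to the margins (0.5 / 1.5); training then *grows*
the hub/non-hub separation rather than shrinking a scattered cloud, which
is the documented qualitative behaviour.

The loss is the mean squared hinge over all hub–hub pairs
(max(0, d−0.5)²) plus all hub/non-hub pairs (max(0, 1.5−d)²), with full
pair enumeration (≤ ~10⁵ pairs at cohort scale). Zero-distance cross pairs
take a zero subgradient. Training is full-batch Adam (β₁ = 0.9,
β₂ = 0.999, ε = 10⁻⁸, lr 0.001 decayed ×0.95 every 10 epochs, weight decay
10⁻⁵ on transforms), with a stratified 10% validation gene set, early
stopping at patience 15, and restoration of the best-validation snapshot.
Backpropagation through the convolution, batch norm and loss is
hand-written and verified against central finite differences to 10⁻⁵
relative error (with a 10⁻⁹ absolute floor for finite-difference roundoff
on near-zero entries).

The hub-independent validation clustering runs k-means directly on the raw
standardized `hub_independent5` features (the annotation-only route);
clustering validation embeddings instead is available by training on that
variant. Cluster agreement around a focus set reports the Jaccard index of
the two plurality focus clusters, a label-permutation p-value
(add-one estimator), the adjusted Rand index of the full assignments, and
Fisher's exact test for focus concentration.

## Statistics

Hypergeometric enrichment uses the exact upper tail P(X ≥ obs) with
Benjamini–Hochberg control across all sets tested together; the expected
count uses the analyzed-gene universe by default (an external background is
just a different universe argument). Fisher's exact test is two-sided by
point-mass summation; odds ratios are sample ORs with the Haldane 0.5
correction only when a zero cell exists (flagged), and Woolf log-interval
CIs. Mann–Whitney uses exact enumeration for samples ≤ 10 without ties and
otherwise a tie-corrected normal approximation *without* continuity
correction, which makes the two-group Kruskal–Wallis p agree with it to
numerical precision. Dunn's post hoc z-tests use pooled mean ranks with tie
correction and Bonferroni adjustment; η² = (H − k + 1)/(n − k).

## Prioritization

priority = 0.2·hub + 0.3·propagated score + 0.5·druggability (weights
configurable, must sum to 1). Genes with missing druggability are excluded
with a logged count — scoring them zero would silently demote genes that
were never assessed. The top-n versus rest comparison is an unpaired
two-sample rank test: the comparison is between disjoint gene groups, so a
paired signed-rank procedure is not applicable.

## Synthetic data: what it emulates, and what it does not

The generator emulates (i) a scale-free confidence-weighted network —
degrees drawn from a bounded discrete power law (exponent = target, upper
cutoff solved so the mean degree matches, default 8) realized by a
configuration model, with confidences uniform on (0.7, 1.0]; (ii) planted
hub cores (top decile of drawn degrees) whose annotation features
(constraint, brain expression, pathway count) are shifted by +1.5 SD;
(iii) stratified evidence categories with two shipped presets for the
high/medium/low/unknown breakdown (the emulated source reports two
incompatible ones; the four-level 139/478/201/75 breakdown is the default);
(iv) co-expression modules sharing a latent factor with noise SD 0.4,
giving population within-module r = 1/(1+σ²) ≈ 0.86 so the r > 0.7
criterion holds with high probability at 50+ samples; and (v) pathway sets
of size 3–30, a configurable fraction sampled with elevated odds for hub
genes as enrichment positive controls.

A degree-sequence construction is used instead of preferential attachment
because growth models cannot produce tail exponents below 2, and the
fitted exponents this emulates sit near 1.5; sampling the degree sequence
directly makes the exponent an honest, recoverable parameter. Node count is
a single free parameter (no modeling of the 2-node bookkeeping discrepancy
in the emulated source).

Not emulated: real gene symbols, true interactome subgraph structure,
developmental-stage structure in expression, or correlated annotation
noise. Passing tests therefore demonstrate algorithmic correctness and
recovery of *planted* structure under the stated statistical assumptions —
not biological validity on real cohorts, and dataset-level published
magnitudes that depend on the real databases (e.g. exact silhouette or
cluster sizes) are out of reach by construction.

At the default odds multiplier (5) the per-set enrichment signal is weak
for small sets (sizes 3–5 cannot reach q < 0.05 at any plausible effect);
the positive-control tests therefore use a strong-odds setting (25), at
which ≥ 80% of sets are significant, and treat odds 5 as a directional
control.

## Problem sizes and determinism

Default validation scales: 893–2000 genes for network-level contracts,
100-run convergence censuses, 100-iteration robustness sweeps, and
100-epoch embedding training — each chosen as the smallest scale at which
the corresponding statistical contract is comfortably testable. Every
stochastic component takes an explicit seed; the pipeline derives per-stage
seeds from one global seed by fixed offsets, and identical configuration
plus seed reproduces every artifact bit-for-bit.

## Known limitations

- The propagation update and the cohesion normalization are
  reconstructions of procedures whose exact equations were not available;
  both are isolated behind single functions and documented above.
- The convergence tolerances are interpreted on squared changes (see
  above); the literal reading is mathematically incompatible with the
  documented iteration counts for any damped fixed-point map of this form.
- Hypergraph spectral communities are sensitive to uncovered (isolated)
  nodes, which carry no hypergraph information and cluster arbitrarily.
- t-SNE coordinates are visualization-only; nothing downstream consumes
  them.
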