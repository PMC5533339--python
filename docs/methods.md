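# Methods

## Problem and model

Given an undirected simple PPI graph G(V, E), a catalog of protein
complexes, an orthology-presence table over s reference organisms and a
subcellular-localization table, the package predicts which proteins are
essential. Prediction is supervised and cross-network: a random forest is
trained on the pooled, labelled feature rows of several networks and applied
to a held-out network (leave-one-network-out), which mimics the realistic
setting where essentiality annotation exists for some interaction datasets
and a new dataset is to be prioritized.

The per-protein features are Den1, Den2, BC, IDC, LC, DOS and SLS (see the
README table). The forest's class-1 probability — the fraction-of-trees
vote — is the essentiality score; proteins are ranked by descending score
with ties broken by protein ID ascending, so every ranking is a
deterministic permutation of the node set.

## Feature definitions and conventions

Several of the underlying formulas leave edge cases open; the package fixes
them as follows.

* **Betweenness** is unnormalized, counts each unordered pair {s, t} once,
  excludes the endpoints, and assigns zero to disconnected pairs. Counting
  ordered pairs would double every value and leave all rankings unchanged.
  Graphs with ≥ 300 nodes are routed through igraph's exact Brandes
  implementation, smaller ones through networkx; the two agree to 1e-8 on
  random graphs (asserted in the tests) and both are compared against an
  exhaustive shortest-path enumeration oracle on graphs of ≤ 8 nodes.
* **Eigenvector centrality** is the principal adjacency eigenvector with
  non-negative entries and unit Euclidean norm, computed by power iteration
  on A + I (the shift is needed because bipartite components have a
  symmetric spectrum and plain iteration oscillates), tolerance 1e-10,
  at most 10,000 iterations. In a disconnected graph only the component
  with the largest adjacency eigenvalue carries mass; other nodes score 0;
  exact ties go to the component containing the smallest node ID.
* **Subgraph centrality** is the diagonal of exp(A): dense `expm` up to
  2000 nodes, symmetric eigendecomposition beyond. Both evaluate the
  closed-walk series exactly; the truncated series Σ_{k≤30} μ_k(v)/k! is
  kept as an independent oracle in the tests.
* **NC** terms with denominator min(deg(v)−1, deg(u)−1) = 0 contribute 0:
  a pendant edge can support no triangle, matching the degenerate case of
  the edge-clustering-coefficient literature.
* **Laplacian centrality** uses the exact degree-based closed form
  E_L(G) = Σ deg² + 2|E| with per-vertex drop deg(v)² + deg(v) +
  2·Σ_{u∈N(v)} deg(u); the spectral definition (eigenvalues of X − W) is
  O(n⁴) per graph and numerically noisier, so it serves as the test oracle
  only (agreement to 1e-9 on 200 random graphs).
* **Den1/Den2** return 0 when the induced node set has ≤ 1 node. Den2's
  node set is N(v) ∪ {v} plus the nodes at distance exactly 2 from v;
  when that ring is empty, Den2 = Den1 by construction.
* **IDC** induces each complex's subgraph from the network's edges —
  complex files carry membership only — and sums v's within-complex degree
  over all complexes containing v.
* **LBCC** uses natural logarithms with an additive epsilon (default 1e-10)
  inside each log. The ordering is invariant to the base (a base change
  rescales all four terms by one positive constant — property-tested), and
  the epsilon keeps zero-evidence proteins finite and at the bottom rather
  than silently dropping their terms.
* **SLC/SLS**: the reference set is the top ceil(0.05·|V|) of the network's
  own LBCC ranking, ties broken by protein ID. SLC is computed per network,
  including a held-out network, because it is a dataset-level enrichment
  statistic, not a label-derived one; it never looks at essentiality
  annotations, so no label leakage occurs. The fractions a_l/a are taken
  over the localization table's full protein universe, which may exceed the
  network.
* **DOS** defaults to scale a = 0.1, the best-performing value in the range
  [0.1, 1]; values outside the range warn but are accepted.

## Forest and protocol

1000 trees (configurable), features-per-split = √7 rounded (the library's
`sqrt` rule), other hyperparameters at scikit-learn defaults, fixed
`random_state`. No feature scaling is applied: forests are invariant to
monotone per-feature rescaling and fewer knobs mean fewer silent
differences between runs. Training rows are one per (protein, network)
pair; a protein present in three training networks contributes three rows,
each carrying its own network context. Single-class training data is an
error. Models persist as a joblib blob plus a JSON sidecar (format version,
column order, seed, training identifiers).

## Evaluation battery

Top-k true-positive counts and precision; the six confusion statistics
(SN, SP, PPV, NPV, F, ACC) with the top ceil(0.20·|V|) of the ranking
called positive (ceil chosen and logged; degenerate denominators yield 0
with an explicit flag instead of NaN); precision–recall and jackknife
curves with one point per rank; percentage overlap of top-k lists; and
stratified, seeded 10-fold cross-validated AUC. AUC uses the midrank tie
convention and equals the exhaustive Mann–Whitney pair statistic
(oracle-tested on small instances).

## Synthetic data

The generator emulates the regularities the method exploits, not yeast
biology itself:

* **Topology**: Barabási–Albert preferential attachment, m = 4 edges per
  new node (mean degree ≈ 8, in the range of the curated yeast networks);
  chosen over Erdős–Rényi so degree-linked features have realistic spread.
* **Labels**: a fraction p_e = 0.23 of proteins (the essential prevalence
  of the large yeast datasets) drawn without replacement with weight
  deg^β, β = 1 by default.
* **Complexes**: 200 neighbourhood-seeded member sets of 3–10 proteins,
  seeds and members oversampling essentials at odds ρ_c = 3.
* **Localization**: 11 locations, 3 of them enriched; every protein gets
  1–3 locations, essentials drawn toward enriched locations at odds
  ρ_l = 3.
* **Orthology**: 99 reference organisms; per-organism presence is
  Bernoulli(0.8) for essentials and Bernoulli(0.3) otherwise.
* **Families** share a protein universe (each network carries a random
  95%), one essential set (drawn once from the first network's degrees)
  and one attachment-order permutation, so hub identity — and with it the
  degree-derived features — correlates across networks while edges and
  annotations carry independent noise.

Everything is driven by `numpy.random.default_rng` with seeds derived from
the spec seed; identical seeds give byte-identical output files.

What passing on this generator shows: the full chain (parsing, features,
cross-network training, ranking, evaluation) recovers a planted multivariate
signal far above prevalence, and collapses to chance when labels are
permuted or the planting is switched off. What it does not show: performance
on real PPI data, where interaction noise is correlated with study bias,
annotations are incomplete in structured ways, and the feature–essentiality
correlations are far weaker than the planted ones — the near-perfect
precisions on synthetic families should not be read as biological accuracy.

## Problem sizes

The default study uses 20 replicate families of four 2000-protein networks
for the planted-signal experiment and 200 random ≤ 8-node graphs for the
oracle comparisons; these sizes give stable means (replicate SD is reported
next to the mean) while keeping a full run in minutes on one CPU.

## Known limitations

* Absolute forest probabilities depend on the library's tree construction;
  only the protocol and the ranking contract are portable, not bit-level
  scores across scikit-learn versions.
* Betweenness is exact, not approximated; very large networks (≫ 10⁵
  nodes) would need an approximation scheme that is out of scope.
* The SLC-on-test-network choice follows the dataset-statistic reading; a
  caller wanting strict train-only localization statistics can compute the
  SLC table on training networks with `slc_table` and pass it to
  `build_features(..., slc=...)`.
* Weighted or directed interaction data are not supported; confidence
  columns in edge lists are ignored.
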