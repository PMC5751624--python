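# Methods

## Model

Disease similarity is computed on an integrated network: a weighted,
undirected gene functional network (GFN) plus one boundary node per
disease, connected with weight 1.0 to the disease's annotated genes.
Diseases are never linked directly; all disease–disease signal travels
through genes.

**Channel model.** For a disease *d* acting as both source and sink, all
other boundary nodes are removed (a boundary node that is neither source
nor sink carries no flow). Let deg(i) be gene *i*'s total incident weight
*including* its edge to *d*, and μ the damping factor. With

- P, the gene×gene matrix P_ij = μ·w_ij/deg(i),
- p0, the emission row p0_j = μ·w_dj/deg(d),
- q, the absorption column q_i = μ·w_id/deg(i),

the emitting visits solve f = p0 + f·P and the absorbing probabilities
solve a = P·a + q; the per-gene weight is w_i = f_i·a_i, the expected
visits along walks that complete at the sink. Both systems are one sparse
LU factorisation of (I − P); for μ < 1 the rows of P are substochastic, so
the system is nonsingular. Residuals are checked against 1e−12 (scaled).
No global normalisation is applied: the downstream cosine is invariant to
any positive rescaling of the weight vectors, so a normalisation
convention would be unobservable.

**Semantic factor.** The ontology is a rooted `IS_A` DAG. Annotations are
propagated bottom-up (true-path rule) before any gene-set size is used;
without propagation a disease's gene set need not be contained in its
ancestors' sets and the factor |G1||G2|/|G_MICA|² could exceed 1. IC(t) =
−ln(|G_t|/|G_root|) (natural log; the Lin ratio is base-invariant). The
MICA is found by minimising propagated-set size over common ancestors —
exactly equivalent to maximising IC, but free of floating-point ties —
with exact ties broken to the lexicographically smallest term id. A pair
involving a disease with an empty propagated set or an all-zero flow
vector scores 0 with a validity flag; self-similarity of a valid disease
is exactly 1.

**ncRNA similarity and RWR.** sim(r1, r2) is the best-match-average of
disease similarity over the two ncRNAs' disease sets. Pooled off-diagonal
upper-triangle scores are standardised with the population standard
deviation (z of the pooled scores then has mean 0, sd 1 by construction);
one-sided p-values are upper-tail standard-normal. The random walk with
restart runs on the full weighted similarity matrix with self-loops
removed; columns are normalised to sum 1, and all-zero columns (fully
isolated ncRNAs) are replaced by the uniform column so the matrix stays
stochastic. Convergence is the L1 difference of successive probability
vectors below 1e−10 (L1 is the natural metric for probability vectors;
mass is conserved to 1e−9 whenever the matrix is column-stochastic).

**Evaluation.** Leave-one-out cross-validation: every disease with ≥ 2
known ncRNAs contributes one trial per association; the held-out ncRNA is
scored against all ncRNAs not associated with the disease (the standard
negative-set convention), trials are pooled, and AUC is the Mann–Whitney
estimator with ties counted one half. The similarity network is built
once from the full association table, as is conventional for this
protocol. The benchmark protocol scores curated positive pairs against a
random pair set `multiplier` times as large, drawn uniformly without
replacement from annotated-disease pairs and disjoint from the benchmark;
iterations use independent child streams of the master seed so each is
individually reproducible. The drug analysis takes all unordered disease
pairs present in both tables, x = similarity, y = Jaccard overlap of drug
sets, and reports Pearson r, r², and the two-sided p.

## Parameters

| parameter | default | meaning |
|---|---|---|
| damping μ | 0.85 | per-step survival of the channel walker; 1−μ dissipates |
| disease–gene edge weight | 1.0 | boundary attachment; GFN weights used as-is (`use_gfn_weights`) |
| restart γ | 0.85 | RWR restart probability; never pinned by the protocol, so it is required configuration and the test suite sweeps 0.1–0.9 |
| RWR tol | 1e−10 | L1 convergence threshold |
| solve residual | 1e−12 | channel linear-solve accuracy |

## Synthetic worlds

`generate_world` builds a self-contained corpus: default 2 clusters, 10
diseases, 40 genes, 12 ncRNAs, 16 drugs, cross-cluster rate (noise) 0.05,
seed 42. The GFN is a stochastic block model (intra-cluster edge
probability 0.3, inter-cluster probability = noise, weights uniform on
[0.5, 2.0], a HumanNet-like log-likelihood scale). Diseases annotate 6
genes drawn from their cluster's pool, each annotation flipped to a
foreign cluster with probability = noise; ncRNAs associate with 3 diseases
and drug sets hold 4 drugs, both mostly within-cluster under the same
noise rule. These sizes keep every protocol (including the 10×-random
benchmark sampling) feasible on the world while exercising all code
paths; all generation is a pure function of (parameters, seed).

The ontology has four levels: root → cluster terms → sibling-group terms
→ diseases. Diseases come in sibling pairs sharing a 4-gene core (of 6),
and the benchmark set is exactly those sibling pairs. This mirrors what a
curated benchmark of similar diseases is: pairs that are *specifically*
similar, not merely members of the same broad category. It is also what
makes the benchmark protocol meaningful at this scale — if every
same-cluster pair were a positive, a random pair set ten times the size
of the benchmark could not be drawn from the remaining pairs, and the
leftover same-cluster pairs would contaminate the negatives badly enough
to cap the expected AUC near 0.78 regardless of the measure's quality.

What the generator does not emulate: realistic degree distributions,
deep or imbalanced ontology shapes, annotation biases, or literature-scale
sparsity. Passing tests demonstrate that the implementation recovers
planted structure under its stated model, not that the measure attains any
particular performance on real corpora.

**Monte-Carlo oracle.** The walk simulator estimates the channel weights
independently of the linear algebra: dissipation is applied before every
move (including the first), matching the analytic contract where μ
multiplies every transition, and each walk contributes (visit counts ×
completion indicator), whose expectation is f_i·a_i by the Markov
decomposition of the two solves. Agreement is asserted within 3 standard
errors per gene at 10⁵ walks on every fixture with ≤ 10 genes.

## Numerical and design choices

- Degree normalisation includes the disease edge in deg(i), so genes
  adjacent to the disease can absorb; the sink is reached through the same
  edges used for emission (source = sink).
- Duplicate/reciprocal GFN edges are merged keeping the maximum weight;
  self-loops and non-positive weights are rejected.
- The similarity matrix is stored dense; at the entity counts this package
  targets (≤ a few thousand) dense is simpler and faster than triplet
  storage.
- The RWR adjacency keeps the full weighted similarity network (no p-value
  cutoff): no threshold is part of the model, and the z-score/p-value
  layer exists for users who want to sparsify explicitly.
- Degenerate inputs fail loudly: all-equal ncRNA scores (undefined
  z-scores), empty seed sets, diseases with no associations, empty score
  lists, zero-variance correlation inputs, and insufficient sampling
  universes all raise with specific messages.
- In the null-scorer control, noise scores are redrawn every iteration;
  with a single fixed draw the mean AUC across iterations would inherit
  the bias of one 70-score sample (sd ≈ 0.035) instead of concentrating
  at 1/2.

## Limitations

- The channel model is specified for undirected, positively weighted
  networks only; directed or signed GFNs are out of scope.
- The walk runs only on the ncRNA similarity network, not on a joint
  heterogeneous disease+ncRNA graph.
- Cross-ontology term mapping (aligning external annotation vocabularies
  to the disease ontology) is assumed done upstream.
- LOOCV builds the similarity network once from all associations; the
  held-out association therefore still influences the network itself,
  which slightly flatters absolute AUCs. This matches the protocol's
  standard form, and the synthetic-world AUCs should be read with that in
  mind.
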