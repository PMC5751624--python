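# infdissim

Information-flow disease similarity on an integrated disease–gene network,
with downstream prioritisation of disease-related lncRNAs and miRNAs.

## The problem

Measuring how similar two diseases are underpins drug repositioning and the
prediction of disease-associated non-coding RNAs. Purely ontology-based
measures (Resnik, Lin, Wang) use only the disease ontology's `IS_A`
hierarchy and ignore how disease genes interact; this package scores
disease pairs by how much *information flow* they share in a weighted gene
functional network (GFN), corrected by a semantic factor from the disease
ontology.

## The measure

Each disease *t* is attached (weight 1) to its annotated genes inside the
GFN and treated as both source and sink of a damped random walk (channel
model, damping μ = 0.85): the walker survives each step with probability μ
and moves to a neighbour proportionally to edge weight. For each gene *i*
the flow weight is

    w_{t,i} = f_i · a_i

where *f<sub>i</sub>* is the expected number of visits to *i* by walks
emitted from *t* and *a<sub>i</sub>* is the probability that a walk from
*i* completes at *t*; both come from a pair of sparse linear solves. The
flow similarity of two diseases is the cosine of their weight vectors,

    Inf(t1, t2) = WV_t1 · WV_t2 / (‖WV_t1‖ ‖WV_t2‖),

and the final score multiplies in a semantic factor built from propagated
gene-set sizes, with *G<sub>MICA</sub>* the gene set of the most
informative common ancestor:

    InfDisSim(t1, t2) = Inf(t1, t2) · |G1| |G2| / |G_MICA|²

Annotation propagation (true-path rule) guarantees G1, G2 ⊆ G_MICA, so the
factor — and the score — stays in [0, 1]. Lin similarity
2·IC(MICA)/(IC(t1)+IC(t2)) is also provided.

Downstream, each lncRNA/miRNA is represented by its associated disease
set; ncRNA similarity is the best-match average of InfDisSim over those
sets, and candidates for a disease are ranked by random walk with restart
(P<sub>t+1</sub> = γP₀ + (1−γ)AP<sub>t</sub>, γ = 0.85, convergence
1e−10) seeded at the disease's known ncRNAs. Evaluation utilities cover
benchmark-vs-random ROC/AUC, leave-one-out cross-validation, and the
correlation of disease similarity with therapeutic drug-set overlap.

## Worked example

Everything runs on generated planted-cluster worlds; no downloads are
needed. `examples/` holds one short script per capability:

```bash
python examples/01_disease_similarity.py
```

```
sibling pair       DOID:3000 ~ DOID:3001: InfDisSim = 0.4676
same-cluster pair  DOID:3000 ~ DOID:3002: InfDisSim = 0.0935
cross-cluster pair DOID:3000 ~ DOID:3005: InfDisSim = 0.0056
```

Planted sibling diseases (high gene overlap, specific common ancestor)
score far above ordinary same-cluster pairs, which in turn dominate
cross-cluster pairs — the separation the measure is built to deliver.

```bash
python examples/02_ncrna_prioritization.py
```

```
disease DOID:3001: seeds = lnc000, lnc001, lnc010
  lnc004  score 0.0194  (same cluster)
  lnc002  score 0.0191  (same cluster)
  ...
leave-one-out AUC over 34 held-out associations: 0.9297
```

Candidates from the disease's own cluster fill the top ranks, and held-out
associations are recovered with AUC ≈ 0.93. `03_benchmark_and_drugs.py`
runs the benchmark protocol (mean AUC 1.0 over 10 iterations on the
planted benchmark) and the drug correlation (r = 0.67, p = 6e−07);
`04_channel_oracle.py` cross-checks the flow solver against direct walk
simulation.

A thin CLI wraps the same functions (`infdissim simulate|flow|sim|predict|
loocv|benchmark`); run `infdissim --help`.

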