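"""Self-contained synthetic worlds with planted cluster structure.

A world emulates the real corpora the pipeline consumes: a small disease
ontology DAG, a modular weighted gene functional network (stochastic block
model), disease-gene annotations concentrated in the network modules,
ncRNA-disease associations with planted disease clusters, and drug sets
mirroring cluster membership.

The ontology has four levels: root -> cluster terms -> sibling-group terms
-> disease terms.  Diseases come in sibling pairs that share most of their
genes; those strongly similar pairs play the role of a curated benchmark
of similar diseases, while ordinary same-cluster pairs are related but
weaker and cross-cluster pairs are near-independent (cross-cluster edge
and association rates are controlled by ``noise``).

The module also provides a Monte-Carlo random-walk oracle that estimates
the channel-model weight vector by direct simulation, independent of the
linear-algebra solver.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .evaluation import BenchmarkSet, DrugAssociationTable
from .flow_network import GeneFunctionalNetwork, IntegratedNetwork
from .ncrna_prediction import AssociationTable
from .ontology import Ontology, Term

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticWorld",
    "OracleEstimate",
    "generate_world",
    "monte_carlo_channel_oracle",
    "write_world",
    "write_obo",
]

ROOT_ID = "DOID:1"


@dataclass
class SyntheticWorld:
    """A generated toy corpus with planted cluster truth."""

    ontology: Ontology
    gfn: GeneFunctionalNetwork
    disease_gene: dict[str, frozenset[str]]
    ncrna_disease: AssociationTable
    disease_drug: DrugAssociationTable
    benchmark: BenchmarkSet
    truth: dict
    seed: int
    params: dict

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted(self.disease_gene))


def _split(items: list, k: int) -> list[list]:
    return [list(part) for part in np.array_split(np.asarray(items, dtype=object), k)]


def generate_world(
    clusters: int = 2,
    diseases: int = 10,
    genes: int = 40,
    ncrnas: int = 12,
    drugs: int = 16,
    noise: float = 0.05,
    seed: int = 42,
    genes_per_disease: int = 6,
    group_core_genes: int = 4,
    diseases_per_ncrna: int = 3,
    drugs_per_disease: int = 4,
    intra_edge_prob: float = 0.30,
    weight_range: tuple[float, float] = (0.5, 2.0),
) -> SyntheticWorld:
    """Generate a planted-cluster world; a pure function of its arguments.

    ``noise`` is the cross-cluster rate: the probability of an
    inter-cluster gene edge, and the per-pick probability that an
    annotation/association/drug lands in a foreign cluster.  ``noise=0``
    produces zero cross-cluster structure.
    """
    if min(clusters, diseases, genes, ncrnas, drugs) <= 0:
        raise ValueError("all counts must be positive")
    if clusters > diseases:
        raise ValueError("cannot have more clusters than diseases")
    if clusters > genes or clusters > drugs:
        raise ValueError("each cluster needs at least one gene and one drug")
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    if group_core_genes >= genes_per_disease:
        raise ValueError("group_core_genes must be smaller than genes_per_disease")

    rng = np.random.default_rng(seed)

    disease_ids = [f"DOID:3{i:03d}" for i in range(diseases)]
    gene_ids = [f"G{i:03d}" for i in range(genes)]
    ncrna_ids = [f"lnc{i:03d}" for i in range(ncrnas)]
    drug_ids = [f"DRUG{i:03d}" for i in range(drugs)]

    disease_blocks = _split(disease_ids, clusters)
    gene_pools = _split(gene_ids, clusters)
    drug_pools = _split(drug_ids, clusters)

    # ontology: root -> cluster terms -> sibling-group terms -> diseases
    terms = [Term(ROOT_ID, "disease root")]
    disease_cluster: dict[str, int] = {}
    groups: list[list[str]] = []
    for c, block in enumerate(disease_blocks):
        cid = f"DOID:10{c:02d}"
        terms.append(Term(cid, f"cluster {c} disease", frozenset({ROOT_ID})))
        for start in range(0, len(block), 2):
            group = block[start : start + 2]
            gid = f"DOID:20{len(groups):02d}"
            terms.append(Term(gid, f"disease group {len(groups)}", frozenset({cid})))
            for d in group:
                terms.append(Term(d, f"disease {d}", frozenset({gid})))
                disease_cluster[d] = c
            groups.append(group)
    ontology = Ontology(terms)

    # annotations: sibling groups share a gene core within the cluster pool
    disease_gene: dict[str, frozenset[str]] = {}
    group_of: dict[str, int] = {}
    for gi, group in enumerate(groups):
        c = disease_cluster[group[0]]
        pool = gene_pools[c]
        core = list(rng.choice(pool, size=min(group_core_genes, len(pool)), replace=False))
        rest = [g for g in pool if g not in core]
        for d in group:
            n_private = genes_per_disease - len(core)
            private = list(rng.choice(rest, size=min(n_private, len(rest)), replace=False))
            chosen = []
            for g in core + private:
                if noise > 0 and clusters > 1 and rng.random() < noise:
                    other = [
                        x for cc, p in enumerate(gene_pools) if cc != c for x in p
                    ]
                    g = str(rng.choice(other))
                chosen.append(g)
            disease_gene[d] = frozenset(chosen)
            group_of[d] = gi

    gene_cluster = {g: c for c, pool in enumerate(gene_pools) for g in pool}
    edges = []
    for i in range(genes):
        for j in range(i + 1, genes):
            gi, gj = gene_ids[i], gene_ids[j]
            p = intra_edge_prob if gene_cluster[gi] == gene_cluster[gj] else noise
            if rng.random() < p:
                edges.append((gi, gj, float(rng.uniform(*weight_range))))
    gfn = GeneFunctionalNetwork(edges, nodes=gene_ids)

    # ncRNA-disease associations, mostly within the ncRNA's own cluster
    ncrna_cluster = {r: i % clusters for i, r in enumerate(ncrna_ids)}
    pairs = set()
    for r in ncrna_ids:
        c = ncrna_cluster[r]
        own = disease_blocks[c]
        other = [d for cc, b in enumerate(disease_blocks) if cc != c for d in b]
        k = min(diseases_per_ncrna, len(own))
        n_cross = (
            int((rng.random(k) < noise).sum()) if (noise > 0 and clusters > 1) else 0
        )
        n_cross = min(n_cross, len(other))
        picked = list(rng.choice(own, size=k - n_cross, replace=False))
        if n_cross:
            picked += list(rng.choice(other, size=n_cross, replace=False))
        for d in picked:
            pairs.add((r, str(d)))
    ncrna_disease = AssociationTable(frozenset(pairs))

    # drug sets mirror cluster membership
    drug_map: dict[str, frozenset[str]] = {}
    for d in disease_ids:
        c = disease_cluster[d]
        own = drug_pools[c]
        other = [x for cc, p in enumerate(drug_pools) if cc != c for x in p]
        k = min(drugs_per_disease, len(own))
        n_cross = (
            int((rng.random(k) < noise).sum()) if (noise > 0 and clusters > 1) else 0
        )
        n_cross = min(n_cross, len(other))
        picked = list(rng.choice(own, size=k - n_cross, replace=False))
        if n_cross:
            picked += list(rng.choice(other, size=n_cross, replace=False))
        drug_map[d] = frozenset(str(x) for x in picked)
    disease_drug = DrugAssociationTable(drug_map)

    # benchmark: the planted strongly-similar sibling pairs (all intra-cluster)
    benchmark = BenchmarkSet.from_pairs(
        (g[0], g[1]) for g in groups if len(g) == 2
    )

    truth = {
        "disease_cluster": disease_cluster,
        "ncrna_cluster": ncrna_cluster,
        "groups": {str(i): g for i, g in enumerate(groups)},
        "benchmark_pairs": sorted(list(p) for p in benchmark.pairs),
    }
    params = dict(
        clusters=clusters, diseases=diseases, genes=genes, ncrnas=ncrnas,
        drugs=drugs, noise=noise, genes_per_disease=genes_per_disease,
        group_core_genes=group_core_genes, diseases_per_ncrna=diseases_per_ncrna,
        drugs_per_disease=drugs_per_disease, intra_edge_prob=intra_edge_prob,
        weight_range=list(weight_range),
    )
    return SyntheticWorld(
        ontology=ontology, gfn=gfn, disease_gene=disease_gene,
        ncrna_disease=ncrna_disease, disease_drug=disease_drug,
        benchmark=benchmark, truth=truth, seed=seed, params=params,
    )


@dataclass
class OracleEstimate:
    """Monte-Carlo estimate of the channel weight vector.

    Per gene: empirical mean of (visit count x walk-completes-at-sink
    indicator) over all walks, with its standard error.
    """

    genes: tuple[str, ...]
    means: np.ndarray
    standard_errors: np.ndarray
    n_walks: int
    n_completed: int


def monte_carlo_channel_oracle(
    net: IntegratedNetwork,
    d: str,
    damping: float = 0.85,
    n_walks: int = 100_000,
    seed: int = 0,
    use_gfn_weights: bool = True,
) -> OracleEstimate:
    """Estimate the channel weight vector of disease ``d`` by simulation.

    Walks start at ``d``; before every move the walker dissipates with
    probability ``1 - damping``, otherwise it steps to a neighbour chosen
    proportionally to edge weight.  Re-entering ``d`` completes the walk.
    The per-gene statistic is the mean over ALL walks of (visits to the
    gene x completion indicator), an unbiased estimate of the analytic
    ``f_i * a_i``.  Other diseases are absent from the substrate, exactly
    as in the analytic contract.
    """
    if d not in net.disease_genes:
        raise KeyError(f"{d!r} is not a boundary node of the network")
    if n_walks < 10_000:
        raise ValueError("oracle needs at least 10^4 walks")
    rng = np.random.default_rng(seed)
    n = net.n_genes
    SINK = -1

    # adjacency lists over genes + the single boundary node d
    nbrs: list[list[int]] = [[] for _ in range(n)]
    wts: list[list[float]] = [[] for _ in range(n)]
    for u, v, w in net.gfn.edges():
        i, j = net.gene_index[u], net.gene_index[v]
        wt = w if use_gfn_weights else 1.0
        nbrs[i].append(j)
        wts[i].append(wt)
        nbrs[j].append(i)
        wts[j].append(wt)
    d_nbrs: list[int] = []
    d_wts: list[float] = []
    for g, w in net.disease_genes[d].items():
        i = net.gene_index[g]
        d_nbrs.append(i)
        d_wts.append(w)
        nbrs[i].append(SINK)
        wts[i].append(w)

    cum = [np.cumsum(w) for w in wts]
    d_cum = np.cumsum(d_wts)

    total = np.zeros(n)
    total_sq = np.zeros(n)
    completed_walks = 0
    visits = np.zeros(n)
    for _ in range(n_walks):
        visits[:] = 0.0
        completed = False
        # first move, from the boundary node
        if rng.random() < damping and d_cum.size:
            current = d_nbrs[int(np.searchsorted(d_cum, rng.random() * d_cum[-1], side="right"))]
            visits[current] += 1.0
            while rng.random() < damping:
                c = cum[current]
                nxt = nbrs[current][int(np.searchsorted(c, rng.random() * c[-1], side="right"))]
                if nxt == SINK:
                    completed = True
                    break
                current = nxt
                visits[current] += 1.0
        if completed:
            completed_walks += 1
            total += visits
            total_sq += visits * visits
    means = total / n_walks
    var = (total_sq - n_walks * means**2) / max(1, n_walks - 1)
    ses = np.sqrt(np.maximum(var, 0.0) / n_walks)
    if completed_walks == 0:
        logger.warning("no walk completed for %r; oracle estimate is all-zero", d)
    return OracleEstimate(net.genes, means, ses, n_walks, completed_walks)


def write_obo(ontology: Ontology, path) -> None:
    """Write an ontology as a minimal OBO 1.2 flat file."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for tid in sorted(ontology.terms):
            term = ontology[tid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term.id}\n")
            fh.write(f"name: {term.name or term.id}\n")
            for p in sorted(term.parents):
                fh.write(f"is_a: {p} ! {ontology[p].name or p}\n")


def write_world(world: SyntheticWorld, directory) -> dict[str, str]:
    """Write every world table in the formats the module readers accept.

    Emits do.obo, gfn.tsv, disease_gene.tsv, ncrna_disease.tsv,
    disease_drug.tsv, benchmark.tsv and truth.json; returns the paths.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {name: os.path.join(directory, fname) for name, fname in [
        ("obo", "do.obo"), ("gfn", "gfn.tsv"), ("disease_gene", "disease_gene.tsv"),
        ("ncrna_disease", "ncrna_disease.tsv"), ("disease_drug", "disease_drug.tsv"),
        ("benchmark", "benchmark.tsv"), ("truth", "truth.json"),
    ]}
    write_obo(world.ontology, paths["obo"])
    with open(paths["gfn"], "w") as fh:
        for u, v, w in sorted(world.gfn.edges()):
            fh.write(f"{u}\t{v}\t{float(w)!r}\n")
    with open(paths["disease_gene"], "w") as fh:
        for d in sorted(world.disease_gene):
            for g in sorted(world.disease_gene[d]):
                fh.write(f"{d}\t{g}\n")
    with open(paths["ncrna_disease"], "w") as fh:
        for r, d in sorted(world.ncrna_disease.pairs):
            fh.write(f"{r}\t{d}\n")
    with open(paths["disease_drug"], "w") as fh:
        for d in world.disease_drug.diseases:
            for drug in sorted(world.disease_drug.get(d)):
                fh.write(f"{d}\t{drug}\n")
    with open(paths["benchmark"], "w") as fh:
        for a, b in sorted(world.benchmark.pairs):
            fh.write(f"{a}\t{b}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(world.truth, fh, indent=2, sort_keys=True)
    return paths
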