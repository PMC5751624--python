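"""Shared fixtures: tiny hand-built networks/ontologies and the default world."""

from __future__ import annotations

import numpy as np
import pytest

from infdissim.flow_network import GeneFunctionalNetwork, IntegratedNetwork
from infdissim.ontology import Ontology, Term, propagate_annotations
from infdissim.pipeline import disease_similarity_pipeline
from infdissim.synthetic import generate_world


def toy_net(gene_edges, disease_genes, extra_genes=()):
    """Build an IntegratedNetwork directly from edge/annotation literals.

    ``disease_genes`` maps disease id -> iterable of genes (edge weight 1).
    """
    annotated = {g for gs in disease_genes.values() for g in gs}
    gfn = GeneFunctionalNetwork(gene_edges, nodes=set(extra_genes) | annotated)
    genes = tuple(sorted(gfn.nodes))
    gene_index = {g: i for i, g in enumerate(genes)}
    dmap = {d: {g: 1.0 for g in gs} for d, gs in disease_genes.items()}
    return IntegratedNetwork(
        gfn=gfn,
        diseases=tuple(disease_genes),
        disease_genes=dmap,
        gene_index=gene_index,
        genes=genes,
        isolated=frozenset(d for d, gs in dmap.items() if not gs),
    )


def diamond_ontology():
    """root <- a, root <- b, a <- c, b <- c."""
    return Ontology(
        [
            Term("root", "root"),
            Term("a", "a", frozenset({"root"})),
            Term("b", "b", frozenset({"root"})),
            Term("c", "c", frozenset({"a", "b"})),
        ]
    )


def random_dag_fixture(seed, n_terms=12, n_genes=30):
    """A random rooted DAG with random annotations, for property tests."""
    rng = np.random.default_rng(seed)
    terms = [Term("T000", "root")]
    for i in range(1, n_terms):
        k = int(rng.integers(1, 3))
        parents = rng.choice(i, size=min(k, i), replace=False)
        terms.append(
            Term(f"T{i:03d}", parents=frozenset(f"T{int(p):03d}" for p in parents))
        )
    ontology = Ontology(terms)
    genes = [f"g{j}" for j in range(n_genes)]
    raw = {}
    for i in range(n_terms):
        if rng.random() < 0.7:
            k = int(rng.integers(1, 5))
            raw[f"T{i:03d}"] = set(rng.choice(genes, size=k, replace=False))
    if "T000" not in raw:
        raw["T000"] = {genes[0]}
    return ontology, propagate_annotations(ontology, raw)


@pytest.fixture(scope="session")
def default_world():
    return generate_world()


@pytest.fixture(scope="session")
def default_pipeline(default_world):
    w = default_world
    return disease_similarity_pipeline(w.ontology, w.disease_gene, w.gfn)
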