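"""Integrated disease-gene network and the channel-model flow weight vector.

Diseases are boundary nodes attached (weight 1) to their annotated genes
inside a weighted gene functional network (GFN).  For one disease ``d``
acting simultaneously as source and sink, a damped random walk starts at
``d``, survives each step with probability ``mu`` (the damping factor) and
moves to a neighbour with probability proportional to edge weight; a walk
"completes" when it re-enters ``d``.  With

    P_ij = mu * w_ij / deg(i)          (gene-gene transitions)
    p0_j = mu * w_dj / deg(d)          (emission from the source)
    q_i  = mu * w_id / deg(i)          (absorption at the sink)

where ``deg(i)`` is the total incident weight of gene ``i`` including its
edge to ``d``, the expected visit counts along completed walks are

    f = p0 (I - P)^-1        (emitting solve)
    a = (I - P)^-1 q         (absorbing solve)

and the per-gene channel weight is ``w_i = f_i * a_i``.  The weight vector
is the disease's N-dimensional flow profile over genes; the flow similarity
of two diseases is the cosine of their profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .ontology import AnnotationMap

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFunctionalNetwork",
    "IntegratedNetwork",
    "FlowConfig",
    "WeightVector",
    "FlowError",
    "read_gfn",
    "build_integrated_network",
    "channel_weight_vector",
    "all_weight_vectors",
    "inf_cosine",
]


class FlowError(RuntimeError):
    """Raised when a channel-model solve fails or returns non-finite values."""


class GeneFunctionalNetwork:
    """Undirected weighted gene-gene graph (HumanNet-style edge list).

    Weights must be positive; self-loops are rejected; duplicate (or
    reciprocal) edges are merged keeping the maximum weight, with a logged
    count.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        merged = 0
        for u, v, w in edges:
            w = float(w)
            if u == v:
                raise ValueError(f"self-loop on gene {u!r}")
            if w <= 0:
                raise ValueError(f"non-positive weight {w} on edge {u!r}-{v!r}")
            if g.has_edge(u, v):
                merged += 1
                w = max(w, g[u][v]["weight"])
            g.add_edge(u, v, weight=w)
        if merged:
            logger.warning("merged %d duplicate gene-gene edges (kept max weight)", merged)
        self.graph = g

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for u, v, d in self.graph.edges(data=True):
            yield u, v, d["weight"]

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def read_gfn(path) -> GeneFunctionalNetwork:
    """Read a gene functional network TSV (gene1, gene2, weight)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["gene1", "gene2", "weight"], dtype={"gene1": str, "gene2": str},
        float_precision="round_trip",
    )
    # tolerate a header row
    if len(df) and not np.issubdtype(np.asarray([df.iloc[0, 2]]).dtype, np.number):
        try:
            float(df.iloc[0, 2])
        except (TypeError, ValueError):
            df = df.iloc[1:]
    return GeneFunctionalNetwork(
        (r.gene1, r.gene2, float(r.weight)) for r in df.itertuples()
    )


@dataclass(frozen=True)
class FlowConfig:
    """Channel-model parameters.

    damping
        Per-step survival probability of the walker (default 0.85);
        ``1 - damping`` is the dissipation probability.
    use_gfn_weights
        When False, gene-gene edges are treated as unweighted (weight 1).
    residual_tol
        Maximum acceptable residual of the linear solves.
    """

    damping: float = 0.85
    use_gfn_weights: bool = True
    residual_tol: float = 1e-12

    def __post_init__(self):
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must lie strictly between 0 and 1")


@dataclass
class IntegratedNetwork:
    """GFN plus disease boundary nodes and their disease-gene edges."""

    gfn: GeneFunctionalNetwork
    diseases: tuple[str, ...]
    disease_genes: dict[str, dict[str, float]]
    gene_index: dict[str, int]
    genes: tuple[str, ...]
    isolated: frozenset[str]
    n_dropped_genes: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def build_integrated_network(
    gfn: GeneFunctionalNetwork,
    annmap: AnnotationMap,
    diseases: Sequence[str],
) -> IntegratedNetwork:
    """Attach each disease to its propagated genes inside the GFN.

    Disease-gene edges get weight 1.0; annotation genes absent from the GFN
    are dropped (logged count).  Diseases left without any surviving gene
    edge are retained but flagged isolated: their weight vector is all-zero.
    """
    genes = tuple(sorted(gfn.nodes))
    gene_index = {g: i for i, g in enumerate(genes)}
    disease_genes: dict[str, dict[str, float]] = {}
    isolated = set()
    dropped = 0
    for d in diseases:
        edges = {}
        for g in annmap.genes(d):
            if g in gene_index:
                edges[g] = 1.0
            else:
                dropped += 1
        disease_genes[d] = edges
        if not edges:
            isolated.add(d)
    if dropped:
        logger.warning("dropped %d disease-gene annotations absent from the GFN", dropped)
    if isolated:
        logger.warning("%d diseases have no gene edges (isolated)", len(isolated))
    return IntegratedNetwork(
        gfn=gfn,
        diseases=tuple(diseases),
        disease_genes=disease_genes,
        gene_index=gene_index,
        genes=genes,
        isolated=frozenset(isolated),
        n_dropped_genes=dropped,
    )


@dataclass(frozen=True)
class WeightVector:
    """Per-disease channel-flow weights over the shared gene index."""

    disease: str
    weights: np.ndarray
    genes: tuple[str, ...]

    def is_zero(self) -> bool:
        return not np.any(self.weights)


def _gene_gene_matrix(net: IntegratedNetwork, use_weights: bool) -> sp.csr_matrix:
    n = net.n_genes
    rows, cols, vals = [], [], []
    for u, v, w in net.gfn.edges():
        i, j = net.gene_index[u], net.gene_index[v]
        wt = w if use_weights else 1.0
        rows += [i, j]
        cols += [j, i]
        vals += [wt, wt]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def channel_weight_vector(
    net: IntegratedNetwork, d: str, cfg: FlowConfig | None = None
) -> WeightVector:
    """Channel-model weight vector of disease ``d`` (source = sink = ``d``).

    All boundary nodes other than ``d`` are removed before the solve.  The
    emitting visits ``f`` and absorbing probabilities ``a`` are obtained by
    two sparse direct solves and combined as ``w_i = f_i * a_i``.
    """
    cfg = cfg or FlowConfig()
    if d not in net.disease_genes:
        raise KeyError(f"{d!r} is not a boundary node of the network")
    n = net.n_genes
    dvec = np.zeros(n)
    for g, w in net.disease_genes[d].items():
        dvec[net.gene_index[g]] = w
    deg_d = dvec.sum()
    if deg_d == 0.0:
        return WeightVector(d, np.zeros(n), net.genes)

    mu = cfg.damping
    W = _gene_gene_matrix(net, cfg.use_gfn_weights)
    deg = np.asarray(W.sum(axis=1)).ravel() + dvec
    deg_safe = np.where(deg > 0, deg, 1.0)
    P = sp.diags(mu / deg_safe) @ W  # row-substochastic for mu < 1
    p0 = mu * dvec / deg_d
    q = mu * dvec / deg_safe

    A = (sp.identity(n, format="csc") - P.tocsc())
    lu = spla.splu(A)
    a = lu.solve(q)
    f = lu.solve(p0, trans="T")

    if not (np.all(np.isfinite(f)) and np.all(np.isfinite(a))):
        raise FlowError(f"non-finite channel solve for disease {d!r}")
    scale = max(1.0, float(np.abs(p0).max()), float(np.abs(q).max()))
    res_f = np.abs(A.T @ f - p0).max()
    res_a = np.abs(A @ a - q).max()
    if max(res_f, res_a) > cfg.residual_tol * scale * n:
        raise FlowError(
            f"channel solve residual {max(res_f, res_a):.3e} exceeds tolerance"
        )
    weights = f * a
    weights[weights < 0] = 0.0  # numerical dust
    return WeightVector(d, weights, net.genes)


def all_weight_vectors(
    net: IntegratedNetwork, cfg: FlowConfig | None = None
) -> tuple[dict[str, WeightVector], dict[str, Exception]]:
    """Channel weight vectors for every boundary disease.

    Per-disease failures are collected rather than fatal; returns
    ``(vectors, failures)``.
    """
    vectors: dict[str, WeightVector] = {}
    failures: dict[str, Exception] = {}
    for d in net.diseases:
        try:
            vectors[d] = channel_weight_vector(net, d, cfg)
        except FlowError as exc:  # pragma: no cover - defensive
            logger.warning("channel solve failed for %r: %s", d, exc)
            failures[d] = exc
    return vectors, failures


def inf_cosine(wv1: WeightVector, wv2: WeightVector) -> float:
    """Flow similarity: cosine of two weight vectors, in [0, 1].

    Returns 0 (with a logged warning) when either vector is all-zero, where
    the cosine is undefined.
    """
    if wv1.genes != wv2.genes:
        raise ValueError("weight vectors use different gene indexes")
    n1 = float(np.linalg.norm(wv1.weights))
    n2 = float(np.linalg.norm(wv2.weights))
    if n1 == 0.0 or n2 == 0.0:
        logger.warning(
            "undefined flow cosine for %r/%r (zero vector)", wv1.disease, wv2.disease
        )
        return 0.0
    return float(np.dot(wv1.weights, wv2.weights) / (n1 * n2))
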