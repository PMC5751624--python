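"""Disease-ontology handling: DAG parsing, annotation propagation and
information-content based (Lin) semantic similarity.

The disease ontology is a rooted DAG over ``IS_A`` (subsumption) edges.
Gene annotations attached to specific disease terms are propagated up the
DAG (true-path rule), so that a parent's gene set always contains every
child's gene set.  Information content is then defined from propagated
gene-set sizes,

    IC(t) = -ln( |G_t| / |G_root| ),

which is zero at the root and grows for rarer (more specific) terms.  The
most informative common ancestor (MICA) of two terms is the common ancestor
with maximal IC, and Lin similarity is ``2*IC(MICA) / (IC(t1)+IC(t2))``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "Term",
    "Ontology",
    "AnnotationMap",
    "OntologyError",
    "UndefinedICError",
    "parse_obo",
    "read_annotations",
    "propagate_annotations",
    "information_content",
    "mica",
    "lin_similarity",
]


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, bad roots)."""


class UndefinedICError(ValueError):
    """Raised when IC is requested for a term with an empty propagated set."""


@dataclass(frozen=True)
class Term:
    """A single ontology term with its direct ``IS_A`` parents."""

    id: str
    name: str = ""
    parents: frozenset[str] = frozenset()


class Ontology:
    """A rooted DAG of :class:`Term` objects connected by ``IS_A`` edges.

    Validates on construction: every referenced parent must exist, the
    graph must be acyclic, and there must be exactly one root (a term
    without parents).
    """

    def __init__(self, terms: Iterable[Term]):
        self._terms: dict[str, Term] = {t.id: t for t in terms}
        self._validate()
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._terms)
        for t in self._terms.values():
            for p in t.parents:
                if p not in self._terms:
                    raise OntologyError(
                        f"term {t.id!r} references unknown parent {p!r}"
                    )
                g.add_edge(t.id, p)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            child, parent = cycle[0][0], cycle[0][1]
            raise OntologyError(
                f"IS_A cycle detected (e.g. edge {child!r} -> {parent!r})"
            )
        roots = [t.id for t in self._terms.values() if not t.parents]
        if len(roots) != 1:
            raise OntologyError(
                f"expected exactly one root term, found {len(roots)}: "
                f"{sorted(roots)[:5]}"
            )
        self.root: str = roots[0]
        self._graph = g

    # -- container protocol -------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self):
        return iter(self._terms)

    def __getitem__(self, term_id: str) -> Term:
        return self._terms[term_id]

    @property
    def terms(self) -> Mapping[str, Term]:
        return self._terms

    # -- DAG queries ---------------------------------------------------------
    def parents(self, term_id: str) -> frozenset[str]:
        return self._terms[term_id].parents

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All ancestors of ``term_id`` including the term itself."""
        if term_id not in self._terms:
            raise KeyError(f"unknown term {term_id!r}")
        cached = self._ancestor_cache.get(term_id)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term_id)) | {term_id}
            self._ancestor_cache[term_id] = cached
        return cached

    def topological_order(self) -> list[str]:
        """Terms ordered so every child precedes all of its ancestors."""
        return list(nx.topological_sort(self._graph))


def parse_obo(path) -> Ontology:
    """Read an OBO flat file into an :class:`Ontology`.

    Only ``is_a`` relationships build the DAG; obsolete terms and all other
    relationship types are dropped.  Raises :class:`OntologyError` when the
    file does not describe a single-rooted DAG.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms = []
    for node, data in graph.nodes(data=True):
        is_a = frozenset(
            parent
            for _, parent, key in graph.out_edges(node, keys=True)
            if key == "is_a"
        )
        terms.append(Term(id=node, name=data.get("name", ""), parents=is_a))
    return Ontology(terms)


def read_annotations(path) -> dict[str, set[str]]:
    """Read a two-column (term id, gene id) TSV into a raw annotation map.

    Lines starting with ``#`` are comments.  A first line whose leading
    field looks like a column label (``disease``/``term``/``doid``/``id``)
    is treated as a header.  Extra columns are ignored.
    """
    raw: dict[str, set[str]] = {}
    with open(path) as fh:
        first = True
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if first:
                first = False
                if fields[0].strip().lower() in {"disease", "disease_id", "term", "doid", "id"}:
                    continue
            if len(fields) < 2:
                continue
            term, gene = fields[0].strip(), fields[1].strip()
            raw.setdefault(term, set()).add(gene)
    return raw


@dataclass(frozen=True)
class AnnotationMap:
    """Raw and DAG-propagated term -> gene-set annotations.

    ``propagated[t]`` is ``raw[t]`` unioned with the propagated sets of all
    descendants of ``t`` (true-path rule), so set inclusion along ``IS_A``
    edges holds by construction.
    """

    raw: Mapping[str, frozenset[str]]
    propagated: Mapping[str, frozenset[str]]
    root: str
    n_skipped: int = 0

    def genes(self, term_id: str) -> frozenset[str]:
        return self.propagated.get(term_id, frozenset())


def propagate_annotations(
    ontology: Ontology, raw: Mapping[str, Iterable[str]]
) -> AnnotationMap:
    """Propagate raw term->gene annotations up the ``IS_A`` DAG.

    Annotations to term ids absent from the ontology are skipped with a
    logged count.  Terms with no annotated descendants receive the empty
    set.
    """
    clean: dict[str, frozenset[str]] = {}
    skipped = 0
    for term, genes in raw.items():
        if term not in ontology:
            skipped += 1
            continue
        clean[term] = frozenset(genes)
    if skipped:
        logger.warning("skipped %d annotations to unknown terms", skipped)

    acc: dict[str, set[str]] = {t: set(clean.get(t, ())) for t in ontology}
    # children precede parents in topological order of the child->parent graph
    for term in ontology.topological_order():
        for parent in ontology.parents(term):
            acc[parent] |= acc[term]
    propagated = {t: frozenset(g) for t, g in acc.items()}
    return AnnotationMap(
        raw={t: frozenset(g) for t, g in clean.items()},
        propagated=propagated,
        root=ontology.root,
        n_skipped=skipped,
    )


def information_content(annmap: AnnotationMap, term_id: str) -> float:
    """IC(t) = -ln(|G_t| / |G_root|), in natural-log units."""
    genes = annmap.genes(term_id)
    if not genes:
        raise UndefinedICError(f"term {term_id!r} has an empty propagated gene set")
    root_genes = annmap.genes(annmap.root)
    return max(0.0, -math.log(len(genes) / len(root_genes)))


def mica(ontology: Ontology, annmap: AnnotationMap, t1: str, t2: str) -> str:
    """Most informative common ancestor of ``t1`` and ``t2``.

    A term counts as its own ancestor.  Because IC is a strictly decreasing
    function of propagated gene-set size, the MICA is the common ancestor
    with the smallest propagated set; ties break to the lexicographically
    smallest term id.
    """
    for t in (t1, t2):
        if t not in ontology:
            raise KeyError(f"unknown term {t!r}")
    common = ontology.ancestors(t1) & ontology.ancestors(t2)
    candidates = [t for t in common if annmap.genes(t)]
    if not candidates:
        raise UndefinedICError(
            f"no common ancestor of {t1!r} and {t2!r} has annotations"
        )
    return min(candidates, key=lambda t: (len(annmap.genes(t)), t))


def lin_similarity(
    ontology: Ontology, annmap: AnnotationMap, t1: str, t2: str
) -> float:
    """Lin semantic similarity ``2*IC(MICA) / (IC(t1) + IC(t2))`` in [0, 1].

    When both terms carry zero IC (both annotation-equivalent to the root)
    the similarity is defined as 1.
    """
    if not annmap.genes(t1) or not annmap.genes(t2):
        logger.warning("lin_similarity: empty propagated set for %r/%r", t1, t2)
        return 0.0
    ic1 = information_content(annmap, t1)
    ic2 = information_content(annmap, t2)
    if ic1 + ic2 == 0.0:
        return 1.0
    m = mica(ontology, annmap, t1, t2)
    return 2.0 * information_content(annmap, m) / (ic1 + ic2)
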