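"""InfDisSim: flow similarity corrected by a semantic MICA gene-set factor.

For diseases t1, t2 with propagated gene sets G1, G2 and most informative
common ancestor gene set G_MICA,

    InfDisSim(t1, t2) = Inf(t1, t2) * |G1| |G2| / |G_MICA|^2

where ``Inf`` is the cosine of the channel-flow weight vectors.  Because
annotations are propagated up the ontology, G1 and G2 are subsets of
G_MICA and the semantic factor lies in (0, 1], keeping the score in [0, 1].
The module also provides the best-match-average similarity between two
disease *sets*, used downstream to compare ncRNAs through their associated
diseases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .flow_network import WeightVector, inf_cosine
from .ontology import AnnotationMap, Ontology, mica

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "infdissim_pair",
    "infdissim_matrix",
    "best_match",
    "set_similarity",
    "read_similarity_tsv",
    "read_similarity_long",
]


@dataclass
class SimilarityMatrix:
    """Symmetric entity-by-entity similarity scores in [0, 1].

    ``valid`` optionally records which entries were computable (pairs
    involving an isolated or unannotated entity score 0 but are flagged
    invalid).
    """

    ids: tuple[str, ...]
    values: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        self._index = {e: i for i, e in enumerate(self.ids)}

    def __contains__(self, entity: str) -> bool:
        return entity in self._index

    def index(self, entity: str) -> int:
        return self._index[entity]

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def write_tsv(self, path) -> None:
        """Wide format: header row/column of ids."""
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    def write_long(self, path) -> None:
        """Long format: id1, id2, score for the upper triangle incl. diagonal."""
        rows = []
        for i, a in enumerate(self.ids):
            for j in range(i, len(self.ids)):
                rows.append((a, self.ids[j], repr(float(self.values[i, j]))))
        pd.DataFrame(rows, columns=["id1", "id2", "score"]).to_csv(
            path, sep="\t", index=False
        )


def read_similarity_tsv(path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return SimilarityMatrix(tuple(df.index.astype(str)), df.to_numpy(dtype=float))


def read_similarity_long(path) -> SimilarityMatrix:
    df = pd.read_csv(
        path, sep="\t", dtype={"id1": str, "id2": str}, float_precision="round_trip"
    )
    ids = tuple(sorted(set(df["id1"]) | set(df["id2"])))
    idx = {e: i for i, e in enumerate(ids)}
    values = np.zeros((len(ids), len(ids)))
    for r in df.itertuples():
        i, j = idx[r.id1], idx[r.id2]
        values[i, j] = values[j, i] = float(r.score)
    return SimilarityMatrix(ids, values)


def infdissim_pair(
    t1: str,
    t2: str,
    weight_vectors: Mapping[str, WeightVector],
    ontology: Ontology,
    annmap: AnnotationMap,
) -> float:
    """InfDisSim score of a disease pair (see module docstring).

    Returns 0 (with a logged warning) when either disease lacks propagated
    genes or has an all-zero flow vector.  Self-similarity of a valid
    disease is exactly 1 (MICA is the term itself and the cosine of a
    vector with itself is 1).
    """
    g1, g2 = annmap.genes(t1), annmap.genes(t2)
    wv1, wv2 = weight_vectors.get(t1), weight_vectors.get(t2)
    if not g1 or not g2 or wv1 is None or wv2 is None or wv1.is_zero() or wv2.is_zero():
        logger.warning("InfDisSim undefined for pair (%r, %r); scoring 0", t1, t2)
        return 0.0
    if t1 == t2:
        return 1.0
    m = mica(ontology, annmap, t1, t2)
    gm = annmap.genes(m)
    if not gm:  # defensive: cannot happen once the root set is non-empty
        return 0.0
    factor = (len(g1) * len(g2)) / (len(gm) ** 2)
    return inf_cosine(wv1, wv2) * factor


def infdissim_matrix(
    diseases: Sequence[str],
    weight_vectors: Mapping[str, WeightVector],
    ontology: Ontology,
    annmap: AnnotationMap,
) -> SimilarityMatrix:
    """All-pairs InfDisSim as a :class:`SimilarityMatrix` with validity flags."""
    ids = tuple(diseases)
    n = len(ids)
    values = np.zeros((n, n))
    valid = np.zeros((n, n), dtype=bool)
    ok = [
        annmap.genes(d) and d in weight_vectors and not weight_vectors[d].is_zero()
        for d in ids
    ]
    for i in range(n):
        for j in range(i, n):
            if ok[i] and ok[j]:
                s = infdissim_pair(ids[i], ids[j], weight_vectors, ontology, annmap)
                values[i, j] = values[j, i] = s
                valid[i, j] = valid[j, i] = True
    return SimilarityMatrix(ids, values, valid=valid)


def best_match(t: str, members: Iterable[str], sim: SimilarityMatrix) -> float:
    """Best-match similarity of disease ``t`` to a disease set (max over members)."""
    members = list(members)
    if not members:
        raise ValueError("disease set must be non-empty")
    return max(sim.get(t, m) for m in members)


def set_similarity(
    set1: Iterable[str], set2: Iterable[str], sim: SimilarityMatrix
) -> float:
    """Best-match-average similarity between two disease sets.

    Averages, over both directions, each member's best match in the other
    set; symmetric and bounded in [0, 1].
    """
    s1, s2 = list(dict.fromkeys(set1)), list(dict.fromkeys(set2))
    if not s1 or not s2:
        raise ValueError("disease sets must be non-empty")
    total = sum(best_match(t, s2, sim) for t in s1)
    total += sum(best_match(t, s1, sim) for t in s2)
    return total / (len(s1) + len(s2))
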