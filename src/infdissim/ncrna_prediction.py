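"""ncRNA similarity networks and RWR prioritisation of disease-related ncRNAs.

Each lncRNA/miRNA is represented by its set of associated diseases; the
similarity of two ncRNAs is the best-match-average InfDisSim of those sets.
The pooled off-diagonal scores are standardised to z-scores (population sd)
with one-sided upper-tail normal p-values.  Disease-related candidates are
then prioritised by random walk with restart on the ncRNA similarity
network,

    P_{t+1} = gamma * P_0 + (1 - gamma) * A @ P_t,

with A the column-normalised adjacency and P_0 uniform over the disease's
known ncRNAs (seeds), iterated until the L1 difference falls below 1e-10.
Leave-one-out cross-validation holds out each known association, re-seeds
with the disease's remaining ncRNAs and scores the held-out ncRNA against
all ncRNAs not known to associate with the disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .disease_similarity import SimilarityMatrix, set_similarity
from .evaluation import roc_auc

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationTable",
    "NcrnaSimilarityNetwork",
    "RWRConfig",
    "ProbabilityVector",
    "LOOCVTrial",
    "LOOCVResult",
    "DegenerateNetworkError",
    "ConvergenceError",
    "read_associations",
    "build_ncrna_similarity",
    "column_normalize",
    "rwr",
    "rank_candidates",
    "loocv_auc",
]


class DegenerateNetworkError(ValueError):
    """All pairwise scores identical: z-scores are undefined."""


class ConvergenceError(RuntimeError):
    """RWR failed to converge within the iteration cap."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class AssociationTable:
    """Unique (ncRNA id, disease id) association pairs."""

    pairs: frozenset[tuple[str, str]]

    @property
    def ncrnas(self) -> tuple[str, ...]:
        return tuple(sorted({r for r, _ in self.pairs}))

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted({d for _, d in self.pairs}))

    def diseases_of(self, ncrna: str) -> frozenset[str]:
        return frozenset(d for r, d in self.pairs if r == ncrna)

    def ncrnas_of(self, disease: str) -> frozenset[str]:
        return frozenset(r for r, d in self.pairs if d == disease)

    def restrict_to_diseases(self, disease_ids: Iterable[str]) -> "AssociationTable":
        """Drop pairs whose disease is unresolvable (logged count)."""
        keep = set(disease_ids)
        kept = frozenset(p for p in self.pairs if p[1] in keep)
        dropped = len(self.pairs) - len(kept)
        if dropped:
            logger.warning("dropped %d associations with unresolvable diseases", dropped)
        return AssociationTable(kept)

    def __len__(self) -> int:
        return len(self.pairs)


def read_associations(path) -> AssociationTable:
    """Read a (ncRNA id, disease id) TSV; an optional third column is ignored."""
    pairs = set()
    with open(path) as fh:
        first = True
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if first:
                first = False
                if fields[0].strip().lower() in {"ncrna", "lncrna", "mirna", "rna", "id"}:
                    continue
            if len(fields) < 2:
                continue
            pairs.add((fields[0].strip(), fields[1].strip()))
    return AssociationTable(frozenset(pairs))


@dataclass
class NcrnaSimilarityNetwork:
    """ncRNA similarity matrix with z-scores and one-sided p-values."""

    sim: SimilarityMatrix
    zscores: np.ndarray
    pvalues: np.ndarray
    assoc: AssociationTable


def build_ncrna_similarity(
    assoc: AssociationTable, dissim: SimilarityMatrix
) -> NcrnaSimilarityNetwork:
    """Build the lncRNA/miRNA similarity network from disease similarity.

    sim(r1, r2) is the best-match-average disease-set similarity; z-scores
    standardise the pooled off-diagonal upper-triangle scores (population
    sd) and p-values are upper-tail standard-normal probabilities.
    """
    assoc = assoc.restrict_to_diseases(dissim.ids)
    ncrnas = assoc.ncrnas
    if not ncrnas:
        raise ValueError("no ncRNA has a resolvable disease association")
    disease_sets = {r: sorted(assoc.diseases_of(r)) for r in ncrnas}
    n = len(ncrnas)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = set_similarity(disease_sets[ncrnas[i]], disease_sets[ncrnas[j]], dissim)
            values[i, j] = values[j, i] = s
    iu = np.triu_indices(n, k=1)
    pooled = values[iu]
    mean, sd = float(pooled.mean()), float(pooled.std(ddof=0))
    if sd == 0.0:
        raise DegenerateNetworkError(
            "all pairwise ncRNA similarity scores are identical; "
            "z-scores are undefined"
        )
    zscores = (values - mean) / sd
    pvalues = norm.sf(zscores)
    return NcrnaSimilarityNetwork(
        sim=SimilarityMatrix(ncrnas, values),
        zscores=zscores,
        pvalues=pvalues,
        assoc=assoc,
    )


@dataclass(frozen=True)
class RWRConfig:
    """Random-walk-with-restart parameters.

    gamma
        Restart probability in (0, 1]; default 0.85.
    tol
        L1 convergence threshold on successive probability vectors.
    max_iter
        Iteration cap; exceeding it raises :class:`ConvergenceError`.
    """

    gamma: float = 0.85
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self):
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class ProbabilityVector:
    """Converged RWR state over ncRNA ids."""

    ids: tuple[str, ...]
    values: np.ndarray

    def get(self, entity: str) -> float:
        return float(self.values[self.ids.index(entity)])


def column_normalize(adjacency: np.ndarray) -> np.ndarray:
    """Divide each column by its sum; all-zero columns become uniform."""
    adjacency = np.asarray(adjacency, dtype=float)
    if np.any(adjacency < 0):
        raise ValueError("adjacency must be non-negative")
    colsum = adjacency.sum(axis=0)
    n = adjacency.shape[0]
    out = np.empty_like(adjacency)
    for j in range(adjacency.shape[1]):
        if colsum[j] > 0:
            out[:, j] = adjacency[:, j] / colsum[j]
        else:
            out[:, j] = 1.0 / n
    return out


def rwr(
    adjacency: SimilarityMatrix | np.ndarray,
    seeds: Iterable[str] | Iterable[int],
    cfg: RWRConfig | None = None,
    ids: Sequence[str] | None = None,
) -> ProbabilityVector:
    """Random walk with restart from uniform seed mass.

    ``adjacency`` may be a :class:`SimilarityMatrix` (seeds are ids) or a
    plain array (seeds are indices, unless ``ids`` maps them).  Iterates
    until the L1 difference between successive states drops below
    ``cfg.tol``.
    """
    cfg = cfg or RWRConfig()
    if isinstance(adjacency, SimilarityMatrix):
        ids = adjacency.ids
        matrix = adjacency.values
        seed_idx = [adjacency.index(s) for s in seeds]
    else:
        matrix = np.asarray(adjacency, dtype=float)
        ids = tuple(ids) if ids is not None else tuple(str(i) for i in range(matrix.shape[0]))
        id_pos = {e: i for i, e in enumerate(ids)}
        seed_idx = [s if isinstance(s, (int, np.integer)) else id_pos[s] for s in seeds]
    if not seed_idx:
        raise ValueError("at least one seed is required")
    A = column_normalize(matrix)
    n = A.shape[0]
    p0 = np.zeros(n)
    p0[list(seed_idx)] = 1.0 / len(seed_idx)
    p = p0.copy()
    for _ in range(cfg.max_iter):
        p_next = cfg.gamma * p0 + (1.0 - cfg.gamma) * (A @ p)
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < cfg.tol:
            return ProbabilityVector(tuple(ids), p)
    raise ConvergenceError(
        f"RWR did not converge in {cfg.max_iter} iterations", residual
    )


def _walk_adjacency(net: NcrnaSimilarityNetwork) -> np.ndarray:
    """Similarity matrix as a walk substrate: self-loops removed."""
    adj = net.sim.values.copy()
    np.fill_diagonal(adj, 0.0)
    return adj


def rank_candidates(
    disease: str,
    assoc: AssociationTable,
    net: NcrnaSimilarityNetwork,
    cfg: RWRConfig | None = None,
) -> list[tuple[str, float]]:
    """Rank non-seed ncRNAs for ``disease`` by RWR probability (descending).

    Seeds are the disease's known ncRNAs and never appear in the output;
    ties break by ncRNA id.
    """
    seeds = sorted(assoc.ncrnas_of(disease) & set(net.sim.ids))
    if not seeds:
        raise ValueError(f"disease {disease!r} has no associated ncRNA in the network")
    p = rwr(_walk_adjacency(net), seeds, cfg, ids=net.sim.ids)
    scores = dict(zip(p.ids, p.values))
    candidates = [r for r in net.sim.ids if r not in set(seeds)]
    return sorted(
        ((r, float(scores[r])) for r in candidates), key=lambda t: (-t[1], t[0])
    )


@dataclass(frozen=True)
class LOOCVTrial:
    ncrna: str
    disease: str
    score: float
    rank: int
    n_candidates: int


@dataclass
class LOOCVResult:
    trials: list[LOOCVTrial]
    labels: np.ndarray
    scores: np.ndarray
    auc: float


def loocv_auc(
    assoc: AssociationTable,
    net: NcrnaSimilarityNetwork,
    cfg: RWRConfig | None = None,
) -> LOOCVResult:
    """Leave-one-out cross-validation of RWR prioritisation.

    For each disease with at least two known ncRNAs and each of its
    associations (r, d): hold the pair out, seed with d's remaining ncRNAs,
    and score r against every ncRNA not associated with d.  Scores and
    labels are pooled across trials; the AUC is the Mann-Whitney estimator
    (ties count one half).
    """
    known = set(net.sim.ids)
    adj = _walk_adjacency(net)
    trials: list[LOOCVTrial] = []
    labels: list[int] = []
    scores: list[float] = []
    for d in sorted(assoc.diseases):
        assoc_rnas = sorted(assoc.ncrnas_of(d) & known)
        if len(assoc_rnas) < 2:
            continue
        for r in assoc_rnas:
            seeds = [s for s in assoc_rnas if s != r]
            p = rwr(adj, seeds, cfg, ids=net.sim.ids)
            score_of = dict(zip(p.ids, p.values))
            candidates = [c for c in net.sim.ids if c == r or c not in set(assoc_rnas)]
            ordered = sorted(candidates, key=lambda c: (-score_of[c], c))
            rank = ordered.index(r) + 1
            trials.append(
                LOOCVTrial(r, d, float(score_of[r]), rank, len(candidates))
            )
            for c in candidates:
                labels.append(1 if c == r else 0)
                scores.append(float(score_of[c]))
    if not trials:
        raise ValueError(
            "no eligible LOOCV trials (every disease has fewer than two ncRNAs)"
        )
    labels_arr = np.asarray(labels)
    scores_arr = np.asarray(scores)
    auc = roc_auc(scores_arr[labels_arr == 1], scores_arr[labels_arr == 0]).auc
    return LOOCVResult(trials, labels_arr, scores_arr, auc)
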