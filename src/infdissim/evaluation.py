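"""Evaluation protocols: benchmark-vs-random ROC/AUC and drug co-occurrence.

The benchmark protocol scores a curated set of similar disease pairs
against a random set ten times its size drawn from annotated-disease
pairs, builds the ROC curve, and repeats the experiment over independent
random sets (100 iterations in the original protocol), reporting the mean
AUC.  The drug analysis correlates disease similarity with the Jaccard
index of the diseases' drug sets (Pearson r, r-squared, two-sided p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr, rankdata
from sklearn.metrics import roc_curve

from .disease_similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkSet",
    "RocResult",
    "BenchmarkResult",
    "DrugAssociationTable",
    "CorrelationResult",
    "read_benchmark",
    "read_drug_associations",
    "jaccard",
    "sample_random_pairs",
    "roc_auc",
    "benchmark_evaluation",
    "drug_similarity_correlation",
]

Pair = tuple[str, str]


def _norm_pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class BenchmarkSet:
    """Curated positive (similar) disease pairs, stored unordered."""

    pairs: frozenset[Pair]

    def __post_init__(self):
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"benchmark pair may not be a self-pair: {a!r}")
            if a > b:
                raise ValueError("benchmark pairs must be normalised (a <= b)")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "BenchmarkSet":
        return cls(frozenset(_norm_pair(a, b) for a, b in pairs))

    @property
    def diseases(self) -> frozenset[str]:
        return frozenset(d for p in self.pairs for d in p)

    def __len__(self) -> int:
        return len(self.pairs)


def read_benchmark(path) -> BenchmarkSet:
    """Read a two-column TSV of similar disease pairs."""
    pairs = []
    with open(path) as fh:
        first = True
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if first:
                first = False
                if fields[0].strip().lower() in {"disease1", "disease_a", "id1"}:
                    continue
            if len(fields) < 2:
                continue
            pairs.append((fields[0].strip(), fields[1].strip()))
    return BenchmarkSet.from_pairs(pairs)


def sample_random_pairs(
    universe: Sequence[str],
    benchmark: BenchmarkSet,
    multiplier: int,
    seed: int | np.random.Generator,
) -> set[Pair]:
    """Sample ``multiplier * |benchmark|`` random disease pairs.

    Pairs are unordered, drawn uniformly without replacement from all
    pairs over ``universe``, and disjoint from the benchmark set.  Raises
    when the universe cannot supply enough pairs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = [
        p for p in combinations(sorted(set(universe)), 2) if p not in benchmark.pairs
    ]
    k = multiplier * len(benchmark)
    if k > len(eligible):
        raise ValueError(
            f"universe supplies only {len(eligible)} non-benchmark pairs, "
            f"need {k}"
        )
    chosen = rng.choice(len(eligible), size=k, replace=False)
    return {eligible[i] for i in chosen}


@dataclass
class RocResult:
    """AUC plus the ROC curve (FPR, TPR) from a threshold sweep."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


def roc_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> RocResult:
    """Mann-Whitney AUC (ties count one half) with the ROC curve.

    AUC = (#{(p, n): p > n} + 0.5 * #{p = n}) / (|pos| * |neg|).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (
        pos.size * neg.size
    )
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, _ = roc_curve(
        labels, np.concatenate([pos, neg]), drop_intermediate=False
    )
    return RocResult(float(auc), fpr, tpr)


@dataclass
class BenchmarkResult:
    aucs: np.ndarray
    mean_auc: float
    sd_auc: float


def benchmark_evaluation(
    scores: Mapping[Pair, float] | SimilarityMatrix,
    benchmark: BenchmarkSet,
    multiplier: int = 10,
    iterations: int = 100,
    seed: int = 0,
    universe: Sequence[str] | None = None,
    retry_cap: int = 1000,
) -> BenchmarkResult:
    """Benchmark-vs-random AUC, averaged over independent random sets.

    Each iteration draws a fresh random pair set from an independent
    substream of ``seed`` (so individual iterations are reproducible),
    scores it against the benchmark pairs and records the ROC AUC.  A
    sampled pair without a score is resampled (logged) up to ``retry_cap``
    times per iteration.
    """
    if isinstance(scores, SimilarityMatrix):
        matrix = scores
        universe = list(universe) if universe is not None else list(matrix.ids)

        def lookup(p: Pair) -> float | None:
            return matrix.get(*p) if p[0] in matrix and p[1] in matrix else None

    else:
        table = {_norm_pair(*k): v for k, v in scores.items()}
        universe = (
            list(universe)
            if universe is not None
            else sorted({d for p in table for d in p})
        )

        def lookup(p: Pair) -> float | None:
            return table.get(p)

    pos = []
    for p in sorted(benchmark.pairs):
        s = lookup(p)
        if s is None:
            raise ValueError(f"no similarity score for benchmark pair {p!r}")
        pos.append(s)

    streams = np.random.SeedSequence(seed).spawn(iterations)
    aucs = []
    for stream in streams:
        rng = np.random.default_rng(stream)
        sampled = sample_random_pairs(universe, benchmark, multiplier, rng)
        neg = []
        retries = 0
        for p in sorted(sampled):
            s = lookup(p)
            while s is None:
                retries += 1
                if retries > retry_cap:
                    raise ValueError("retry cap exceeded while resampling scored pairs")
                p = next(iter(sample_random_pairs(universe, benchmark, 1, rng)))
                s = lookup(p)
            neg.append(s)
        if retries:
            logger.warning("resampled %d unscored pairs", retries)
        aucs.append(roc_auc(pos, neg).auc)
    aucs_arr = np.asarray(aucs)
    return BenchmarkResult(aucs_arr, float(aucs_arr.mean()), float(aucs_arr.std(ddof=0)))


@dataclass(frozen=True)
class DrugAssociationTable:
    """Disease id -> set of therapeutic drug ids."""

    drugs: Mapping[str, frozenset[str]]

    def __post_init__(self):
        for d, ds in self.drugs.items():
            if not ds:
                raise ValueError(f"disease {d!r} retained with an empty drug set")

    def __contains__(self, disease: str) -> bool:
        return disease in self.drugs

    def get(self, disease: str) -> frozenset[str]:
        return self.drugs[disease]

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted(self.drugs))


def read_drug_associations(path) -> DrugAssociationTable:
    """Read a (disease id, drug id) TSV."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        first = True
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if first:
                first = False
                if fields[0].strip().lower() in {"disease", "disease_id", "doid"}:
                    continue
            if len(fields) < 2:
                continue
            table.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return DrugAssociationTable({d: frozenset(s) for d, s in table.items()})


def jaccard(a: Iterable, b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n_pairs: int


def drug_similarity_correlation(
    dissim: SimilarityMatrix, drugs: DrugAssociationTable
) -> CorrelationResult:
    """Pearson correlation of disease similarity with drug-set Jaccard overlap.

    The pair universe is every unordered pair of diseases present in both
    the similarity matrix and the drug table; needs at least 3 pairs and
    non-zero variance on both axes.
    """
    shared = sorted(set(dissim.ids) & set(drugs.diseases))
    pairs = list(combinations(shared, 2))
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} eligible disease pairs; need at least 3")
    x = np.array([dissim.get(a, b) for a, b in pairs])
    y = np.array([jaccard(drugs.get(a), drugs.get(b)) for a, b in pairs])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in similarity or drug-overlap scores")
    r, p = pearsonr(x, y)
    return CorrelationResult(float(r), float(r) ** 2, float(p), len(pairs))
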