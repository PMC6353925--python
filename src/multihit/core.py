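"""Weighted-set-cover discovery of multi-hit gene combinations.

The training tumor set is the universe; each candidate h-tuple of genes is
the subset of tumors carrying protein-altering mutations in *all* its genes.
Each candidate gets the weight

    w = (N_t + N_n) / (alpha * TP + TN)

over the currently active (unselected) samples, where TP is the number of
active tumors covered, TN the number of active normals *not* covered, and
0 <= alpha <= 1 trades sensitivity against specificity (default 0.1). Lower
weight means higher carcinogenic likelihood. The greedy approximation
repeatedly picks the minimum-weight candidate and retires the samples it
covers until every tumor is covered, so the training true-positive rate of a
complete run is exactly 1.0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortLabels, MutationMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class Combination:
    """An h-tuple of distinct genes with its counts and weight at selection."""

    genes: tuple[str, ...]
    weight: float
    counts: ConfusionCounts
    covered_tumors: frozenset[str]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("combination genes must be distinct")
        if tuple(sorted(self.genes)) != tuple(self.genes):
            raise ValueError("combination genes must be sorted")


@dataclass
class CoverSolution:
    """Ordered greedy selections with the per-iteration trace."""

    combinations: list[Combination]
    uncoverable: list[str] = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)

    @property
    def total_weight(self) -> float:
        return float(sum(c.weight for c in self.combinations))

    @property
    def gene_tuples(self) -> list[tuple[str, ...]]:
        return [c.genes for c in self.combinations]


@dataclass
class GreedyConfig:
    alpha: float = 0.1
    h: int = 2
    exclude_covered_normals: bool = True
    oracle_cap: int = 100_000  # max candidates exhaustive_best_step will score

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.h < 1:
            raise ValueError("h must be >= 1")


def covers(sample_row: np.ndarray, gene_idx: np.ndarray) -> bool:
    """True iff the sample has a 1 at every combination gene column."""
    if len(gene_idx) == 0:
        raise ValueError("combination must contain at least one gene")
    return bool(sample_row[gene_idx].all())


def covers_by_name(matrix: MutationMatrix, sample_id: str,
                   genes: tuple[str, ...]) -> bool:
    return covers(matrix.sample_row(sample_id), matrix.gene_indices(genes))


def coverage_vector(matrix: MutationMatrix, genes) -> np.ndarray:
    """Boolean vector over matrix samples: covered by all genes of the tuple."""
    idx = matrix.gene_indices(genes)
    return matrix.data[:, idx].all(axis=1)


def confusion_counts(genes, matrix: MutationMatrix, labels: CohortLabels,
                     active=None) -> ConfusionCounts:
    """TP/FP/TN/FN of one combination over the active samples.

    Tumors covered by every gene are TP, uncovered tumors FN; normals covered
    are FP, uncovered normals TN. An empty active set gives all-zero counts.
    """
    if active is None:
        active = matrix.samples
    active = list(active)
    if not active:
        return ConfusionCounts(0, 0, 0, 0)
    idx = matrix.sample_indices(active)
    cov = coverage_vector(matrix, genes)[idx]
    is_t = np.array([labels.is_tumor(s) for s in active])
    TP = int((cov & is_t).sum())
    FN = int((~cov & is_t).sum())
    FP = int((cov & ~is_t).sum())
    TN = int((~cov & ~is_t).sum())
    return ConfusionCounts(TP=TP, FP=FP, TN=TN, FN=FN)


def combination_weight(counts: ConfusionCounts, alpha: float,
                       n_active_tumor: int, n_active_normal: int) -> float:
    """Inverse accuracy weight (N_t + N_n)/(alpha*TP + TN); +inf if denominator 0."""
    n = n_active_tumor + n_active_normal
    if n < 1:
        raise ValueError("need at least one active sample")
    denom = alpha * counts.TP + counts.TN
    if denom == 0:
        return math.inf
    return n / denom


def enumerate_candidates(matrix: MutationMatrix, labels: CohortLabels,
                         active=None, h: int = 2):
    """Yield each sorted h-tuple of genes covering >= 1 active tumor.

    Tuples are produced at most once, in lexicographic order. Pruning to
    TP >= 1 is exact: a tuple covering no active tumor can never help the
    cover. Candidates are enumerated from the mutated gene sets of active
    tumor samples, so cost scales with observed mutations, not with C(G, h).
    """
    if h < 1:
        raise ValueError("h must be >= 1")
    if active is None:
        active = matrix.samples
    tumors = [s for s in active if labels.is_tumor(s)]
    seen: set[tuple[str, ...]] = set()
    for s in tumors:
        row = matrix.sample_row(s)
        genes = [g for g, v in zip(matrix.genes, row) if v]
        for combo in itertools.combinations(sorted(genes), h):
            seen.add(combo)
    yield from sorted(seen)


def _score(genes, matrix, labels, active, alpha):
    counts = confusion_counts(genes, matrix, labels, active)
    n_t = counts.TP + counts.FN
    n_n = counts.TN + counts.FP
    w = combination_weight(counts, alpha, n_t, n_n)
    return w, counts


def _better(cand, best):
    """Ordering on (weight, counts, genes): lower weight, then larger TP,
    then lexicographically smaller gene tuple."""
    w, counts, genes = cand
    bw, bcounts, bgenes = best
    if w != bw:
        return w < bw
    if counts.TP != bcounts.TP:
        return counts.TP > bcounts.TP
    return genes < bgenes


def exhaustive_best_step(matrix: MutationMatrix, labels: CohortLabels,
                         active, config: GreedyConfig) -> Combination:
    """Brute-force the minimum-weight candidate over the active samples.

    Test oracle for a single greedy iteration; refuses instances whose
    candidate count exceeds config.oracle_cap, and raises if every candidate
    has infinite weight.
    """
    candidates = list(enumerate_candidates(matrix, labels, active, config.h))
    if len(candidates) > config.oracle_cap:
        raise ValueError(
            f"{len(candidates)} candidates exceed oracle cap {config.oracle_cap}")
    best = None
    for genes in candidates:
        w, counts = _score(genes, matrix, labels, active, config.alpha)
        cand = (w, counts, genes)
        if best is None or _better(cand, best):
            best = cand
    if best is None or math.isinf(best[0]):
        raise ValueError("no usable candidate: all weights infinite or none cover a tumor")
    w, counts, genes = best
    cov = coverage_vector(matrix, genes)
    idx = matrix.sample_indices(active)
    covered_tumors = frozenset(
        s for s, c in zip(active, cov[idx]) if c and labels.is_tumor(s))
    return Combination(genes, w, counts, covered_tumors)


def greedy_cover(matrix: MutationMatrix, labels: CohortLabels,
                 config: GreedyConfig | None = None,
                 samples=None) -> CoverSolution:
    """Greedy weighted-set-cover over the given samples (default: all).

    Each iteration rescoring uses only the active (unselected) samples.
    Covered tumors are always retired; covered normals are retired too when
    config.exclude_covered_normals (default). Tumors with fewer than h
    mutated genes can never be covered: they are reported in
    solution.uncoverable and the run terminates with a partial cover rather
    than looping.
    """
    if config is None:
        config = GreedyConfig()
    if samples is None:
        samples = list(matrix.samples)
    labels.validate_matrix(matrix.subset_samples(samples))

    n_mut = {s: int(matrix.sample_row(s).sum()) for s in samples}
    uncoverable = [s for s in samples
                   if labels.is_tumor(s) and n_mut[s] < config.h]
    if uncoverable:
        log.warning("%d tumor samples have < %d mutated genes and cannot "
                    "be covered", len(uncoverable), config.h)
    active = [s for s in samples if s not in set(uncoverable)]

    solution = CoverSolution(combinations=[], uncoverable=uncoverable)
    while any(labels.is_tumor(s) for s in active):
        n_t = sum(1 for s in active if labels.is_tumor(s))
        n_n = len(active) - n_t
        best = None
        for genes in enumerate_candidates(matrix, labels, active, config.h):
            w, counts = _score(genes, matrix, labels, active, config.alpha)
            cand = (w, counts, genes)
            if best is None or _better(cand, best):
                best = cand
        if best is None:  # no candidate covers any active tumor
            solution.uncoverable.extend(
                s for s in active if labels.is_tumor(s))
            break
        w, counts, genes = best
        cov = coverage_vector(matrix, genes)
        idx = matrix.sample_indices(active)
        covered = {s for s, c in zip(active, cov[idx]) if c}
        covered_tumors = frozenset(s for s in covered if labels.is_tumor(s))
        combo = Combination(genes, w, counts, covered_tumors)
        solution.combinations.append(combo)
        solution.trace.append({
            "iteration": len(solution.combinations),
            "active_tumors": n_t,
            "active_normals": n_n,
            "genes": list(genes),
            "weight": w,
            "TP": counts.TP, "FP": counts.FP,
            "TN": counts.TN, "FN": counts.FN,
        })
        retire = {s for s in covered
                  if labels.is_tumor(s) or config.exclude_covered_normals}
        active = [s for s in active if s not in retire]
    return solution


def search_space_size(G: int, h_max: int) -> int:
    """Exact number of candidate combinations: sum_{c=2}^{h_max} C(G, c)."""
    if not G >= h_max >= 2:
        raise ValueError("need G >= h_max >= 2")
    return sum(math.comb(G, c) for c in range(2, h_max + 1))


def greedy_complexity(N: int, G: int, h_max: int) -> int:
    """The N*M product bounding the greedy algorithm's work."""
    return N * search_space_size(G, h_max)
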