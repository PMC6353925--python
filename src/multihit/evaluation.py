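"""Train/test partitioning and sensitivity/specificity evaluation.

A sample is predicted tumor when it is covered by (carries every gene of) at
least one discovered combination. Sensitivity is TP/(TP+FN) over tumor
samples, specificity TN/(TN+FP) over normal samples, with 95% Wilson score
intervals. Display rounding is half-up to integer percent; machine outputs
keep the raw proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .cohort import TEST, TRAIN, CohortLabels, MutationMatrix
from .core import ConfusionCounts, CoverSolution, coverage_vector


@dataclass(frozen=True)
class EvaluationResult:
    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None

    def as_dict(self) -> dict:
        return {
            "TP": self.counts.TP, "FP": self.counts.FP,
            "TN": self.counts.TN, "FN": self.counts.FN,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_ci": self.sensitivity_ci,
            "specificity_ci": self.specificity_ci,
        }


def stratified_split(labels: CohortLabels, train_fraction: float,
                     seed: int) -> CohortLabels:
    """Assign train/test independently within tumors and normals.

    Train size per stratum is round(n * fraction) (at least 1, at most n-1),
    deterministic given the seed. A stratum with fewer than 2 samples cannot
    be split and raises.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    partition: dict[str, str] = {}
    for stratum in (labels.tumors(), labels.normals()):
        if len(stratum) < 2:
            raise ValueError(
                f"stratum with {len(stratum)} samples cannot be split")
        n_train = int(round(train_fraction * len(stratum)))
        n_train = min(max(n_train, 1), len(stratum) - 1)
        order = rng.permutation(sorted(stratum))
        for i, s in enumerate(order):
            partition[s] = TRAIN if i < n_train else TEST
    return CohortLabels(dict(labels.status), partition,
                        dict(labels.cancer_type))


def predict_label(sample_row: np.ndarray, solution: CoverSolution,
                  matrix: MutationMatrix) -> str:
    """'tumor' iff the sample is covered by >= 1 selected combination."""
    for combo in solution.combinations:
        idx = matrix.gene_indices(combo.genes)
        if sample_row[idx].all():
            return "tumor"
    return "normal"


def _predicted_positive(solution: CoverSolution,
                        matrix: MutationMatrix) -> np.ndarray:
    pos = np.zeros(matrix.n_samples, dtype=bool)
    for combo in solution.combinations:
        pos |= coverage_vector(matrix, combo.genes)
    return pos


def evaluate(solution: CoverSolution, matrix: MutationMatrix,
             labels: CohortLabels, cohort: str | None = None,
             level: float = 0.95) -> EvaluationResult:
    """Confusion counts and sensitivity/specificity over one cohort.

    cohort is 'train', 'test', or None for every labeled sample in the
    matrix. A cohort with no tumors leaves sensitivity (and its CI) as None
    rather than 0; likewise for specificity with no normals.
    """
    if cohort is None:
        samples = list(matrix.samples)
    else:
        in_cohort = set(labels.cohort(cohort))
        samples = [s for s in matrix.samples if s in in_cohort]
    if not samples:
        raise ValueError("empty evaluation cohort")
    idx = matrix.sample_indices(samples)
    pos = _predicted_positive(solution, matrix)[idx]
    is_t = np.array([labels.is_tumor(s) for s in samples])
    counts = ConfusionCounts(
        TP=int((pos & is_t).sum()), FN=int((~pos & is_t).sum()),
        FP=int((pos & ~is_t).sum()), TN=int((~pos & ~is_t).sum()))
    sens = spec = sens_ci = spec_ci = None
    if counts.TP + counts.FN > 0:
        sens = counts.TP / (counts.TP + counts.FN)
        sens_ci = confidence_interval(counts.TP, counts.TP + counts.FN, level)
    if counts.TN + counts.FP > 0:
        spec = counts.TN / (counts.TN + counts.FP)
        spec_ci = confidence_interval(counts.TN, counts.TN + counts.FP, level)
    return EvaluationResult(counts, sens, spec, sens_ci, spec_ci)


def evaluate_by_type(solution_by_type: dict[str, CoverSolution],
                     matrix: MutationMatrix, labels: CohortLabels,
                     cohort: str | None = None) -> dict[str, EvaluationResult]:
    """Per-cancer-type evaluation plus a Total row from summed counts."""
    results: dict[str, EvaluationResult] = {}
    agg = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for ctype, solution in sorted(solution_by_type.items()):
        type_samples = {s for s, c in labels.cancer_type.items() if c == ctype}
        sub = matrix.subset_samples([s for s in matrix.samples
                                     if s in type_samples])
        res = evaluate(solution, sub, labels, cohort)
        results[ctype] = res
        for k in agg:
            agg[k] += getattr(res.counts, k)
    results["Total"] = result_from_counts(ConfusionCounts(**agg))
    return results


def result_from_counts(counts: ConfusionCounts,
                       level: float = 0.95) -> EvaluationResult:
    """EvaluationResult computed from raw confusion counts."""
    sens = spec = sens_ci = spec_ci = None
    if counts.TP + counts.FN > 0:
        sens = counts.TP / (counts.TP + counts.FN)
        sens_ci = confidence_interval(counts.TP, counts.TP + counts.FN, level)
    if counts.TN + counts.FP > 0:
        spec = counts.TN / (counts.TN + counts.FP)
        spec_ci = confidence_interval(counts.TN, counts.TN + counts.FP, level)
    return EvaluationResult(counts, sens, spec, sens_ci, spec_ci)


def confidence_interval(successes: int, n: int,
                        level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval (no continuity correction) for a proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def percent(x: float) -> int:
    """Half-up rounding to integer percent, for table display."""
    return int(math.floor(x * 100 + 0.5))
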