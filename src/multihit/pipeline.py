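"""End-to-end orchestration: split, discover, evaluate, analyse.

`run_pipeline` is the library entry point behind the CLI's composite `run`
command; it returns everything the reports are built from and is fully
deterministic given the config's seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import analysis
from .cohort import TEST, TRAIN, CohortLabels, MutationMatrix
from .core import CoverSolution, GreedyConfig, greedy_cover
from .evaluation import EvaluationResult, evaluate, percent, stratified_split


@dataclass
class RunConfig:
    alpha: float = 0.1
    h: int = 2
    exclude_covered_normals: bool = True
    train_fraction: float = 0.75
    seed: int = 0
    correlation_threshold: float = 0.25

    def greedy(self) -> GreedyConfig:
        return GreedyConfig(alpha=self.alpha, h=self.h,
                            exclude_covered_normals=self.exclude_covered_normals)


@dataclass
class RunResult:
    config: RunConfig
    labels: CohortLabels
    solution: CoverSolution
    train_eval: EvaluationResult
    test_eval: EvaluationResult
    statistics: analysis.CombinationStatistics
    correlations: list[dict] = field(default_factory=list)


def run_pipeline(matrix: MutationMatrix, labels: CohortLabels,
                 config: RunConfig | None = None) -> RunResult:
    """Split the cohort, run the greedy cover on the training samples, and
    evaluate the solution on both cohorts."""
    if config is None:
        config = RunConfig()
    labels = stratified_split(labels, config.train_fraction, config.seed)
    train = [s for s in matrix.samples if labels.partition.get(s) == TRAIN]
    solution = greedy_cover(matrix, labels, config.greedy(), samples=train)
    train_eval = evaluate(solution, matrix, labels, TRAIN)
    test_eval = evaluate(solution, matrix, labels, TEST)
    stats = analysis.combination_statistics(solution, matrix, labels)
    correlations = analysis.solution_correlations(
        solution, matrix, labels, threshold=config.correlation_threshold)
    return RunResult(config, labels, solution, train_eval, test_eval,
                     stats, correlations)


def write_reports(result: RunResult, outdir) -> None:
    """Serialise a run: config, solution table, trace, evaluation, analyses."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(result.config), fh, indent=2, sort_keys=True)

    rows = []
    for it, combo in enumerate(result.solution.combinations, start=1):
        c = combo.counts
        rows.append({"iteration": it, "genes": "+".join(combo.genes),
                     "TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN,
                     "weight": combo.weight})
    pd.DataFrame(rows).to_csv(outdir / "solution.tsv", sep="\t", index=False)
    with open(outdir / "trace.json", "w") as fh:
        json.dump(result.solution.trace, fh, indent=2)

    evaluation = {
        "train": result.train_eval.as_dict(),
        "test": result.test_eval.as_dict(),
        "train_sensitivity_pct": percent(result.train_eval.sensitivity)
        if result.train_eval.sensitivity is not None else None,
        "test_sensitivity_pct": percent(result.test_eval.sensitivity)
        if result.test_eval.sensitivity is not None else None,
        "test_specificity_pct": percent(result.test_eval.specificity)
        if result.test_eval.specificity is not None else None,
        "uncoverable_samples": result.solution.uncoverable,
    }
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(evaluation, fh, indent=2, sort_keys=True)

    stats = result.statistics
    with open(outdir / "combination_statistics.json", "w") as fh:
        json.dump({
            "occurrence": {"+".join(k): v for k, v in stats.occurrence.items()},
            "histogram": {str(k): v for k, v in stats.histogram.items()},
            "multi_combination_fraction": stats.multi_combination_fraction,
        }, fh, indent=2, sort_keys=True)
    pd.DataFrame(result.correlations).to_csv(
        outdir / "correlations.tsv", sep="\t", index=False)
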