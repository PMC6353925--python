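"""Post-hoc analyses of a cover solution.

Three questions about a discovered combination set:

* are the genes inside each combination statistically independent in the
  normal cohort (Pearson correlation of their binary mutation vectors), and
  do they sit on different chromosomes — both checks that a combination is
  not an artifact of a shared background cause;
* how often does each combination occur in tumors, and how many tumors carry
  several combinations (a signature that 2-hit pairs are subsets of deeper
  combinations);
* within a combination's genes, which mutated positions are tumor-exclusive
  (candidate drivers) versus shared with normals (candidate passengers).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import NORMAL, TUMOR, CohortLabels, MutationMatrix
from .core import CoverSolution, coverage_vector
from .io_maf import VariantRecord, is_protein_altering

log = logging.getLogger(__name__)


def gene_vector(matrix: MutationMatrix, labels: CohortLabels, gene: str,
                cohort: str = NORMAL) -> np.ndarray:
    """Binary mutation-status vector for one gene over one cohort's samples."""
    members = labels.normals() if cohort == NORMAL else labels.tumors()
    members = [s for s in matrix.samples if s in set(members)]
    idx = matrix.sample_indices(members)
    return matrix.gene_column(gene)[idx]


def pearson_correlation(v1: np.ndarray, v2: np.ndarray) -> float:
    """Pearson r between two equal-length binary vectors.

    A zero-variance vector makes r undefined; returns NaN with a warning
    rather than 0, since 0 would assert independence that was never measured.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1 or len(v1) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if v1.std() == 0 or v2.std() == 0:
        log.warning("zero-variance vector: correlation undefined")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, _ = stats.pearsonr(v1, v2)
    return float(r)


def solution_correlations(solution: CoverSolution, matrix: MutationMatrix,
                          labels: CohortLabels, cohort: str = NORMAL,
                          threshold: float = 0.25) -> list[dict]:
    """Pairwise Pearson r for the genes inside each combination.

    Computed over normal samples by default. Pairs with |r| >= threshold
    (default 0.25) are flagged as correlated.
    """
    rows = []
    for combo in solution.combinations:
        for i, g1 in enumerate(combo.genes):
            for g2 in combo.genes[i + 1:]:
                r = pearson_correlation(
                    gene_vector(matrix, labels, g1, cohort),
                    gene_vector(matrix, labels, g2, cohort))
                rows.append({
                    "combination": "+".join(combo.genes),
                    "gene1": g1, "gene2": g2, "pearson_r": r,
                    "correlated": bool(abs(r) >= threshold)
                    if not np.isnan(r) else None,
                })
    return rows


@dataclass
class CombinationStatistics:
    occurrence: dict[tuple[str, ...], float]  # fraction of tumors covered
    histogram: dict[int, int]                 # combinations-per-tumor counts
    multi_combination_fraction: float         # tumors with >= 2 combinations


def combination_statistics(solution: CoverSolution, matrix: MutationMatrix,
                           labels: CohortLabels) -> CombinationStatistics:
    """Occurrence and overlap of combinations across the tumor cohort.

    Occurrence fractions may sum above 1 because one tumor can carry several
    combinations; the histogram counts, per tumor, how many combinations it
    contains, and always sums to the tumor count.
    """
    if not solution.combinations:
        raise ValueError("solution is empty")
    tumors = [s for s in matrix.samples if labels.is_tumor(s)]
    idx = matrix.sample_indices(tumors)
    per_tumor = np.zeros(len(tumors), dtype=int)
    occurrence = {}
    for combo in solution.combinations:
        cov = coverage_vector(matrix, combo.genes)[idx]
        occurrence[combo.genes] = float(cov.mean()) if len(tumors) else 0.0
        per_tumor += cov.astype(int)
    histogram = dict(sorted(Counter(per_tumor.tolist()).items()))
    multi = float((per_tumor >= 2).mean()) if len(tumors) else 0.0
    return CombinationStatistics(occurrence, histogram, multi)


def chromosome_colocation(solution: CoverSolution,
                          locations: dict[str, str]) -> dict:
    """Flag combinations whose genes all share one chromosome.

    Combinations with a gene missing from the location table are flagged
    unknown and excluded from the same-chromosome summary count.
    """
    flags: dict[tuple[str, ...], bool | None] = {}
    for combo in solution.combinations:
        chroms = []
        missing = [g for g in combo.genes if g not in locations]
        if missing:
            log.warning("no chromosome location for %s; combination %s "
                        "excluded from co-location summary",
                        ", ".join(missing), "+".join(combo.genes))
            flags[combo.genes] = None
            continue
        chroms = [locations[g] for g in combo.genes]
        flags[combo.genes] = len(set(chroms)) == 1
    return {
        "flags": flags,
        "n_same_chromosome": sum(1 for v in flags.values() if v is True),
        "n_known": sum(1 for v in flags.values() if v is not None),
    }


def read_gene_locations(path) -> dict[str, str]:
    """Gene -> chromosome from a TSV with columns gene, chromosome[, start, end]."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene" not in df.columns or "chromosome" not in df.columns:
        raise ValueError("location table needs columns gene and chromosome")
    return dict(zip(df["gene"], df["chromosome"]))


@dataclass
class LocusProfile:
    """Per-position variant counts in a gene, tumors vs normals, restricted
    to samples covered by one combination.

    Positions are (chromosome, 1-based position) pairs — a genomic proxy for
    protein residue positions, since consequence re-annotation is out of
    scope here.
    """

    gene: str
    combination: tuple[str, ...]
    tumor_counts: dict[tuple[str, int], int] = field(default_factory=dict)
    normal_counts: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def tumor_exclusive(self) -> set[tuple[str, int]]:
        return set(self.tumor_counts) - set(self.normal_counts)

    @property
    def normal_exclusive(self) -> set[tuple[str, int]]:
        return set(self.normal_counts) - set(self.tumor_counts)

    @property
    def shared(self) -> set[tuple[str, int]]:
        return set(self.tumor_counts) & set(self.normal_counts)


def locus_contrast(gene: str, combination: tuple[str, ...],
                   records: list[VariantRecord], matrix: MutationMatrix,
                   labels: CohortLabels) -> LocusProfile:
    """Contrast per-position mutations of one combination gene across cohorts.

    Restricts to samples covered by the combination, then tabulates
    protein-altering variant counts per genomic position separately for
    tumor and normal samples. Tumor-exclusive positions are candidate driver
    loci; positions mutated in both cohorts are candidate passengers.
    """
    if gene not in combination:
        raise ValueError(f"{gene} is not part of {'+'.join(combination)}")
    cov = coverage_vector(matrix, combination)
    covered = {s for s, c in zip(matrix.samples, cov) if c}
    profile = LocusProfile(gene=gene, combination=tuple(combination))
    for rec in records:
        if rec.gene != gene or rec.sample_id not in covered:
            continue
        if not is_protein_altering(rec.variant_classification):
            continue
        key = (rec.chromosome, rec.position)
        target = (profile.tumor_counts if labels.is_tumor(rec.sample_id)
                  else profile.normal_counts)
        target[key] = target.get(key, 0) + 1
    return profile
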