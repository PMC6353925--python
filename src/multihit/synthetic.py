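"""Synthetic tumor/normal cohorts with planted multi-hit combinations.

The generator emulates the structure the discovery algorithm assumes: each
tumor carries one planted h-gene combination (all its genes mutated), and
with probability ``p_multi`` a second one — mimicking tumors that contain
multiple combinations. Every sample, tumor and normal alike, additionally
receives independent passenger (background) mutations at per-gene rate
``p_bg``. Normals never receive a planted combination. Defaults reflect a
desk-scale study cohort: 60 genes, 5 disjoint planted pairs, 80 tumors and
60 normals with a 5% passenger rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import NORMAL, TUMOR, CohortLabels, MutationMatrix

#: Classifications cycled through when materialising a matrix as MAF rows.
_MAF_CLASSES = ("Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
                "Frame_Shift_Ins", "In_Frame_Del")


@dataclass
class PlantedModel:
    """Generative model for a cohort with planted combinations.

    G : number of genes; K : number of planted combinations of h genes each
    (K*h <= G, tuples disjoint); n_t, n_n : tumor / normal sample counts;
    p_bg : per-sample per-gene passenger mutation probability; p_multi :
    probability a tumor carries a second planted combination; weights :
    assignment probabilities over the K combinations (uniform by default).
    """

    G: int = 60
    K: int = 5
    h: int = 2
    n_t: int = 80
    n_n: int = 60
    p_bg: float = 0.05
    p_multi: float = 0.2
    weights: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K * self.h > self.G:
            raise ValueError(
                f"cannot plant {self.K} disjoint {self.h}-tuples in {self.G} genes")
        if not (0 <= self.p_bg <= 1 and 0 <= self.p_multi <= 1):
            raise ValueError("p_bg and p_multi must be probabilities")
        if self.weights is not None and len(self.weights) != self.K:
            raise ValueError("weights must have length K")

    def gene_names(self) -> list[str]:
        width = len(str(self.G))
        return [f"G{i:0{width}d}" for i in range(1, self.G + 1)]


def planted_combinations(model: PlantedModel,
                         rng: np.random.Generator) -> list[tuple[str, ...]]:
    """Draw K disjoint sorted h-tuples of gene symbols."""
    genes = model.gene_names()
    chosen = rng.choice(model.G, size=model.K * model.h, replace=False)
    tuples = []
    for k in range(model.K):
        block = chosen[k * model.h:(k + 1) * model.h]
        tuples.append(tuple(sorted(genes[i] for i in block)))
    return sorted(tuples)


def simulate_cohort(model: PlantedModel):
    """Simulate (matrix, labels, truth) from a planted model.

    truth maps each tumor sample to the list of planted combinations it
    carries. Gene columns mutated in no sample are dropped so a cohort
    round-trips exactly through MAF serialisation and matrix rebuilding.
    Deterministic given model.seed.
    """
    rng = np.random.default_rng(model.seed)
    genes = model.gene_names()
    combos = planted_combinations(model, rng)
    if model.K > 0:
        weights = model.weights
        if weights is None:
            weights = [1.0 / model.K] * model.K
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    else:
        w = np.zeros(0)

    t_width = len(str(max(model.n_t, model.n_n)))
    tumor_ids = [f"T{i:0{t_width}d}" for i in range(1, model.n_t + 1)]
    normal_ids = [f"N{i:0{t_width}d}" for i in range(1, model.n_n + 1)]
    samples = tumor_ids + normal_ids
    gcol = {g: j for j, g in enumerate(genes)}

    data = (rng.random((len(samples), model.G)) < model.p_bg).astype(np.int8)
    truth: dict[str, list[tuple[str, ...]]] = {}
    for i, s in enumerate(tumor_ids):
        if model.K == 0:
            truth[s] = []
            continue
        picks = [int(rng.choice(model.K, p=w))]
        if model.K > 1 and rng.random() < model.p_multi:
            second = int(rng.choice(model.K, p=w))
            if second != picks[0]:
                picks.append(second)
        truth[s] = [combos[k] for k in sorted(picks)]
        for combo in truth[s]:
            for g in combo:
                data[i, gcol[g]] = 1

    status = {s: TUMOR for s in tumor_ids}
    status.update({s: NORMAL for s in normal_ids})
    labels = CohortLabels(status)
    # sorted sample order matches build_mutation_matrix, so a cohort
    # round-trips through MAF serialisation to an identical matrix
    order = np.argsort(samples)
    matrix = MutationMatrix([samples[i] for i in order], genes,
                            data[order]).drop_empty_genes()
    return matrix, labels, truth


# deterministic per-gene pseudo-coordinates for MAF serialisation
def _gene_locus(gene: str, gene_rank: int) -> tuple[str, int]:
    chrom = str(gene_rank % 22 + 1)
    position = 1_000_000 + 10_000 * gene_rank
    return chrom, position


def gene_location_table(matrix: MutationMatrix) -> pd.DataFrame:
    """Synthetic gene -> chromosome table matching write_maf's coordinates."""
    rows = []
    for rank, g in enumerate(matrix.genes):
        chrom, pos = _gene_locus(g, rank)
        rows.append({"gene": g, "chromosome": chrom,
                     "start": pos, "end": pos + 5_000})
    return pd.DataFrame(rows)


def write_maf(matrix: MutationMatrix, path) -> None:
    """Serialise a matrix as a MAF-dialect file, one row per incidence.

    Each (sample, gene) = 1 cell becomes one variant row with a
    protein-altering classification chosen deterministically from the gene's
    rank, and deterministic synthetic coordinates, so reading the file back
    and rebuilding the matrix reproduces it exactly.
    """
    rows = ["#version synthetic",
            "\t".join(("Hugo_Symbol", "Chromosome", "Start_Position",
                       "Variant_Classification", "Tumor_Sample_Barcode"))]
    for i, s in enumerate(matrix.samples):
        for rank, g in enumerate(matrix.genes):
            if matrix.data[i, rank]:
                chrom, pos = _gene_locus(g, rank)
                cls = _MAF_CLASSES[rank % len(_MAF_CLASSES)]
                rows.append("\t".join((g, chrom, str(pos), cls, s)))
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
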