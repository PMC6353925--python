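"""Reading MAF-dialect variant tables and building mutation matrices.

The input is the tab-separated mutation annotation format (MAF) dialect used
for somatic calls: one row per variant with at least the columns
``Hugo_Symbol``, ``Chromosome``, ``Start_Position``, ``Variant_Classification``
and ``Tumor_Sample_Barcode``. Lines starting with ``#`` are comments. Only
protein-altering variants (missense, nonsense, exonic indels, ...) count
toward the binary gene-level incidence matrix; everything else (silent,
intronic, UTR, ...) is filtered out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cohort import CohortLabels, MutationMatrix

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
)

#: MAF Variant_Classification terms treated as protein-altering.
#: Splice_Site is excluded: the filter is exon/protein-centric. The set is a
#: module-level default; pass `vocabulary=` to override.
PROTEIN_ALTERING = frozenset(
    s.lower()
    for s in (
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Translation_Start_Site",
    )
)

NON_PROTEIN_ALTERING = frozenset(
    s.lower()
    for s in (
        "Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank",
        "IGR", "RNA", "Splice_Site",
    )
)


class MafFormatError(ValueError):
    """A MAF-dialect file violates the expected layout."""


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant call.

    position is the 1-based genomic start coordinate (MAF convention);
    chromosome labels are kept verbatim.
    """

    sample_id: str
    gene: str
    chromosome: str
    position: int
    variant_classification: str
    is_tumor: bool

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.gene:
            raise ValueError("gene symbol is empty")


def is_protein_altering(variant_classification: str,
                        vocabulary: frozenset[str] = PROTEIN_ALTERING) -> bool:
    """True iff the classification denotes a protein-altering variant.

    Matching is case-insensitive; unrecognised terms return False.
    """
    return variant_classification.strip().lower() in vocabulary


def read_variant_table(path, is_tumor: bool) -> list[VariantRecord]:
    """Parse a MAF-dialect file into VariantRecords, preserving row order.

    Raises MafFormatError naming the first missing required column. An empty
    file (header only, or nothing) yields an empty list with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise MafFormatError(f"missing required column: {col}")
    if df.empty:
        log.warning("no variant rows in %s", path)
        return []
    records = []
    for row in df.itertuples(index=False):
        records.append(
            VariantRecord(
                sample_id=row.Tumor_Sample_Barcode,
                gene=row.Hugo_Symbol,
                chromosome=row.Chromosome,
                position=int(row.Start_Position),
                variant_classification=row.Variant_Classification,
                is_tumor=is_tumor,
            )
        )
    return records


def build_mutation_matrix(records: list[VariantRecord], labels: CohortLabels,
                          vocabulary: frozenset[str] = PROTEIN_ALTERING,
                          ) -> MutationMatrix:
    """Collapse protein-altering records into a binary sample x gene matrix.

    Entry (s, g) is 1 iff at least one protein-altering record maps sample s
    to gene g; repeated variants collapse to the same 1. Genes mutated in no
    sample are dropped. Samples and genes are sorted for determinism. Every
    record's sample must be labeled; samples that are labeled but have no
    qualifying variant still appear as all-zero rows only if present in
    `labels.status` AND in the records — unseen samples are added as zero
    rows so the cohort stays complete.
    """
    unrecognised: dict[str, int] = {}
    pairs: set[tuple[str, str]] = set()
    seen_samples: set[str] = set()
    for rec in records:
        if rec.sample_id not in labels.status:
            raise ValueError(f"unlabeled sample barcode: {rec.sample_id}")
        seen_samples.add(rec.sample_id)
        cls = rec.variant_classification.strip().lower()
        if cls in vocabulary:
            pairs.add((rec.sample_id, rec.gene))
        elif cls not in NON_PROTEIN_ALTERING:
            unrecognised[rec.variant_classification] = (
                unrecognised.get(rec.variant_classification, 0) + 1)
    if unrecognised:
        log.warning("unrecognised variant classifications treated as "
                    "non-protein-altering: %s", unrecognised)

    samples = sorted(labels.status)
    genes = sorted({g for _, g in pairs})
    import numpy as np
    data = np.zeros((len(samples), len(genes)), dtype=np.int8)
    srow = {s: i for i, s in enumerate(samples)}
    gcol = {g: j for j, g in enumerate(genes)}
    for s, g in pairs:
        data[srow[s], gcol[g]] = 1
    return MutationMatrix(samples, genes, data)
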