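"""Core in-memory containers: the binary mutation matrix and cohort labels.

A cohort is represented by two objects: a :class:`MutationMatrix` holding the
samples x genes incidence of protein-altering somatic mutations (entry 1 iff
the sample carries at least one qualifying variant in the gene), and a
:class:`CohortLabels` mapping each sample to its tumor/normal status and,
optionally, to a train/test partition and a cancer type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
TRAIN = "train"
TEST = "test"


@dataclass
class MutationMatrix:
    """Binary sample x gene incidence matrix.

    Parameters
    ----------
    samples : list of str
        Ordered, duplicate-free sample barcodes (rows).
    genes : list of str
        Ordered, duplicate-free gene symbols (columns).
    data : ndarray of shape (n_samples, n_genes)
        0/1 incidence; entry (i, j) is 1 iff sample i carries at least one
        protein-altering variant in gene j.
    """

    samples: list[str]
    genes: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.samples), len(self.genes)):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._gene_index = {g: j for j, g in enumerate(self.genes)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def sample_row(self, sample_id: str) -> np.ndarray:
        return self.data[self._sample_index[sample_id]]

    def gene_column(self, gene: str) -> np.ndarray:
        try:
            return self.data[:, self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_indices(self, genes) -> np.ndarray:
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes not in matrix: {', '.join(missing)}")
        return np.array([self._gene_index[g] for g in genes], dtype=np.intp)

    def sample_indices(self, samples) -> np.ndarray:
        return np.array([self._sample_index[s] for s in samples], dtype=np.intp)

    def subset_samples(self, samples) -> "MutationMatrix":
        idx = self.sample_indices(samples)
        return MutationMatrix(list(samples), list(self.genes), self.data[idx])

    def drop_empty_genes(self) -> "MutationMatrix":
        """Drop gene columns mutated in no sample."""
        keep = self.data.sum(axis=0) > 0
        return MutationMatrix(
            list(self.samples),
            [g for g, k in zip(self.genes, keep) if k],
            self.data[:, keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.samples, columns=self.genes)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "MutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, MutationMatrix):
            return NotImplemented
        return (self.samples == other.samples and self.genes == other.genes
                and np.array_equal(self.data, other.data))


@dataclass
class CohortLabels:
    """Per-sample tumor/normal status, optional train/test split and cancer type."""

    status: dict[str, str]
    partition: dict[str, str] = field(default_factory=dict)
    cancer_type: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.status.values()} - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"invalid status values: {sorted(bad)}")
        bad = {v for v in self.partition.values()} - {TRAIN, TEST}
        if bad:
            raise ValueError(f"invalid partition values: {sorted(bad)}")

    @property
    def n_tumor(self) -> int:
        return sum(1 for v in self.status.values() if v == TUMOR)

    @property
    def n_normal(self) -> int:
        return sum(1 for v in self.status.values() if v == NORMAL)

    def is_tumor(self, sample_id: str) -> bool:
        return self.status[sample_id] == TUMOR

    def tumors(self) -> list[str]:
        return [s for s, v in self.status.items() if v == TUMOR]

    def normals(self) -> list[str]:
        return [s for s, v in self.status.items() if v == NORMAL]

    def cohort(self, which: str) -> list[str]:
        """Samples assigned to partition `which` ('train' or 'test')."""
        if which not in (TRAIN, TEST):
            raise ValueError(f"unknown cohort {which!r}")
        return [s for s, v in self.partition.items() if v == which]

    def validate_matrix(self, matrix: MutationMatrix) -> None:
        missing = [s for s in matrix.samples if s not in self.status]
        if missing:
            raise ValueError(f"unlabeled samples: {', '.join(missing[:5])}")

    def to_tsv(self, path) -> None:
        rows = []
        for s, st in self.status.items():
            rows.append({
                "sample_id": s,
                "status": st,
                "partition": self.partition.get(s, ""),
                "cancer_type": self.cancer_type.get(s, ""),
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CohortLabels":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        if "sample_id" not in df.columns or "status" not in df.columns:
            raise ValueError("labels file needs columns sample_id and status")
        status = dict(zip(df["sample_id"], df["status"]))
        partition = {}
        if "partition" in df.columns:
            partition = {s: p for s, p in zip(df["sample_id"], df["partition"]) if p}
        cancer_type = {}
        if "cancer_type" in df.columns:
            cancer_type = {s: c for s, c in zip(df["sample_id"], df["cancer_type"]) if c}
        return cls(status, partition, cancer_type)
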