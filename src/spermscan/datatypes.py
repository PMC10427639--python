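"""Shared in-memory containers for the spermatogenesis pipeline.

The pipeline moves three core objects between stages: a sparse UMI count
matrix with cell barcodes and gene identifiers (:class:`UmiMatrix`), a map
from gene to chromosome arm and chromosome class (:class:`GeneAnnotation`),
and a hard partition of cells into clusters with an optional developmental
stage order (:class:`ClusterAssignment`).

Counts are stored cells x genes (rows = cells) throughout; the on-disk
10x orientation (genes x cells) is handled at the I/O boundary only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Chromosome arms making up the autosomal complement.
AUTOSOME_ARMS = ("2R", "2L", "3R", "3L")

#: All recognised arm labels. Unplaced Y contigs are collapsed to "Y".
KNOWN_ARMS = AUTOSOME_ARMS + ("X", "Y", "MT")

#: Chromosome classes used by the dosage analysis.
CLASSES = ("autosome", "X", "Y", "MT")

_ARM_TO_CLASS = {arm: "autosome" for arm in AUTOSOME_ARMS}
_ARM_TO_CLASS.update({"X": "X", "Y": "Y", "MT": "MT"})


def arm_to_class(arm: str) -> str:
    """Map a chromosome-arm label to its class (autosome/X/Y/MT/UNKNOWN)."""
    return _ARM_TO_CLASS.get(arm, "UNKNOWN")


@dataclass
class UmiMatrix:
    """Sparse cells x genes UMI count matrix.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, rows = cells, columns = genes.
    barcodes
        Unique cell barcodes, one per row.
    gene_ids
        Unique gene identifiers, one per column.
    """

    counts: sp.csr_matrix
    barcodes: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n, g = self.counts.shape
        if n != len(self.barcodes):
            raise ValueError(
                f"matrix has {n} rows but {len(self.barcodes)} barcodes"
            )
        if g != len(self.gene_ids):
            raise ValueError(
                f"matrix has {g} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate cell barcodes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if data.size and np.any(data != np.round(data)):
                raise ValueError("non-integer counts")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def genes_detected_per_cell(self) -> np.ndarray:
        """Number of genes with count >= 1 in each cell."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def depth_per_cell(self) -> np.ndarray:
        """Total UMI count per cell."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def counts_per_gene(self) -> np.ndarray:
        """Total UMI count per gene across all cells."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, index: np.ndarray) -> "UmiMatrix":
        return UmiMatrix(self.counts[index], self.barcodes[index], self.gene_ids)

    def subset_genes(self, index: np.ndarray) -> "UmiMatrix":
        return UmiMatrix(self.counts[:, index], self.barcodes, self.gene_ids[index])

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class GeneAnnotation:
    """Gene -> chromosome arm mapping with derived chromosome class.

    Arms outside :data:`KNOWN_ARMS` are preserved but classed as UNKNOWN.
    """

    arms: pd.Series  # index: gene_id, values: arm label

    def __post_init__(self) -> None:
        self.arms = pd.Series(self.arms, dtype=object)
        if self.arms.index.has_duplicates:
            dup = self.arms[self.arms.index.duplicated(keep=False)]
            conflicting = dup.groupby(level=0).nunique()
            if (conflicting > 1).any():
                bad = conflicting[conflicting > 1].index.tolist()
                raise ValueError(f"conflicting arms for gene(s) {bad}")
            self.arms = self.arms[~self.arms.index.duplicated()]

    @classmethod
    def from_mapping(cls, mapping) -> "GeneAnnotation":
        return cls(pd.Series(dict(mapping), dtype=object))

    def arm_of(self, gene_ids) -> np.ndarray:
        """Arm label per gene; genes absent from the annotation are UNKNOWN."""
        out = self.arms.reindex(np.asarray(gene_ids, dtype=object)).to_numpy(object)
        missing = pd.isna(out)
        if missing.any():
            out[missing] = "UNKNOWN"
        return out.astype(object)

    def class_of(self, gene_ids) -> np.ndarray:
        """Chromosome class (autosome/X/Y/MT/UNKNOWN) per gene."""
        arms = self.arm_of(gene_ids)
        return np.array([arm_to_class(a) for a in arms], dtype=object)


@dataclass
class ClusterAssignment:
    """Hard partition of cells into clusters labelled 1..k.

    ``stage_order``, when present, lists the cluster labels in developmental
    order and drives every "consecutive cluster" comparison downstream.
    """

    labels: pd.Series  # index: barcode, values: int label in 1..k
    k: int
    stage_order: list[int] | None = None
    inertia: float | None = None
    run_inertias: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels).astype(int)
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate barcodes in cluster assignment")
        observed = set(self.labels.unique())
        if not observed <= set(range(1, self.k + 1)):
            raise ValueError(f"labels {sorted(observed)} outside 1..{self.k}")
        if self.stage_order is not None:
            if sorted(self.stage_order) != list(range(1, self.k + 1)):
                raise ValueError("stage_order must be a permutation of 1..k")

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    def sizes(self) -> pd.Series:
        """Cluster sizes indexed by label, including empty labels."""
        counts = self.labels.value_counts()
        return counts.reindex(range(1, self.k + 1), fill_value=0).sort_index()

    def labels_for(self, barcodes) -> np.ndarray:
        """Labels aligned to the given barcode order; raises on missing cells."""
        aligned = self.labels.reindex(np.asarray(barcodes, dtype=object))
        if aligned.isna().any():
            missing = aligned.index[aligned.isna()].tolist()[:5]
            raise ValueError(f"cluster labels missing for cells, e.g. {missing}")
        return aligned.to_numpy(int)

    def ordered_labels(self) -> list[int]:
        """Stage order if set, else ascending label order (with a warning)."""
        if self.stage_order is not None:
            return list(self.stage_order)
        warnings.warn("no stage_order set; using ascending label order")
        return list(range(1, self.k + 1))
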