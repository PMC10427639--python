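"""Inclusion filters and QC summaries for the count matrix.

Filters mirror the dataset's stated inclusion rules: cells expressing at
least ``min_genes`` distinct genes are retained, then genes expressed in
at least one (retained) cell. A separate cluster-aware gene filter keeps
genes detected in at least one cell cluster; when the clustering
partitions all cells it coincides with the plain gene filter, but it is
exposed on its own because the chromosome-level analysis states it as its
own inclusion rule.

All filters preserve cell/gene order, are idempotent, and never alter
retained counts. The fixed composition order is cells first, then genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import ClusterAssignment, UmiMatrix

log = logging.getLogger(__name__)


@dataclass
class QcSummary:
    n_cells: int
    n_genes: int
    median_genes_per_cell: float
    total_umi: int
    genes_per_cell: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_genes": self.n_genes,
            "median_genes_per_cell": self.median_genes_per_cell,
            "total_umi": self.total_umi,
        }


def filter_cells_min_genes(m: UmiMatrix, min_genes: int = 200) -> UmiMatrix:
    """Retain cells detecting at least ``min_genes`` distinct genes (>=)."""
    if min_genes < 0:
        raise ValueError("min_genes must be non-negative")
    detected = m.genes_detected_per_cell()
    keep = detected >= min_genes
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("cell filter: removed %d / %d cells below %d genes",
                 n_removed, m.n_cells, min_genes)
    if not keep.any():
        log.warning("cell filter removed every cell (min_genes=%d)", min_genes)
    return m.subset_cells(np.flatnonzero(keep))


def filter_genes_expressed(m: UmiMatrix) -> UmiMatrix:
    """Retain genes with at least one UMI in at least one cell."""
    keep = m.counts_per_gene() >= 1
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("gene filter: removed %d / %d undetected genes",
                 n_removed, m.n_genes)
    return m.subset_genes(np.flatnonzero(keep))


def filter_genes_cluster_expressed(
    m: UmiMatrix, clusters: ClusterAssignment
) -> UmiMatrix:
    """Retain genes with at least one UMI summed within some cluster.

    Raises if any matrix cell lacks a cluster label. Equals
    :func:`filter_genes_expressed` whenever the clusters partition all
    cells, but is the analysis-specific threshold for the dosage stage.
    """
    labels = clusters.labels_for(m.barcodes)  # raises on missing cells
    keep = np.zeros(m.n_genes, dtype=bool)
    for lab in np.unique(labels):
        in_cluster = np.flatnonzero(labels == lab)
        cluster_total = np.asarray(m.counts[in_cluster].sum(axis=0)).ravel()
        keep |= cluster_total >= 1
    return m.subset_genes(np.flatnonzero(keep))


def qc_summary(m: UmiMatrix) -> QcSummary:
    """Cell/gene counts, total UMI mass, and median genes detected per cell."""
    detected = m.genes_detected_per_cell()
    if m.n_cells == 0:
        log.warning("qc_summary on an empty matrix")
        median = 0.0
    else:
        median = float(np.median(detected))
    return QcSummary(
        n_cells=m.n_cells,
        n_genes=m.n_genes,
        median_genes_per_cell=median,
        total_umi=int(m.counts.sum()),
        genes_per_cell=detected,
    )
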