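"""Reading and writing the 10x triplet layout and annotation tables.

A 10x directory holds ``matrix.mtx`` (MatrixMarket coordinate integer,
1-based indices, conventionally genes x cells), ``features.tsv``
(gene_id, gene_name, chromosome arm) and ``barcodes.tsv``. Gzip-compressed
variants (``.gz`` suffix on any of the three) are accepted transparently.

In memory the matrix is always cells x genes; orientation on disk is
inferred by matching the MatrixMarket dimensions against the line counts
of the two TSV files.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import KNOWN_ARMS, GeneAnnotation, UmiMatrix

log = logging.getLogger(__name__)

_TRIPLET = ("matrix.mtx", "features.tsv", "barcodes.tsv")


def _find(directory: Path, name: str) -> Path:
    for candidate in (directory / name, directory / (name + ".gz")):
        if candidate.exists():
            return candidate
    raise FileNotFoundError(f"{name}[.gz] not found in {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_lines(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_10x_triplet(directory) -> UmiMatrix:
    """Load a 10x triplet directory into a cells x genes :class:`UmiMatrix`.

    The on-disk orientation (10x writes genes x cells) is detected from the
    dimension header; matrices already stored cells x genes round-trip too.

    Raises
    ------
    ValueError
        If the declared dimensions match neither TSV orientation, if values
        are non-integer or negative, or if barcodes are duplicated.
    """
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    features = _read_lines(_find(directory, "features.tsv"))
    barcodes = _read_lines(_find(directory, "barcodes.tsv"))

    with _open_text(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.coo_matrix(mat)
    if mat.data.size and np.any(mat.data != np.round(mat.data)):
        raise ValueError(f"{mtx_path}: non-integer values in count matrix")
    if mat.data.size and mat.data.min() < 0:
        raise ValueError(f"{mtx_path}: negative values in count matrix")

    n_genes, n_cells = len(features), len(barcodes)
    if mat.shape == (n_genes, n_cells):
        mat = mat.T  # standard 10x orientation: genes x cells on disk
    elif mat.shape == (n_cells, n_genes):
        pass
    else:
        raise ValueError(
            f"matrix dimensions {mat.shape} match neither genes x cells "
            f"({n_genes} x {n_cells}) nor cells x genes"
        )

    gene_ids = [line.split("\t")[0] for line in features]
    return UmiMatrix(sp.csr_matrix(mat, dtype=np.int64), np.array(barcodes, dtype=object), np.array(gene_ids, dtype=object))


def write_10x_triplet(m: UmiMatrix, directory, gene_annotation: GeneAnnotation | None = None) -> None:
    """Write a matrix as a 10x triplet (genes x cells on disk, 1-based).

    ``features.tsv`` carries (gene_id, gene_name, arm); the gene name
    defaults to the gene id and the arm to the annotation lookup (UNKNOWN
    when no annotation is given).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "matrix.mtx", "wb") as fh:
        scipy.io.mmwrite(
            fh, sp.coo_matrix(m.counts.T, dtype=np.int64), field="integer"
        )
    arms = (
        gene_annotation.arm_of(m.gene_ids)
        if gene_annotation is not None
        else np.full(m.n_genes, "UNKNOWN", dtype=object)
    )
    with open(directory / "features.tsv", "wt") as fh:
        for gid, arm in zip(m.gene_ids, arms):
            fh.write(f"{gid}\t{gid}\t{arm}\n")
    with open(directory / "barcodes.tsv", "wt") as fh:
        for bc in m.barcodes:
            fh.write(f"{bc}\n")


def read_gene_annotation(path) -> GeneAnnotation:
    """Read a two-column (gene_id, arm) TSV into a :class:`GeneAnnotation`.

    Unrecognised arm strings are kept verbatim (they class as UNKNOWN) and
    logged; a gene listed twice with conflicting arms is an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 tab-separated columns")
    # a 3-column file is treated as a features.tsv (gene_id, name, arm)
    arm_col = 2 if df.shape[1] >= 3 else 1
    series = pd.Series(df.iloc[:, arm_col].values, index=df.iloc[:, 0].values)
    unknown = sorted(set(series.unique()) - set(KNOWN_ARMS))
    if unknown:
        log.warning(
            "annotation %s: %d unrecognised arm label(s) mapped to UNKNOWN: %s",
            path, len(unknown), unknown[:10],
        )
    return GeneAnnotation(series)


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    ann.arms.to_csv(path, sep="\t", header=False)
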