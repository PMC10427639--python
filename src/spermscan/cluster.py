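"""Depth normalization, PCA embedding, and k-means clustering.

The stage reproduces a standard droplet pipeline: scale every cell to a
common depth target (the median cell depth by default), log2(1 + x)
transform, rank genes by dispersion of the normalized values, embed the
top genes with an exact SVD, and partition cells with Lloyd's k-means
(k-means++ seeding, best of ``n_init`` restarts by inertia). Cluster
labels are renumbered by decreasing size so label 1 is always the largest
cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .datatypes import ClusterAssignment, UmiMatrix

log = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Sparse cells x genes matrix of log2(1 + depth-scaled counts)."""

    values: sp.csr_matrix
    barcodes: np.ndarray
    gene_ids: np.ndarray
    target_depth: float

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class Embedding:
    """PCA coordinates of cells plus per-component explained variance."""

    coords: np.ndarray            # cells x d
    explained_variance: np.ndarray
    barcodes: np.ndarray
    gene_index: np.ndarray        # columns of the normalized matrix used

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]

    def scaled(self, factor: float) -> "Embedding":
        return Embedding(self.coords * factor, self.explained_variance * factor**2,
                         self.barcodes, self.gene_index)


def normalize_log(m: UmiMatrix, target: float | str = "median") -> NormalizedMatrix:
    """Scale each cell to a common total, then log2(1 + x) entrywise.

    ``target`` is either a positive number or ``"median"`` (the median
    per-cell depth). Cells with zero total are dropped with a warning —
    they carry no expression signal and cannot be scaled.
    """
    depth = m.depth_per_cell().astype(float)
    keep = depth > 0
    if not keep.all():
        log.warning("normalize_log: dropping %d zero-depth cell(s)",
                    int((~keep).sum()))
        m = m.subset_cells(np.flatnonzero(keep))
        depth = depth[keep]
    if isinstance(target, str):
        if target != "median":
            raise ValueError(f"unknown target {target!r}")
        target_depth = float(np.median(depth))
    else:
        target_depth = float(target)
        if target_depth <= 0:
            raise ValueError("target depth must be positive")
    scale = target_depth / depth
    x = sp.csr_matrix(m.counts, dtype=float)
    x = sp.diags(scale) @ x
    x.data = np.log2(1.0 + x.data)  # zeros map to zero: sparsity preserved
    return NormalizedMatrix(sp.csr_matrix(x), m.barcodes, m.gene_ids, target_depth)


def gene_dispersion(x: NormalizedMatrix) -> np.ndarray:
    """Variance/mean of each gene's normalized values (0 where mean is 0)."""
    v = x.values
    n = v.shape[0]
    mean = np.asarray(v.mean(axis=0)).ravel()
    sq = np.asarray(v.multiply(v).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * (n / max(n - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    return disp


def pca_embed(
    x: NormalizedMatrix, n_components: int = 10, n_top_genes: int = 1000
) -> Embedding:
    """Exact-SVD principal components of the top dispersion-ranked genes.

    Component signs follow a fixed convention (the largest-magnitude gene
    loading of each component is positive) so embeddings are deterministic.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    disp = gene_dispersion(x)
    n_top = min(n_top_genes, len(disp))
    # stable top-n: sort by (-dispersion, column index)
    order = np.lexsort((np.arange(len(disp)), -disp))
    top = np.sort(order[:n_top])
    dense = np.asarray(x.values[:, top].todense())
    dense -= dense.mean(axis=0, keepdims=True)
    max_rank = min(dense.shape)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds rank bound {max_rank}")
    u, s, vt = np.linalg.svd(dense, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(n_components), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    coords = u * s * flip
    explained = s**2 / max(dense.shape[0] - 1, 1)
    return Embedding(coords, explained, x.barcodes, top)


def kmeans_cluster(
    e: Embedding, k: int, seed: int, n_init: int = 10
) -> ClusterAssignment:
    """Best-of-``n_init`` Lloyd k-means on the embedding, labels 1..k.

    Labels are renumbered by decreasing cluster size (ties by first
    occurrence). ``run_inertias`` on the returned assignment records every
    restart's inertia; the kept solution attains their minimum.
    """
    n = e.coords.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside 2..{n}")
    if np.unique(e.coords, axis=0).shape[0] < k:
        raise ValueError(f"k={k} exceeds the number of distinct points")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_init)
    best = None
    inertias = []
    for s in run_seeds:
        km = KMeans(n_clusters=k, n_init=1, init="k-means++",
                    random_state=int(s), algorithm="lloyd").fit(e.coords)
        inertias.append(float(km.inertia_))
        if best is None or km.inertia_ < best.inertia_:
            best = km
    raw = best.labels_
    sizes = pd.Series(raw).value_counts()  # sorted desc, stable
    relabel = {old: new for new, old in enumerate(sizes.index, start=1)}
    labels = pd.Series([relabel[lab] for lab in raw],
                       index=pd.Index(e.barcodes))
    return ClusterAssignment(labels=labels, k=k, inertia=float(best.inertia_),
                             run_inertias=inertias)


def sweep_k(
    e: Embedding, k_range=range(2, 11), seed: int = 0, n_init: int = 10
) -> dict[int, ClusterAssignment]:
    """k-means assignments for every k in ``k_range`` (default 2..10)."""
    return {int(k): kmeans_cluster(e, int(k), seed, n_init) for k in k_range}
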