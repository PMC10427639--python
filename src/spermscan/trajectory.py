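"""Simplified pseudotime: a minimum spanning tree over cluster centroids.

The root cluster is picked automatically as the one with peak mean
normalized expression of a chosen premeiotic marker (a stand-in for the
manual root choice one would make from a marker's expression peak).
Cluster centroids in PCA space are joined by their Euclidean minimum
spanning tree; a cell's pseudotime is the tree distance from the root
centroid to its own cluster's centroid plus the cell's distance to that
centroid, shifted so the minimum is exactly zero. Within-cluster spread
therefore orders cells inside each cluster, and scaling the embedding
scales pseudotime by the same factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial.distance import cdist

from .cluster import Embedding, NormalizedMatrix
from .datatypes import ClusterAssignment, UmiMatrix

log = logging.getLogger(__name__)


@dataclass
class TrajectoryResult:
    root_cluster: int
    cluster_order: list[int]          # clusters sorted by tree distance from root
    cluster_distances: pd.Series      # label -> tree distance from root centroid
    edges: list[tuple[int, int]]      # MST edges as (label, label)
    pseudotime: pd.Series             # barcode -> non-negative real


def select_root(
    m: UmiMatrix | NormalizedMatrix,
    clusters: ClusterAssignment,
    root_marker: str,
) -> int:
    """Cluster with maximal mean depth-normalized expression of a marker."""
    if isinstance(m, NormalizedMatrix):
        gene_ids, barcodes, values = m.gene_ids, m.barcodes, m.values
    else:
        from .cluster import normalize_log

        norm = normalize_log(m)
        gene_ids, barcodes, values = norm.gene_ids, norm.barcodes, norm.values
    idx = np.flatnonzero(gene_ids == root_marker)
    if idx.size == 0:
        raise ValueError(f"root marker {root_marker!r} absent from matrix")
    expr = np.asarray(values[:, idx[0]].todense()).ravel()
    labels = clusters.labels_for(barcodes)
    means = pd.Series(expr).groupby(labels).mean()
    top = means[means == means.max()].index
    if len(top) > 1:
        log.warning("root marker ties across clusters %s; taking smallest label",
                    list(top))
    return int(min(top))


def pseudotime_mst(
    e: Embedding, clusters: ClusterAssignment, root: int
) -> TrajectoryResult:
    """MST-over-centroids pseudotime rooted at ``root``."""
    labels = clusters.labels_for(e.barcodes)
    present = sorted(np.unique(labels))
    if len(present) < 2:
        raise ValueError("need at least 2 non-empty clusters")
    if root not in present:
        raise ValueError(f"root cluster {root} is empty or unknown")
    if not np.all(np.isfinite(e.coords)):
        raise ValueError("embedding contains non-finite values")

    centroids = np.vstack([e.coords[labels == lab].mean(axis=0)
                           for lab in present])
    dist = cdist(centroids, centroids)
    # degenerate identical centroids: break ties by label via a tiny,
    # deterministic perturbation of the distance matrix
    coincident = (dist == 0) & ~np.eye(len(present), dtype=bool)
    if coincident.any():
        log.warning("identical cluster centroids; tie-broken by label")
        jitter = 1e-12 * (np.add.outer(np.arange(len(present)),
                                       np.arange(len(present))) + 1)
        dist = dist + np.where(coincident, jitter, 0.0)

    mst = minimum_spanning_tree(dist)
    tree = mst + mst.T
    root_idx = present.index(root)
    tree_dist = shortest_path(tree, indices=root_idx, directed=False)
    # an MST spans all nodes, so every distance is finite
    cluster_distances = pd.Series(tree_dist, index=present)

    mst_coo = mst.tocoo()
    edges = [(present[i], present[j]) for i, j in zip(mst_coo.row, mst_coo.col)]

    d_of_label = dict(zip(present, tree_dist))
    own = np.linalg.norm(
        e.coords - centroids[[present.index(l) for l in labels]], axis=1
    )
    pt = np.array([d_of_label[l] for l in labels]) + own
    pt -= pt.min()  # root-adjacent minimum pinned to exactly zero
    order = [lab for _, lab in sorted(zip(tree_dist, present))]
    return TrajectoryResult(
        root_cluster=int(root),
        cluster_order=[int(l) for l in order],
        cluster_distances=cluster_distances,
        edges=edges,
        pseudotime=pd.Series(pt, index=pd.Index(e.barcodes)),
    )
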