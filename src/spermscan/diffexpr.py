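"""Cluster-vs-rest differential expression and enrichment utilities.

Each cluster is compared against all remaining cells ("globally
distinguishing" DE): per gene, the log2 fold change of depth-normalized
mean expression (with a pseudocount tied to the normalization depth) and
a two-sided rank-sum p-value, Benjamini-Hochberg adjusted within the
cluster's gene family. A gene is *enriched* in a cluster when
log2FC > 1 and adjusted p < 0.05.

On top of the DE table: the UpSet-style partition of enriched genes by
their exact cluster-membership set, the cluster x chromosome-arm
breakdown, marker-based cell-type annotation of clusters, and a generic
one-sided hypergeometric over-representation test for gene categories.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import dosage
from .datatypes import ClusterAssignment, GeneAnnotation, UmiMatrix

log = logging.getLogger(__name__)

LOG2FC_CUTOFF = 1.0
ALPHA = 0.05


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1] and non-NaN")
    return multipletests(p, method="fdr_bh")[1]


def globally_distinguishing_de(
    m: UmiMatrix,
    clusters: ClusterAssignment,
    log2fc_cutoff: float = LOG2FC_CUTOFF,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Cluster-vs-rest DE over every (cluster, gene) pair.

    Cells are scaled to the median depth (linear, no log); the fold change
    is ``log2((mean_c + eps) / (mean_rest + eps))`` with
    ``eps = 1 / median depth`` so zero-mean groups stay finite. The
    p-value is the two-sided rank-sum test of the normalized counts of the
    cluster's cells against all others, BH-adjusted within each cluster
    across all genes.
    """
    labels = clusters.labels_for(m.barcodes)
    present = sorted(np.unique(labels))
    if len(present) < 2:
        raise ValueError("need at least 2 non-empty clusters for DE")
    depth = m.depth_per_cell().astype(float)
    if np.any(depth == 0):
        raise ValueError("zero-depth cells present; run QC filtering first")
    median_depth = float(np.median(depth))
    eps = 1.0 / median_depth
    norm = (m.counts.multiply((median_depth / depth)[:, None])).tocsc()
    dense = np.asarray(norm.todense())

    use_exact = m.n_cells <= dosage.EXACT_MAX_N
    if not use_exact:
        ranks, tie = dosage.pooled_rank_precompute(dense)

    frames = []
    for lab in present:
        in_c = labels == lab
        mean_c = dense[in_c].mean(axis=0)
        mean_rest = dense[~in_c].mean(axis=0)
        log2fc = np.log2((mean_c + eps) / (mean_rest + eps))
        if use_exact:
            p = np.array([
                dosage.wilcoxon_rank_sum(dense[in_c, j], dense[~in_c, j])
                for j in range(dense.shape[1])
            ])
        else:
            p = dosage.rank_sum_pvalues_split(ranks, tie, in_c)
        p_adj = benjamini_hochberg(p)
        frames.append(pd.DataFrame({
            "cluster": lab, "gene_id": m.gene_ids, "log2fc": log2fc,
            "p": p, "p_adj": p_adj,
            "enriched": (log2fc > log2fc_cutoff) & (p_adj < alpha),
        }))
    return pd.concat(frames, ignore_index=True)


def enrichment_partition(de: pd.DataFrame) -> dict[frozenset, int]:
    """UpSet-style partition: exact cluster-membership set -> gene count.

    Every gene enriched somewhere is counted once, under the full set of
    clusters in which it is enriched, so the counts partition the
    enriched-gene universe.
    """
    enriched = de[de["enriched"]]
    membership = enriched.groupby("gene_id")["cluster"].agg(frozenset)
    return membership.value_counts().to_dict()


def enrichment_by_chromosome(
    de: pd.DataFrame, ann: GeneAnnotation
) -> pd.DataFrame:
    """Cross-tabulation of enriched genes: cluster rows x chromosome arms."""
    enriched = de[de["enriched"]]
    if enriched.empty:
        return pd.DataFrame()
    arms = ann.arm_of(enriched["gene_id"].to_numpy())
    return pd.crosstab(enriched["cluster"], pd.Series(arms, name="arm"))


def annotate_clusters(
    de: pd.DataFrame, markers: pd.DataFrame
) -> dict[int, tuple[str, float]]:
    """Assign each cluster the cell type whose markers it most enriches.

    ``markers`` has columns (gene_id, cell_type, stage_rank). The score of
    (cluster, type) sums max(log2fc, 0) over the type's markers that are
    enriched in the cluster; the argmax type wins, ties broken toward the
    earlier stage_rank, and score-0 clusters are "unassigned". Marker
    genes absent from the DE table are skipped with a warning.
    """
    if markers.empty:
        raise ValueError("marker table is empty")
    known_genes = set(de["gene_id"])
    missing = sorted(set(markers["gene_id"]) - known_genes)
    if missing:
        log.warning("%d marker gene(s) absent from the matrix, e.g. %s",
                    len(missing), missing[:5])
        markers = markers[markers["gene_id"].isin(known_genes)]
    enriched = de[de["enriched"]].merge(markers, on="gene_id")
    out: dict[int, tuple[str, float]] = {}
    for cluster in sorted(de["cluster"].unique()):
        sub = enriched[enriched["cluster"] == cluster]
        if sub.empty:
            out[int(cluster)] = ("unassigned", 0.0)
            continue
        scores = (sub.assign(score=sub["log2fc"].clip(lower=0))
                     .groupby("cell_type")
                     .agg(score=("score", "sum"), stage_rank=("stage_rank", "min")))
        scores = scores.sort_values(["score", "stage_rank"],
                                    ascending=[False, True])
        best_type = scores.index[0]
        best_score = float(scores.iloc[0]["score"])
        if best_score <= 0:
            out[int(cluster)] = ("unassigned", 0.0)
        else:
            out[int(cluster)] = (str(best_type), best_score)
    return out


def hypergeom_overrepresentation(
    query: set, categories: dict[str, set], universe: set
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each category.

    For a category with K members in a universe of N genes, and a query of
    n genes hitting k of them, p is the upper-tail probability of >= k
    hits; BH adjustment across categories. A stand-in for database-backed
    ontology enrichment: the categories are caller-supplied gene sets.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    import scipy.stats

    n_universe, n_query = len(universe), len(query)
    rows = []
    for term, members in categories.items():
        members = set(members) & universe
        k = len(query & members)
        p = float(scipy.stats.hypergeom.sf(k - 1, n_universe, len(members),
                                           n_query))
        rows.append({"term": term, "k": k, "K": len(members), "n": n_query,
                     "N": n_universe, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["p_adj"] = benjamini_hochberg(df["p"].to_numpy()) if len(df) else []
    return df
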