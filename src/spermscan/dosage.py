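"""Chromosome-class dosage statistics: the pipeline's core computation.

Three linked analyses, all on a filtered cells x genes UMI matrix with a
chromosome annotation and a cluster assignment:

* per-cell RNA content — the summed UMIs mapping to autosomes, the X, or
  the Y contigs, compared between consecutive developmental clusters with
  rank-sum tests under Bonferroni correction;
* per-gene per-cluster log2(counts + 1) values, the substrate for
* X/A and Y/A ratio statistics — within each cluster the median
  log-transformed count of the sex-linked genes is compared with the
  autosomal median; the ratio 2**(median_X - median_A) estimates the
  linear-scale expression ratio, a rank-sum test measures departure from
  1:1, and a rule classifies the regime (dosage compensated at ~1,
  uncompensated single-copy expression at ~0.5, silenced below that).

The two-sided Wilcoxon rank-sum p-value is computed exactly (full
enumeration of the rank-sum null via dynamic programming) for small
tie-free samples, and by the tie- and continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .datatypes import ClusterAssignment, GeneAnnotation, UmiMatrix

log = logging.getLogger(__name__)

#: largest combined sample size handled by exact enumeration
EXACT_MAX_N = 12

REGIMES = ("dosage_compensated", "overexpression", "no_compensation",
           "silenced", "indeterminate")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _rank_sum_counts(n: int, n1: int) -> tuple[int, ...]:
    """Number of size-``n1`` subsets of ranks {1..n} with each possible sum.

    Index w of the returned tuple counts subsets summing to w. Standard
    subset-sum dynamic programming; exact integer arithmetic.
    """
    max_sum = n * (n + 1) // 2
    ways = [[0] * (max_sum + 1) for _ in range(n1 + 1)]
    ways[0][0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            row_k, row_km1 = ways[k], ways[k - 1]
            for w in range(max_sum, r - 1, -1):
                if row_km1[w - r]:
                    row_k[w] += row_km1[w - r]
    return tuple(ways[n1])


def _exact_two_sided_p(w_obs: float, n1: int, n2: int) -> float:
    """P(|W - E[W]| >= |w_obs - E[W]|) under the exact rank-sum null."""
    n = n1 + n2
    counts = _rank_sum_counts(n, n1)
    # work with 2W - n1(n+1) so deviations are exact integers
    d_obs = abs(round(2 * w_obs) - n1 * (n + 1))
    total = comb(n, n1)
    hits = sum(c for w, c in enumerate(counts)
               if c and abs(2 * w - n1 * (n + 1)) >= d_obs)
    return hits / total


def _approx_two_sided_p(r1: float, n1: int, n2: int, tie_term: float) -> float:
    """Normal approximation with tie and continuity correction."""
    n = n1 + n2
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    dev = abs(u - mu)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * scipy.stats.norm.sf(z)))


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the pooled sample has at most ``EXACT_MAX_N``
    observations and no ties; tie- and continuity-corrected normal
    approximation otherwise. Identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    ranks = scipy.stats.rankdata(pooled)
    r1 = float(ranks[: a.size].sum())
    n1, n2 = a.size, b.size
    has_ties = len(np.unique(pooled)) < pooled.size
    if n1 + n2 <= EXACT_MAX_N and not has_ties:
        return _exact_two_sided_p(r1, n1, n2)
    return _approx_two_sided_p(r1, n1, n2, _tie_term(pooled))


def pooled_rank_precompute(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column ranks and tie terms of a dense cells x genes matrix.

    Shared across every cluster-vs-rest comparison on the same matrix,
    since pooled ranking does not depend on the split.
    """
    ranks = np.empty_like(x, dtype=np.float64)
    tie = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        col = x[:, j]
        ranks[:, j] = scipy.stats.rankdata(col)
        tie[j] = _tie_term(col)
    return ranks, tie


def rank_sum_pvalues_split(
    ranks: np.ndarray, tie: np.ndarray, in_group: np.ndarray
) -> np.ndarray:
    """Vectorised approximate rank-sum p per column for one group split.

    ``ranks``/``tie`` come from :func:`pooled_rank_precompute`;
    ``in_group`` is the boolean cell mask of the first sample. Matches the
    approximation branch of :func:`wilcoxon_rank_sum` column by column.
    """
    n = ranks.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    r1 = ranks[in_group].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    dev = np.abs(u - mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, np.maximum(dev - 0.5, 0.0) / np.sqrt(var), 0.0)
    p = np.minimum(1.0, 2.0 * scipy.stats.norm.sf(z))
    return np.where(var > 0, p, 1.0)


def bonferroni(p, m: int) -> np.ndarray:
    """Bonferroni adjustment min(1, m * p); requires m >= number of tests."""
    p = np.asarray(p, dtype=float)
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than {p.size} tests")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# RNA content per cell
# ---------------------------------------------------------------------------

def rna_content_per_cell(
    m: UmiMatrix, ann: GeneAnnotation, clusters: ClusterAssignment
) -> pd.DataFrame:
    """Summed UMIs per cell mapping to each chromosome class.

    Columns: barcode, cluster, umi_autosome, umi_X, umi_Y, and separately
    umi_MT and umi_unknown (excluded from the three analysis classes).
    """
    classes = ann.class_of(m.gene_ids)
    labels = clusters.labels_for(m.barcodes)
    out = {"barcode": m.barcodes, "cluster": labels}
    for cls, col in [("autosome", "umi_autosome"), ("X", "umi_X"),
                     ("Y", "umi_Y"), ("MT", "umi_MT"),
                     ("UNKNOWN", "umi_unknown")]:
        mask = classes == cls
        if mask.any():
            out[col] = np.asarray(m.counts[:, mask].sum(axis=1)).ravel()
        else:
            out[col] = np.zeros(m.n_cells, dtype=np.int64)
    return pd.DataFrame(out)


def compare_content_consecutive(
    content: pd.DataFrame,
    stage_order,
    classes=("autosome", "X", "Y"),
) -> pd.DataFrame:
    """Rank-sum tests on per-cell RNA content between consecutive clusters.

    One two-sided test per (adjacent stage pair, chromosome class);
    Bonferroni family size = pairs x classes. Direction is the sign of the
    median difference (later minus earlier). Pairs with a cluster of fewer
    than 2 cells get an indeterminate (NaN) p and are logged.
    """
    stage_order = list(stage_order)
    col = {"autosome": "umi_autosome", "X": "umi_X", "Y": "umi_Y",
           "MT": "umi_MT"}
    rows = []
    for early, late in zip(stage_order[:-1], stage_order[1:]):
        g_early = content[content["cluster"] == early]
        g_late = content[content["cluster"] == late]
        for cls in classes:
            a = g_early[col[cls]].to_numpy(float)
            b = g_late[col[cls]].to_numpy(float)
            if a.size < 2 or b.size < 2:
                log.warning("pair %s->%s class %s: cluster with <2 cells; "
                            "p indeterminate", early, late, cls)
                p = np.nan
                direction = "indeterminate"
            else:
                p = wilcoxon_rank_sum(b, a)
                diff = np.median(b) - np.median(a)
                direction = ("increase" if diff > 0
                             else "decrease" if diff < 0 else "none")
            rows.append({"pair": f"{early}->{late}", "class": cls,
                         "p": p, "direction": direction})
    df = pd.DataFrame(rows)
    m_tests = (len(stage_order) - 1) * len(classes)
    df["p_adj"] = np.minimum(1.0, m_tests * df["p"])
    return df[["pair", "class", "p", "p_adj", "direction"]]


# ---------------------------------------------------------------------------
# per-gene per-cluster log counts and ratio statistics
# ---------------------------------------------------------------------------

@dataclass
class GeneClusterCounts:
    """Summed counts and log2(count + 1) per (cluster, gene)."""

    raw: np.ndarray       # k x genes, integer sums over each cluster's cells
    log2: np.ndarray      # k x genes, log2(raw + 1)
    cluster_labels: list[int]
    gene_ids: np.ndarray


def gene_cluster_log_counts(
    m: UmiMatrix, clusters: ClusterAssignment
) -> GeneClusterCounts:
    """Sum each gene's counts over every cluster's cells; log2(sum + 1).

    Genes should already be restricted to those expressed in at least one
    cluster (see ``qc.filter_genes_cluster_expressed``).
    """
    labels = clusters.labels_for(m.barcodes)
    present = sorted(np.unique(labels))
    onehot = sp.csr_matrix(
        (np.ones(len(labels)),
         (np.searchsorted(present, labels), np.arange(len(labels)))),
        shape=(len(present), len(labels)),
    )
    raw = np.asarray((onehot @ m.counts).todense()).astype(np.int64)
    return GeneClusterCounts(raw=raw, log2=np.log2(raw + 1.0),
                             cluster_labels=[int(c) for c in present],
                             gene_ids=m.gene_ids)


def xa_ratio_per_cluster(
    glc: GeneClusterCounts,
    ann: GeneAnnotation,
    class_of_interest: str = "X",
    alpha: float = 0.05,
    band_no_dc: tuple[float, float] = (0.4, 0.65),
    floor_silenced: float = 0.4,
    family_size: int | None = None,
    drop_zero_genes: bool = False,
    ratio_scale: str = "linear",
) -> pd.DataFrame:
    """Sex-to-autosome expression ratio statistics per cluster.

    For every cluster: the median log2(count + 1) over the genes of
    ``class_of_interest`` (X or Y) and over autosomal genes, the ratio
    ``2**(median_class - median_A)`` (linear scale; ``ratio_scale="log"``
    instead divides the two log medians, for sensitivity analysis), a
    rank-sum p for the class-vs-autosome comparison, Bonferroni adjustment
    across clusters (``family_size`` overrides the default family of one
    test per cluster), and the regime classification.

    ``drop_zero_genes`` excludes genes with zero counts in that cluster
    from its medians; the default keeps them at log value 0.
    """
    if class_of_interest not in ("X", "Y"):
        raise ValueError("class_of_interest must be 'X' or 'Y'")
    classes = ann.class_of(glc.gene_ids)
    cls_mask = classes == class_of_interest
    aut_mask = classes == "autosome"
    if cls_mask.sum() < 2 or aut_mask.sum() < 2:
        raise ValueError(
            f"need >= 2 genes in class {class_of_interest} and autosomes; "
            f"got {int(cls_mask.sum())} and {int(aut_mask.sum())}"
        )
    rows = []
    for i, label in enumerate(glc.cluster_labels):
        logs = glc.log2[i]
        raws = glc.raw[i]
        cm, am = cls_mask.copy(), aut_mask.copy()
        if drop_zero_genes:
            cm &= raws > 0
            am &= raws > 0
        x_logs, a_logs = logs[cm], logs[am]
        if x_logs.size < 2 or a_logs.size < 2:
            log.warning("cluster %s: too few expressed genes for ratio", label)
            rows.append({"cluster": label, "class": class_of_interest,
                         "median_class": np.nan, "median_A": np.nan,
                         "ratio": np.nan, "p": np.nan})
            continue
        m_c = float(np.median(x_logs))
        m_a = float(np.median(a_logs))
        if ratio_scale == "linear":
            ratio = float(2.0 ** (m_c - m_a))
        elif ratio_scale == "log":
            ratio = float(m_c / m_a) if m_a != 0 else np.nan
        else:
            raise ValueError("ratio_scale must be 'linear' or 'log'")
        rows.append({"cluster": label, "class": class_of_interest,
                     "median_class": m_c, "median_A": m_a, "ratio": ratio,
                     "p": wilcoxon_rank_sum(x_logs, a_logs)})
    df = pd.DataFrame(rows)
    m_family = family_size if family_size is not None else len(df)
    df["p_adj"] = bonferroni(df["p"].to_numpy(), m_family)
    df["regime"] = [
        classify_regime(r, pa, alpha=alpha, band_no_dc=band_no_dc,
                        floor_silenced=floor_silenced)
        if np.isfinite(r) and np.isfinite(pa) else "indeterminate"
        for r, pa in zip(df["ratio"], df["p_adj"])
    ]
    return df


def classify_regime(
    ratio: float,
    p_adj: float,
    alpha: float = 0.05,
    band_no_dc: tuple[float, float] = (0.4, 0.65),
    floor_silenced: float = 0.4,
) -> str:
    """Classify a cluster's dosage regime from its ratio and adjusted p.

    No significant departure from 1:1 means dosage compensation; a
    significant ratio above 1 is overexpression; a significant ratio in
    the band around 0.5 is plain single-copy expression without
    compensation; significantly below the band is silencing (the MSCI
    signature); a significant ratio between the band and 1 is left
    indeterminate.
    """
    if p_adj >= alpha:
        return "dosage_compensated"
    if ratio > 1:
        return "overexpression"
    if band_no_dc[0] <= ratio <= band_no_dc[1]:
        return "no_compensation"
    if ratio < floor_silenced:
        return "silenced"
    return "indeterminate"
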