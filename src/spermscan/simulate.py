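"""Synthetic germline UMI-count generator with known ground truth.

The generator emulates the structure of a droplet-based testis dataset:
eight ordered germline clusters of very unequal size, a log-normal spread
of per-gene baseline means, per-cell library-size variation, negative
binomial (gamma-Poisson) counting noise, marker-gene programs spiked into
chosen clusters, and per-cluster multiplicative chromosome-class regimes
(the injected X/A, Y/A and mitochondrial profiles that the dosage analysis
must recover).

For gene *g* of chromosome class *K* and cell *i* of cluster *c*::

    counts[i, g] ~ NB(mean = L_i * mu_g * m_gc * F[c, K],  size = theta)

with ``L_i`` the cell's library factor (log-normal, mean 1), ``mu_g`` the
log-normal baseline mean, ``m_gc`` the marker fold (1 unless gene *g* is a
marker spiked into cluster *c*) and ``F`` the cluster x class factor
matrix. Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CLASSES, GeneAnnotation, UmiMatrix, arm_to_class

#: arm order used when laying out genes
_ARM_ORDER = ("2R", "2L", "3R", "3L", "X", "Y", "MT")

#: inferred germline cell types, in developmental order
STAGE_CELL_TYPES = (
    "hub cells",
    "germline stem cells",
    "primary spermatogonia",
    "late spermatogonia/primary spermatocytes",
    "spermatocytes",
    "late spermatocytes/early spermatids",
    "late spermatids",
    "mature spermatozoa",
)


@dataclass(frozen=True)
class MarkerSpec:
    """A marker program: one gene spiked ``fold``-times in ``clusters``."""

    gene_index: int
    clusters: tuple[int, ...]
    fold: float
    cell_type: str | None = None

    def __post_init__(self):
        if self.fold < 1:
            raise ValueError(f"marker fold must be >= 1, got {self.fold}")
        if self.gene_index < 0:
            raise ValueError("marker gene_index must be non-negative")


@dataclass
class SimulationConfig:
    """Parameters of the generative model; defaults are deliberately small.

    ``class_factor`` is (n_clusters x 4) over the class order
    ``("autosome", "X", "Y", "MT")``; ``stage_order`` lists cluster labels
    (1..k) in true developmental order.
    """

    seed: int = 0
    cluster_sizes: list[int] = field(default_factory=lambda: [60, 60])
    genes_per_class: dict[str, int] = field(
        default_factory=lambda: {"2R": 100, "2L": 100, "3R": 100, "3L": 100,
                                 "X": 40, "Y": 5, "MT": 3}
    )
    base_mean_log_mu: float = math.log(0.28)
    base_mean_log_sigma: float = 0.2
    nb_dispersion: float = 2.0
    libsize_log_sigma: float = 0.35
    class_factor: np.ndarray | None = None
    marker_spec: list[MarkerSpec] = field(default_factory=list)
    stage_order: list[int] | None = None
    y_baseline_scale: float = 0.1  # Y genes transcribed far below autosomal baseline

    def __post_init__(self) -> None:
        sizes = np.asarray(self.cluster_sizes)
        if sizes.size == 0 or np.any(sizes < 1) or np.any(sizes != sizes.astype(int)):
            raise ValueError("cluster_sizes must be positive integers")
        self.cluster_sizes = [int(s) for s in sizes]
        for arm, n in self.genes_per_class.items():
            if arm not in _ARM_ORDER:
                raise ValueError(f"unknown arm {arm!r} in genes_per_class")
            if n < 0 or int(n) != n:
                raise ValueError(f"gene count for {arm} must be a non-negative integer")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        k = len(self.cluster_sizes)
        if self.class_factor is None:
            self.class_factor = np.ones((k, len(CLASSES)))
        self.class_factor = np.asarray(self.class_factor, dtype=float)
        if self.class_factor.shape != (k, len(CLASSES)):
            raise ValueError(
                f"class_factor must be ({k}, {len(CLASSES)}), got {self.class_factor.shape}"
            )
        if np.any(self.class_factor <= 0):
            raise ValueError("class factors must be positive")
        if self.stage_order is None:
            self.stage_order = list(range(1, k + 1))
        if sorted(self.stage_order) != list(range(1, k + 1)):
            raise ValueError("stage_order must be a permutation of 1..k")
        n_genes = self.n_genes
        for ms in self.marker_spec:
            if ms.gene_index >= n_genes:
                raise ValueError(f"marker gene index {ms.gene_index} out of range")
            if not set(ms.clusters) <= set(range(1, k + 1)):
                raise ValueError(f"marker clusters {ms.clusters} outside 1..{k}")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def n_cells(self) -> int:
        return int(sum(self.cluster_sizes))

    @property
    def n_genes(self) -> int:
        return int(sum(self.genes_per_class.get(a, 0) for a in _ARM_ORDER))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class GroundTruth:
    """What the generator knows and downstream stages must recover."""

    true_cluster: pd.Series       # barcode -> cluster label (1..k)
    true_pseudorank: pd.Series    # barcode -> 0-based developmental rank
    class_factor: np.ndarray      # (k x 4) injected factors, class order CLASSES
    markers: list[MarkerSpec]
    stage_order: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"barcode": self.true_cluster.index,
             "cluster": self.true_cluster.values,
             "rank": self.true_pseudorank.values}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def gene_layout(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (gene_ids, arms) layout for a config."""
    ids, arms = [], []
    for arm in _ARM_ORDER:
        n = config.genes_per_class.get(arm, 0)
        ids.extend(f"G{arm}_{i:05d}" for i in range(n))
        arms.extend([arm] * n)
    return np.array(ids, dtype=object), np.array(arms, dtype=object)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[UmiMatrix, GeneAnnotation, GroundTruth]:
    """Draw a UMI matrix from the generative model.

    Returns the cells x genes count matrix, the matching gene annotation
    (gene -> arm), and the ground truth (cluster labels, developmental
    ranks, injected factors, marker list). Bit-identical across calls with
    the same config and seed.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids, arms = gene_layout(config)
    class_idx = np.array([CLASSES.index(arm_to_class(a)) for a in arms])

    mu = rng.lognormal(config.base_mean_log_mu, config.base_mean_log_sigma,
                       size=len(gene_ids))
    mu[arms == "Y"] *= config.y_baseline_scale

    n_cells = config.n_cells
    sigma_l = config.libsize_log_sigma
    lib = rng.lognormal(-0.5 * sigma_l**2, sigma_l, size=n_cells)  # mean 1

    # marker fold per (cluster, gene), multiplicative over overlapping specs
    folds: dict[int, dict[int, float]] = {}
    for ms in config.marker_spec:
        for c in ms.clusters:
            folds.setdefault(c, {})
            folds[c][ms.gene_index] = folds[c].get(ms.gene_index, 1.0) * ms.fold

    cluster_of = np.repeat(np.arange(1, config.n_clusters + 1), config.cluster_sizes)
    theta = config.nb_dispersion
    blocks = []
    start = 0
    for c, size in enumerate(config.cluster_sizes, start=1):
        gene_mean = mu * config.class_factor[c - 1, class_idx]
        if c in folds:
            gidx = np.fromiter(folds[c].keys(), dtype=int)
            gene_mean = gene_mean.copy()
            gene_mean[gidx] *= np.fromiter(folds[c].values(), dtype=float)
        mean = lib[start:start + size, None] * gene_mean[None, :]
        if np.isinf(theta):
            block = rng.poisson(mean)
        else:
            block = rng.poisson(rng.gamma(theta, mean / theta))
        blocks.append(sp.csr_matrix(block, dtype=np.int64))
        start += size

    counts = sp.vstack(blocks, format="csr")
    barcodes = np.array([f"BC{i:06d}-1" for i in range(n_cells)], dtype=object)
    matrix = UmiMatrix(counts, barcodes, gene_ids)
    annotation = GeneAnnotation(pd.Series(arms, index=gene_ids))
    rank_of_label = {lab: r for r, lab in enumerate(config.stage_order)}
    truth = GroundTruth(
        true_cluster=pd.Series(cluster_of, index=barcodes),
        true_pseudorank=pd.Series([rank_of_label[c] for c in cluster_of], index=barcodes),
        class_factor=config.class_factor.copy(),
        markers=list(config.marker_spec),
        stage_order=list(config.stage_order),
    )
    return matrix, annotation, truth


# ---------------------------------------------------------------------------
# canonical configurations
# ---------------------------------------------------------------------------

#: cluster sizes in developmental order (hub cells ... mature spermatozoa);
#: sums to 4443 cells with the smallest cluster of 11 and largest of 1338.
TESTIS_LIKE_CLUSTER_SIZES = (11, 50, 200, 600, 900, 1338, 800, 544)

#: injected X/A regime along the stages: compensated hub cells, overexpressing
#: GSCs, uncompensated primary spermatogonia, then progressive silencing.
TESTIS_LIKE_X_FACTORS = (1.0, 1.11, 0.5, 0.3, 0.25, 0.2, 0.15, 0.1)

#: mild meiotic bump on the Y contigs; mitochondrial surge in spermatozoa.
TESTIS_LIKE_Y_FACTORS = (1.0, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 1.0)
TESTIS_LIKE_MT_FACTORS = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 8.0)

#: gene index of the vasa-like root marker (premeiotic, peaks in GSCs)
ROOT_MARKER_INDEX = 0

_OWN_BLOCK = 25    # genes uniquely marking one stage
_BRIDGE_BLOCK = 15  # genes shared by two consecutive stages
_OWN_FOLD = 8.0
_BRIDGE_FOLD = 6.0
_ROOT_FOLD = 12.0
# the somatic hub cells are a different lineage from the germline: beyond the
# stage block they carry a strong somatic program (hub markers are observed at
# log2 fold changes near 10 in testis data), without which an 11-cell cluster
# is invisible to dispersion-ranked gene selection
_HUB_BLOCK = 30
_HUB_FOLD = 150.0
_GSC_FOLD = 16.0   # stem-cell maintenance genes are sharply GSC-enriched


def default_testis_config(seed: int = 0) -> SimulationConfig:
    """Configuration emulating the real germline dataset's structure.

    4443 cells in 8 stage-ordered clusters (11..1338 cells), ~11k genes
    across the five chromosome arms plus Y contigs and mitochondrial genes,
    marker programs with single-stage and consecutive-stage (bridge) blocks
    so that neighbouring stages share expression, and the canonical
    chromosome-class regimes above. The baseline-mean constants are
    calibrated so the median genes-detected per cell lands near the
    2000-3500 window typical of this tissue.
    """
    sizes = list(TESTIS_LIKE_CLUSTER_SIZES)
    k = len(sizes)
    factor = np.ones((k, len(CLASSES)))
    factor[:, CLASSES.index("X")] = TESTIS_LIKE_X_FACTORS
    factor[:, CLASSES.index("Y")] = TESTIS_LIKE_Y_FACTORS
    factor[:, CLASSES.index("MT")] = TESTIS_LIKE_MT_FACTORS

    markers: list[MarkerSpec] = [
        MarkerSpec(ROOT_MARKER_INDEX, (2,), _ROOT_FOLD, STAGE_CELL_TYPES[1])
    ]
    next_gene = 1
    for s in range(k):  # stage-specific programs
        fold = _GSC_FOLD if s == 1 else _OWN_FOLD
        for _ in range(_OWN_BLOCK):
            markers.append(MarkerSpec(next_gene, (s + 1,), fold,
                                      STAGE_CELL_TYPES[s]))
            next_gene += 1
    for s in range(k - 1):  # programs persisting into the next stage
        for _ in range(_BRIDGE_BLOCK):
            markers.append(MarkerSpec(next_gene, (s + 1, s + 2), _BRIDGE_FOLD))
            next_gene += 1
    for _ in range(_HUB_BLOCK):  # somatic lineage program of the hub cells
        markers.append(MarkerSpec(next_gene, (1,), _HUB_FOLD,
                                  STAGE_CELL_TYPES[0]))
        next_gene += 1

    return SimulationConfig(
        seed=seed,
        cluster_sizes=sizes,
        genes_per_class={"2R": 2500, "2L": 2500, "3R": 2500, "3L": 2500,
                         "X": 1000, "Y": 50, "MT": 15},
        class_factor=factor,
        marker_spec=markers,
        stage_order=list(range(1, k + 1)),
    )


def ratio_recovery_config(
    x_factors,
    cells_per_cluster: int = 500,
    n_x_genes: int = 1000,
    n_autosomal_genes: int = 10000,
    seed: int = 0,
) -> SimulationConfig:
    """Marker-free config with one cluster per injected X/A factor.

    Used to test that the dosage statistics recover known X regimes from
    a clean simulation (no marker programs, uniform Y/MT factors).
    """
    x_factors = list(x_factors)
    k = len(x_factors)
    per_arm = n_autosomal_genes // 4
    extra = n_autosomal_genes - 4 * per_arm
    factor = np.ones((k, len(CLASSES)))
    factor[:, CLASSES.index("X")] = x_factors
    return SimulationConfig(
        seed=seed,
        cluster_sizes=[cells_per_cluster] * k,
        genes_per_class={"2R": per_arm + extra, "2L": per_arm,
                         "3R": per_arm, "3L": per_arm,
                         "X": n_x_genes, "Y": 0, "MT": 0},
        class_factor=factor,
        stage_order=list(range(1, k + 1)),
    )


def default_marker_table(config: SimulationConfig) -> pd.DataFrame:
    """Marker table (gene_id, cell_type, stage_rank) for annotation tests.

    Lists every single-stage marker of the config (bridge markers carry no
    cell type and are omitted).
    """
    gene_ids, _ = gene_layout(config)
    rank = {t: r for r, t in enumerate(STAGE_CELL_TYPES)}
    rows = [
        {"gene_id": gene_ids[ms.gene_index], "cell_type": ms.cell_type,
         "stage_rank": rank.get(ms.cell_type, 0)}
        for ms in config.marker_spec
        if ms.cell_type is not None
    ]
    return pd.DataFrame(rows, columns=["gene_id", "cell_type", "stage_rank"])


def root_marker_gene(config: SimulationConfig) -> str:
    """Gene id of the config's vasa-like root marker (first typed marker)."""
    gene_ids, _ = gene_layout(config)
    for ms in config.marker_spec:
        if ms.cell_type == STAGE_CELL_TYPES[1]:
            return str(gene_ids[ms.gene_index])
    raise ValueError("config has no germline-stem-cell marker to use as root")
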