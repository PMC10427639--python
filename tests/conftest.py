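import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import spermscan as ss
from spermscan import cluster as cl
from spermscan import qc
from spermscan.datatypes import ClusterAssignment, GeneAnnotation, UmiMatrix


def make_matrix(dense, barcodes=None, gene_ids=None) -> UmiMatrix:
    dense = np.asarray(dense)
    n, g = dense.shape
    barcodes = barcodes or [f"cell{i}" for i in range(n)]
    gene_ids = gene_ids or [f"gene{j}" for j in range(g)]
    return UmiMatrix(sp.csr_matrix(dense), np.array(barcodes, dtype=object),
                     np.array(gene_ids, dtype=object))


@pytest.fixture
def tiny_annotation():
    return GeneAnnotation.from_mapping(
        {"gene0": "X", "gene1": "2L", "gene2": "Y", "gene3": "MT",
         "gene4": "3R", "gene5": "weird"}
    )


@pytest.fixture(scope="session")
def testis_sim():
    """One testis-like simulation shared by the slow whole-pipeline tests."""
    cfg = ss.default_testis_config(seed=2026)
    matrix, annotation, truth = ss.simulate_counts(cfg)
    return cfg, matrix, annotation, truth


@pytest.fixture(scope="session")
def testis_clustered(testis_sim):
    """QC'd, normalized, embedded and k=8-clustered testis-like simulation."""
    cfg, matrix, annotation, truth = testis_sim
    filtered = qc.filter_genes_expressed(qc.filter_cells_min_genes(matrix, 200))
    norm = cl.normalize_log(filtered)
    emb = cl.pca_embed(norm)
    clusters = cl.kmeans_cluster(emb, 8, seed=11)
    return filtered, norm, emb, clusters


def two_cluster_assignment(barcodes, n_first) -> ClusterAssignment:
    labels = pd.Series([1] * n_first + [2] * (len(barcodes) - n_first),
                       index=pd.Index(barcodes))
    return ClusterAssignment(labels=labels, k=2)
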