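import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_matrix, two_cluster_assignment
from spermscan import diffexpr
from spermscan.datatypes import GeneAnnotation


def brute_force_rank_sum_p(a, b):
    """Independent oracle: enumerate every assignment of the pooled ranks."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    w_obs = ranks[: len(a)].sum()
    n, n1 = len(pooled), len(a)
    mu = n1 * (n + 1) / 2
    hits = total = 0
    for sub in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(sub)].sum() - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total


def test_benjamini_hochberg_step_up():
    np.testing.assert_allclose(
        diffexpr.benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(diffexpr.benjamini_hochberg([0.2]), [0.2])
    np.testing.assert_allclose(
        diffexpr.benjamini_hochberg([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])


def test_benjamini_hochberg_rejects_nan():
    with pytest.raises(ValueError):
        diffexpr.benjamini_hochberg([0.1, np.nan])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_benjamini_hochberg_properties(p):
    adj = diffexpr.benjamini_hochberg(p)
    assert np.all(adj >= np.asarray(p) - 1e-12)  # adjustment never lowers p
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in sorted order


def test_de_matches_hand_computation_on_four_cells():
    """log2fc and p on a 4-cell, 2-gene matrix equal brute-force values."""
    dense = np.array([[10, 1], [8, 0], [0, 5], [1, 7]])
    m = make_matrix(dense)
    clusters = two_cluster_assignment(m.barcodes, 2)
    de = diffexpr.globally_distinguishing_de(m, clusters)

    depth = dense.sum(axis=1)
    median_depth = np.median(depth)
    norm = dense * (median_depth / depth)[:, None]
    eps = 1.0 / median_depth
    for cluster, rows in ((1, [0, 1]), (2, [2, 3])):
        rest = [i for i in range(4) if i not in rows]
        for g, gene in enumerate(["gene0", "gene1"]):
            expect_fc = np.log2((norm[rows, g].mean() + eps)
                                / (norm[rest, g].mean() + eps))
            expect_p = brute_force_rank_sum_p(norm[rows, g], norm[rest, g])
            row = de[(de.cluster == cluster) & (de.gene_id == gene)].iloc[0]
            assert row.log2fc == pytest.approx(expect_fc)
            assert row.p == pytest.approx(expect_p, abs=1e-12)


def test_de_null_gene_not_enriched():
    rng = np.random.default_rng(0)
    dense = rng.poisson(5, size=(40, 3))
    m = make_matrix(dense)
    clusters = two_cluster_assignment(m.barcodes, 20)
    de = diffexpr.globally_distinguishing_de(m, clusters)
    assert np.all(np.abs(de.log2fc) < 0.5)
    assert not de.enriched.any()


def test_de_antisymmetric_for_two_equal_clusters():
    rng = np.random.default_rng(1)
    dense = rng.poisson(4, size=(30, 5)) + 1
    m = make_matrix(dense)
    clusters = two_cluster_assignment(m.barcodes, 15)
    de = diffexpr.globally_distinguishing_de(m, clusters)
    fc = de.pivot(index="gene_id", columns="cluster", values="log2fc")
    np.testing.assert_allclose(fc[1], -fc[2], atol=1e-10)


def test_enrichment_flag_follows_rule():
    rng = np.random.default_rng(2)
    dense = rng.poisson(5, size=(60, 50))
    dense[:30, 0] += 40  # strongly enriched in cluster 1, small depth shift
    m = make_matrix(dense)
    clusters = two_cluster_assignment(m.barcodes, 30)
    de = diffexpr.globally_distinguishing_de(m, clusters)
    flagged = de[de.enriched]
    assert set(zip(flagged.cluster, flagged.gene_id)) == {(1, "gene0")}
    assert np.all(de.p_adj >= de.p - 1e-12)


def test_enrichment_partition_toy_and_conservation():
    de = pd.DataFrame({
        "cluster": [1, 1, 2, 2, 1],
        "gene_id": ["a", "b", "b", "c", "d"],
        "log2fc": 2.0, "p": 0.001, "p_adj": 0.001,
        "enriched": [True, True, True, True, False],
    })
    part = diffexpr.enrichment_partition(de)
    assert part == {frozenset({1}): 1, frozenset({1, 2}): 1, frozenset({2}): 1}
    assert sum(part.values()) == 3  # distinct enriched genes


def test_enrichment_by_chromosome_row_sums():
    de = pd.DataFrame({
        "cluster": [1, 1, 2],
        "gene_id": ["a", "b", "c"],
        "log2fc": 2.0, "p": 0.001, "p_adj": 0.001, "enriched": True,
    })
    ann = GeneAnnotation.from_mapping({"a": "X", "b": "2R", "c": "X"})
    table = diffexpr.enrichment_by_chromosome(de, ann)
    assert table.loc[1].sum() == 2 and table.loc[2].sum() == 1
    assert table.loc[1, "X"] == 1
    empty = diffexpr.enrichment_by_chromosome(de[de.cluster > 5], ann)
    assert empty.empty


def test_annotate_clusters_scores_and_ties():
    de = pd.DataFrame({
        "cluster": [1, 1, 1, 2],
        "gene_id": ["m1", "m2", "m3", "m1"],
        "log2fc": [3.0, 1.5, 2.0, 0.2],
        "p": 0.001, "p_adj": 0.001,
        "enriched": [True, True, True, False],
    })
    markers = pd.DataFrame({
        "gene_id": ["m1", "m2", "m3", "absent"],
        "cell_type": ["A", "A", "B", "B"],
        "stage_rank": [0, 0, 1, 1],
    })
    result = diffexpr.annotate_clusters(de, markers)
    assert result[1] == ("A", pytest.approx(4.5))  # 3.0 + 1.5 beats 2.0
    assert result[2] == ("unassigned", 0.0)        # nothing enriched


def test_annotate_clusters_warns_on_missing_marker(caplog):
    de = pd.DataFrame({"cluster": [1, 2], "gene_id": ["g", "g"],
                       "log2fc": [2.0, 0.0], "p": 0.01, "p_adj": 0.01,
                       "enriched": [True, False]})
    markers = pd.DataFrame({"gene_id": ["g", "nope"],
                            "cell_type": ["A", "B"], "stage_rank": [0, 1]})
    with caplog.at_level("WARNING"):
        result = diffexpr.annotate_clusters(de, markers)
    assert result[1][0] == "A"
    assert any("absent" in r.message for r in caplog.records)


def test_hypergeom_closed_form():
    universe = {f"g{i}" for i in range(10)}
    query = {"g0", "g1", "g2", "g3"}
    categories = {"hit": {"g0", "g1", "g2", "g3", "g4"},
                  "miss": {"g5", "g6", "g7", "g8", "g9"},
                  "self": set(query)}
    table = diffexpr.hypergeom_overrepresentation(query, categories, universe)
    t = table.set_index("term")
    # P(all 4 draws in a 5-member category) = C(5,4)*C(5,0)/C(10,4)
    assert t.loc["hit", "p"] == pytest.approx(5 / 210)
    assert t.loc["miss", "p"] == pytest.approx(1.0)
    assert t.loc["self", "p"] == pytest.approx(1 / 210)
    assert t.loc["self", "k"] == 4


def test_hypergeom_input_validation():
    with pytest.raises(ValueError, match="universe"):
        diffexpr.hypergeom_overrepresentation(set(), {}, set())
    with pytest.raises(ValueError, match="subset"):
        diffexpr.hypergeom_overrepresentation({"x"}, {}, {"y"})
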