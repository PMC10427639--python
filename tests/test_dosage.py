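import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from conftest import make_matrix, two_cluster_assignment
from spermscan import dosage
from spermscan.datatypes import ClusterAssignment, GeneAnnotation


def enumeration_oracle(a, b):
    """Two-sided rank-sum p by full enumeration of rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    n, n1 = len(pooled), len(a)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2
    hits = total = 0
    for sub in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(sub)].sum() - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxonRankSum:
    def test_identical_multisets_give_p_one(self):
        assert dosage.wilcoxon_rank_sum([1.0, 5.0, 5.0], [1.0, 5.0, 5.0]) == 1.0
        assert dosage.wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_hand_enumerated_two_vs_two(self):
        # a fully below b: 2 of the C(4,2)=6 rank splits are as extreme
        assert dosage.wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            dosage.wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(1, 5), (3, 3), (4, 5), (2, 8)])
    def test_exact_branch_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            assert dosage.wilcoxon_rank_sum(a, b) == pytest.approx(
                enumeration_oracle(a, b), abs=1e-12)

    def test_matches_scipy_exact_and_asymptotic(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=5), rng.normal(size=6)
        assert dosage.wilcoxon_rank_sum(a, b) == pytest.approx(
            scipy.stats.mannwhitneyu(a, b, method="exact").pvalue, abs=1e-12)
        a, b = rng.normal(size=40), rng.normal(size=55) + 0.4
        assert dosage.wilcoxon_rank_sum(a, b) == pytest.approx(
            scipy.stats.mannwhitneyu(a, b, method="asymptotic",
                                     use_continuity=True).pvalue, abs=1e-12)

    def test_branch_agreement_at_boundary(self):
        """Exact and approximate p differ by < 0.02 at pooled n = 12."""
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(100):
            a, b = rng.normal(size=6), rng.normal(size=6)
            pooled = np.concatenate([a, b])
            ranks = scipy.stats.rankdata(pooled)
            exact = dosage.wilcoxon_rank_sum(a, b)
            approx = dosage._approx_two_sided_p(float(ranks[:6].sum()), 6, 6, 0.0)
            worst = max(worst, abs(exact - approx))
        assert worst < 0.02

    def test_vectorised_split_matches_scalar_approx(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(3, size=(30, 8)).astype(float)
        mask = np.zeros(30, dtype=bool)
        mask[:12] = True
        ranks, tie = dosage.pooled_rank_precompute(x)
        p_vec = dosage.rank_sum_pvalues_split(ranks, tie, mask)
        for j in range(8):
            pooled = x[:, j]
            expected = dosage._approx_two_sided_p(
                float(scipy.stats.rankdata(pooled)[mask].sum()), 12, 18,
                dosage._tie_term(pooled))
            assert p_vec[j] == pytest.approx(expected, abs=1e-12)


def test_bonferroni_arithmetic_and_validation():
    np.testing.assert_allclose(dosage.bonferroni([0.01], 8), [0.08])
    np.testing.assert_allclose(dosage.bonferroni([0.5], 8), [1.0])
    np.testing.assert_allclose(dosage.bonferroni([0.3], 1), [0.3])
    with pytest.raises(ValueError):
        dosage.bonferroni([0.1, 0.2], 1)


@pytest.fixture
def toy_annotation():
    return GeneAnnotation.from_mapping(
        {"gene0": "X", "gene1": "2L", "gene2": "Y", "gene3": "MT",
         "gene4": "nonsense"})


def test_rna_content_hand_matrix(toy_annotation):
    m = make_matrix([[3, 4, 1, 9, 2],
                     [0, 5, 0, 0, 0]])
    clusters = two_cluster_assignment(m.barcodes, 1)
    content = dosage.rna_content_per_cell(m, toy_annotation, clusters)
    row = content.iloc[0]
    assert (row.umi_autosome, row.umi_X, row.umi_Y) == (4, 3, 1)
    assert row.umi_MT == 9 and row.umi_unknown == 2
    # cell expressing only autosomal genes
    row2 = content.iloc[1]
    assert (row2.umi_autosome, row2.umi_X, row2.umi_Y) == (5, 0, 0)
    # conservation: per-class totals equal the class's gene column sums
    assert content.umi_X.sum() == m.to_dense()[:, 0].sum()
    assert content.umi_autosome.sum() == m.to_dense()[:, 1].sum()


def test_content_comparison_exact_and_counting(toy_annotation):
    content = pd.DataFrame({
        "barcode": [f"c{i}" for i in range(6)],
        "cluster": [1, 1, 1, 2, 2, 2],
        "umi_autosome": [5, 5, 5, 50, 50, 50],
        "umi_X": [10, 11, 12, 10, 11, 12],
        "umi_Y": [0, 0, 0, 0, 0, 0],
        "umi_MT": 0, "umi_unknown": 0,
    })
    tests = dosage.compare_content_consecutive(content, [1, 2])
    assert len(tests) == 3  # (k-1) pairs x 3 classes
    aut = tests[tests["class"] == "autosome"].iloc[0]
    # (5,5,5) vs (50,50,50): complete separation; the within-group ties
    # route this through the tie-corrected approximation, which calls the
    # increase significant before correction
    assert aut.p == pytest.approx(scipy.stats.mannwhitneyu(
        [50, 50, 50], [5, 5, 5], method="asymptotic",
        use_continuity=True).pvalue, abs=1e-12)
    assert aut.p < 0.05
    assert aut.direction == "increase"
    ycls = tests[tests["class"] == "Y"].iloc[0]
    assert ycls.p == 1.0 and ycls.direction == "none"
    assert np.all(tests.p_adj >= tests.p - 1e-12)


def test_content_comparison_flags_tiny_cluster(caplog):
    content = pd.DataFrame({
        "barcode": ["a", "b", "c"], "cluster": [1, 2, 2],
        "umi_autosome": [1, 2, 3], "umi_X": [1, 2, 3],
        "umi_Y": [0, 0, 0], "umi_MT": 0, "umi_unknown": 0,
    })
    with caplog.at_level("WARNING"):
        tests = dosage.compare_content_consecutive(content, [1, 2])
    assert tests.p.isna().all()
    assert (tests.direction == "indeterminate").all()


def test_gene_cluster_log_counts_values():
    m = make_matrix([[0, 3, 1],
                     [0, 4, 0]])
    clusters = two_cluster_assignment(m.barcodes, 2)
    # single cluster containing both cells
    single = ClusterAssignment(
        labels=pd.Series({"cell0": 1, "cell1": 1}), k=1)
    glc = dosage.gene_cluster_log_counts(m, single)
    np.testing.assert_array_equal(glc.raw[0], [0, 7, 1])
    np.testing.assert_allclose(glc.log2[0], [0.0, 3.0, 1.0])  # log2(raw+1)
    del clusters


class TestXaRatio:
    def make_glc(self, x_raw, a_raw):
        raw = np.array([list(x_raw) + list(a_raw)])
        gene_ids = np.array(
            [f"x{i}" for i in range(len(x_raw))]
            + [f"a{i}" for i in range(len(a_raw))], dtype=object)
        ann = GeneAnnotation.from_mapping(
            {**{f"x{i}": "X" for i in range(len(x_raw))},
             **{f"a{i}": "2R" for i in range(len(a_raw))}})
        glc = dosage.GeneClusterCounts(
            raw=raw, log2=np.log2(raw + 1.0), cluster_labels=[1],
            gene_ids=gene_ids)
        return glc, ann

    def test_identical_distributions_give_unit_ratio(self):
        glc, ann = self.make_glc([1, 3, 7], [1, 3, 7])
        row = dosage.xa_ratio_per_cluster(glc, ann, "X").iloc[0]
        assert row.ratio == 1.0 and row.p == 1.0
        assert row.regime == "dosage_compensated"

    def test_toy_medians_and_halved_ratio(self):
        # X log2 values (1,2,3) vs autosomal (2,3,4): medians 2 and 3
        glc, ann = self.make_glc([1, 3, 7], [3, 7, 15])
        row = dosage.xa_ratio_per_cluster(glc, ann, "X").iloc[0]
        assert row.median_class == 2.0 and row.median_A == 3.0
        assert row.ratio == pytest.approx(0.5)

    def test_tie_free_toy_p_is_exactly_enumerated(self):
        # X log2 (0,1,2) vs A (3,4,5): complete separation of 3 vs 3
        glc, ann = self.make_glc([0, 1, 3], [7, 15, 31])
        row = dosage.xa_ratio_per_cluster(glc, ann, "X").iloc[0]
        assert row.p == pytest.approx(2 / 20, abs=1e-12)

    def test_ratio_invariant_to_depth_scaling_at_high_counts(self):
        rng = np.random.default_rng(0)
        x = rng.integers(2000, 50000, size=40)
        a = rng.integers(2000, 50000, size=200)
        glc1, ann = self.make_glc(x, a)
        glc2, _ = self.make_glc(8 * x, 8 * a)
        r1 = dosage.xa_ratio_per_cluster(glc1, ann, "X").iloc[0].ratio
        r2 = dosage.xa_ratio_per_cluster(glc2, ann, "X").iloc[0].ratio
        assert r2 == pytest.approx(r1, rel=1e-3)

    def test_too_few_class_genes_rejected(self):
        glc, ann = self.make_glc([5], [1, 2, 3])
        with pytest.raises(ValueError, match="need >= 2"):
            dosage.xa_ratio_per_cluster(glc, ann, "X")

    def test_log_ratio_scale_option(self):
        glc, ann = self.make_glc([1, 3, 7], [3, 7, 15])
        row = dosage.xa_ratio_per_cluster(glc, ann, "X",
                                          ratio_scale="log").iloc[0]
        assert row.ratio == pytest.approx(2.0 / 3.0)


class TestClassifyRegime:
    @pytest.mark.parametrize("ratio,p_adj,expected", [
        (1.113, 0.002, "overexpression"),     # X peak in germline stem cells
        (0.488, 1e-70, "no_compensation"),    # single-copy X expression
        (1.0, 1.0, "dosage_compensated"),
        (0.95, 0.5, "dosage_compensated"),    # not significant, whatever ratio
        (0.30, 0.001, "silenced"),            # meiotic silencing signature
        (0.80, 0.001, "indeterminate"),       # significant but between regimes
        (0.65, 0.001, "no_compensation"),     # band edges inclusive
        (0.40, 0.001, "no_compensation"),
    ])
    def test_rule(self, ratio, p_adj, expected):
        assert dosage.classify_regime(ratio, p_adj) == expected

    def test_thresholds_configurable(self):
        assert dosage.classify_regime(0.8, 0.001,
                                      band_no_dc=(0.7, 0.9)) == "no_compensation"
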