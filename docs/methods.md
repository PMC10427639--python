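# Methods

## The scientific question and the statistics

In male insects the X chromosome is present in a single copy. Three
chromosome-wide regimes are distinguishable from expression data within a
population of cells:

- **dosage compensation** — X-linked output is up-regulated to match the
  two-copy autosomes, so the X-to-autosome expression ratio X/A ≈ 1;
- **no compensation** — the single X is transcribed at per-copy parity
  with the autosomes, X/A ≈ 0.5;
- **silencing** — X/A falls below what a copy-number effect alone can
  explain; during spermatogenesis this is the signature of meiotic sex
  chromosome inactivation (MSCI), which begins around meiosis and persists
  into the postmeiotic stages.

The pipeline estimates the regime per cell cluster. Counts for each gene
are summed over the cluster's cells and transformed as log2(count + 1).
Within a cluster, let `m_X` and `m_A` be the medians of these per-gene log
values over X-linked and autosomal genes. The reported ratio is

    X/A = 2^(m_X − m_A)

i.e. the linear-scale ratio of the median-typical expression levels. The
alternative of dividing the two log medians directly is exposed behind
`ratio_scale="log"` for sensitivity analysis, but it is not the default:
interpreting "0.5" as halved expression is only coherent on the linear
scale, and the quotient of logarithms depends on the arbitrary pseudocount
and count depth.

Departure from 1:1 is tested with a two-sided Wilcoxon rank-sum test on
the two per-gene log-value vectors, Bonferroni-corrected across clusters
(one family per class pair, the default `m` = number of clusters;
configurable for stricter families). The regime call is rule-based:

| condition                                | call                |
|------------------------------------------|---------------------|
| adjusted p ≥ α (= 0.05)                  | dosage_compensated  |
| significant, ratio > 1                   | overexpression      |
| significant, ratio ∈ [0.40, 0.65]        | no_compensation     |
| significant, ratio < 0.40                | silenced            |
| significant, ratio ∈ (0.65, 1]           | indeterminate       |

The band edges implement "approximately 0.5" and "approximately 1"
explicitly; they are configurable arguments, and the defaults are
deliberately wide enough that sampling noise around a true 0.5 does not
leak into the silenced call.

Per-cell **RNA content** (the summed UMIs mapping to autosomes, X, and Y
contigs; mitochondrial and unannotated genes tallied separately) is
compared between *consecutive* clusters of the developmental order with
the same rank-sum test, Bonferroni family = (pairs × classes).

## The Wilcoxon rank-sum implementation

The rank-sum p-value is computed by this package rather than delegated,
because the exact-versus-approximate branching is part of the contract:

- pooled n ≤ 12 and no ties: exact two-sided p from the full null
  distribution of the rank sum, obtained by subset-sum dynamic programming
  in integer arithmetic (`P(|W − E W| ≥ |w_obs − E W|)`);
- otherwise: normal approximation with tie correction and a 0.5 continuity
  correction.

Identical constant samples return p = 1. At the branch boundary (n = 12,
tie-free) the two methods agree to < 0.02, which is verified in the test
suite, as is exact agreement (≤ 1e-12) with full enumeration for all
tie-free inputs with pooled n ≤ 10 and agreement with an independent
library implementation on both branches. For the cluster-vs-rest DE scan
the pooled ranking of each gene is computed once and reused for every
cluster split — the pooled ranks do not depend on the split — which makes
the per-cluster p-values identical to the scalar routine at a fraction of
the cost.

## Differential expression and enrichment

Cells are scaled to the median depth (linear scale). For cluster c and
gene g,

    log2FC = log2((mean_c + ε) / (mean_rest + ε)),   ε = 1 / median depth,

and p comes from the rank-sum test of the gene's normalized counts in c
versus all other cells. Benjamini–Hochberg runs within each cluster across
genes (the most common family convention). A gene is *enriched* iff
log2FC > 1 and adjusted p < 0.05. The pseudocount ε ties the fold-change
floor to the depth scale so zero-mean groups stay finite without
dominating moderate counts.

Marker-based annotation scores each (cluster, cell type) as the sum of
positive fold changes of that type's markers *that are enriched in the
cluster*; the argmax type wins, ties break toward the earlier stage, and
score-0 clusters stay "unassigned". Over-representation of arbitrary gene
categories uses the one-sided hypergeometric upper tail with BH across
terms — a database-free stand-in for ontology-service analyses.

## Clustering and pseudotime

Normalization: per-cell scaling to a common target depth (median by
default) followed by log2(1 + x). Gene selection: top 1000 genes by
dispersion (variance/mean) of the normalized values. Embedding: exact SVD
of the centered selection, 10 components, with a fixed sign convention
(largest-|loading| coordinate positive) for determinism. Clustering:
Lloyd k-means with k-means++ seeding, best of 10 restarts by inertia,
labels renumbered by decreasing size. All of these are configurable; the
defaults are ordinary droplet-pipeline choices made explicit and testable.

Pseudotime deliberately replaces learned principal graphs with something
desk-scale and deterministic: the Euclidean minimum spanning tree over
cluster centroids in the embedding. The root cluster is the one with peak
mean normalized expression of a chosen premeiotic marker. A cell's
pseudotime is the tree distance from the root centroid to its cluster's
centroid plus its own distance to that centroid, shifted so the minimum is
exactly zero. Only the ordinal structure is meaningful; units are
arbitrary, and scaling the embedding scales pseudotime linearly.

## The synthetic-data generator

For gene g (chromosome class K, baseline mean μ_g) and cell i (cluster c,
library factor L_i):

    counts[i, g] ~ NegativeBinomial(mean = L_i · μ_g · m_gc · F[c, K],
                                    size = θ)

- μ_g is log-normal; Y-contig baselines are scaled down 10× (the Y is
  expressed at very low levels throughout spermatogenesis);
- L_i is log-normal with mean 1 (σ = 0.35), giving a realistic depth
  spread that normalization must remove;
- m_gc is the marker fold: stage-specific blocks (25 genes, fold 8), 
  "bridge" blocks shared by consecutive stages (15 genes, fold 6) so that
  neighbouring stages are transcriptionally adjacent and a spanning tree
  over centroids follows the developmental chain, a vasa-like root marker
  (fold 12) peaking in the stem-cell-like cluster, and a strong somatic
  program in the hub-like cluster (30 genes, fold 150; hub markers in real
  testis data reach log2 fold changes near 10). Without that somatic
  program an 11-cell cluster is invisible to dispersion-ranked gene
  selection — variance/mean over 4443 cells barely registers a program
  confined to 0.25% of them;
- F is the cluster × class factor matrix carrying the injected regimes.
  The testis-like defaults: X factors (1.0, 1.11, 0.5, 0.3, 0.25, 0.2,
  0.15, 0.1) along the stage order, a mild meiotic bump on the Y, and a
  mitochondrial surge in the spermatozoa-like cluster.

Calibrated constants: `base_mean_log_mu = ln 0.28` sets the detected-genes
median of the testis-like configuration near 2300 (within the 2000–3500
window typical of this tissue); `base_mean_log_sigma = 0.2` was chosen by
a power analysis so that a 1.11× shift of 1000 X genes against 10 000
autosomal genes is reliably detectable by the rank-sum test at
Bonferroni-corrected α = 0.05 — with a much wider baseline spread the
median test has no power against an 11% shift at these gene counts;
`nb_dispersion θ = 2` keeps standard UMI overdispersion.

What the generator does *not* emulate: ambient RNA, doublets, batch
effects, gene–gene correlation beyond the shared factors, per-gene
dispersion variation, FACS selection distortions of cluster proportions,
or read-level artefacts. Passing recovery tests therefore demonstrates the
statistics are implemented correctly and are identifiable under clean
conditions, not that real data meet these assumptions.

## Numerical and degenerate-input choices

- Genes with zero counts in a cluster enter that cluster's median at log
  value 0 by default (`drop_zero_genes` excludes them); the summed-counts
  basis makes the ratio invariant to the sum-versus-mean choice within a
  cluster.
- Zero-depth cells are dropped with a warning at normalization; clusters
  with < 2 cells give indeterminate content comparisons; ratio rows with
  too few expressed genes are NaN with regime "indeterminate".
- MatrixMarket files are 1-based on disk (format standard), 0-based in
  memory; the 10x genes × cells orientation is auto-detected against the
  TSV line counts. Unrecognised chromosome arms map to class UNKNOWN and
  are excluded from both the autosomal reference and the content classes.
- k-means determinism is per (data, seed); permuting the input cells can
  change the restart draws, so order invariance is guaranteed (and tested)
  at the level of the recovered partition, not the internal run order.
- Identical cluster centroids in the trajectory are tie-broken by label
  via an infinitesimal deterministic perturbation.

## Problem sizes in the verification suite

The replicated checks use deliberately small configurations chosen to
make their Monte-Carlo tolerances explicit: regime recovery uses the
canonical 1000 X / 10 000 autosomal genes × 500 cells per cluster over 20
replicates; the global-null calibration uses 200 replicates of 150 cells ×
400 genes (dosage) and 100 replicates of 150 cells × 200 genes (DE). The
testis-like configuration (4443 cells × 11 065 genes) runs once per suite
invocation and is shared across the clustering and trajectory checks.

## Known limitations

- The cluster-vs-rest test reuses the cells of the tested cluster in the
  pooled ranking; p-values are valid per comparison but not independent
  across clusters.
- The Bonferroni family for the ratio test defaults to one test per
  cluster per class pair; analyses that sweep both X and Y should consider
  doubling `family_size`.
- MST pseudotime cannot represent branching trajectories; clusters off the
  main path (e.g. somatic hub cells) are placed by their attachment edge,
  which inflates their apparent pseudotime rather than excluding them.
- The regime rule classifies marginal ratios (significant, between 0.65
  and 1) as indeterminate rather than forcing a biological label.
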