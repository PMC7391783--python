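# Methods

## Scope and model

`spherotype` describes functional heterogeneity in two-timepoint
spheroid scRNA-seq: it partitions cells into subpopulations from the
correlation structure of overdispersed genes, attaches biology to each
subpopulation by gene set enrichment, condenses the enriched pathways
into a Jaccard-linked map, and extracts the differentially expressed
genes that drive the map's collections. The statistical core — the
weighted running-sum enrichment statistic with its permutation null, the
overdispersion score, the elbow rule, and the permutation DE test — is
implemented in this package; standard numerics (K-means, Gaussian
mixtures, UMAP, graph components) come from scikit-learn, umap-learn and
networkx.

## Quality control

Cells must detect (count > 0) at least `qc_min_genes` genes
(default 1000, the usual droplet-library floor); the cell filter runs
first, then genes with zero total count over the retained cells are
dropped — a gene seen only in discarded cells disappears. The filter is
idempotent. "Detected genes" (not total reads) is the interpretation of
library complexity used throughout.

## Normalization

Each cell is scaled to a common total (`scale`, default 1e4) and
log1p-transformed. Pearson correlation on raw counts is dominated by
library depth, so normalization always precedes the distance
computation. No batch correction or imputation is attempted.

## Overdispersion score

Per gene, the top `winsor_k = 2` values are clipped to the next-largest
value so one or two outlier cells cannot masquerade as biological
variance. Log variance is regressed on log mean by a running mean over
30 equal-occupancy bins (linearly interpolated between bin centers);
the score is the residual divided by the within-bin residual standard
deviation. Standardizing within local mean bins makes scores comparable
across the expression range: on pure Poisson data the per-bin mean score
is ~0 and fewer than 5% of genes score above 2 (checked by test).
Zero-variance genes are floored to the smallest positive variance and
fall to the bottom of the ranking. Selection takes the top
`features_top_n` (default 6000) scores; ties break by higher mean, then
gene id. The fraction of total per-gene variance carried by a selection
is reported (`variance_fraction`); at the 6000-gene default this is a
property of the data, and on the compact synthetic datasets (≤ 6000
genes) it saturates at 1.

## Distance, embedding, and the two clustering routes

Cell–cell distance is `1 − r` (Pearson over the selected genes), in
[0, 2]. The 2-D embedding is UMAP with `metric="precomputed"`,
`n_epochs = 300` and a fixed seed; constant cell profiles are an error
naming the offending cell.

K-means runs at k = 1..`kmax` (default 8; 25 restarts each) and the
elbow rule picks `k* = argmax_k SSE(k−1) − 2·SSE(k) + SSE(k+1)` over
interior k, ties toward smaller k. Two degeneracies fall back to k = 2
with a warning: a non-decreasing SSE curve, and a near-flat curve whose
two largest second differences are within 25% of each other (no clear
curvature winner — the signature of structureless data, where the
absolute second difference is otherwise maximal at small k by
arithmetic alone).

A known fragility, observed rather than hidden: when clusters are fully
separated, the UMAP k-nn graph is disconnected and the relative
placement of the islands is arbitrary. If the layout lands the islands
near-collinearly, one 2-split removes more than two thirds of the SSE
and the second-difference rule prefers k = 2. The variance-space
K-means does not suffer from this, which is why the pipeline's headline
clustering (the one feeding DE and key genes) is K-means in the
variable-gene space; the UMAP-space run is still computed and reported,
and the cross-method concordance table covers all four routes.

EM clustering fits Gaussian mixtures for k = 1..`kmax` over spherical,
diagonal and full covariances and takes the BIC minimum; non-converged
or singular candidates are skipped. In the gene space (d ≫ n) a raw-
coordinate mixture is not identifiable — BIC oscillates between k = 1
and overfit solutions — so the variance-space EM route first projects
onto 10 principal components, the standard remedy. The EM routes
over-split gracefully: extra components subdivide true clusters, which
the pathway-level concordance (below) reabsorbs.

## GSEA

Ranking: signal-to-noise `(μ_a − μ_b)/(σ_a + σ_b)` with each σ floored
at `max(0.2·|μ|, 0.2)`; ties break lexicographically. The running sum
adds `|s|^p / Σ_hits |s|^p` at set members (p = 1) and subtracts
`1/(N − N_h)` elsewhere; it always ends at 0. ES is the signed maximum
deviation (ties prefer the positive peak); the leading edge is the
members at-or-before a positive peak, at-or-after a negative one.

Null: `n_perm ≥ 100` permutations (default 1000). Phenotype mode
relabels cells and re-ranks (vectorized across permutations); when
either group has < 7 cells it falls back, with a warning, to random
same-size gene sets on the fixed observed ranking (sets of equal size
share one null, which is exactly what that null conditions on). Nominal
p is the same-sign permuted fraction at least as extreme; NES divides
ES by the mean same-sign permuted ES; FDR q follows the sign-stratified
pooled-NES procedure, clipped to [0, 1]. Sets are size-filtered to
[15, 500] members present in the universe. Significance uses strict
inequalities: FDR < 0.05 and p < 0.01, positive ES for "enriched in
this cluster". On exchangeable data the nominal p of 50 random sets is
uniform (KS test, checked), with the caveat that at 50 sets a single
null set occasionally lands below the joint threshold.

## Enrichment map and concordance

Nodes are significant pathways; their gene subset is the leading edge
by default (an `expressed_set` mode restricted to the detected universe
is available — the choice changes node sizes, not the machinery).
Edges require Jaccard strictly above 0.4; collections are the connected
components, labeled with their three most frequent name tokens after
stripping source prefixes (REACTOME, KEGG, HALLMARK, GO, PID, BIOCARTA)
and a small editable stopword list; ties alphabetical, with a flagged
fallback to the pathway name when everything is stopworded. Export:
GraphML (lossless), SIF (topology), JSON (graph + collections).

Cross-method concordance scores every cluster pair across methods by
the Jaccard of their enriched-pathway name sets, matched at ≥ 0.7
(non-strict — a correspondence at exactly 0.7 counts). Many-to-one
matches are expected: an over-split EM cluster matches the K-means
cluster it came from. Clusters with no enriched pathway are emitted
with Jaccard 0 and the note "undefined function".

## Differential expression, Venn, markers, key genes

Per gene, `log2FC = log2((mean_b + c)/(mean_a + c))` on library-size-
normalized means (pseudocount c = 1); the empirical p is
`(1 + #{permuted |log2FC*| ≥ |log2FC|})/(n_perm + 1)` under random
relabeling. The permutation statistic depends only on the unordered
cell partition and the sampled partitions only on the sorted combined
cells, so swapping the groups negates log2FC and preserves p exactly.
Type-I control on exchangeable data: P(p < 0.01) ≈ 0.01 (checked
at ≤ 0.02).

Across the three pairwise comparisons (thresholds |log2FC| > 1.5,
p < 0.01, strict), a gene is cluster-X-specific when it is significant
in both comparisons involving X, with a consistent direction for X, and
not significant in the third — the operational reading of "specific for
a cluster, not for one comparison". Genes significant in all three form
the core. Markers are cluster-specific genes at |log2FC| > 2 (strict),
ordered by magnitude. Note an intrinsic shrinkage effect: for a planted
fold change of exactly 4×, the expected observed log2FC is
`log2((4m + c)/(m + c)) < 2` (compounded by the compositional effect of
normalization), so at the default planted effect of 2 only the upper
noise tail of each program clears the strict marker bar — marker calls
are near-perfectly specific but deliberately conservative. At planted
effects ≥ 3 the programs are recovered essentially in full (checked).

Key genes: per map collection, representative genes are the
leading-edge genes appearing in ≥ 2 of its pathways (a singleton
collection contributes its whole leading edge); each DE gene scores one
hit per collection containing it, and the key genes are the argmax
(ties all reported).

## Synthetic data

The generator emulates: two timepoints with different subpopulation
mixtures (defaults tuned so one cluster is ~85% late cells, one ~80%
early, one mixed, at 170 + 230 cells); 2000 genes with log-normal
baseline means; per-cluster disjoint 100-gene programs shifted by
log2 FC 2; NB counts with dispersion 0.3 (variance m + 0.3 m²);
log-normal library sizes (σ = 0.35); and 20% post-hoc Bernoulli dropout,
independent of the mean — the simplest mechanism that stresses the DE
stage (a mean-dependent variant is not modeled). Programs are emitted
as a GMT collection plus 5 size-matched decoy sets from non-program
genes. Not modeled, hence not demonstrated by passing tests: spatial
gradients and necrotic-core biology, batch effects, cell-cycle
structure, mean-dependent dropout, and the correlated gene-gene
covariance of real transcriptomes; real data is also far less separable
than the planted default, so recovery there is a harder problem than
the one these tests certify.

The sample-size estimator is the normal-approximation formula
`n = ⌈z² p(1−p)/E²⌉` without finite-population correction (z the
two-sided quantile at the chosen confidence). At E = 5%, 90% confidence
it gives 271 at p = 0.5 and 115 at p = 0.88.

## Determinism and problem sizes

One master seed fans out to per-stage seeds via
`(seed·1000003 + crc32(stage)) mod 2³¹`, so adding a stage never
perturbs another stage's stream. All stochastic components (simulator,
K-means restarts, mixtures, UMAP, both permutation tests) are seeded;
identical config + seed + input reproduce the run summary byte for
byte. Default analysis sizes — 2000 × 400 simulated counts, 1000
permutations for GSEA and DE, 25 K-means restarts, kmax 8 — keep a full
end-to-end run under a minute on one CPU; the test suite and the
acceptance script use these same sizes.

## Known limitations

- The overdispersion score is a trend-residual (PAGODA-style), not a
  full error-model fit; rankings agree on strong signals but the exact
  variance fractions of a selection are implementation-dependent.
- The DE stage is a permutation fold-change test, not a dropout-aware
  mixture model; it inherits the conservatism described above.
- The elbow and BIC model selections answer "how many clusters" only up
  to the geometry caveats documented here; the concordance table is the
  robustness instrument, not any single route.
- Collection naming is token frequency, not ontology-aware
  summarization.
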