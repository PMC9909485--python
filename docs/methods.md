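# Methods

This note documents the statistical procedures implemented in
`tissuemark`, the defaults and the reasoning behind them, what the
synthetic generator does and does not emulate, and the numerical
conventions for degenerate inputs.

## Composite tissue-association criterion

For each gene and each tissue, the tissue's samples are compared against
the pooled samples of every other tissue (one-vs-rest). A (gene, tissue)
pair is called a marker when all three gates pass:

| statistic | gate | notes |
|---|---|---|
| Wilcoxon rank-sum p (two-sided) | p < 10⁻¹⁰ | exact enumeration when both groups ≤ 12 and untied; otherwise normal approximation with mid-rank tie correction and continuity correction |
| fold change | ≥ 25 | (mean TPM in tissue + 10⁻⁴) / (mean TPM in rest + 10⁻⁴) |
| LDA ROC-AUC | ≥ 0.85 | resubstitution AUC of a one-feature pooled-variance linear discriminant, target tissue positive |

Design choices that were genuinely open:

* **Fold change uses group means, not medians, with a 10⁻⁴ pseudocount on
  both sides.** Sparsely expressed receptor genes have median 0 in most
  tissues, which would make a median ratio degenerate; the pseudocount is
  the same constant used for the log transform elsewhere, so one constant
  governs all zero-handling. An all-zero gene gets fold change exactly 1.
* **The Wilcoxon test is two-sided and the LDA AUC is orientation-free.**
  For a single feature the discriminant score is an affine transform of
  the expression value, so the AUC equals the Mann–Whitney AUC
  U/(n₁n₂) — or its complement when the fitted discriminant direction
  (sign of the mean difference over the pooled within-class variance) is
  negative. A strongly *under*-expressed gene therefore also scores a high
  AUC and a small p; directionality of the call is enforced exclusively by
  the fold-change gate. With zero pooled variance the AUC is taken directly
  from the class constants (1, 0, or 0.5 on equality); with equal class
  means the score is constant and the AUC is 0.5.
* **No cross-validation.** The criterion is descriptive (which genes
  separate a tissue in this data set), not a generalization benchmark; with
  one feature, CV would only add variance.

The per-tissue heat-map statistic is the z-score, across tissues, of each
gene's per-tissue median TPM, using the sample (n−1) standard deviation;
genes constant across tissues map to an all-zero row.

## Co-expression network

Input is log10(TPM + 10⁻⁴) after a detection filter (TPM > 0 in at least
`min_detected_samples` samples; an integer count, or a fraction of the
selected samples when < 1). Steps:

1. **Soft threshold.** For each candidate power β (default 1..20), signed
   adjacency is computed and the connectivity distribution k is tested for
   approximate scale-freeness: k is histogrammed into 10 log-spaced bins
   (equal width in log10 k), and R² of the regression of log10 p(k) on
   log10 k is recorded, negated when the slope is positive. The chosen β is
   the smallest power with R² ≥ 0.8, else the argmax-R² power with a
   warning. Equal-count binning is *not* used: it makes p(k) constant by
   construction and the fit degenerate. Mean connectivity decreases
   strictly in β, which is tested as an invariant.
2. **Adjacency and TOM.** Signed adjacency a = ((1 + cor)/2)^β maps
   correlation monotonically onto [0, 1] (cor −1 → 0); the topological
   overlap TOM₍ᵢⱼ₎ = (Σ₍ᵤ≠ᵢ,ⱼ₎ a₍ᵢᵤ₎a₍ᵤⱼ₎ + a₍ᵢⱼ₎)/(min(kᵢ,kⱼ) + 1 − a₍ᵢⱼ₎)
   credits shared neighbors. Zero-variance genes get correlation 0 by
   convention (adjacency (1/2)^β) with a warning. TOM correctness is pinned
   to a triple-loop brute-force oracle at 10⁻¹².
3. **Module detection.** Average-linkage hierarchical clustering of
   1 − TOM with a **static cut at 0.75 of the tallest merge height**;
   clusters below `min_module_size` (default 30) are labelled
   "unassigned". The fraction was chosen structurally, not per-dataset: on
   log-scale co-expression data, coherent modules finish assembling in the
   bottom third of the dendrogram while mutually independent genes accrete
   onto existing clusters only near the top, so a cut in the upper region
   (e.g. 0.99) merges background into modules and manufactures a giant
   spurious cluster even on unstructured input. At 0.75 the planted-module
   benchmark is recovered (ARI ≥ 0.9 across seeds) *and* fully independent
   input yields no module at all. The fraction, like every other knob, is
   config-exposed. The full dynamic-hybrid tree cut with PAM is out of
   scope.
4. **Eigengenes and merging.** A module's eigengene is the first principal
   component (unit norm) of its per-gene standardized submatrix, sign-
   oriented to correlate positively with the module mean profile; a
   single-gene module's eigengene is that gene's standardized profile.
   Modules whose eigengene dissimilarity 1 − cor falls below the merge
   height (default 0.25) are merged iteratively, recomputing eigengenes
   each pass to a fixed point; the merge history is recorded.
5. **Labels and export.** Module labels are color names in decreasing
   module-size order (ties broken toward the cluster containing the
   earliest gene), following the field convention that makes "the black
   module" a stable reference. Edges with TOM above the cutoff (default
   0.025) are exported as weighted TSV and SIF. Internally genes are
   processed in lexicographic order so the fit is bit-reproducible under
   input permutations.

## Maximum-MI sub-networks

Within one module, a conservative network keeps per gene at most one
edge: the link to its maximum-mutual-information partner, provided the MI
exceeds a permutation-null threshold. Ties at the argmax resolve toward
the lexicographically smallest gene ID. Connected components of the
resulting undirected graph are the sub-networks; a component's size rank
answers "which gene sits in the largest sub-network".

MI estimators (the original method names none, so both are provided and
config-exposed):

* `gaussian_rank` (default): ranks → normal scores, MI = −½ ln(1 − ρ²)
  with ρ their Pearson correlation. Exact for a Gaussian copula, invariant
  under strictly monotone transforms, deterministic. For |ρ| → 1 the
  estimate is capped by clipping ρ² at 1 − 10⁻¹² (≈ 13.8 nats).
* `binned`: plug-in MI over an equal-frequency 2-D histogram with
  Miller–Madow correction (Kₓ + Kᵧ − Kₓᵧ − 1)/(2n) over occupied cells,
  floored at 0. The per-axis bin count defaults to ⌈√(n/5)⌉ so each joint
  cell keeps about five expected counts; with √n bins per axis the joint
  histogram is so sparse that the corrected estimate retains ~0.27 nats of
  bias on independent inputs at n = 1000, versus ≤ 0.01 at the chosen
  default.

The significance threshold pools MI values of permuted gene vectors
against randomly chosen partners (100 permutations, ≤ 10,000 null pairs)
and takes the (1 − α) quantile, α = 0.01 — small α therefore means a
*higher* threshold. Everything is deterministic given the seed. Constant
input vectors yield MI 0 with a warning.

## Enrichment

Over-representation of a query set against a GMT annotation:
p = P[X ≥ k] for X ~ Hypergeometric(N, K, n) (observed overlap included),
Benjamini–Hochberg q-values over all tested terms, and a report filter of
q ≤ 0.05 *and* overlap k ≥ 10, both boundaries inclusive. The universe
defaults to all genes that survived the network detection filter (the
background actually tested); restricting to annotated genes is a config
switch. GO DAG structure (ancestor propagation) is out of scope — the
annotation is taken as supplied.

## Synthetic data generator

Per gene g and sample s of tissue t, in order: latent log10 level
ℓ = μ_g + Σ_m λ_{g,m} z_{m,s} + ε with ε ~ N(0, σ) and module factors
z ~ N(0, f_m); markers add log10(fold) in their target tissue;
TPM = 10^ℓ; dropout zeroes the value with probability p_g, but never in a
marker's target tissue (so the planted fold change is realized — a
generator convention, not a property of real data). One seed feeds
deterministic per-component substreams. Two same-module genes with
loadings λ₁, λ₂ have limiting log-scale correlation
λ₁λ₂f² / √((λ₁²f² + σ²)(λ₂²f² + σ²)), which the tests verify at n = 2000.

Defaults emulate the regime the screen is designed for: log-normal
baselines (μ ~ N(0, 0.5) in log10 TPM), residual noise σ = 0.3, dropout
0.6 for receptor-like genes, markers at fold 50, modules with loading 0.9
and unit factor sd. The bundled study conditions are 10 tissues × 100
samples with 20 planted markers among 400 receptor-like genes, extended
for the end-to-end demo by three 40-gene modules and 120 unstructured
background genes.

What the generator does **not** emulate — and hence what passing tests do
not establish about real atlases: library-size and batch effects,
count-level noise (values are continuous log-normal, not re-sampled
counts), correlated tissues (factors are tissue-independent), gene-length
or mappability artifacts, and annotation incompleteness. Recovery numbers
on synthetic data are a correctness check of the machinery, not an
estimate of real-data sensitivity.

## Problem sizes and numerical conventions

The test suite and the acceptance script run planted-recovery benchmarks
at 200 genes × 200 samples (module recovery, 5–10 seeds), 60 genes × 200
samples (MI sub-networks), 400 genes × 1000 samples (marker screen), 2000
null simulations for the rank-test calibration, and 100 random ≤ 8-node
matrices for the TOM oracle — sizes chosen so the full suite completes in
a couple of minutes on one CPU while keeping every Monte-Carlo bound
comfortably away from its threshold.

Serialization is tab-separated text at 6 significant digits; read/write
round-trips are lossless at that precision. Dropped rows (empty tissue
labels, empty gene sets, sub-threshold tissues) are always logged, never
silent. Validation, format and empty-result errors are distinct exception
types mapped to CLI exit codes 2, 3 and 4.

## Known limitations

* The static tree cut trades the adaptivity of dynamic tree cutting for
  determinism; very heterogeneous module tightness within one dataset may
  require adjusting `cut_height_fraction` or `min_module_size`.
* The scale-free R² target is rarely reached on small synthetic matrices;
  the argmax fallback (with warning) is then used, which is the documented
  contract.
* The permutation MI threshold is a pooled quantile, not a per-pair test;
  it controls the bulk null level, not per-edge family-wise error.
* One-feature LDA AUC is symmetric in direction; do not interpret a
  passing AUC alone as over-expression (the fold-change gate does that).
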