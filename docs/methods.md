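# Methods

## Model

`svglrt` detects spatially variable genes (SVGs) in spatially resolved
transcriptomics (SRT) by treating pre-computed spatial clusters as a proxy
for space and asking, per gene, whether mean expression differs across
clusters. For gene *g* in spot *i* belonging to cluster *c(i)*, counts are
modeled as negative binomial (NB):

    x_gi ~ NB(mu_gi, phi_g),      Var = mu (1 + mu * phi)
    log(mu_gi) = log(M_i) + beta_{g,c(i)}                (single sample)
    log(mu_gi) = log(M_i) + beta_{g,c(i)} + gamma_{g,j(i)}   (multi-sample)

where `M_i` is the effective library size (total count × TMM factor),
`phi_g` the gene-wise dispersion, and `gamma_{g,j}` sample effects with
`gamma_{g,1} = 0`. A gene is spatially variable when the null hypothesis
`beta_{g,1} = ... = beta_{g,C}` is rejected by a likelihood-ratio test
(LRT) against the chi-square distribution with `C − 1` degrees of freedom.
In multi-sample mode the sample terms are retained in both the full and the
reduced model, so only the spatial structure is tested; joint modeling of
replicates pools evidence and raises power for SVGs whose pattern is
consistent across samples.

The individual-cluster test replaces the cluster factor with a one-vs-rest
indicator per cluster (1 df), reporting the direction (`high`/`low`) of the
indicator coefficient; the *key cluster* of a gene is the cluster with the
smallest one-vs-rest p-value (ties: larger |coefficient|, then cluster
order). With only two clusters the one-vs-rest and global designs span the
same column space, so the cluster test is only offered for C ≥ 3.

Assumptions worth stating: spatial clusters are given and adequate
summaries of the spatial expression structure (the method cannot find
patterns orthogonal to the clustering); counts are NB at spot level;
spot-level depth is a multiplicative nuisance fully captured by the offset.

## Normalization

Effective library sizes use the trimmed mean of M-values (TMM). The
reference spot is the one whose upper-quartile count fraction (over genes
expressed in that spot) is closest to the mean such fraction. For each spot
vs the reference, genes expressed in both contribute a log-ratio M, a log
abundance A, and a precision weight equal to the inverse of the
delta-method (binomial) variance of M; genes outside the central 40% of M
(30% trimmed per tail) or the central 90% of A (5% per tail) are discarded,
and the factor is `2^(weighted mean of retained M)`. Factors are rescaled
to geometric mean 1. The implementation was cross-checked against both a
direct-formula brute-force evaluation (agreement to 1e-10) and
`edgeR::calcNormFactors` (agreement to 1e-6) on composition-biased
fixtures. A library-size-only fallback (`use_tmm=False`, `--no-tmm`) is
provided.

## Fitting

Per-gene NB GLMs are fitted by iteratively reweighted least squares (IRLS)
with the log link and fixed dispersion, vectorized across genes (one
weighted-least-squares solve per gene per iteration, batched). Step-halving
(up to 10 halvings) guards against deviance increases; convergence is a
relative deviance change below 1e-8, with a 50-iteration cap. Starting
values are means `mu0 = y + mean(y)/6` — for indicator designs the first
IRLS step then lands essentially on log cluster-mean rates, and the 1/6
shim keeps zero observations finite. All-zero genes are fitted at the
boundary (log-likelihood 0, the limit mu → 0) and reported with NA
p-values; they are excluded from BH ranking and listed last.

IRLS optima were validated against derivative-free Nelder-Mead
maximization of the exact NB log-likelihood (agreement to 1e-6 on random
fixtures) and against closed-form Poisson MLEs at phi = 0.

## Dispersion estimation

Dispersions are estimated by Cox-Reid adjusted profile likelihood (APL):
`APL_g(phi) = ll_g(beta_hat(phi); phi) − 0.5 log det(X' W X)`, which
corrects the profile likelihood for the estimation of the mean
coefficients. The APL is evaluated on a 21-point log-spaced grid over
[1e-4, 10] and maximizers are refined by golden-section search in log-phi
(warm-starting each refit from the cached fitted means).

- **common**: maximizer of the summed APL over genes;
- **trended**: lowess fit (frac 0.5) of per-gene log maximizers against
  mean log2-CPM, clipped to the grid range; falls back to the common value
  when fewer than 10 genes are available;
- **tagwise**: maximizer of `APL_g(phi) − (prior_df/2)(log phi − log
  phi_trend,g)^2`, i.e. an empirical-Bayes normal prior on log-dispersion
  centered at the trend with precision `prior_df` (default 10). As
  `prior_df → ∞` the tagwise estimates collapse onto the trend exactly,
  which fixes the strength semantics of the prior; the quadratic-penalty
  form was chosen over a weighted-average-of-APLs scheme because it makes
  that limit exact and the shrinkage strength interpretable.

The same tagwise dispersions are shared between the full and reduced fits
of each test. The fast cluster-test mode reuses the tagwise dispersions
from the global design for all C one-vs-rest designs; the full mode
re-estimates them per design (C extra APL passes). On the synthetic
benchmarks the two modes pick the same key cluster for ≥ 95% of true SVGs
while fast mode does one dispersion pass instead of C + 1.

Recovery was checked by simulation: NB data with phi = 0.5 (500 spots, 200
genes) yields a median tagwise estimate within [0.4, 0.6].

## Multiple testing

Benjamini-Hochberg step-up with monotonicity enforcement, NA passthrough
(NAs excluded from the family size). The global test is one family; the
cluster test adjusts within each cluster's gene vector — the per-cluster
family structure is a declared choice, since each cluster's calls answer a
separate scientific question ("which genes deviate in this region?").

## Synthetic benchmarks

`simulate_synthetic` places spots on a square grid cut into contiguous
vertical cluster bands (counts or proportions given by `clusters_spec`),
draws per-gene baseline means log-normal(log 3, 1) — typical sparse SRT
abundances of a few counts per spot — and spot depths uniform over a
3-fold range, then draws NB counts with a common phi (default 0.5, a
typical SRT spot-level overdispersion). SVG effects are multiplicative:
`2^log2fc` with strong/weak tiers defaulting to log2FC 1.0/0.5.

Spatial profiles: `bottom_right` and `circular` split the tissue by
coordinates (half of the SVGs are elevated inside the region, half in its
complement — the symmetric construction keeps regional library mass
balanced); `annotations` contrasts a designated cluster set against the
rest; `mixture` gives each SVG its own elevated cluster, with key clusters
distributed equally over clusters, and `inverted_mixture` depletes each
SVG's own cluster instead. Equal distribution of key clusters matters: if
every SVG shared one small region, that region's library mass would be
inflated by half the transcriptome, a composition bias outside what
trimmed-mean normalization can absorb and unlike the multi-pattern
structure of real tissues.

`simulate_from_anchor` instead rearranges real (or synthetic) counts:
SVG genes are rank-split so the largest values land in the key region
(random order within region), non-SVGs are permuted across the tissue.
Every gene's marginal count multiset is conserved exactly, so the marginal
distribution is that of the anchor data by construction.
`simulate_multisample` applies independent rearrangements per sample under
one shared truth table, yielding replicates with consistent SVGs.
Noisy clustering is emulated by `relabel_clusters` (random relabeling of a
chosen fraction of spots).

What the generators do *not* emulate: platform artifacts (spot swapping,
segmentation errors), mean-dependent dispersion trends, spatial
autocorrelation within clusters, zero inflation beyond NB, or clusters
estimated from the expression data itself (the double-dipping of spatially
resolved clustering). Passing benchmarks therefore demonstrate correctness
of the inference machinery under the NB-with-given-clusters model, not
robustness to clustering error on real tissue.

## Benchmark metrics and problem sizes

TPR and observed FDR are computed at fixed BH thresholds (default grid
0.01/0.05/0.1/0.2; NA p-values count as not called; empty call sets have
observed FDR 0). Null calibration is a one-sample KS test of
truth-negative p-values against U(0,1). Ranking coherency across samples
is the mean pairwise Jaccard index of top-k gene sets. Key-cluster
accuracy is the fraction of true SVGs whose predicted key cluster matches
the truth.

The packaged benchmark suite (tests and `scripts/acceptance.py`) uses
1000 genes × 500 spots (null calibration), 1000 × 1000 with 5 clusters
(mixture FDR/power), three replicates of 400 × 400 (multi-sample gain),
and 400 × 800 with 5 clusters (key-cluster benchmarks) — sizes at which
binomial noise on the reported rates is a few percent and a full run
completes in minutes on one core.

## Numerical choices and degenerate inputs

- LRT statistics are clipped at 0; deficits beyond −1e-6 (non-convergence)
  flag the gene and yield NA p-values.
- Linear predictors are clipped to ±700 before exponentiation; fitted
  means are floored at 1e-10.
- A ridge of 1e-10 is added to the weighted normal equations.
- One cluster level → error ("spatial test undefined"); cluster levels
  confounded with sample → error naming the levels; spots lacking a cluster
  label are dropped with a warning; a filter that empties the data names
  the offending threshold.
- Circular-mask radii are found by bisection on the inside-spot fraction
  (60 iterations); median splits fall back to a strict inequality when ties
  would swallow the whole tissue.

## Known limitations

- Exact numerical equality with any particular DGE toolchain is not
  claimed; equivalence is established statistically (calibration, power,
  parameter recovery) and against the oracles described above.
- The chi-square LRT is asymptotic; with very few spots per cluster or
  extremely sparse genes, p-values can drift from nominal (the quasi-
  likelihood F-test variant is out of scope).
- Default filters (gene: ≥ 20 counts and expressed in ≥ 10 spots; spot:
  ≥ 10 counts) are sensible for Visium-scale data and fully configurable;
  they are not tuned per technology.
- Testing spatial variability *within* a cluster is out of scope; so is
  spatially resolved clustering itself.
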