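# svglrt

Spatially variable gene (SVG) detection for spatially resolved
transcriptomics (SRT), for analysts who already have spatial clusters —
from manual annotation or a spatially resolved clustering tool — and want
calibrated, per-gene tests of spatial variability, including on specific
regions of interest and across biological replicates.

## The method

Spatial clusters summarize the tissue's spatial expression structure.
`svglrt` fits, for every gene *g*, a negative-binomial GLM on spot-level
counts with the clusters as covariates:

    x_gi ~ NB(mu_gi, phi_g),    log(mu_gi) = log(M_i) + beta_gc

where `M_i` is the effective library size of spot *i* (total count × TMM
normalization factor), `beta_gc` the abundance of gene *g* in cluster *c*,
and `phi_g` the gene-wise dispersion (variance `mu(1 + mu phi)`), estimated
by Cox–Reid adjusted profile likelihood with empirical-Bayes shrinkage
toward an abundance trend. A likelihood-ratio test of

    H0: beta_g1 = ... = beta_gC

against the chi-square with C − 1 df flags genes whose expression varies
across the tissue; Benjamini–Hochberg adjustment controls the FDR.
Three testing modes:

- **global** — one test per gene across all clusters;
- **individual cluster** (C ≥ 3) — one-vs-rest test per gene and cluster
  with the direction of change (`high`/`low`) and, per gene, the *key
  cluster* driving its spatial variability; a `fast` mode recycles the
  global dispersion estimates instead of re-estimating per cluster;
- **multi-sample** — with biological replicates, a sample effect
  `gamma_gj` is added and retained under the null, so spatial structure is
  tested jointly across samples, which raises power for consistent SVGs.

The package also ships the benchmark machinery: synthetic NB generators
and anchor-count rearrangement simulators for five spatial profiles
(bottom/right, circular, annotations, mixture, inverted mixture) with
ground truth, plus TPR/FDR, null-uniformity, Jaccard-coherency and
key-cluster-accuracy metrics. See `docs/methods.md` for the full model and
numerical details.

## Worked example

```python
import svglrt as sv

# synthetic benchmark: 600 spots, 4 clusters, 30% SVGs (2-fold, phi=0.5)
cm, spots, truth = sv.simulate_synthetic(
    n_spots=600, n_genes=300, clusters_spec=4, prop_svg=0.3,
    phi=0.5, pattern="mixture", seed=11,
)
res = sv.test_global(cm, spots, min_gene_count=10, min_gene_spots=5, min_spot_count=5)
print(res.head(5).to_string(index=False))
hits = sv.top_svgs(res, fdr_threshold=0.05)
print(f"{len(hits)} SVGs at 5% FDR (90 genes simulated as spatially variable)")
print(sv.tpr_fdr(res, truth, thresholds=[0.05]).to_string(index=False))
```

prints

```
gene_id   lrt_stat  df       pvalue          fdr  mean_logcpm
 g00249 131.910633 3.0 2.095587e-28 4.446283e-26    11.500494
 g00246 130.397626 3.0 4.440003e-28 4.446283e-26    12.254977
 g00143 130.394777 3.0 4.446283e-28 4.446283e-26    11.918733
 g00041 124.959870 3.0 6.592788e-27 4.944591e-25    11.311167
 g00120 118.418353 3.0 1.690647e-25 1.014388e-23    10.946507
80 SVGs at 5% FDR (90 genes simulated as spatially variable)
 threshold  n_called      tpr    fdr
      0.05        80 0.877778 0.0125
```

Each row is a gene, ranked by p-value: `lrt_stat` is the likelihood-ratio
statistic on `df = C − 1 = 3` degrees of freedom, `fdr` the BH-adjusted
p-value, and `mean_logcpm` the average log2 counts-per-million. At the 5%
FDR threshold the test recovers 88% of the planted SVGs with an observed
false discovery proportion of 1.2%.

On real data, read inputs instead of simulating:

```python
cm = sv.read_count_matrix("counts.mtx")          # or .csv/.tsv/.h5ad
spots = sv.read_spot_table("spots.tsv")          # spot_id, x, y, cluster[, sample]
res = sv.test_global(cm, spots)                  # multi-sample mode if sample column present
cres = sv.test_cluster(cm, spots, mode="fast")   # per-cluster tests, C >= 3
key = sv.identify_key_cluster(cres)
```

The same pipeline is available from the shell:

```sh
svglrt simulate --pattern mixture --n-spots 1000 --n-genes 500 --seed 1 --out-prefix sim/
svglrt test-global --counts sim/sim.mtx --meta sim/sim.meta.tsv --out run/results.tsv
svglrt test-cluster --counts sim/sim.mtx --meta sim/sim.meta.tsv --mode fast --out run/cluster.tsv
svglrt evaluate --results run/results.tsv --truth sim/sim.truth.tsv --report run/report.json
svglrt benchmark --pattern mixture --seeds 1..5 --out bench/
```

Every run writes its resolved configuration (`config.json`) and a log next
to its outputs.

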