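"""Spatially-variable-gene tests.

``test_global`` asks, per gene, whether mean expression differs across
spatial clusters at all (LRT with C - 1 df); ``test_cluster`` asks, per gene
and per cluster, whether that cluster's mean differs from the rest of the
tissue (one-vs-rest indicator, 1 df), reporting the direction of the change.
When the metadata carries a sample column with two or more levels, both
tests retain sample effects in full and reduced models and test the cluster
terms only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CountMatrix, SpotTable, align
from .io import sort_results
from . import nbglm
from .nbglm import DesignMatrix, build_design, estimate_dispersions, fit_genes_glm, mean_log_cpm
from .preprocess import filter_counts, tmm_factors, effective_sizes, NormFactors

__all__ = [
    "test_global",
    "test_cluster",
    "identify_key_cluster",
    "adjust_bh",
    "top_svgs",
]


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone); NA pass through."""
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        bad = p[ok][(p[ok] < 0) | (p[ok] > 1)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    out = np.full(p.shape, np.nan)
    m = int(ok.sum())
    if m == 0:
        return out
    sub = p[ok]
    order = np.argsort(sub, kind="stable")
    ranked = sub[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def _prepare(
    cm: CountMatrix,
    spots: SpotTable,
    min_gene_count: int,
    min_gene_spots: int,
    min_spot_count: int,
    use_tmm: bool,
):
    cm, spots = align(cm, spots)
    cm = filter_counts(cm, min_gene_count, min_gene_spots, min_spot_count)
    if cm.n_spots != spots.n_spots:
        keep = pd.Index(spots.spot_id).get_indexer(pd.Index(cm.spot_ids))
        spots = spots.subset(keep)
    if use_tmm:
        nf = tmm_factors(cm)
    else:
        lib = cm.counts.sum(axis=1).astype(float)
        nf = NormFactors(lib_size=lib, tmm_factor=np.ones(cm.n_spots))
    eff = effective_sizes(cm, nf)
    return cm, spots, np.log(eff), eff


def test_global(
    cm: CountMatrix,
    spots: SpotTable,
    min_gene_count: int = 20,
    min_gene_spots: int = 10,
    min_spot_count: int = 10,
    use_tmm: bool = True,
    prior_df: float = 10.0,
    dispersions: nbglm.DispersionEstimates | None = None,
) -> pd.DataFrame:
    """Global SVG test: does a gene's mean expression vary across clusters?

    Returns a per-gene results table (gene_id, lrt_stat, df, pvalue, fdr,
    mean_logcpm) sorted by ascending p-value. Genes that end up all-zero
    after filtering are reported with NA p-values, last.
    """
    cm, spots, offsets, eff = _prepare(
        cm, spots, min_gene_count, min_gene_spots, min_spot_count, use_tmm
    )
    design = build_design(spots, model="auto")
    Y = cm.counts.astype(float)
    if dispersions is None:
        dispersions = estimate_dispersions(Y, design, offsets, prior_df=prior_df)
    phi = dispersions.tagwise
    full = fit_genes_glm(Y, design.matrix, offsets, phi)
    red = fit_genes_glm(Y, design.reduced, offsets, phi)
    stat, pval, flagged = nbglm.lrt(full.loglik, red.loglik, design.df_test)
    all_zero = np.asarray(full.all_zero)
    pval = np.where(all_zero | flagged, np.nan, pval)
    res = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "lrt_stat": stat,
            "df": float(design.df_test),
            "pvalue": pval,
            "fdr": adjust_bh(pval),
            "mean_logcpm": mean_log_cpm(Y, eff),
        }
    )
    res.attrs["dispersions"] = dispersions
    res.attrs["n_clusters"] = spots.n_clusters
    res.attrs["n_samples"] = spots.n_samples
    res.attrs["fit_diagnostics"] = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "phi_tagwise": dispersions.tagwise,
            "phi_trended": dispersions.trended,
            "phi_common": dispersions.common,
            "loglik_full": np.asarray(full.loglik),
            "loglik_reduced": np.asarray(red.loglik),
            "mean_logcpm": dispersions.mean_logcpm,
        }
    )
    return sort_results(res)


def _cluster_design(spots: SpotTable, level) -> DesignMatrix:
    ind = (spots.cluster == level).astype(float)
    n = spots.n_spots
    if spots.n_samples >= 2:
        sdum = np.zeros((n, spots.n_samples - 1))
        codes = spots.sample_codes()
        for j in range(1, spots.n_samples):
            sdum[codes == j, j - 1] = 1.0
        full = np.column_stack([np.ones(n), ind, sdum])
        reduced = np.column_stack([np.ones(n), sdum])
        labels = ["intercept", f"cluster:{level}"] + [
            f"sample:{l}" for l in spots.sample_levels[1:]
        ]
        return DesignMatrix(full, reduced, labels, ["intercept"] + labels[2:])
    full = np.column_stack([np.ones(n), ind])
    return DesignMatrix(full, np.ones((n, 1)), ["intercept", f"cluster:{level}"], ["intercept"])


def test_cluster(
    cm: CountMatrix,
    spots: SpotTable,
    mode: str = "fast",
    min_gene_count: int = 20,
    min_gene_spots: int = 10,
    min_spot_count: int = 10,
    use_tmm: bool = True,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Individual-cluster SVG test (one-vs-rest, per gene and cluster).

    ``mode='full'`` re-estimates dispersions under each one-vs-rest design;
    ``mode='fast'`` recycles the tagwise dispersions from the global design,
    trading a small amount of accuracy for one dispersion pass instead of C.
    Requires C >= 3 (with two clusters this is the global test). BH
    adjustment is applied within each cluster's gene family.
    """
    if mode not in ("full", "fast"):
        raise ValueError(f"mode must be 'full' or 'fast', got {mode!r}")
    cm, spots, offsets, eff = _prepare(
        cm, spots, min_gene_count, min_gene_spots, min_spot_count, use_tmm
    )
    if spots.n_clusters < 3:
        raise ValueError(
            "individual-cluster testing needs >= 3 clusters; with 2 clusters "
            "it coincides with the global test (use test_global)"
        )
    Y = cm.counts.astype(float)
    global_design = build_design(spots, model="auto")
    disp_global = estimate_dispersions(Y, global_design, offsets, prior_df=prior_df)
    logcpm = mean_log_cpm(Y, eff)
    frames = []
    for level in spots.cluster_levels:
        design = _cluster_design(spots, level)
        if mode == "full":
            disp = estimate_dispersions(Y, design, offsets, prior_df=prior_df)
        else:
            disp = disp_global
        phi = disp.tagwise
        full = fit_genes_glm(Y, design.matrix, offsets, phi)
        red = fit_genes_glm(Y, design.reduced, offsets, phi)
        stat, pval, flagged = nbglm.lrt(full.loglik, red.loglik, 1)
        all_zero = np.asarray(full.all_zero)
        pval = np.where(all_zero | flagged, np.nan, pval)
        coef = full.beta[:, 1]  # one-vs-rest indicator coefficient
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": cm.gene_ids,
                    "cluster": str(level),
                    "lrt_stat": stat,
                    "df": 1.0,
                    "pvalue": pval,
                    "fdr": adjust_bh(pval),
                    "mean_logcpm": logcpm,
                    "coef": coef,
                    "sign": np.where(coef >= 0, "high", "low"),
                }
            )
        )
    res = pd.concat(frames, ignore_index=True)
    res.attrs["cluster_levels"] = [str(l) for l in spots.cluster_levels]
    return res


def identify_key_cluster(cluster_results: pd.DataFrame) -> pd.DataFrame:
    """Per gene, the cluster with the smallest one-vs-rest p-value.

    Ties are broken by the larger absolute indicator coefficient, then by
    cluster order of appearance. Genes whose p-values are all NA get an NA
    key cluster.
    """
    levels = cluster_results.attrs.get(
        "cluster_levels", list(pd.unique(cluster_results["cluster"]))
    )
    order = {c: i for i, c in enumerate(levels)}
    rows = []
    for gene, grp in cluster_results.groupby("gene_id", sort=True):
        ok = grp[~grp["pvalue"].isna()]
        if ok.empty:
            rows.append((gene, None, None, np.nan))
            continue
        coef = ok["coef"] if "coef" in ok.columns else 0.0
        ranked = ok.assign(
            _negabs=-np.abs(coef), _ord=[order.get(c, len(order)) for c in ok["cluster"]]
        ).sort_values(["pvalue", "_negabs", "_ord"], kind="stable")
        best = ranked.iloc[0]
        rows.append((gene, best["cluster"], best.get("sign"), best["pvalue"]))
    return pd.DataFrame(rows, columns=["gene_id", "key_cluster", "sign", "pvalue"])


def top_svgs(
    results: pd.DataFrame, fdr_threshold: float = 0.05, n: int | None = None
) -> list:
    """Genes ranked by ascending p-value (ties by gene id).

    With ``n`` given, the first ``n`` ranked genes regardless of threshold;
    otherwise all genes at fdr <= ``fdr_threshold``.
    """
    df = sort_results(results)
    if n is not None:
        return df["gene_id"].head(n).tolist()
    hit = df[df["fdr"].notna() & (df["fdr"] <= fdr_threshold)]
    return hit["gene_id"].tolist()
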