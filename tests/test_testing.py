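import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

import svglrt as sv
from svglrt.testing import adjust_bh, identify_key_cluster, top_svgs


# ---------------------------------------------------------------- BH


def test_bh_hand_computed():
    np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_single_and_degenerate():
    assert adjust_bh([0.2])[0] == pytest.approx(0.2)
    np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)


def test_bh_na_passthrough():
    out = adjust_bh([0.01, np.nan, 0.04])
    assert np.isnan(out[1])
    # NA excluded from the family size m
    np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError, match="outside"):
        adjust_bh([0.5, 1.5])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
def test_bh_dominates_pvalues_and_is_monotone(pvals):
    p = np.array(pvals)
    fdr = adjust_bh(p)
    assert (fdr >= p - 1e-12).all() and (fdr <= 1.0).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(fdr[order]) >= -1e-12).all()


# ---------------------------------------------------------------- ranking helpers


def _results(pvals, genes=None, fdr=None):
    genes = genes or [f"g{i}" for i in range(len(pvals))]
    return pd.DataFrame(
        {
            "gene_id": genes,
            "pvalue": pvals,
            "fdr": fdr if fdr is not None else adjust_bh(pvals),
        }
    )


def test_top_svgs_threshold_and_n():
    res = _results([0.001, 0.5, 0.01])
    assert top_svgs(res, fdr_threshold=1.0) == ["g0", "g2", "g1"]
    assert top_svgs(res, n=0) == []
    assert top_svgs(res, fdr_threshold=0.0) == []
    assert top_svgs(res, n=2) == ["g0", "g2"]


def test_identify_key_cluster_argmin_and_ties():
    res = pd.DataFrame(
        {
            "gene_id": ["g"] * 3,
            "cluster": ["c1", "c2", "c3"],
            "pvalue": [0.001, 0.5, 0.9],
            "coef": [1.0, 0.5, -0.2],
            "sign": ["high", "high", "low"],
        }
    )
    key = identify_key_cluster(res)
    assert key.loc[0, "key_cluster"] == "c1"
    tied = pd.DataFrame(
        {
            "gene_id": ["g"] * 2,
            "cluster": ["c1", "c2"],
            "pvalue": [0.1, 0.1],
            "coef": [0.1, 2.0],
            "sign": ["high", "high"],
        }
    )
    assert identify_key_cluster(tied).loc[0, "key_cluster"] == "c2"


def test_identify_key_cluster_all_na():
    res = pd.DataFrame(
        {
            "gene_id": ["g"],
            "cluster": ["c1"],
            "pvalue": [np.nan],
            "coef": [0.0],
            "sign": ["high"],
        }
    )
    assert identify_key_cluster(res)["key_cluster"].isna().all()


# ---------------------------------------------------------------- global test


@pytest.fixture(scope="module")
def two_cluster_sim():
    """400 spots, 2 clusters; 100 genes with a 4-fold cluster effect + 100 flat."""
    cm, spots, truth = sv.simulate_synthetic(
        n_spots=400,
        n_genes=200,
        clusters_spec=2,
        prop_svg=0.5,
        log2fc={"strong": 2.0},
        pattern="annotations",
        phi=0.4,
        seed=7,
    )
    return cm, spots, truth


def test_global_test_power_and_fdr(two_cluster_sim):
    cm, spots, truth = two_cluster_sim
    res = sv.test_global(cm, spots, min_gene_count=1, min_gene_spots=1, min_spot_count=1)
    curve = sv.tpr_fdr(res, truth, thresholds=[0.05])
    assert curve.loc[0, "tpr"] >= 0.9
    assert curve.loc[0, "fdr"] <= 0.10


def test_shuffled_labels_destroy_signal(two_cluster_sim):
    cm, spots, _ = two_cluster_sim
    rng = np.random.default_rng(1)
    shuffled = sv.SpotTable(
        spots.spot_id, spots.x, spots.y, rng.permutation(spots.cluster), spots.sample
    )
    res = sv.test_global(cm, shuffled, min_gene_count=1, min_gene_spots=1, min_spot_count=1)
    assert len(sv.top_svgs(res, fdr_threshold=0.05)) <= 10


def test_results_invariant_to_input_permutation(two_cluster_sim):
    cm, spots, _ = two_cluster_sim
    rng = np.random.default_rng(3)
    perm_s = rng.permutation(cm.n_spots)
    perm_g = rng.permutation(cm.n_genes)
    cm2 = sv.CountMatrix(cm.counts[perm_s][:, perm_g], cm.spot_ids[perm_s], cm.gene_ids[perm_g])
    res1 = sv.test_global(cm, spots, min_gene_count=1, min_gene_spots=1, min_spot_count=1)
    res2 = sv.test_global(cm2, spots.subset(perm_s), min_gene_count=1, min_gene_spots=1, min_spot_count=1)
    m = res1.merge(res2, on="gene_id", suffixes=("_a", "_b"))
    np.testing.assert_allclose(m["lrt_stat_a"], m["lrt_stat_b"], rtol=1e-6, atol=1e-8)


def test_global_equals_one_vs_rest_with_two_clusters(two_cluster_sim):
    """With C=2 the cluster-means design spans the same space as
    intercept+indicator, so the global LRT is the one-vs-rest LRT."""
    from svglrt.nbglm import build_design, fit_genes_glm, lrt
    from svglrt.testing import _cluster_design

    cm, spots, _ = two_cluster_sim
    Y = cm.counts[:, :40].astype(float)
    off = np.log(Y.sum(axis=1) + 1)
    d_global = build_design(spots, model="single")
    d_ovr = _cluster_design(spots, spots.cluster_levels[0])
    phi = 0.4
    sg = lrt(
        fit_genes_glm(Y, d_global.matrix, off, phi).loglik,
        fit_genes_glm(Y, d_global.reduced, off, phi).loglik,
        1,
    )[0]
    so = lrt(
        fit_genes_glm(Y, d_ovr.matrix, off, phi).loglik,
        fit_genes_glm(Y, d_ovr.reduced, off, phi).loglik,
        1,
    )[0]
    np.testing.assert_allclose(sg, so, atol=1e-6)


def test_constant_gene_is_not_called(two_cluster_sim):
    cm, spots, _ = two_cluster_sim
    counts = cm.counts.copy()
    counts[:, 0] = 5  # perfectly flat gene
    cm2 = sv.CountMatrix(counts, cm.spot_ids, cm.gene_ids)
    res = sv.test_global(cm2, spots, min_gene_count=1, min_gene_spots=1, min_spot_count=1)
    g0 = res[res["gene_id"] == cm.gene_ids[0]]
    assert g0["fdr"].iloc[0] > 0.05


# ---------------------------------------------------------------- cluster test


@pytest.fixture(scope="module")
def three_cluster_sim():
    cm, spots, truth = sv.simulate_synthetic(
        n_spots=450,
        n_genes=150,
        clusters_spec=3,
        prop_svg=0.4,
        phi=0.4,
        pattern="mixture",
        seed=11,
    )
    return cm, spots, truth


def test_cluster_test_requires_three_clusters(two_cluster_sim):
    cm, spots, _ = two_cluster_sim
    with pytest.raises(ValueError, match="3 clusters"):
        sv.test_cluster(cm, spots, min_gene_count=1, min_gene_spots=1, min_spot_count=1)


def test_cluster_test_finds_planted_cluster(three_cluster_sim):
    cm, spots, truth = three_cluster_sim
    res = sv.test_cluster(cm, spots, mode="fast", min_gene_count=1, min_gene_spots=1, min_spot_count=1)
    key = identify_key_cluster(res)
    acc = sv.key_cluster_accuracy(key, truth)
    assert acc >= 0.9
    # planted genes are high in their own cluster
    svg = truth[truth["is_svg"]]
    merged = key.merge(svg, on="gene_id", suffixes=("_pred", "_true"))
    assert (merged["sign"] == "high").mean() >= 0.9


def test_uniform_genes_not_called_per_cluster(three_cluster_sim):
    cm, spots, truth = three_cluster_sim
    res = sv.test_cluster(cm, spots, mode="fast", min_gene_count=1, min_gene_spots=1, min_spot_count=1)
    nulls = set(truth.loc[~truth["is_svg"], "gene_id"])
    null_rows = res[res["gene_id"].isin(nulls)]
    frac_called = (null_rows["fdr"] <= 0.05).groupby(null_rows["gene_id"]).any().mean()
    assert frac_called <= 0.10


def test_replicating_a_sample_increases_evidence(two_cluster_sim):
    """Stacking J noisy copies of a sample and testing jointly gives smaller
    p-values for true SVGs than testing one copy alone."""
    cm, spots, truth = two_cluster_sim
    reps = 3
    counts = np.vstack([cm.counts] * reps)
    ids = np.concatenate([[f"r{j}_{s}" for s in cm.spot_ids] for j in range(reps)])
    stacked = sv.CountMatrix(counts, ids, cm.gene_ids)
    meta = sv.SpotTable(
        ids,
        np.tile(spots.x, reps),
        np.tile(spots.y, reps),
        np.tile(spots.cluster, reps),
        np.repeat([f"rep{j}" for j in range(reps)], cm.n_spots),
    )
    multi = sv.test_global(stacked, meta, min_gene_count=1, min_gene_spots=1, min_spot_count=1)
    single = sv.test_global(cm, spots, min_gene_count=1, min_gene_spots=1, min_spot_count=1)
    svgs = truth.loc[truth["is_svg"], "gene_id"]
    pm = multi.set_index("gene_id").loc[svgs, "pvalue"]
    ps = single.set_index("gene_id").loc[svgs, "pvalue"]
    assert (pm.to_numpy() <= ps.to_numpy() + 1e-12).mean() >= 0.95


def test_invalid_mode_rejected(three_cluster_sim):
    cm, spots, _ = three_cluster_sim
    with pytest.raises(ValueError, match="mode"):
        sv.test_cluster(cm, spots, mode="turbo")
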