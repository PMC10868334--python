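"""Benchmark metrics: TPR/FDR curves, top-k Jaccard coherency, null
p-value uniformity, key-cluster accuracy.

``benchmark_report`` returns (and the CLI serializes) a JSON object with
keys: ``curve`` — list of ``{threshold, n_called, tpr, fdr}`` records;
``null_ks`` — ``{statistic, pvalue, n}`` for the truth-negative p-values
(present when >= 20 are available); ``key_cluster_accuracy`` — a fraction
(present when key-cluster predictions are supplied).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import kstest

__all__ = [
    "tpr_fdr",
    "jaccard_top_k",
    "null_uniformity",
    "key_cluster_accuracy",
    "benchmark_report",
]

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1, 0.2)


def _truth_lookup(truth: pd.DataFrame) -> pd.Series:
    return truth.set_index("gene_id")["is_svg"].astype(bool)


def tpr_fdr(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """True-positive rate and observed FDR of ``fdr <= q`` calls per threshold.

    NA p-values count as not called at every threshold. With no true SVGs
    the TPR is NA; an empty call set has observed FDR 0.
    """
    is_svg = _truth_lookup(truth)
    df = results[["gene_id", "fdr"]].copy()
    df["is_svg"] = df["gene_id"].map(is_svg)
    if df["is_svg"].isna().any():
        missing = df.loc[df["is_svg"].isna(), "gene_id"].tolist()
        raise ValueError(f"genes missing from truth: {missing[:5]}")
    n_svg = int(df["is_svg"].sum())
    rows = []
    for q in thresholds:
        called = df["fdr"].notna() & (df["fdr"] <= q)
        tp = int((called & df["is_svg"]).sum())
        fp = int((called & ~df["is_svg"]).sum())
        rows.append(
            {
                "threshold": q,
                "n_called": int(called.sum()),
                "tpr": tp / n_svg if n_svg else np.nan,
                "fdr": fp / max(1, int(called.sum())),
            }
        )
    return pd.DataFrame(rows)


def jaccard_top_k(rankings: dict | list, k: int) -> tuple[pd.DataFrame, float]:
    """Jaccard index of top-k gene sets over all unordered sample pairs.

    ``rankings`` maps sample name to a gene list ordered best-first (a plain
    list of rankings gets positional names). Returns the pairwise matrix and
    the mean over pairs.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not isinstance(rankings, dict):
        rankings = {f"sample{i + 1}": r for i, r in enumerate(rankings)}
    if len(rankings) < 2:
        raise ValueError("need >= 2 rankings")
    for name, r in rankings.items():
        if len(r) < k:
            raise ValueError(f"ranking {name!r} shorter than k={k}")
    tops = {name: set(list(r)[:k]) for name, r in rankings.items()}
    names = list(tops)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    vals = []
    for a, b in itertools.combinations(names, 2):
        j = len(tops[a] & tops[b]) / len(tops[a] | tops[b])
        mat.loc[a, b] = mat.loc[b, a] = j
        vals.append(j)
    return mat, float(np.mean(vals))


def null_uniformity(pvalues) -> tuple[float, float]:
    """One-sample KS test of truth-negative p-values against U(0, 1)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no non-NA null p-values")
    if p.size < 20:
        raise ValueError(f"need >= 20 null p-values, got {p.size}")
    res = kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)


def key_cluster_accuracy(predicted: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of true SVGs whose predicted key cluster matches the truth."""
    t = truth[truth["is_svg"]].set_index("gene_id")["key_cluster"]
    if t.empty:
        return np.nan
    pred = predicted.set_index("gene_id")["key_cluster"]
    common = t.index.intersection(pred.index)
    if len(common) == 0:
        raise ValueError("no true SVGs present in predictions")
    return float((pred.loc[common].astype(str) == t.loc[common].astype(str)).mean())


def benchmark_report(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    predicted_key: pd.DataFrame | None = None,
    thresholds=DEFAULT_THRESHOLDS,
) -> dict:
    """Aggregate metrics for one simulation run as a JSON-serializable dict."""
    curve = tpr_fdr(results, truth, thresholds)
    is_svg = _truth_lookup(truth)
    nulls = results.loc[~results["gene_id"].map(is_svg).astype(bool), "pvalue"]
    report: dict = {
        "curve": curve.to_dict(orient="records"),
    }
    nn = nulls.dropna()
    if len(nn) >= 20:
        ks_stat, ks_p = null_uniformity(nn)
        report["null_ks"] = {"statistic": ks_stat, "pvalue": ks_p, "n": int(len(nn))}
    if predicted_key is not None:
        report["key_cluster_accuracy"] = key_cluster_accuracy(predicted_key, truth)
    return report
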