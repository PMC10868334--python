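"""Gene/spot filtering and TMM effective library sizes.

The trimmed mean of M-values (TMM, Robinson & Oshlack 2010) corrects
between-spot composition bias: for each spot a scaling factor is computed as
the precision-weighted, doubly trimmed mean of per-gene log-ratios against a
reference spot. The effective library size ``M_i`` (total count x factor) is
used downstream as the GLM log-offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import CountMatrix

__all__ = ["NormFactors", "filter_counts", "tmm_factors", "effective_sizes"]


@dataclass(eq=False)
class NormFactors:
    """Per-spot library sizes and TMM factors (geometric mean 1)."""

    lib_size: np.ndarray
    tmm_factor: np.ndarray

    @property
    def effective_size(self) -> np.ndarray:
        return self.lib_size * self.tmm_factor


def filter_counts(
    cm: CountMatrix,
    min_gene_count: int = 20,
    min_gene_spots: int = 10,
    min_spot_count: int = 10,
) -> CountMatrix:
    """Drop low-signal genes, then low-coverage spots.

    A gene is retained iff its total count is >= ``min_gene_count`` AND it is
    expressed (count > 0) in >= ``min_gene_spots`` spots; afterwards a spot
    is retained iff its total (over retained genes) is >= ``min_spot_count``.
    """
    if min(min_gene_count, min_gene_spots, min_spot_count) < 0:
        raise ValueError("filter thresholds must be non-negative")
    gene_total = cm.counts.sum(axis=0)
    gene_spots = (cm.counts > 0).sum(axis=0)
    keep_genes = (gene_total >= min_gene_count) & (gene_spots >= min_gene_spots)
    if not keep_genes.any():
        raise ValueError(
            f"gene filter (min_gene_count={min_gene_count}, "
            f"min_gene_spots={min_gene_spots}) removed all genes"
        )
    cm = cm.subset_genes(np.flatnonzero(keep_genes))
    spot_total = cm.counts.sum(axis=1)
    keep_spots = spot_total >= min_spot_count
    if not keep_spots.any():
        raise ValueError(f"spot filter (min_spot_count={min_spot_count}) removed all spots")
    return cm.subset_spots(np.flatnonzero(keep_spots))


def _upper_quartile_fraction(counts: np.ndarray, lib_size: np.ndarray) -> np.ndarray:
    """75th percentile of counts/lib_size over expressed genes, per spot."""
    n = counts.shape[0]
    out = np.empty(n)
    for k in range(n):
        pos = counts[k][counts[k] > 0]
        out[k] = np.quantile(pos / lib_size[k], 0.75) if pos.size else 0.0
    return out


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: int | None = None,
) -> NormFactors:
    """TMM normalization factors, rescaled to geometric mean 1.

    Parameters
    ----------
    trim_m, trim_a
        Fractions of genes trimmed from each tail of the M (log-ratio) and
        A (log-abundance) distributions.
    ref
        Index of the reference spot; by default the spot whose
        upper-quartile count fraction is closest to the mean such fraction.
    """
    counts = np.asarray(cm.counts, dtype=float)
    n_spots = counts.shape[0]
    if n_spots < 2:
        raise ValueError("TMM requires at least 2 spots")
    lib = counts.sum(axis=1)
    if (lib <= 0).any():
        bad = cm.spot_ids[lib <= 0]
        raise ValueError(f"spots with zero total count: {list(bad[:5])}")
    if ref is None:
        f75 = _upper_quartile_fraction(counts, lib)
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(n_spots)
    yr, nr = counts[ref], lib[ref]
    for k in range(n_spots):
        if k == ref:
            continue
        factors[k] = _tmm_pair(counts[k], lib[k], yr, nr, trim_m, trim_a, cm.spot_ids[k])
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(lib_size=cm.counts.sum(axis=1).astype(float), tmm_factor=factors)


def _tmm_pair(yk, nk, yr, nr, trim_m, trim_a, spot_id) -> float:
    both = (yk > 0) & (yr > 0)
    if not both.any():
        warnings.warn(
            f"spot {spot_id!r} shares no expressed genes with the reference; "
            "TMM factor set to 1",
            stacklevel=3,
        )
        return 1.0
    pk, pr = yk[both] / nk, yr[both] / nr
    m = np.log2(pk / pr)
    a = 0.5 * np.log2(pk * pr)
    # precision weight = inverse binomial variance of the log-ratio
    v = (nk - yk[both]) / (nk * yk[both]) + (nr - yr[both]) / (nr * yr[both])
    w = 1.0 / v
    n = m.size
    # doubly trimmed: keep genes whose M- and A-ranks both fall inside the
    # trimmed window (ranks average over ties)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() <= 0:
        return 1.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def effective_sizes(cm: CountMatrix, nf: NormFactors) -> np.ndarray:
    """Effective library sizes M_i = lib_size_i x tmm_factor_i."""
    if len(nf.lib_size) != cm.n_spots:
        raise ValueError("normalization factors not aligned with count matrix")
    return nf.effective_size
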