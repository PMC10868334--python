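"""Benchmark data generators with ground truth.

Two families of generators are provided. ``simulate_from_anchor`` rearranges
real (or previously simulated) counts: for each spatially variable gene the
observed values are rank-split so that high values land in a designated
tissue region, which preserves every gene's marginal count distribution
exactly; non-SVGs are obtained by randomly permuting measurements across the
tissue. ``simulate_synthetic`` draws counts de novo from a negative-binomial
model on a spot grid with cluster structure, multiplicative region effects
(strong/weak tiers) and spot-level depth variation.

Five spatial profiles are supported: ``bottom_right`` (half-tissue split),
``circular`` (inside vs outside a disk), ``annotations`` (a designated
cluster set vs the rest), ``mixture`` (one small cluster highly abundant)
and ``inverted_mixture`` (one small cluster lowly abundant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CountMatrix, SpotTable

__all__ = [
    "PATTERNS",
    "PatternMask",
    "make_mask",
    "simulate_from_anchor",
    "simulate_synthetic",
    "simulate_synthetic_multisample",
    "simulate_multisample",
    "relabel_clusters",
]

PATTERNS = ("bottom_right", "circular", "annotations", "mixture", "inverted_mixture")

# direction policy per pattern: fraction of SVGs that are *high* in the key
# region; the rest are high in the complementary region
_HIGH_FRACTION = {
    "bottom_right": 0.5,
    "circular": 0.5,
    "annotations": 0.5,
    "mixture": 1.0,
    "inverted_mixture": 0.0,
}


@dataclass(eq=False)
class PatternMask:
    """Binary spatial partition: a key region versus the rest."""

    region: np.ndarray  # per-spot region label
    pattern: str
    key_region: str

    @property
    def in_key(self) -> np.ndarray:
        return self.region == self.key_region

    def __post_init__(self) -> None:
        if not self.in_key.any():
            raise ValueError("key region is empty")
        if self.in_key.all():
            raise ValueError("key region covers every spot")


def make_mask(
    spots: SpotTable,
    pattern: str,
    params: dict | None = None,
    seed: int = 0,
) -> PatternMask:
    """Partition the tissue into a key region and its complement.

    ``bottom_right`` splits at the median coordinate (``params['axis']`` in
    {'y', 'x'}, default 'y'; key = low side); ``circular`` takes a disk at
    the coordinate centroid whose radius is found by bisection so that
    ``params['target']`` (default 0.5) of the spots fall inside;
    ``annotations`` takes ``params['clusters']`` (default: the first cluster
    level) versus the rest; ``mixture`` / ``inverted_mixture`` take one small
    cluster (``params['cluster']``, default the smallest) versus the rest.
    """
    params = dict(params or {})
    n = spots.n_spots
    if pattern == "bottom_right":
        axis = params.get("axis", "y")
        coord = spots.y if axis == "y" else spots.x
        med = np.median(coord)
        low = coord <= med
        # guard: a heavily tied median can swallow the whole tissue
        if low.all() or not low.any():
            low = coord < med
        region = np.where(low, "bottom" if axis == "y" else "left", "top" if axis == "y" else "right")
        return PatternMask(region.astype(object), pattern, "bottom" if axis == "y" else "left")
    if pattern == "circular":
        target = float(params.get("target", 0.5))
        cx, cy = spots.x.mean(), spots.y.mean()
        dist = np.hypot(spots.x - cx, spots.y - cy)
        lo, hi = 0.0, float(dist.max())
        for _ in range(60):  # bisection on the inside fraction
            mid = (lo + hi) / 2
            if (dist <= mid).sum() / n < target:
                lo = mid
            else:
                hi = mid
        inside = dist <= hi
        region = np.where(inside, "inside", "outside").astype(object)
        return PatternMask(region, pattern, "inside")
    if pattern in ("annotations", "mixture", "inverted_mixture"):
        if spots.n_clusters < 2:
            raise ValueError(f"pattern {pattern!r} requires cluster labels with >= 2 levels")
        if pattern == "annotations":
            chosen = params.get("clusters", [spots.cluster_levels[0]])
            if isinstance(chosen, str):
                chosen = [chosen]
            chosen = [str(c) for c in chosen]
            missing = set(chosen) - set(map(str, spots.cluster_levels))
            if missing:
                raise ValueError(f"unknown cluster label(s): {sorted(missing)}")
            key = "+".join(chosen)
            region = np.where(np.isin(spots.cluster.astype(str), chosen), key, "rest").astype(object)
            return PatternMask(region, pattern, key)
        chosen = params.get("cluster")
        if chosen is None:
            sizes = [(spots.cluster == lev).sum() for lev in spots.cluster_levels]
            chosen = spots.cluster_levels[int(np.argmin(sizes))]
        chosen = str(chosen)
        region = np.where(spots.cluster.astype(str) == chosen, chosen, "rest").astype(object)
        return PatternMask(region, pattern, chosen)
    raise ValueError(f"unknown pattern {pattern!r}; choose from {PATTERNS}")


def _exact_split(names, weights, total, rng) -> np.ndarray:
    """Multiset of ``names`` with sizes proportional to weights, exact after rounding."""
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    counts = np.floor(weights * total).astype(int)
    counts[: total - counts.sum()] += 1
    pool = np.repeat(names, counts).astype(object)
    rng.shuffle(pool)
    return pool


def _assign_truth(
    gene_ids: np.ndarray,
    prop_svg: float,
    pattern: str,
    key_regions,
    tier_props: dict[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    g = len(gene_ids)
    if not 0.0 <= prop_svg <= 1.0:
        raise ValueError("prop_svg must be in [0, 1]")
    n_svg = int(round(prop_svg * g))
    svg_idx = rng.choice(g, size=n_svg, replace=False)
    is_svg = np.zeros(g, dtype=bool)
    is_svg[svg_idx] = True
    tier = np.array([None] * g, dtype=object)
    tier[svg_idx] = _exact_split(list(tier_props), list(tier_props.values()), n_svg, rng)
    direction = np.array([None] * g, dtype=object)
    n_high = int(round(_HIGH_FRACTION[pattern] * n_svg))
    dirs = np.array(["high"] * n_high + ["low"] * (n_svg - n_high), dtype=object)
    rng.shuffle(dirs)
    direction[svg_idx] = dirs
    key = np.array([None] * g, dtype=object)
    if isinstance(key_regions, str):
        key[svg_idx] = key_regions
    else:
        # SVG spatial profiles distributed equally among the candidate regions
        key[svg_idx] = _exact_split(list(key_regions), np.ones(len(key_regions)), n_svg, rng)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_svg": is_svg,
            "pattern": np.where(is_svg, pattern, None),
            "key_cluster": key,
            "tier": tier,
            "direction": direction,
        }
    )


def simulate_from_anchor(
    cm: CountMatrix,
    mask: PatternMask,
    prop_svg: float = 0.5,
    seed: int = 0,
    truth: pd.DataFrame | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Rearrange anchor counts into the mask's spatial pattern.

    Every gene's count multiset is preserved exactly: SVG genes are
    rank-split (high values into the key region for direction ``high``, into
    the complement for ``low``, random order within region), non-SVGs are
    permuted across all spots. Passing a ``truth`` table (from a previous
    call) reuses gene assignments, enabling consistent multi-sample
    simulations.
    """
    if len(mask.region) != cm.n_spots:
        raise ValueError("mask does not cover the anchor's spots")
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = _assign_truth(
            cm.gene_ids, prop_svg, mask.pattern, mask.key_region, {"anchor": 1.0}, rng
        )
    else:
        if set(truth["gene_id"]) != set(cm.gene_ids):
            raise ValueError("truth table gene universe does not match the anchor")
        truth = truth.set_index("gene_id").loc[cm.gene_ids].reset_index()
    in_key = mask.in_key
    n_key = int(in_key.sum())
    key_pos = np.flatnonzero(in_key)
    rest_pos = np.flatnonzero(~in_key)
    out = np.empty_like(cm.counts)
    is_svg = truth["is_svg"].to_numpy()
    direction = truth["direction"].to_numpy()
    for j in range(cm.n_genes):
        vals = cm.counts[:, j]
        if not is_svg[j]:
            out[:, j] = rng.permutation(vals)
            continue
        srt = np.sort(vals)
        if direction[j] == "high":
            key_vals, rest_vals = srt[-n_key:], srt[:-n_key]
        else:
            key_vals, rest_vals = srt[:n_key], srt[n_key:]
        out[key_pos, j] = rng.permutation(key_vals)
        out[rest_pos, j] = rng.permutation(rest_vals)
    return CountMatrix(out, cm.spot_ids.copy(), cm.gene_ids.copy()), truth


def _grid_spots(n_spots: int, clusters_spec, sample: str | None = None) -> SpotTable:
    side = int(np.ceil(np.sqrt(n_spots)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    x = xs.ravel()[:n_spots].astype(float)
    y = ys.ravel()[:n_spots].astype(float)
    if isinstance(clusters_spec, int):
        props = np.full(clusters_spec, 1.0 / clusters_spec)
    else:
        props = np.asarray(list(clusters_spec), dtype=float)
        props = props / props.sum()
    c = len(props)
    if c < 2:
        raise ValueError("clusters_spec must define >= 2 clusters")
    # contiguous vertical bands: sort by (x, y) and cut into blocks
    order = np.lexsort((y, x))
    bounds = np.round(np.cumsum(props) * n_spots).astype(int)
    labels = np.empty(n_spots, dtype=object)
    start = 0
    for k, stop in enumerate(bounds):
        labels[order[start:stop]] = f"c{k + 1}"
        start = stop
    prefix = "" if sample is None else f"{sample}_"
    ids = np.array([f"{prefix}s{i:05d}" for i in range(n_spots)], dtype=object)
    return SpotTable(
        ids, x, y, labels, None if sample is None else np.full(n_spots, sample, dtype=object)
    )


def simulate_synthetic(
    n_spots: int = 1000,
    n_genes: int = 500,
    clusters_spec=5,
    prop_svg: float = 0.5,
    log2fc: dict[str, float] | None = None,
    tier_props: dict[str, float] | None = None,
    phi: float = 0.5,
    lib_size_range: tuple[float, float] = (50_000.0, 150_000.0),
    pattern: str = "mixture",
    baseline_log_mean: float = np.log(3.0),
    baseline_log_sd: float = 1.0,
    seed: int = 0,
    truth: pd.DataFrame | None = None,
    sample: str | None = None,
) -> tuple[CountMatrix, SpotTable, pd.DataFrame]:
    """Fully synthetic NB benchmark dataset on a spot grid.

    Spots are laid on a square grid and partitioned into contiguous cluster
    bands per ``clusters_spec`` (a cluster count or proportions). Baseline
    gene means are log-normal; SVG genes receive a multiplicative
    ``2**log2fc[tier]`` effect inside (direction ``high``) or outside-scaled
    (direction ``low``) the pattern's key region; counts are drawn from
    NB(mu_gi * M_i / mean(M), phi) with spot depths M_i uniform in
    ``lib_size_range``. ``phi = 0`` draws Poisson counts.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    log2fc = dict(log2fc or {"strong": 1.0, "weak": 0.5})
    tier_props = dict(tier_props or {k: 1.0 for k in log2fc})
    if set(tier_props) - set(log2fc):
        raise ValueError("tier_props names must be a subset of log2fc names")
    rng = np.random.default_rng(seed)
    spots = _grid_spots(n_spots, clusters_spec, sample=sample)
    per_gene_key = pattern in ("mixture", "inverted_mixture")
    gene_ids = np.array([f"g{j:05d}" for j in range(n_genes)], dtype=object)
    if truth is None:
        if per_gene_key:
            # each SVG follows its own cluster profile, equally distributed
            key_regions = [str(l) for l in spots.cluster_levels]
        else:
            key_regions = make_mask(spots, pattern, seed=seed).key_region
        truth = _assign_truth(gene_ids, prop_svg, pattern, key_regions, tier_props, rng)
    else:
        truth = truth.set_index("gene_id").loc[gene_ids].reset_index()
    if not per_gene_key:
        in_key = make_mask(spots, pattern, seed=seed).in_key
    base = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_genes))
    effect = np.ones((n_spots, n_genes))
    cluster_str = spots.cluster.astype(str)
    for j in np.flatnonzero(truth["is_svg"].to_numpy()):
        fc = 2.0 ** log2fc[truth["tier"].iat[j]]
        region = cluster_str == truth["key_cluster"].iat[j] if per_gene_key else in_key
        if truth["direction"].iat[j] == "high":
            effect[region, j] = fc
        elif per_gene_key:
            # inverted profile: the gene's own small region is depleted
            effect[region, j] = 1.0 / fc
        else:
            # "low" = highly abundant in the complementary region, which keeps
            # the two regions' library mass balanced
            effect[~region, j] = fc
    depth = rng.uniform(*lib_size_range, size=n_spots)
    mu = base[None, :] * effect * (depth / depth.mean())[:, None]
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))
    return CountMatrix(counts.astype(np.int64), spots.spot_id, gene_ids), spots, truth


def simulate_synthetic_multisample(
    n_samples: int = 3,
    seed: int = 0,
    **kwargs,
) -> tuple[CountMatrix, SpotTable, pd.DataFrame, list]:
    """J synthetic replicates sharing SVG identities, patterns and directions.

    Returns the stacked dataset (sample column set) plus the list of
    per-sample (CountMatrix, SpotTable) pairs; the truth table is common to
    all replicates by construction.
    """
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_samples)
    truth = None
    singles = []
    for j in range(n_samples):
        cmj, spotsj, truth = simulate_synthetic(
            seed=int(seeds[j]), truth=truth, sample=f"rep{j + 1}", **kwargs
        )
        singles.append((cmj, spotsj))
    counts = np.vstack([cm.counts for cm, _ in singles])
    spot_ids = np.concatenate([cm.spot_ids for cm, _ in singles])
    combined_cm = CountMatrix(counts, spot_ids, singles[0][0].gene_ids)
    combined_spots = SpotTable(
        spot_ids,
        np.concatenate([sp.x for _, sp in singles]),
        np.concatenate([sp.y for _, sp in singles]),
        np.concatenate([sp.cluster for _, sp in singles]),
        np.concatenate([sp.sample for _, sp in singles]),
    )
    return combined_cm, combined_spots, truth, singles


def simulate_multisample(
    anchors: list[tuple[CountMatrix, SpotTable]],
    pattern: str = "mixture",
    prop_svg: float = 0.5,
    seed: int = 0,
    loose: bool = False,
    mask_params: dict | None = None,
) -> tuple[list[tuple[CountMatrix, pd.DataFrame]], pd.DataFrame]:
    """Anchor-based multi-sample simulation with consistent SVGs.

    The same genes are designated SVG, with the same pattern and direction,
    in every sample; each sample's counts are rearranged independently given
    that shared truth. Anchors must share the gene universe (``loose=True``
    intersects instead of failing).
    """
    if len(anchors) < 2:
        raise ValueError("need >= 2 anchor samples")
    universes = [set(cm.gene_ids) for cm, _ in anchors]
    shared = set.intersection(*universes)
    if any(u != shared for u in universes):
        if not loose:
            raise ValueError(
                "anchor samples have mismatched gene universes; pass loose=True to intersect"
            )
        warnings.warn(f"intersecting gene universes down to {len(shared)} genes")
        anchors = [
            (
                cm.subset_genes(np.flatnonzero(np.isin(cm.gene_ids, sorted(shared)))),
                sp,
            )
            for cm, sp in anchors
        ]
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(anchors))
    truth = None
    out = []
    for (cm, sp), s in zip(anchors, seeds):
        mask = make_mask(sp, pattern, params=mask_params, seed=int(s))
        cm_sim, truth = simulate_from_anchor(
            cm, mask, prop_svg=prop_svg, seed=int(s), truth=truth
        )
        out.append((cm_sim, truth))
    return out, truth


def relabel_clusters(spots: SpotTable, fraction: float, seed: int = 0) -> SpotTable:
    """Emulate noisy spatial clustering by randomly relabeling some spots."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = spots.n_spots
    k = int(round(fraction * n))
    pick = rng.choice(n, size=k, replace=False)
    labels = spots.cluster.copy()
    levels = np.array(spots.cluster_levels, dtype=object)
    labels[pick] = rng.choice(levels, size=k)
    return SpotTable(spots.spot_id, spots.x, spots.y, labels, spots.sample)
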