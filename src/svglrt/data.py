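"""Core in-memory containers: count matrix and spot metadata.

Counts are stored spots x genes throughout the package. Cluster and sample
levels are ordered by first appearance in the metadata table; that order
fixes coefficient indices in downstream design matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "SpotTable", "align"]


@dataclass(eq=False)
class CountMatrix:
    """Integer spot x gene expression table.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape (n_spots, n_genes).
    spot_ids, gene_ids
        Unique string identifiers for rows and columns.
    """

    counts: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n, g = self.counts.shape
        if n < 1 or g < 1:
            raise ValueError("count matrix must have at least one spot and one gene")
        if len(self.spot_ids) != n:
            raise ValueError(f"{len(self.spot_ids)} spot ids for {n} rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} columns")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            rounded = np.rint(as_int)
            bad = ~np.isclose(as_int, rounded, atol=1e-9) | ~np.isfinite(as_int)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-integer count {self.counts[i, j]!r} at spot "
                    f"{self.spot_ids[i]!r}, gene {self.gene_ids[j]!r}"
                )
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count {self.counts[i, j]} at spot "
                f"{self.spot_ids[i]!r}, gene {self.gene_ids[j]!r}"
            )
        for name, ids in (("spot", self.spot_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                dup = pd.Index(ids)
                dup = sorted(set(dup[dup.duplicated()]))
                raise ValueError(f"duplicate {name} ids: {dup[:5]}")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_spots(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.counts[index], self.spot_ids[index], self.gene_ids)

    def subset_genes(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.counts[:, index], self.spot_ids, self.gene_ids[index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.spot_ids, columns=self.gene_ids)


@dataclass(eq=False)
class SpotTable:
    """Per-spot coordinates, spatial cluster label and optional sample label."""

    spot_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cluster: np.ndarray
    sample: np.ndarray | None = None
    cluster_levels: list = field(default_factory=list)
    sample_levels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spot_id = np.asarray(self.spot_id, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.cluster = np.asarray(self.cluster, dtype=object).astype(str).astype(object)
        n = len(self.spot_id)
        if len(set(self.spot_id)) != n:
            raise ValueError("duplicate spot ids in metadata")
        if not (len(self.x) == len(self.y) == len(self.cluster) == n):
            raise ValueError("metadata columns have inconsistent lengths")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            bad = self.spot_id[~(np.isfinite(self.x) & np.isfinite(self.y))]
            raise ValueError(f"non-finite coordinates for spots {list(bad[:5])}")
        if not self.cluster_levels:
            self.cluster_levels = list(pd.unique(self.cluster))
        if self.sample is not None:
            self.sample = np.asarray(self.sample, dtype=object).astype(str).astype(object)
            if len(self.sample) != n:
                raise ValueError("sample column length mismatch")
            if not self.sample_levels:
                self.sample_levels = list(pd.unique(self.sample))

    @property
    def n_spots(self) -> int:
        return len(self.spot_id)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_levels)

    @property
    def n_samples(self) -> int:
        return len(self.sample_levels) if self.sample is not None else 1

    def cluster_codes(self) -> np.ndarray:
        """Integer codes into ``cluster_levels`` (first-appearance order)."""
        lut = {lev: i for i, lev in enumerate(self.cluster_levels)}
        return np.array([lut[c] for c in self.cluster], dtype=np.intp)

    def sample_codes(self) -> np.ndarray:
        if self.sample is None:
            return np.zeros(self.n_spots, dtype=np.intp)
        lut = {lev: i for i, lev in enumerate(self.sample_levels)}
        return np.array([lut[s] for s in self.sample], dtype=np.intp)

    def subset(self, index: np.ndarray) -> "SpotTable":
        sub = SpotTable(
            self.spot_id[index],
            self.x[index],
            self.y[index],
            self.cluster[index],
            None if self.sample is None else self.sample[index],
        )
        return sub

    def to_frame(self) -> pd.DataFrame:
        d = {"spot_id": self.spot_id, "x": self.x, "y": self.y, "cluster": self.cluster}
        if self.sample is not None:
            d["sample"] = self.sample
        return pd.DataFrame(d)


def align(cm: CountMatrix, spots: SpotTable) -> tuple[CountMatrix, SpotTable]:
    """Align a count matrix with a spot table on spot ids.

    Spots present in the counts but missing a cluster label (i.e. absent from
    the metadata) are dropped with a warning; spots in the metadata without
    counts are an error. The returned pair shares the metadata's spot order.
    """
    counts_idx = pd.Index(cm.spot_ids)
    meta_idx = pd.Index(spots.spot_id)
    missing_counts = meta_idx.difference(counts_idx)
    if len(missing_counts):
        raise ValueError(
            f"spots in metadata without counts: {sorted(missing_counts)[:10]}"
        )
    dropped = counts_idx.difference(meta_idx)
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} spot(s) without cluster label: "
            f"{sorted(dropped)[:10]}",
            stacklevel=2,
        )
    pos = counts_idx.get_indexer(meta_idx)
    cm2 = cm.subset_spots(pos)
    empty = [
        lev for lev in spots.cluster_levels if not (spots.cluster == lev).any()
    ]
    if empty:
        raise ValueError(f"empty cluster level(s) after alignment: {empty}")
    return cm2, spots
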