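"""Readers and writers for count matrices, spot metadata and results tables.

Supported count formats: dense CSV/TSV (spots in rows by default), Matrix
Market triplets with 10x-style ``barcodes``/``features`` sidecars, and
AnnData HDF5 (``.h5ad``). Results are written as TSV sorted by ascending
p-value with ties broken by gene id.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import CountMatrix, SpotTable

__all__ = ["read_count_matrix", "read_spot_table", "write_results", "write_count_matrix_mtx"]

_RESULT_FLOATS = ["lrt_stat", "df", "pvalue", "fdr", "mean_logcpm"]


def _read_sidecar(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_count_matrix(
    path: str | os.PathLike,
    format: str | None = None,
    spots_in_rows: bool = True,
) -> CountMatrix:
    """Read a spot x gene count matrix.

    Parameters
    ----------
    path
        For ``mtx``: the ``.mtx`` file; ``<stem>.barcodes.tsv`` and
        ``<stem>.features.tsv`` sidecars (or ``barcodes.tsv``/``features.tsv``
        in the same directory) supply spot and gene ids. For ``csv``/``tsv``:
        a dense table with header row of gene ids and first column of spot
        ids (set ``spots_in_rows=False`` for the transposed layout). For
        ``h5-anndata``: an ``.h5ad`` file whose X holds raw counts.
    format
        One of ``mtx``, ``csv``, ``tsv``, ``h5-anndata``; inferred from the
        file extension when omitted.
    """
    path = Path(path)
    if format is None:
        ext = path.suffix.lower()
        format = {
            ".mtx": "mtx",
            ".csv": "csv",
            ".tsv": "tsv",
            ".txt": "tsv",
            ".h5ad": "h5-anndata",
        }.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from extension {ext!r}")
    if format == "mtx":
        return _read_mtx(path)
    if format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", index_col=0)
        if not spots_in_rows:
            df = df.T
        return CountMatrix(
            df.to_numpy(),
            df.index.astype(str).to_numpy(),
            df.columns.astype(str).to_numpy(),
        )
    if format == "h5-anndata":
        import anndata

        ad = anndata.read_h5ad(path)
        x = ad.layers["counts"] if "counts" in ad.layers else ad.X
        if scipy.sparse.issparse(x):
            x = x.toarray()
        return CountMatrix(
            np.asarray(x),
            ad.obs_names.astype(str).to_numpy(),
            ad.var_names.astype(str).to_numpy(),
        )
    raise ValueError(f"unknown format {format!r}")


def _read_mtx(path: Path) -> CountMatrix:
    mat = scipy.io.mmread(path)
    mat = scipy.sparse.coo_matrix(mat).toarray()
    candidates = [
        (path.with_suffix("").with_suffix(".barcodes.tsv"), path.with_suffix("").with_suffix(".features.tsv")),
        (Path(str(path)[: -len(path.suffix)] + ".barcodes.tsv"), Path(str(path)[: -len(path.suffix)] + ".features.tsv")),
        (path.parent / "barcodes.tsv", path.parent / "features.tsv"),
    ]
    barcodes = features = None
    for bpath, fpath in candidates:
        if bpath.exists() and fpath.exists():
            barcodes, features = _read_sidecar(bpath), _read_sidecar(fpath)
            break
    if barcodes is None:
        raise FileNotFoundError(
            f"no barcodes/features sidecars found next to {path}"
        )
    n_spots, n_genes = len(barcodes), len(features)
    if mat.shape == (n_spots, n_genes):
        pass
    elif mat.shape == (n_genes, n_spots):
        mat = mat.T  # 10x convention stores genes in rows
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {n_spots} barcodes x "
            f"{n_genes} features nor its transpose"
        )
    return CountMatrix(mat, np.array(barcodes, dtype=object), np.array(features, dtype=object))


def write_count_matrix_mtx(cm: CountMatrix, prefix: str | os.PathLike) -> None:
    """Write counts as ``<prefix>.mtx`` with barcode/feature sidecars."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", scipy.sparse.coo_matrix(cm.counts))
    for suffix, ids in ((".barcodes.tsv", cm.spot_ids), (".features.tsv", cm.gene_ids)):
        with open(str(prefix) + suffix, "w") as fh:
            fh.write("\n".join(map(str, ids)) + "\n")


def read_spot_table(path: str | os.PathLike) -> SpotTable:
    """Read spot metadata (TSV/CSV with spot_id, x, y, cluster[, sample])."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"spot_id": str, "cluster": str, "sample": str})
    required = {"spot_id", "x", "y", "cluster"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spot table missing mandatory column(s): {sorted(missing)}")
    if df[["x", "y"]].isna().any().any():
        bad = df.loc[df[["x", "y"]].isna().any(axis=1), "spot_id"].tolist()
        raise ValueError(f"NaN coordinate for spots {bad[:5]}")
    return SpotTable(
        df["spot_id"].to_numpy(),
        df["x"].to_numpy(float),
        df["y"].to_numpy(float),
        df["cluster"].to_numpy(),
        df["sample"].to_numpy() if "sample" in df.columns else None,
    )


def write_spot_table(spots: SpotTable, path: str | os.PathLike) -> None:
    spots.to_frame().to_csv(path, sep="\t", index=False)


def sort_results(results: pd.DataFrame) -> pd.DataFrame:
    """Stable result ordering: ascending p-value, ties by gene id, NA last."""
    df = results.copy()
    key = df["pvalue"].fillna(np.inf)
    order = np.lexsort((df["gene_id"].to_numpy(), key.to_numpy()))
    return df.iloc[order].reset_index(drop=True)


def write_results(results: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a results table as TSV, sorted by p-value then gene id."""
    cols = ["gene_id"]
    if "cluster" in results.columns:
        cols.append("cluster")
    cols += [c for c in _RESULT_FLOATS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    df = sort_results(results)[cols]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.15g", na_rep="NA")


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA", dtype={"gene_id": str, "cluster": str})
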