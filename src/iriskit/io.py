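"""Shared file I/O: 10x-style MTX triplets, TIFF images, masks, truth JSON.

Counts travel as the standard Matrix Market triplet (``matrix.mtx`` with
genes as rows and barcodes as columns, ``features.tsv``, ``barcodes.tsv``)
plus ``libraries.csv`` (library_id, condition, replicate) and — when
available — a ``cells.csv`` carrying per-nucleus metadata so the write/read
round trip is the identity on counts, gene order, barcode order, and
annotations.
"""

from __future__ import annotations

import gzip as gzip_mod
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_tiff",
    "write_tiff",
    "read_mask",
    "write_mask",
]


def write_mtx_triplet(adata, outdir, gzip: bool = False) -> None:
    """Write an AnnData of raw counts as a 10x-style MTX triplet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    if not sparse.issparse(x):
        x = sparse.csr_matrix(x)
    mtx_path = outdir / ("matrix.mtx.gz" if gzip else "matrix.mtx")
    if gzip:
        with gzip_mod.open(mtx_path, "wb") as fh:
            spio.mmwrite(fh, x.T.astype(np.int64), field="integer")
    else:
        spio.mmwrite(str(mtx_path), x.T.astype(np.int64), field="integer")

    features = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "gene_name": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    features.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if {"library_id", "condition", "replicate"} <= set(adata.obs.columns):
        libs = (
            adata.obs[["library_id", "condition", "replicate"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )
        libs.to_csv(outdir / "libraries.csv", index=False)
    if len(adata.obs.columns):
        adata.obs.to_csv(outdir / "cells.csv")


def _check_mtx_header(path: Path) -> None:
    opener = gzip_mod.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.readline()
    if not first.startswith("%%MatrixMarket"):
        raise ValueError(
            f"{path}: line 1: malformed Matrix Market header {first[:40]!r}"
        )


def read_mtx_triplet(indir):
    """Read a 10x-style MTX triplet back into an AnnData (nuclei x genes)."""
    import anndata as ad

    indir = Path(indir)
    mtx_path = indir / "matrix.mtx"
    if not mtx_path.exists():
        mtx_path = indir / "matrix.mtx.gz"
    if not mtx_path.exists():
        raise FileNotFoundError(f"no matrix.mtx[.gz] under {indir}")
    _check_mtx_header(mtx_path)
    x = spio.mmread(str(mtx_path)).T.tocsr().astype(np.int32)
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    genes = features[0].astype(str).tolist()
    barcodes = (
        pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
        .astype(str)
        .tolist()
    )
    if x.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix shape {x.shape} does not match "
            f"{len(barcodes)} barcodes x {len(genes)} features"
        )
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    cells_path = indir / "cells.csv"
    if cells_path.exists():
        cells = pd.read_csv(cells_path, index_col=0)
        obs = cells.reindex(barcodes)
    adata = ad.AnnData(
        X=x,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    return adata


def write_tiff(img: np.ndarray, path, dtype=np.uint16) -> None:
    """Write an image (or Z-stack) as TIFF, clipping into the dtype range."""
    arr = np.asarray(img)
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        arr = np.clip(np.rint(arr), info.min, info.max).astype(dtype)
    else:
        arr = arr.astype(dtype)
    tifffile.imwrite(str(path), arr)


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean or label mask as a single-channel TIFF."""
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    tifffile.imwrite(str(path), arr)


def read_mask(path) -> np.ndarray:
    return tifffile.imread(str(path))
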