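"""Nucleus-level QC, normalization, pseudobulk averaging and clustering.

The QC rule retains a nucleus when its mitochondrial read fraction is at most
``max_mito_fraction`` (default 1%) and its total transcript count lies in
``[min_transcripts, max_transcripts]`` (default [500, 6000]); exclusion is by
strict inequality, so boundary nuclei are kept.

Normalization is library-size log-normalization (log-CPM at scale 10,000,
natural log1p). The original study normalized with a regularized
negative-binomial regression; every statistic computed downstream here
(pseudobulk R², percent-expressing, z-scaled means, t-test differential
expression) is equally well-defined under log-normalization, so this module
keeps normalization behind one pluggable operation rather than re-deriving
the regression model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "QCThresholds",
    "QCReport",
    "PseudobulkProfile",
    "qc_filter",
    "normalize",
    "pseudobulk",
    "dotplot_stats",
    "cluster_atlas",
]


@dataclass(frozen=True)
class QCThresholds:
    max_mito_fraction: float = 0.01
    min_transcripts: int = 500
    max_transcripts: int = 6000

    def __post_init__(self):
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.min_transcripts >= self.max_transcripts:
            raise ValueError("min_transcripts must be < max_transcripts")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed_by_reason: dict[str, int]
    per_nucleus: pd.DataFrame  # total, mito_fraction, retained, reasons

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def to_frame(self) -> pd.DataFrame:
        return self.per_nucleus


def _mito_mask(var_names: Sequence[str], prefixes: Sequence[str]) -> np.ndarray:
    lowered = tuple(p.lower() for p in prefixes)
    return np.array([str(g).lower().startswith(lowered) for g in var_names])


def qc_filter(adata, thresholds: QCThresholds = QCThresholds(),
              mito_prefixes: Sequence[str] = ("mt-",)):
    """Filter nuclei on mitochondrial fraction and total transcript count.

    Returns the retained subset (a copy) and a :class:`QCReport` listing the
    removal count per reason; a nucleus failing several rules is counted
    under each. An empty result is a warning, not an error; an unresolvable
    mitochondrial gene set is an error.
    """
    mito = _mito_mask(adata.var_names, mito_prefixes)
    if not mito.any():
        raise ValueError(
            f"no genes match mitochondrial prefixes {tuple(mito_prefixes)}"
        )
    x = adata.X
    if not sparse.issparse(x):
        x = sparse.csr_matrix(x)
    totals = np.asarray(x.sum(axis=1)).ravel()
    mito_counts = np.asarray(x[:, mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)

    low = totals < thresholds.min_transcripts
    high = totals > thresholds.max_transcripts
    himito = mito_frac > thresholds.max_mito_fraction
    retained = ~(low | high | himito)

    reasons = []
    for l, h, m in zip(low, high, himito):
        r = [name for name, bad in
             (("low_count", l), ("high_count", h), ("high_mito", m)) if bad]
        reasons.append(";".join(r))
    per_nucleus = pd.DataFrame(
        {
            "total": totals,
            "mito_fraction": mito_frac,
            "retained": retained,
            "reasons": reasons,
        },
        index=adata.obs_names,
    )
    report = QCReport(
        n_input=adata.n_obs,
        n_retained=int(retained.sum()),
        removed_by_reason={
            "low_count": int(low.sum()),
            "high_count": int(high.sum()),
            "high_mito": int(himito.sum()),
        },
        per_nucleus=per_nucleus,
    )
    if report.n_retained == 0:
        import warnings

        warnings.warn("QC filtering removed every nucleus", stacklevel=2)
    return adata[retained].copy(), report


def normalize(adata, scale: float = 10_000.0):
    """Library-size log-normalize: ``ln(1 + count * scale / total)``.

    Returns a copy whose ``X`` holds the normalized values (sparse, zero
    pattern preserved) with the raw counts kept in ``layers["counts"]``.
    Totals are recomputed from the matrix as passed, so run after QC.
    """
    out = adata.copy()
    x = out.X
    if not sparse.issparse(x):
        x = sparse.csr_matrix(x)
    x = x.astype(float).tocsr()
    totals = np.asarray(x.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("cannot normalize: nucleus with zero total counts")
    out.layers["counts"] = x.copy()
    norm = x.multiply((scale / totals)[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out.X = norm
    out.uns["normalization"] = {"method": "log-cpm", "scale": float(scale)}
    return out


@dataclass
class PseudobulkProfile:
    """Average normalized (de-logged) expression per group.

    ``values`` is genes x groups; columns are a MultiIndex over the groupby
    keys (cell type, condition by default). Averaging follows the
    de-log-then-mean convention: per cell ``expm1`` of the log-normalized
    value, then the arithmetic mean over the group's cells.
    """

    values: pd.DataFrame
    n_cells: pd.Series
    min_cells: int = 10

    @property
    def flagged(self) -> list:
        """Groups with fewer than ``min_cells`` contributing nuclei."""
        return list(self.n_cells.index[self.n_cells < self.min_cells])

    def group(self, *key) -> pd.Series:
        key = key[0] if len(key) == 1 else tuple(key)
        return self.values[key]

    def has_group(self, *key) -> bool:
        key = key[0] if len(key) == 1 else tuple(key)
        return key in self.values.columns


def pseudobulk(adata, groupby: Sequence[str] = ("cell_type", "condition"),
               min_cells: int = 10) -> PseudobulkProfile:
    """Average de-logged normalized expression per (cell type, condition)."""
    groupby = list(groupby)
    x = adata.X
    if not sparse.issparse(x):
        x = sparse.csr_matrix(x)
    x = x.tocsr()
    keys = pd.MultiIndex.from_frame(adata.obs[groupby].astype(object))
    cols = {}
    ncells = {}
    for key in keys.unique():
        rows = np.flatnonzero(keys == key)
        sub = x[rows]
        delog = sub.copy()
        delog.data = np.expm1(delog.data)
        cols[key] = np.asarray(delog.mean(axis=0)).ravel()
        ncells[key] = len(rows)
    values = pd.DataFrame(cols, index=adata.var_names)
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=groupby)
    n_cells = pd.Series(ncells)
    n_cells.index = pd.MultiIndex.from_tuples(n_cells.index, names=groupby)
    return PseudobulkProfile(values=values, n_cells=n_cells, min_cells=min_cells)


def dotplot_stats(adata, genes: Sequence[str], cell_types: Sequence[str] | None = None,
                  clip: float = 2.5) -> pd.DataFrame:
    """Dot-plot statistics: percent expressing and z-scaled mean expression.

    ``pct_expressing`` is the percentage of a type's cells with a raw count
    above zero (normalization-scale invariant). ``scaled_mean`` is the
    per-gene z-score (population sd) of the group-mean log-normalized
    expression across the displayed cell types, clipped to ``±clip``; a gene
    with identical means everywhere scores 0 by convention.
    """
    if "counts" not in adata.layers:
        raise ValueError("dotplot_stats needs a normalized matrix with a counts layer")
    if cell_types is None:
        cell_types = list(pd.unique(adata.obs["cell_type"].astype(str)))
    genes = list(genes)
    missing = [g for g in genes if g not in adata.var_names.tolist()]
    if missing:
        raise ValueError(f"genes not in matrix: {missing}")
    gcols = [adata.var_names.get_loc(g) for g in genes]
    raw = adata.layers["counts"].tocsc()[:, gcols]
    norm = adata.X.tocsc()[:, gcols]
    ct = adata.obs["cell_type"].astype(str).to_numpy()

    pct = np.zeros((len(cell_types), len(genes)))
    means = np.zeros_like(pct)
    for i, t in enumerate(cell_types):
        rows = np.flatnonzero(ct == t)
        if rows.size == 0:
            raise ValueError(f"no cells of type {t!r}")
        pct[i] = 100.0 * np.asarray((raw[rows] > 0).mean(axis=0)).ravel()
        means[i] = np.asarray(norm[rows].mean(axis=0)).ravel()

    mu = means.mean(axis=0, keepdims=True)
    sd = means.std(axis=0, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (means - mu) / sd, 0.0)
    z = np.clip(z, -clip, clip)

    records = []
    for i, t in enumerate(cell_types):
        for j, g in enumerate(genes):
            records.append((g, t, pct[i, j], z[i, j]))
    return pd.DataFrame(
        records, columns=["gene", "cell_type", "pct_expressing", "scaled_mean"]
    )


def cluster_atlas(adata, n_pcs: int = 30, k_neighbors: int = 15,
                  resolution: float = 0.2, seed: int = 0) -> pd.Series:
    """Graph community detection over principal components.

    Scaled expression -> PCA (``n_pcs`` components) -> kNN graph
    (``k_neighbors``) -> Leiden communities at ``resolution``. Deterministic
    given ``seed``. Input must be the QC-filtered, normalized matrix.
    """
    import scanpy as sc

    if adata.n_obs <= n_pcs:
        raise ValueError(
            f"need more than n_pcs={n_pcs} nuclei to cluster, got {adata.n_obs}"
        )
    work = adata.copy()
    sc.pp.scale(work, max_value=10)
    sc.tl.pca(work, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(work, n_neighbors=k_neighbors, random_state=seed)
    sc.tl.leiden(
        work,
        resolution=resolution,
        random_state=seed,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    labels = work.obs["leiden"].astype(str)
    labels.name = "cluster"
    return labels
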