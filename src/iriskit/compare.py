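"""Condition-comparison statistics on pseudobulk profiles.

Pairwise R² is the squared Pearson correlation of log10 average normalized
expression across genes — the quantity plotted in per-cell-type scatter
comparisons. ΔR² summarizes dilation asymmetry per cell type as
R²(constricted vs untreated) − R²(dilated vs untreated); since the
constricted iris is transcriptionally near-identical to the untreated iris,
that comparison estimates technical variability, and a positive Δ means the
dilated transcriptome moved further from baseline than technical noise
alone would.

Differential expression follows the thresholded two-sample design: an
equal-variance Student's t-test per gene on normalized values, Bonferroni
correction with the total number of genes in the dataset (not the number
tested), and a gene "passes" when |log2 fold change| > 0.6 and the adjusted
p-value is below 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .atlas import PseudobulkProfile

__all__ = [
    "ComparisonR2",
    "pairwise_r2",
    "delta_r2",
    "replicate_concordance",
    "de_genes",
]


@dataclass
class ComparisonR2:
    cell_type: str
    pair: tuple[str, str]
    r_squared: float
    n_genes: int
    n_cells: tuple[int, int]
    pseudocount: float


def pairwise_r2(profile: PseudobulkProfile, cell_type: str,
                cond_a: str, cond_b: str, pseudocount: float = 1.0) -> ComparisonR2:
    """Squared Pearson correlation of log10(avg expression + pseudocount).

    Restricted to genes with nonzero average expression on at least one
    side (both-zero genes carry no information and make the log degenerate
    at zero pseudocount). Symmetric in the pair order.
    """
    for cond in (cond_a, cond_b):
        key = (cell_type, cond)
        if not profile.has_group(*key):
            raise ValueError(f"group {key} absent from profile")
        if profile.n_cells[key] < profile.min_cells:
            raise ValueError(
                f"group {key} has {profile.n_cells[key]} cells "
                f"(< min_cells={profile.min_cells})"
            )
    x = profile.group(cell_type, cond_a).to_numpy(dtype=float)
    y = profile.group(cell_type, cond_b).to_numpy(dtype=float)
    keep = (x > 0) | (y > 0)
    lx = np.log10(x[keep] + pseudocount)
    ly = np.log10(y[keep] + pseudocount)
    r = stats.pearsonr(lx, ly).statistic
    return ComparisonR2(
        cell_type=cell_type,
        pair=(cond_a, cond_b),
        r_squared=float(r * r),
        n_genes=int(keep.sum()),
        n_cells=(int(profile.n_cells[(cell_type, cond_a)]),
                 int(profile.n_cells[(cell_type, cond_b)])),
        pseudocount=pseudocount,
    )


def delta_r2(profile: PseudobulkProfile, untreated: str = "untreated",
             dilated: str = "dilated", constricted: str = "constricted",
             pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-cell-type dilation asymmetry of pseudobulk R².

    ``delta = R²(constricted vs untreated) − R²(dilated vs untreated)``;
    the subtraction order makes a positive delta mean a larger dilation
    effect. Cell types absent (or under ``min_cells``) in any of the three
    conditions are excluded with a warning.
    """
    cell_types = sorted({ct for ct, _ in profile.values.columns})
    rows = []
    for ct in cell_types:
        try:
            cu = pairwise_r2(profile, ct, constricted, untreated, pseudocount)
            du = pairwise_r2(profile, ct, dilated, untreated, pseudocount)
        except ValueError as err:
            warnings.warn(f"delta_r2: skipping {ct!r}: {err}", stacklevel=2)
            continue
        rows.append(
            {
                "cell_type": ct,
                "r2_constricted_vs_untreated": cu.r_squared,
                "r2_dilated_vs_untreated": du.r_squared,
                "delta": cu.r_squared - du.r_squared,
            }
        )
    return pd.DataFrame(rows).set_index("cell_type") if rows else pd.DataFrame(
        columns=["r2_constricted_vs_untreated", "r2_dilated_vs_untreated", "delta"]
    )


def replicate_concordance(adata) -> pd.DataFrame:
    """Pearson r between replicate libraries of the same condition.

    For each library, the per-gene average normalized expression (de-logged
    mean over all its nuclei) is computed; every within-condition library
    pair is correlated on the log10(x + 1) scale — the same scale as the
    scatter comparisons. Input is a normalized matrix covering the libraries
    to compare.
    """
    x = adata.X
    if not sparse.issparse(x):
        x = sparse.csr_matrix(x)
    x = x.tocsr()
    libs = adata.obs["library_id"].astype(str)
    conds = adata.obs["condition"].astype(str)
    lib_ids = list(pd.unique(libs))
    profiles = {}
    lib_cond = {}
    for lib in lib_ids:
        rows = np.flatnonzero((libs == lib).to_numpy())
        sub = x[rows]
        delog = sub.copy()
        delog.data = np.expm1(delog.data)
        profiles[lib] = np.log10(np.asarray(delog.mean(axis=0)).ravel() + 1.0)
        lib_cond[lib] = conds.iloc[rows[0]]
    records = []
    for i, a in enumerate(lib_ids):
        for b in lib_ids[i + 1:]:
            if lib_cond[a] != lib_cond[b]:
                continue
            r = stats.pearsonr(profiles[a], profiles[b]).statistic
            records.append(
                {
                    "condition": lib_cond[a],
                    "library_a": a,
                    "library_b": b,
                    "pearson_r": float(r),
                }
            )
    return pd.DataFrame(records)


def de_genes(adata, cell_type: str, cond_a: str, cond_b: str,
             lfc_threshold: float = 0.6, alpha: float = 0.05,
             eps: float = 0.01, min_cells: int = 3) -> pd.DataFrame:
    """Thresholded differential expression between two conditions.

    Per gene: equal-variance Student's t on the normalized values of
    ``cell_type`` nuclei in ``cond_a`` vs ``cond_b``; log2 fold change from
    de-logged group means with pseudocount ``eps``; Bonferroni multiplier
    equal to the total gene count of the dataset. Genes with zero variance
    on both sides and equal means get p = 1 by convention. Result is sorted
    by |log2 fold change|, descending.
    """
    ct = adata.obs["cell_type"].astype(str).to_numpy()
    cond = adata.obs["condition"].astype(str).to_numpy()
    rows_a = np.flatnonzero((ct == cell_type) & (cond == cond_a))
    rows_b = np.flatnonzero((ct == cell_type) & (cond == cond_b))
    na, nb = rows_a.size, rows_b.size
    if na < min_cells or nb < min_cells:
        raise ValueError(
            f"need >= {min_cells} cells per side; got {na} ({cond_a}) "
            f"and {nb} ({cond_b}) for {cell_type!r}"
        )
    x = adata.X
    if not sparse.issparse(x):
        x = sparse.csr_matrix(x)
    a = np.asarray(x[rows_a].todense(), dtype=float)
    b = np.asarray(x[rows_b].todense(), dtype=float)

    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, (ma - mb) / np.where(se > 0, se, 1.0), 0.0)
        degenerate = (se == 0) & (ma != mb)
        t = np.where(degenerate, np.inf * np.sign(ma - mb), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where((se == 0) & (ma == mb), 1.0, p)

    n_genes_total = adata.n_vars
    p_adj = np.minimum(p * n_genes_total, 1.0)
    lfc = np.log2((np.expm1(a).mean(axis=0) + eps)
                  / (np.expm1(b).mean(axis=0) + eps))
    passes = (np.abs(lfc) > lfc_threshold) & (p_adj < alpha)

    out = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "p_adjusted": p_adj,
            "passes": passes,
        },
        index=adata.var_names,
    )
    return out.sort_values("log2_fold_change", key=np.abs, ascending=False)
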