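"""Quality control and normalization of UMI count matrices.

Cells are removed when their library size or gene complexity is too low
(absolute thresholds, plus an optional per-batch one-standard-deviation
rule), or when a marker of apoptosis (normalized mitochondrial rRNA
expression) is elevated.  Genes in the lower third of mean expression are
dropped.  The retained matrix is normalized by dividing each cell by the
square root of its library size and each gene by its standard deviation
(no centering, so zeros are preserved and the matrix stays sparse), then
capped at 10.

Counts travel as AnnData: integer UMIs in ``.X``, strain/batch in ``.obs``,
chromosome and mitochondrial flags in ``.var``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "NormalizedMatrix",
    "filter_cells",
    "filter_genes",
    "normalize",
    "mito_fraction",
    "validate_counts",
]


def validate_counts(adata: ad.AnnData) -> None:
    """Check the CountMatrix invariants: nonnegative integers, unique ids."""
    x = adata.X
    data = x.data if sparse.issparse(x) else np.asarray(x)
    if data.size and (data < 0).any():
        raise ValueError("counts must be nonnegative")
    if data.size and np.any(data != np.round(data)):
        raise ValueError("counts must be integers")
    if adata.obs_names.duplicated().any() or adata.var_names.duplicated().any():
        raise ValueError("cell and gene ids must be unique")


@dataclass
class NormalizedMatrix:
    """The expression matrix the factorization consumes.

    ``values`` is dense cells x genes; ``cell_divisor`` is the sqrt library
    size each cell was divided by and ``gene_scale`` the per-gene standard
    deviation; ``cell_ids``/``gene_ids`` index back into the source counts.
    """

    values: np.ndarray
    cell_ids: pd.Index
    gene_ids: pd.Index
    cell_divisor: np.ndarray
    gene_scale: np.ndarray
    cap: float
    cell_meta: pd.DataFrame | None = None
    gene_meta: pd.DataFrame | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _cell_stats(adata: ad.AnnData) -> tuple[np.ndarray, np.ndarray]:
    x = adata.X
    if sparse.issparse(x):
        umi = np.asarray(x.sum(axis=1)).ravel()
        n_genes = np.asarray((x > 0).sum(axis=1)).ravel()
    else:
        umi = np.asarray(x).sum(axis=1)
        n_genes = (np.asarray(x) > 0).sum(axis=1)
    return umi.astype(float), n_genes.astype(float)


def filter_cells(
    adata: ad.AnnData,
    min_umi: int = 200,
    min_genes: int = 50,
    apply_sd_rule: bool = False,
    mito_gene: str | None = None,
    mito_norm_threshold: float = 2.0,
    exclude_cells: list[str] | None = None,
    return_report: bool = False,
):
    """Remove low-quality cells.

    Rules, all evaluated on the original matrix in one pass:

    - total UMI count below ``min_umi`` or genes expressed below
      ``min_genes``;
    - with ``apply_sd_rule``, UMI count or gene count more than one standard
      deviation below the mean for that cell's batch (globally, with a
      warning, when no batch labels are present);
    - normalized expression of ``mito_gene`` (count / sqrt(library size),
      scaled to unit variance over all cells) above
      ``mito_norm_threshold``;
    - membership in an explicit ``exclude_cells`` list (stand-in for manual
      embedding-based removal).

    Returns the subsetted AnnData, plus a per-cell report when
    ``return_report`` (cell id, kept flag, removal reasons, UMI total, gene
    count, mito fraction where flags exist).
    """
    validate_counts(adata)
    umi, n_genes = _cell_stats(adata)
    reasons = [[] for _ in range(adata.n_obs)]

    for i in np.where(umi < min_umi)[0]:
        reasons[i].append("low_umi")
    for i in np.where(n_genes < min_genes)[0]:
        reasons[i].append("low_genes")

    if apply_sd_rule:
        if "batch" in adata.obs:
            groups = adata.obs["batch"].to_numpy()
        else:
            warnings.warn(
                "no batch labels; applying the SD rule globally", stacklevel=2
            )
            groups = np.zeros(adata.n_obs, dtype=int)
        for g in pd.unique(groups):
            m = groups == g
            for stat, tag in ((umi, "sd_umi"), (n_genes, "sd_genes")):
                cut = stat[m].mean() - stat[m].std(ddof=1 if m.sum() > 1 else 0)
                for i in np.where(m & (stat < cut))[0]:
                    reasons[i].append(tag)

    if mito_gene is not None:
        if mito_gene not in adata.var_names:
            raise KeyError(f"mito gene {mito_gene!r} not in the matrix")
        j = adata.var_names.get_loc(mito_gene)
        col = adata.X[:, j]
        col = np.asarray(col.todense()).ravel() if sparse.issparse(col) else np.asarray(col).ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            norm_col = np.where(umi > 0, col / np.sqrt(umi), 0.0)
        sd = norm_col.std(ddof=1)
        if sd > 0:
            norm_col = norm_col / sd
        for i in np.where(norm_col > mito_norm_threshold)[0]:
            reasons[i].append("mito_marker")

    if exclude_cells:
        excl = set(exclude_cells)
        for i, cid in enumerate(adata.obs_names):
            if cid in excl:
                reasons[i].append("excluded_list")

    keep = np.array([not r for r in reasons])
    if not keep.any():
        raise ValueError("all cells removed by quality filters")
    out = adata[keep].copy()
    if not return_report:
        return out
    report = pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "kept": keep,
            "reasons": [";".join(r) for r in reasons],
            "umi_total": umi,
            "n_genes": n_genes,
        }
    )
    if "mitochondrial" in adata.var:
        report["mito_fraction"] = mito_fraction(adata)
    return out, report


def filter_genes(adata: ad.AnnData, lower_fraction: float = 1.0 / 3.0) -> ad.AnnData:
    """Remove the genes in the lower ``lower_fraction`` of expression means.

    The number removed is floor(G * lower_fraction); ties at the boundary
    are resolved by stable gene order (earlier genes removed first).
    """
    if not (0.0 <= lower_fraction < 1.0):
        raise ValueError("lower_fraction must be in [0, 1)")
    if adata.n_vars < 3:
        raise ValueError("need at least 3 genes")
    if lower_fraction == 0.0:
        return adata.copy()
    x = adata.X
    means = (
        np.asarray(x.mean(axis=0)).ravel()
        if sparse.issparse(x)
        else np.asarray(x).mean(axis=0)
    )
    n_remove = int(np.floor(adata.n_vars * lower_fraction))
    order = np.argsort(means, kind="stable")
    keep = np.ones(adata.n_vars, dtype=bool)
    keep[order[:n_remove]] = False
    return adata[:, keep].copy()


def normalize(
    adata: ad.AnnData,
    cap: float = 10.0,
    cell_transform: str = "libsize_sqrt",
) -> NormalizedMatrix:
    """Normalize a filtered count matrix.

    Each cell is divided by the square root of its total UMI count
    (``cell_transform='libsize_sqrt'``; ``'sqrt_counts'`` instead takes the
    square root of every entry), each gene column is divided by its sample
    standard deviation (no centering, so zeros stay zeros), and values are
    capped at ``cap``.
    """
    validate_counts(adata)
    x = adata.X
    dense = np.asarray(x.todense(), dtype=float) if sparse.issparse(x) else np.asarray(x, dtype=float)
    totals = dense.sum(axis=1)
    if (totals == 0).any():
        bad = int(np.where(totals == 0)[0][0])
        raise ValueError(f"cell {adata.obs_names[bad]!r} has zero total count")
    if cell_transform == "libsize_sqrt":
        divisor = np.sqrt(totals)
        vals = dense / divisor[:, None]
    elif cell_transform == "sqrt_counts":
        divisor = np.ones_like(totals)
        vals = np.sqrt(dense)
    else:
        raise ValueError(f"unknown cell_transform {cell_transform!r}")
    scale = vals.std(axis=0, ddof=1)
    if (scale == 0).any():
        bad = int(np.where(scale == 0)[0][0])
        raise ValueError(f"gene {adata.var_names[bad]!r} has zero variance")
    vals = vals / scale[None, :]
    np.minimum(vals, cap, out=vals)
    return NormalizedMatrix(
        values=vals,
        cell_ids=adata.obs_names.copy(),
        gene_ids=adata.var_names.copy(),
        cell_divisor=divisor,
        gene_scale=scale,
        cap=cap,
        cell_meta=adata.obs.copy(),
        gene_meta=adata.var.copy(),
    )


def mito_fraction(adata: ad.AnnData) -> np.ndarray:
    """Fraction of each cell's UMIs on mitochondrial genes."""
    if "mitochondrial" not in adata.var:
        raise KeyError("gene metadata must contain a 'mitochondrial' flag")
    flags = adata.var["mitochondrial"].to_numpy().astype(bool)
    if not flags.any():
        raise ValueError("no mitochondrial genes flagged")
    x = adata.X
    if sparse.issparse(x):
        mito = np.asarray(x[:, flags].sum(axis=1)).ravel()
        total = np.asarray(x.sum(axis=1)).ravel()
    else:
        mito = np.asarray(x)[:, flags].sum(axis=1)
        total = np.asarray(x).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(total > 0, mito / total, 0.0)
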