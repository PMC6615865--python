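"""Imputation from the factor model and held-out-read cross-validation.

Reads are split so each is assigned to a test set with probability
``p_test`` and to training otherwise; because read assignment is
exchangeable this is exact per-entry binomial thinning.  A predictor is any
cells x genes matrix of predicted expression; quality is measured per cell
by the rank prediction accuracy curve (RPAC): genes are ranked by predicted
expression from high to low and the curve accumulates the fraction of that
cell's test reads captured up to each rank.  The area under the curve (AUC,
trapezoidal) is 0.5 in expectation for a random predictor and higher for
anything informative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .annotation import fisher_2x2, top_genes
from .sda import SDA

__all__ = [
    "SplitCounts",
    "RPACResult",
    "impute",
    "split_reads",
    "rpac",
    "evaluate_predictors",
    "unimputed_predictor",
    "meancell_predictor",
    "compare_imputations",
]

logger = logging.getLogger(__name__)


@dataclass
class SplitCounts:
    """An 80/20-style read split: train + test equals the source exactly."""

    train: ad.AnnData
    test: ad.AnnData
    p_test: float
    seed: int


@dataclass
class RPACResult:
    """One cell's rank prediction accuracy curve.

    ``rank_fraction`` runs from 0 to 1 inclusive; ``cum_test_fraction``
    starts at 0, ends at 1 and is non-decreasing.
    """

    rank_fraction: np.ndarray
    cum_test_fraction: np.ndarray
    auc: float
    predictor: str = ""


def impute(model: SDA, exclude_components: tuple[int, ...] = ()) -> np.ndarray:
    """Imputed expression: the product of cell scores and gene loadings,
    with any excluded components' rows zeroed first."""
    return model.impute(exclude_components)


def split_reads(counts: ad.AnnData, p_test: float = 0.2, seed: int = 0) -> SplitCounts:
    """Assign each read to test with probability ``p_test``; per-entry
    binomial thinning, exact conservation train + test = source."""
    if not (0.0 < p_test < 1.0):
        raise ValueError("p_test must be in (0, 1)")
    rng = np.random.default_rng(seed)
    x = counts.X
    if sparse.issparse(x):
        x = x.tocsr()
        test_data = rng.binomial(x.data.astype(np.int64), p_test)
        test = x.copy()
        test.data = test_data
        train = x.copy()
        train.data = x.data - test_data
        test.eliminate_zeros()
        train.eliminate_zeros()
    else:
        x = np.asarray(x, dtype=np.int64)
        test = rng.binomial(x, p_test)
        train = x - test
    mk = lambda m: ad.AnnData(X=m, obs=counts.obs.copy(), var=counts.var.copy())
    return SplitCounts(train=mk(train), test=mk(test), p_test=p_test, seed=seed)


def rpac(predicted: np.ndarray, test_counts: np.ndarray, predictor: str = "") -> RPACResult:
    """RPAC for one cell.

    Genes are sorted by predicted expression descending; tied predictions
    contribute the average of their test reads per tied rank (the expected
    curve under a random tie order, so the result is deterministic and
    permutation-invariant).  The AUC integrates the curve over rank
    fraction by the trapezoidal rule, endpoints (0,0) and (1,1) included.
    """
    predicted = np.asarray(predicted, dtype=float)
    test_counts = np.asarray(test_counts, dtype=float)
    if predicted.shape != test_counts.shape or predicted.ndim != 1:
        raise ValueError("predicted and test_counts must be equal-length vectors")
    total = test_counts.sum()
    if total <= 0:
        raise ValueError("cell has no test reads")
    g = predicted.size
    order = np.argsort(-predicted, kind="stable")
    sorted_pred = predicted[order]
    sorted_test = test_counts[order]
    # average test reads within tied-prediction groups
    boundaries = np.flatnonzero(np.diff(sorted_pred)) + 1
    group_id = np.zeros(g, dtype=int)
    group_id[boundaries] = 1
    group_id = np.cumsum(group_id)
    sums = np.bincount(group_id, weights=sorted_test)
    sizes = np.bincount(group_id)
    per_rank = sums[group_id] / sizes[group_id]
    cum = np.concatenate([[0.0], np.cumsum(per_rank)]) / total
    ranks = np.arange(g + 1) / g
    auc = float(np.trapezoid(cum, ranks))
    return RPACResult(rank_fraction=ranks, cum_test_fraction=cum, auc=auc,
                      predictor=predictor)


def unimputed_predictor(train: ad.AnnData) -> np.ndarray:
    """Training counts scaled by each cell's total UMI count.  Cells with an
    empty training row fall back to the mean-cell (per-gene total) ranking."""
    x = train.X
    dense = np.asarray(x.todense(), dtype=float) if sparse.issparse(x) else np.asarray(x, dtype=float)
    totals = dense.sum(axis=1)
    pred = np.zeros_like(dense)
    ok = totals > 0
    pred[ok] = dense[ok] / totals[ok, None]
    if (~ok).any():
        logger.info("%d cells with empty training rows fall back to mean-cell",
                    int((~ok).sum()))
        pred[~ok] = dense.sum(axis=0) / max(dense.sum(), 1.0)
    return pred


def meancell_predictor(train: ad.AnnData) -> np.ndarray:
    """The sum of training reads for each gene across all cells; every cell
    receives the identical prediction vector."""
    x = train.X
    sums = (
        np.asarray(x.sum(axis=0)).ravel()
        if sparse.issparse(x)
        else np.asarray(x).sum(axis=0)
    ).astype(float)
    return np.broadcast_to(sums, (train.n_obs, train.n_vars)).copy()


def evaluate_predictors(
    predictors: Mapping[str, np.ndarray | Callable[[ad.AnnData], np.ndarray]],
    split: SplitCounts,
) -> pd.DataFrame:
    """Per-cell RPAC AUC for each named predictor.

    A predictor is a cells x genes matrix of predictions on the split's
    cells/genes, or a callable applied to the training AnnData.  Cells with
    zero test reads are skipped (logged).  Returns a tidy frame (cell_id,
    predictor, auc).
    """
    test = split.test.X
    test_dense = (
        np.asarray(test.todense(), dtype=float)
        if sparse.issparse(test)
        else np.asarray(test, dtype=float)
    )
    cell_ids = split.test.obs_names
    test_totals = test_dense.sum(axis=1)
    usable = test_totals > 0
    if (~usable).any():
        logger.info("skipping %d cells with no test reads", int((~usable).sum()))

    rows = []
    for name, pred in predictors.items():
        mat = pred(split.train) if callable(pred) else np.asarray(pred, dtype=float)
        if mat.shape != test_dense.shape:
            raise ValueError(
                f"predictor {name!r} has shape {mat.shape}, expected {test_dense.shape}"
            )
        for i in np.where(usable)[0]:
            res = rpac(mat[i], test_dense[i], predictor=name)
            rows.append((cell_ids[i], name, res.auc))
    return pd.DataFrame(rows, columns=["cell_id", "predictor", "auc"])


def compare_imputations(
    imp1: np.ndarray,
    imp2: np.ndarray,
    model: SDA,
    n_least: int = 500,
    alpha: float = 0.05,
    n_top: int = 500,
    gene_ids: pd.Index | None = None,
    cmle: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-gene agreement of two imputations, and which components explain
    the disagreement.

    Computes the per-gene Pearson correlation of the two imputed matrices
    across cells (constant genes recorded as NaN), then Fisher-tests the
    ``n_least`` least-correlated genes against each component's top-gene
    sets (positive and negative sides, ``n_top`` genes each), Bonferroni-
    corrected across components x sides.

    Returns (per-gene r, enrichment table with a Bonferroni-significant
    flag at ``alpha``).
    """
    imp1 = np.asarray(imp1, dtype=float)
    imp2 = np.asarray(imp2, dtype=float)
    if imp1.shape != imp2.shape:
        raise ValueError("imputation matrices must have equal shapes")
    n, g = imp1.shape
    a = imp1 - imp1.mean(axis=0)
    b = imp2 - imp2.mean(axis=0)
    sa = a.std(axis=0)
    sb = b.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a * b).mean(axis=0) / (sa * sb)
    constant = (sa == 0) | (sb == 0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant genes: correlation undefined",
            stacklevel=2,
        )
        r[constant] = np.nan

    defined = np.where(~np.isnan(r))[0]
    order = defined[np.argsort(r[defined], kind="stable")]
    least = set(order[:n_least].tolist())

    k = model.loadings_.shape[0]
    n_tests = 2 * k
    rows = []
    for comp in range(k):
        for side in ("P", "N"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                top = top_genes(model.loadings_, comp, side=side, n=n_top)
            top_set = set(top.tolist())
            a11 = len(least & top_set)
            a12 = len(top_set) - a11
            a21 = len(least) - a11
            a22 = g - len(top_set) - a21
            if a11 + a12 == 0:
                continue
            sample_or, cmle_or, p = fisher_2x2(a11, a12, a21, a22, cmle=cmle)
            rows.append(
                (comp, side, a11, sample_or, cmle_or, p,
                 min(1.0, p * n_tests), p * n_tests <= alpha)
            )
    table = pd.DataFrame(
        rows,
        columns=["component", "side", "overlap", "odds_ratio",
                 "cmle_odds_ratio", "p", "p_bonferroni", "significant"],
    )
    return r, table
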