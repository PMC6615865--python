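"""Component annotation and exact enrichment statistics.

Top-gene extraction per component side, one-sidedness of cell scores,
strain enrichment of strongly loading cells, and 2x2 exact tests (Fisher)
with both the sample odds ratio ad/bc and the conditional maximum-
likelihood odds ratio, as used for GWAS-hit, ChIP-target, gene-set and
histology-count enrichment.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "top_genes",
    "fisher_2x2",
    "geneset_enrichment",
    "one_sidedness",
    "strain_enrichment",
    "tubule_positive_test",
]


def top_genes(
    loadings: np.ndarray,
    component: int,
    side: str = "P",
    n: int = 250,
    gene_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Top ``n`` genes of one component by loading, positive or negative side.

    Side 'P' sorts descending, 'N' ascending; ties are broken by stable gene
    order.  Returns gene indices, or ids when ``gene_ids`` is given.  A
    component with no negative loadings yields an empty 'N' list with a
    warning.
    """
    loadings = np.asarray(loadings, dtype=float)
    row = loadings[component]
    if n > row.size:
        raise ValueError("n exceeds the number of genes")
    if side == "P":
        order = np.argsort(-row, kind="stable")
    elif side == "N":
        if not (row < 0).any():
            warnings.warn(
                f"component {component} has no negative loadings", stacklevel=2
            )
            return np.array([], dtype=int)
        order = np.argsort(row, kind="stable")
    else:
        raise ValueError("side must be 'P' or 'N'")
    idx = order[:n]
    if gene_ids is not None:
        return np.asarray(gene_ids)[idx]
    return idx


def _cmle_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Conditional MLE of the odds ratio given the table margins.

    Solves the conditional score equation E[a | psi] = a for the
    noncentral hypergeometric distribution, with the root found on an
    inverse scale at the conventional tolerance — the procedure of the
    standard exact-test implementation (R ``fisher.test``), so published
    odds ratios reproduce to their printed precision.  (A root solved to
    machine precision differs in the third significant digit for extreme
    tables.)
    """
    from scipy.optimize import brentq
    from scipy.stats import nchypergeom_fisher

    N = a + b + c + d
    K = a + b            # first-row margin (successes in the population)
    n = a + c            # first-column margin (sample size)
    lo = max(0, n - (N - K))
    hi = min(K, n)
    if a == lo:
        return 0.0
    if a == hi:
        return np.inf

    def cond_mean(psi: float) -> float:
        return float(nchypergeom_fisher.mean(N, K, n, psi))

    tol = float(np.finfo(float).eps) ** 0.25
    mu1 = cond_mean(1.0)
    if mu1 > a:
        return float(brentq(lambda t: cond_mean(t) - a, 1e-300, 1.0, xtol=tol))
    if mu1 < a:
        root = brentq(
            lambda t: cond_mean(1.0 / t) - a, np.finfo(float).eps, 1.0,
            xtol=tol,
        )
        return float(1.0 / root)
    return 1.0


def fisher_2x2(
    a: int, b: int, c: int, d: int, cmle: bool = True
) -> tuple[float, float, float]:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (sample odds ratio ad/bc, conditional-MLE odds ratio, two-sided
    p).  The two-sided p sums the hypergeometric probabilities of all tables
    with the observed margins that are no more probable than the observed
    one (the minimum-likelihood convention).  The conditional MLE requires a
    numerical optimization; pass ``cmle=False`` in bulk scans to skip it
    (reported as NaN).
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be nonnegative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero table: odds ratio and p undefined")
    if b * c == 0:
        sample_or = np.inf if a * d > 0 else np.nan
    else:
        sample_or = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    cmle_or = _cmle_odds_ratio(a, b, c, d) if cmle else np.nan
    return float(sample_or), cmle_or, float(p)


def one_sidedness(cell_scores: np.ndarray) -> float:
    """Cell score range ratio max(|max|, |min|) / min(|max|, |min|).

    Components with ratio above 5 are treated as one-sided (their minor
    loading side is skipped in enrichment).  A score range touching zero on
    one side gives an infinite ratio.
    """
    s = np.asarray(cell_scores, dtype=float)
    if s.size == 0 or np.all(s == s.flat[0]):
        raise ValueError("cell scores must be non-constant")
    hi, lo = abs(float(s.max())), abs(float(s.min()))
    big, small = max(hi, lo), min(hi, lo)
    return np.inf if small == 0 else big / small


def geneset_enrichment(
    gene_sets: Mapping[str, Sequence[str]],
    loadings: np.ndarray,
    gene_ids: Sequence[str],
    n_top: int = 250,
    sides: Sequence[str] = ("P", "N"),
    universe: Sequence[str] | None = None,
    correction: str = "bh",
    alpha: float = 0.05,
    cell_scores: np.ndarray | None = None,
    one_sided_ratio: float = 5.0,
    cmle: bool = True,
) -> pd.DataFrame:
    """Gene-set enrichment of each component's top genes, per side.

    One 2x2 exact test per (set, component, side): membership in the set
    against membership in the component's top ``n_top`` genes, within the
    universe (the loading matrix's genes by default).  When ``cell_scores``
    is given, one-sided components (range ratio > ``one_sided_ratio``)
    have their minor side skipped.  Multiple testing by Benjamini-Hochberg
    ('bh') or 'bonferroni'.
    """
    gene_ids = np.asarray(gene_ids)
    if universe is None:
        universe_set = set(gene_ids.tolist())
    else:
        universe_set = set(universe) & set(gene_ids.tolist())
    k = loadings.shape[0]

    skip: dict[int, str] = {}
    if cell_scores is not None:
        for comp in range(k):
            sc = cell_scores[:, comp]
            ratio = one_sidedness(sc)
            if ratio > one_sided_ratio:
                skip[comp] = "N" if abs(sc.max()) >= abs(sc.min()) else "P"

    rows = []
    for set_id, members in gene_sets.items():
        mem = set(members) & universe_set
        if not mem:
            warnings.warn(f"gene set {set_id!r} has no genes in the universe",
                          stacklevel=2)
            continue
        for comp in range(k):
            for side in sides:
                if skip.get(comp) == side:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    top = top_genes(loadings, comp, side=side, n=n_top,
                                    gene_ids=gene_ids)
                top_set = set(np.asarray(top).tolist()) & universe_set
                if not top_set:
                    continue
                a = len(mem & top_set)
                b = len(mem) - a
                c = len(top_set) - a
                d = len(universe_set) - a - b - c
                sample_or, cmle_or, p = fisher_2x2(a, b, c, d, cmle=cmle)
                rows.append((set_id, comp, side, a, sample_or, cmle_or, p))
    out = pd.DataFrame(
        rows,
        columns=["gene_set", "component", "side", "overlap",
                 "odds_ratio", "cmle_odds_ratio", "p"],
    )
    if len(out):
        if correction == "bh":
            out["q"] = stats.false_discovery_control(out["p"], method="bh")
        elif correction == "bonferroni":
            out["q"] = np.minimum(1.0, out["p"] * len(out))
        else:
            raise ValueError("correction must be 'bh' or 'bonferroni'")
        out["significant"] = out["q"] <= alpha
    return out


def strain_enrichment(
    cell_scores: np.ndarray,
    strain_labels: Sequence,
    score_threshold: float = 2.0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Strain composition of each component's strongly loading cells.

    Under the null that component loadings are distributed across cells
    regardless of strain, the fraction f_ij of strongly loading cells
    (|score| > threshold) on component j belonging to strain i matches that
    strain's overall cell fraction p_i; f_ij > p_i marks enrichment.

    Returns (f as components x strains, p per strain, enriched flags);
    components with no strong cells get NaN rows and no flags.
    """
    scores = np.asarray(cell_scores, dtype=float)
    strains = pd.Series(np.asarray(strain_labels))
    if len(strains) != scores.shape[0]:
        raise ValueError("strain labels must match the number of cells")
    levels = strains.unique()
    p = strains.value_counts(normalize=True).reindex(levels)
    k = scores.shape[1]
    f = pd.DataFrame(np.nan, index=range(k), columns=levels)
    for comp in range(k):
        strong = np.abs(scores[:, comp]) > score_threshold
        if not strong.any():
            warnings.warn(f"component {comp} has no strongly loading cells",
                          stacklevel=2)
            continue
        f.loc[comp] = (
            strains[strong].value_counts(normalize=True).reindex(levels).fillna(0.0)
        )
    enriched = f.gt(p, axis=1) & f.notna()
    return f, p, enriched


def tubule_positive_test(
    pos_a: int, total_a: int, pos_b: int, total_b: int
) -> tuple[float, float, float]:
    """Compare positive-tubule frequencies between two genotypes.

    Returns (percent_a, percent_b, two-sided Fisher p), percentages at one
    decimal place, testing the null that the positive frequency is the same
    in both groups.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if pos_a > total_a or pos_b > total_b:
        raise ValueError("positives cannot exceed totals")
    _, _, p = fisher_2x2(pos_a, total_a - pos_a, pos_b, total_b - pos_b)
    return (
        round(100.0 * pos_a / total_a, 1),
        round(100.0 * pos_b / total_b, 1),
        p,
    )
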