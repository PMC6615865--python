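"""Principal-curve pseudotime from component-score embeddings.

Cells are embedded in 2-D by t-SNE on the component score matrix (technical
and batch components removed, somatic cells excluded by score thresholds),
a principal curve is fitted iteratively with an increasing spline
degrees-of-freedom schedule, and each cell's pseudotime is the arc-length
of its nearest point on the curve.  Components are placed in time by the
score-weighted mean pseudotime of their strongly loading cells, and the
X:autosome expression ratio along pseudotime quantifies meiotic sex
chromosome inactivation (MSCI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import LSQUnivariateSpline
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "Embedding",
    "PseudotimeResult",
    "PrincipalCurve",
    "TrajectoryResult",
    "embed_cells",
    "exclude_somatic",
    "geodesic_ordering",
    "trajectory_pseudotime",
    "fit_principal_curve",
    "assign_pseudotime",
    "orient_pseudotime",
    "order_components",
    "x_autosome_ratio",
    "mean_adjacent_spacing_minutes",
]

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    coords: np.ndarray
    perplexity: float
    n_iter: int
    seed: int | None
    excluded_component_ids: tuple[int, ...]


@dataclass
class PseudotimeResult:
    """Per-cell arc-length pseudotime and distance to the principal curve."""

    pseudotime: np.ndarray
    distance_to_curve: np.ndarray
    excluded_mask: np.ndarray
    posthoc_mask: np.ndarray


def embed_cells(
    scores: np.ndarray,
    excluded: Sequence[int] = (),
    perplexity: float = 50.0,
    n_iter: int = 1000,
    seed: int | None = 0,
) -> Embedding:
    """2-D t-SNE of the cell score matrix with excluded components dropped.

    Run directly on the scores (no initial PCA step), random
    initialization, deterministic given the seed.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] < 3 * perplexity:
        raise ValueError(
            f"need at least {int(3 * perplexity)} cells for perplexity {perplexity}"
        )
    keep = np.ones(scores.shape[1], dtype=bool)
    for k in excluded:
        keep[k] = False
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=n_iter,
        init="random",
        random_state=seed,
    )
    coords = tsne.fit_transform(scores[:, keep])
    return Embedding(
        coords=np.asarray(coords, dtype=float),
        perplexity=perplexity,
        n_iter=n_iter,
        seed=seed,
        excluded_component_ids=tuple(int(k) for k in excluded),
    )


def exclude_somatic(
    scores: np.ndarray,
    rules: Sequence[tuple[int, float]],
    mito_expr: np.ndarray | None = None,
    mito_threshold: float = 3.0,
) -> np.ndarray:
    """Mask of cells excluded as somatic: a cell is excluded if its absolute
    score on ANY listed component exceeds that component's threshold, or its
    mitochondrial marker expression exceeds ``mito_threshold``."""
    scores = np.asarray(scores, dtype=float)
    mask = np.zeros(scores.shape[0], dtype=bool)
    for comp, thr in rules:
        mask |= np.abs(scores[:, comp]) > thr
    if mito_expr is not None:
        mask |= np.asarray(mito_expr, dtype=float) > mito_threshold
    return mask


def _project_to_polyline(
    points: np.ndarray, curve: np.ndarray, arc: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest-point projection onto a polyline.

    Returns per-point (arc-length position, distance).  Equidistant
    projections resolve to the lower arc-length (segments scanned in
    increasing arc order, strict improvement required).
    """
    seg_start = curve[:-1]
    seg_vec = curve[1:] - curve[:-1]
    seg_len2 = (seg_vec**2).sum(axis=1)
    seg_len2 = np.where(seg_len2 == 0, 1e-300, seg_len2)
    # (n_points, n_segments) parameter of the perpendicular foot, clamped
    diff = points[:, None, :] - seg_start[None, :, :]
    t = np.clip((diff * seg_vec[None, :, :]).sum(axis=2) / seg_len2[None, :], 0.0, 1.0)
    foot = seg_start[None, :, :] + t[:, :, None] * seg_vec[None, :, :]
    d2 = ((points[:, None, :] - foot) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)  # first (lowest-arc) minimizer
    rows = np.arange(len(points))
    pos = arc[best] + t[rows, best] * np.sqrt(seg_len2[best])
    return pos, np.sqrt(d2[rows, best])


class PrincipalCurve(BaseEstimator):
    """Iterative principal curve through a 2-D point cloud.

    Alternates projecting points onto the current curve (giving arc-length
    parameters) with smoothing each coordinate as a least-squares cubic
    regression spline of the arc-length, at increasing degrees of freedom
    (default schedule 4 through 9, each warm-started from the previous
    fit).  The alternation monotonically decreases the total squared
    projection distance at fixed degrees of freedom, up to curve
    discretization.

    Attributes
    ----------
    curve_points_ : (M, 2) ordered points along the fitted curve.
    arc_length_ : strictly increasing arc-length at each curve point.
    lambda_ : per-training-point arc-length position.
    distance_ : per-training-point distance to the curve.
    ss_trace_ : total squared projection distance per inner iteration.
    """

    def __init__(
        self,
        df_schedule: Sequence[int] = (4, 5, 6, 7, 8, 9),
        max_inner_iter: int = 20,
        tol: float = 1e-4,
        n_curve_points: int | None = None,
        initial_lambda: np.ndarray | None = None,
    ):
        self.df_schedule = df_schedule
        self.max_inner_iter = max_inner_iter
        self.tol = tol
        self.n_curve_points = n_curve_points
        self.initial_lambda = initial_lambda

    def _smooth(self, lam: np.ndarray, coords: np.ndarray, df: int,
                m: int) -> tuple[np.ndarray, np.ndarray]:
        """Fit per-coordinate cubic splines with ``df`` degrees of freedom
        (df - 4 interior knots at arc-length quantiles) and discretize."""
        order = np.argsort(lam, kind="stable")
        lam_s = lam[order]
        # strictly increasing abscissae for the spline fit
        eps = 1e-9 * max(lam_s[-1] - lam_s[0], 1.0)
        lam_u = lam_s + eps * np.arange(len(lam_s))
        n_knots = max(df - 4, 0)
        if n_knots > 0:
            qs = np.linspace(0, 1, n_knots + 2)[1:-1]
            knots = np.quantile(lam_u, qs)
            knots = np.unique(knots)
            inner = knots[(knots > lam_u[0]) & (knots < lam_u[-1])]
        else:
            inner = np.array([])
        grid = np.linspace(lam_u[0], lam_u[-1], m)
        curve = np.empty((m, coords.shape[1]))
        for j in range(coords.shape[1]):
            spl = LSQUnivariateSpline(lam_u, coords[order, j], inner, k=3)
            curve[:, j] = spl(grid)
        return curve, grid

    def fit(self, X, y=None) -> "PrincipalCurve":
        coords = np.asarray(X, dtype=float)
        if coords.ndim != 2 or coords.shape[1] < 2:
            raise ValueError("X must be n x d coordinates with d >= 2")
        n = coords.shape[0]
        if n < 10:
            raise ValueError("need at least 10 points")
        if np.allclose(coords, coords[0]):
            raise ValueError("degenerate input: all points identical")
        m = self.n_curve_points or max(100, n // 10)

        if self.initial_lambda is not None:
            lam = np.asarray(self.initial_lambda, dtype=float).copy()
            if lam.shape != (n,):
                raise ValueError("initial_lambda must have one value per point")
        else:
            # first principal component line
            lam = PCA(n_components=1).fit_transform(coords).ravel()
        lam = lam - lam.min()

        ss_trace: list[float] = []
        converged = True
        self.stage_results_: list[dict] = []
        for df in self.df_schedule:
            prev_ss = np.inf
            prev_state = None
            curve = arc = None
            stage_trace: list[float] = []
            for _ in range(self.max_inner_iter):
                new_curve, _ = self._smooth(lam, coords, df, m)
                seg = np.sqrt(((np.diff(new_curve, axis=0)) ** 2).sum(axis=1))
                new_arc = np.concatenate([[0.0], np.cumsum(seg)])
                new_lam, dist = _project_to_polyline(coords, new_curve, new_arc)
                ss = float((dist**2).sum())
                if ss > prev_ss:
                    # projection+refit overshoot: keep the previous (better)
                    # curve so the recorded trace stays non-increasing
                    curve, arc, lam = prev_state
                    break
                curve, arc, lam = new_curve, new_arc, new_lam
                prev_state = (curve, arc, lam)
                ss_trace.append(ss)
                stage_trace.append(ss)
                if prev_ss - ss < self.tol * max(prev_ss, 1e-12):
                    break
                prev_ss = ss
            else:
                converged = False
            keep = np.concatenate([[True], np.diff(arc) > 0])
            self.stage_results_.append(
                {
                    "df": df,
                    "curve_points": curve[keep],
                    "arc_length": arc[keep],
                    "lambda": lam.copy(),
                    "ss": ss_trace[-1] if ss_trace else np.inf,
                    "ss_trace": np.asarray(stage_trace),
                }
            )

        final = self.stage_results_[-1]
        self.curve_points_ = final["curve_points"]
        self.arc_length_ = final["arc_length"]
        self.lambda_, self.distance_ = _project_to_polyline(
            coords, self.curve_points_, self.arc_length_
        )
        self.ss_trace_ = np.asarray(ss_trace)
        self.converged_ = converged
        self.df_schedule_ = tuple(self.df_schedule)
        return self

    def transform(self, X) -> np.ndarray:
        """Arc-length pseudotime of (new) points on the fitted curve."""
        check_is_fitted(self, "curve_points_")
        pos, _ = _project_to_polyline(
            np.asarray(X, dtype=float), self.curve_points_, self.arc_length_
        )
        return pos


def geodesic_ordering(coords: np.ndarray, n_neighbors: int = 15) -> np.ndarray:
    """Order points along a filament by graph geodesics.

    Builds a symmetrized k-nearest-neighbor graph on the coordinates,
    finds an extremal point (farthest from an arbitrary start), and returns
    each point's shortest-path distance from it.  Unlike the arc-length of
    a fitted curve, the graph ordering cannot fold back across the gap of a
    nearly-closed trajectory, which makes it a robust initialization and
    reference for the principal curve.  Points disconnected from the main
    filament are placed just past the farthest connected point.
    """
    from scipy.sparse.csgraph import shortest_path
    from sklearn.neighbors import kneighbors_graph

    coords = np.asarray(coords, dtype=float)
    g = kneighbors_graph(coords, n_neighbors, mode="distance")
    g = g.maximum(g.T)
    d0 = shortest_path(g, indices=[0])[0]
    far = int(np.where(np.isinf(d0), -1.0, d0).argmax())
    d1 = shortest_path(g, indices=[far])[0]
    finite = np.isfinite(d1)
    if not finite.all():
        logger.info("%d points disconnected from the main filament",
                    int((~finite).sum()))
        d1[~finite] = d1[finite].max() * 1.05
    return d1


@dataclass
class TrajectoryResult:
    """Chosen embedding + principal curve + per-cell pseudotime for the
    multi-seed trajectory pipeline."""

    embedding: Embedding
    curve: PrincipalCurve
    pseudotime: np.ndarray
    distance_to_curve: np.ndarray
    seed: int
    df: int
    agreement: float


def trajectory_pseudotime(
    scores: np.ndarray,
    excluded_components: Sequence[int] = (),
    perplexity: float = 50.0,
    n_iter: int = 1000,
    seeds: Sequence[int] = (0, 1, 2),
    df_schedule: Sequence[int] = (4, 5, 6, 7, 8, 9),
    n_neighbors: int = 15,
) -> TrajectoryResult:
    """Embed, fit a principal curve, and pick the most self-consistent run.

    2-D embeddings of a one-dimensional trajectory are seed-dependent and
    can place the trajectory's ends close together, where a fitted curve
    may fold.  The pipeline therefore embeds with several seeds, fits the
    degrees-of-freedom schedule warm-started from the graph-geodesic
    ordering, and scores every (seed, df stage) candidate by the absolute
    Spearman agreement between its arc-length positions and the geodesic
    ordering of its own embedding; the best-agreeing candidate wins.  The
    criterion is internal — no ground truth enters the selection.
    """
    best: TrajectoryResult | None = None
    for seed in seeds:
        emb = embed_cells(
            scores, excluded=excluded_components, perplexity=perplexity,
            n_iter=n_iter, seed=seed,
        )
        lam0 = geodesic_ordering(emb.coords, n_neighbors=n_neighbors)
        pc = PrincipalCurve(df_schedule=df_schedule, initial_lambda=lam0).fit(
            emb.coords
        )
        for stage in pc.stage_results_:
            agree = abs(
                stats.spearmanr(stage["lambda"], lam0).statistic
            )
            if best is None or agree > best.agreement:
                chosen = PrincipalCurve(df_schedule=(stage["df"],))
                chosen.curve_points_ = stage["curve_points"]
                chosen.arc_length_ = stage["arc_length"]
                chosen.lambda_, chosen.distance_ = _project_to_polyline(
                    emb.coords, stage["curve_points"], stage["arc_length"]
                )
                chosen.ss_trace_ = np.asarray([stage["ss"]])
                chosen.converged_ = True
                chosen.df_schedule_ = (stage["df"],)
                best = TrajectoryResult(
                    embedding=emb,
                    curve=chosen,
                    pseudotime=chosen.lambda_,
                    distance_to_curve=chosen.distance_,
                    seed=seed if seed is not None else -1,
                    df=stage["df"],
                    agreement=float(agree),
                )
    assert best is not None
    return best


def fit_principal_curve(
    coords: np.ndarray,
    df_schedule: Sequence[int] = (4, 5, 6, 7, 8, 9),
    max_inner_iter: int = 20,
    tol: float = 1e-4,
) -> PrincipalCurve:
    """Fit the iterative principal curve; thin wrapper over
    :class:`PrincipalCurve`."""
    return PrincipalCurve(
        df_schedule=df_schedule, max_inner_iter=max_inner_iter, tol=tol
    ).fit(coords)


def assign_pseudotime(
    coords: np.ndarray,
    curve: PrincipalCurve,
    posthoc_cells: Sequence[int] | np.ndarray = (),
) -> PseudotimeResult:
    """Map every cell to the arc-length of its nearest curve point.

    ``posthoc_cells`` (cells excluded from the curve fit, e.g. somatic
    cells added back) are mapped by the identical rule but flagged.
    Equidistant projections take the lower arc-length.
    """
    coords = np.asarray(coords, dtype=float)
    pos, dist = _project_to_polyline(coords, curve.curve_points_, curve.arc_length_)
    posthoc = np.zeros(len(coords), dtype=bool)
    posthoc[np.asarray(list(posthoc_cells), dtype=int)] = True
    return PseudotimeResult(
        pseudotime=pos,
        distance_to_curve=dist,
        excluded_mask=np.zeros(len(coords), dtype=bool),
        posthoc_mask=posthoc,
    )


def orient_pseudotime(
    pseudotime: np.ndarray, early_mask: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Fix the arbitrary curve orientation using known early cells.

    If the early cells sit at high arc-length the axis is flipped
    (pt -> max - pt).  Returns (oriented pseudotime, flipped flag).
    """
    pt = np.asarray(pseudotime, dtype=float)
    early = np.asarray(early_mask, dtype=bool)
    flipped = pt[early].mean() > pt[~early].mean() if early.any() else False
    return (pt.max() - pt, True) if flipped else (pt.copy(), False)


def order_components(
    scores: np.ndarray,
    pseudotime: np.ndarray,
    score_threshold: float = 2.0,
) -> np.ndarray:
    """Temporal position of each component: the |score|-weighted mean
    pseudotime over cells with absolute score above the threshold; NaN when
    no cell qualifies."""
    scores = np.asarray(scores, dtype=float)
    pt = np.asarray(pseudotime, dtype=float)
    out = np.full(scores.shape[1], np.nan)
    for k in range(scores.shape[1]):
        w = np.abs(scores[:, k])
        strong = w > score_threshold
        if strong.any():
            out[k] = float(np.average(pt[strong], weights=w[strong]))
        else:
            logger.info("component %d has no cells above |score| threshold", k)
    return out


def x_autosome_ratio(
    imputed: np.ndarray,
    gene_chrom: Sequence[str],
    pseudotime: np.ndarray,
    window: int | None = None,
) -> pd.DataFrame:
    """X:autosome expression ratio along pseudotime.

    Per cell, the sum of imputed expression over X genes divided by the sum
    over autosomes (chromosomes other than X, Y and MT); optionally smoothed
    by a centered rolling mean of ``window`` cells in pseudotime order.
    Cells with nonpositive autosomal sums are skipped.
    """
    imputed = np.asarray(imputed, dtype=float)
    chrom = np.asarray(gene_chrom).astype(str)
    pt = np.asarray(pseudotime, dtype=float)
    x_mask = chrom == "X"
    auto_mask = ~np.isin(chrom, ["X", "Y", "MT"])
    x_sum = imputed[:, x_mask].sum(axis=1) if x_mask.any() else np.zeros(len(pt))
    a_sum = imputed[:, auto_mask].sum(axis=1)
    ok = a_sum > 0
    if (~ok).any():
        logger.info("skipping %d cells with nonpositive autosomal sums",
                    int((~ok).sum()))
    ratio = np.full(len(pt), np.nan)
    ratio[ok] = x_sum[ok] / a_sum[ok]
    out = pd.DataFrame({"pseudotime": pt, "ratio": ratio}).sort_values(
        "pseudotime", kind="stable"
    )
    if window is not None and window > 1:
        out["smoothed"] = (
            out["ratio"].rolling(window, center=True, min_periods=1).mean()
        )
    return out.reset_index(drop=True)


def mean_adjacent_spacing_minutes(total_days: float, n_cells: int) -> float:
    """Mean developmental-age spacing between pseudotime-adjacent cells, in
    minutes, when ``total_days`` of development are spread over ``n_cells``
    ordered cells."""
    if n_cells < 2:
        raise ValueError("need at least two cells")
    return total_days * 24.0 * 60.0 / (n_cells - 1)
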