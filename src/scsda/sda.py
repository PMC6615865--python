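"""Sparse Bayesian factor decomposition with a spike-and-slab prior (SDA).

Model: X_cg = sum_k A_ck B_kg + eps_cg with eps_cg ~ N(0, 1/lambda_g),
A_ck ~ N(0, 1), and B_kg = S_kg W_kg where S_kg ~ Bernoulli(rho_k) (the
spike: a point mass at zero) and W_kg ~ N(0, 1/beta_k) (the slab).
Conjugate hyperpriors: rho_k ~ Beta(a_rho, b_rho), beta_k ~ Gamma(a_beta,
b_beta), lambda_g ~ Gamma(a_lambda, b_lambda).  The posterior inclusion
probability PIP_kg = q(S_kg = 1) measures how confidently a gene loads on a
component.

Inference is mean-field variational coordinate ascent.  Each block update
(one component's loadings across all genes, one component's scores across
all cells, then the conjugate hyperparameter blocks) is the exact
conditional maximizer of the evidence lower bound (ELBO, the negative
variational free energy), so the ELBO is non-decreasing across iterations —
this is asserted at every iteration and doubles as a correctness check of
the update algebra.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, linalg as sla
from scipy.special import betaln, digamma, gammaln, xlogy
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .qc import NormalizedMatrix

__all__ = [
    "SDA",
    "fit_sda",
    "sparsify",
    "sparsity_profile",
    "match_components",
    "procrustes_compare",
    "flag_single_cell_components",
    "flag_technical_components",
]

_LOG2PI = np.log(2.0 * np.pi)


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, NormalizedMatrix):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def _kl_gamma(a: np.ndarray, b: np.ndarray, a0: float, b0: float) -> np.ndarray:
    """KL(Gamma(a, rate b) || Gamma(a0, rate b0))."""
    return (
        (a - a0) * digamma(a)
        - gammaln(a)
        + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )


def _kl_beta(a: np.ndarray, b: np.ndarray, a0: float, b0: float) -> np.ndarray:
    return (
        betaln(a0, b0)
        - betaln(a, b)
        + (a - a0) * digamma(a)
        + (b - b0) * digamma(b)
        + (a0 - a + b0 - b) * digamma(a + b)
    )


class SDA(BaseEstimator, TransformerMixin):
    """Spike-and-slab sparse factor analysis fitted by variational Bayes.

    Parameters
    ----------
    n_components : number of latent components K.
    max_iter : maximum coordinate-ascent sweeps.
    elbo_tol : relative ELBO-change convergence tolerance.
    pip_change_tol : tolerance on the fraction of PIPs crossing 0.5 between
        sweeps (both tolerances must be met to stop early).
    a_rho, b_rho, a_beta, b_beta, a_lambda, b_lambda : hyperprior
        parameters (Beta on the slab inclusion probability, Gamma on the
        slab and noise precisions).
    rho_fixed : fix the inclusion probability instead of learning it;
        ``rho_fixed=1`` gives dense Bayesian factor analysis.
    warmup_iters : sweeps during which PIPs stay at 0.5 and the rho/beta
        blocks are not updated, so components can grow into structure
        before the spike can prune them (still exact coordinate ascent;
        the ELBO stays monotone).
    random_state : seed for the score initialization.

    Attributes
    ----------
    cell_scores_ : (n_cells, K) posterior mean scores A.
    loadings_ : (K, n_genes) posterior mean loadings E[B] = PIP * slab mean.
    pip_ : (K, n_genes) posterior inclusion probabilities.
    rho_, beta_, lambda_ : posterior means of the conjugate blocks.
    elbo_trace_ : ELBO after every sweep (non-decreasing).
    """

    def __init__(
        self,
        n_components: int = 50,
        max_iter: int = 10000,
        elbo_tol: float = 1e-6,
        pip_change_tol: float = 1e-4,
        a_rho: float = 1.0,
        b_rho: float = 1.0,
        a_beta: float = 1e-3,
        b_beta: float = 1e-3,
        a_lambda: float = 1e-3,
        b_lambda: float = 1e-3,
        rho_fixed: float | None = None,
        warmup_iters: int = 25,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.elbo_tol = elbo_tol
        self.pip_change_tol = pip_change_tol
        self.a_rho = a_rho
        self.b_rho = b_rho
        self.a_beta = a_beta
        self.b_beta = b_beta
        self.a_lambda = a_lambda
        self.b_lambda = b_lambda
        self.rho_fixed = rho_fixed
        self.warmup_iters = warmup_iters
        self.random_state = random_state

    # -- internal state helpers -------------------------------------------

    def _expected_sq_residual(self, R: np.ndarray) -> np.ndarray:
        """E[(X - A B)^2] summed over cells, per gene."""
        sum_m2 = (self._M**2).sum(axis=0)          # (K,)
        sum_a2 = sum_m2 + self._N * self._v        # (K,)
        q = (R**2).sum(axis=0)
        q += sum_a2 @ self._EB2
        q -= sum_m2 @ (self._EB**2)
        return q

    def _elbo(self, R: np.ndarray) -> float:
        N, G, K = self._N, self._G, self.n_components
        e_log_lam = digamma(self._al) - np.log(self._bl)
        e_lam = self._al / self._bl
        q = self._expected_sq_residual(R)
        ell = float(
            (N / 2.0) * (e_log_lam - _LOG2PI).sum() - 0.5 * (e_lam * q).sum()
        )

        kl_a = 0.5 * (
            (self._M**2).sum() + N * self._v.sum() - N * K - N * np.log(self._v).sum()
        )

        gam, mu, s2 = self._gamma, self._mu, self._s2
        e_log_beta = digamma(self._ab) - np.log(self._bb)
        e_beta = self._ab / self._bb
        if self.rho_fixed is not None:
            e_log_rho = np.full(K, np.log(self.rho_fixed) if self.rho_fixed > 0 else -np.inf)
            e_log_1mrho = np.full(
                K, np.log1p(-self.rho_fixed) if self.rho_fixed < 1 else 0.0
            )
        else:
            e_log_rho = digamma(self._ar) - digamma(self._ar + self._br)
            e_log_1mrho = digamma(self._br) - digamma(self._ar + self._br)
        sw = (
            gam * e_log_rho[:, None]
            + (1.0 - gam) * e_log_1mrho[:, None]
            + gam * 0.5 * (e_log_beta[:, None] - _LOG2PI - e_beta[:, None] * (mu**2 + s2))
            - xlogy(gam, gam)
            - xlogy(1.0 - gam, 1.0 - gam)
            + gam * 0.5 * (np.log(2.0 * np.pi * s2) + 1.0)
        ).sum()

        kl_rho = 0.0
        if self.rho_fixed is None:
            kl_rho = _kl_beta(self._ar, self._br, self.a_rho, self.b_rho).sum()
        kl_beta = _kl_gamma(self._ab, self._bb, self.a_beta, self.b_beta).sum()
        kl_lambda = _kl_gamma(self._al, self._bl, self.a_lambda, self.b_lambda).sum()
        return float(ell - kl_a + sw - kl_rho - kl_beta - kl_lambda)

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None) -> "SDA":
        X = _as_matrix(X)
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        N, G = X.shape
        K = self.n_components
        if K < 1:
            raise ValueError("n_components must be >= 1")
        if K > min(N, G):
            warnings.warn(
                f"K={K} exceeds min(n_cells, n_genes)={min(N, G)}", stacklevel=2
            )
        if self.rho_fixed is not None and not (0.0 < self.rho_fixed <= 1.0):
            raise ValueError("rho_fixed must be in (0, 1]")
        rng = np.random.default_rng(self.random_state)
        self._N, self._G = N, G

        # variational state
        self._M = rng.standard_normal((N, K))       # q(A) means
        self._v = np.ones(K)                        # q(A) variances (per component)
        self._gamma = np.full((K, G), 0.5)          # PIP
        self._mu = np.zeros((K, G))                 # slab means
        self._s2 = np.ones((K, G))                  # slab variances
        self._EB = self._gamma * self._mu
        self._EB2 = self._gamma * (self._mu**2 + self._s2)
        self._ar = np.full(K, self.a_rho)
        self._br = np.full(K, self.b_rho)
        # precision posteriors start at E=1 with O(1) shape; starting at a
        # diffuse prior shape makes E[log beta] so negative that every PIP
        # collapses to the spike on the first sweep
        self._ab = np.full(K, max(self.a_beta, 1.0))
        self._bb = np.full(K, max(self.b_beta, 1.0))
        self._al = np.full(G, self.a_lambda + N / 2.0)
        self._bl = np.full(G, self.b_lambda + N / 2.0)  # E[lambda]=1 at start

        R = X - self._M @ self._EB
        elbo_trace: list[float] = []
        prev_pip = self._gamma > 0.5
        self.converged_ = False

        for it in range(self.max_iter):
            e_lam = self._al / self._bl
            e_beta = self._ab / self._bb
            e_log_beta = digamma(self._ab) - np.log(self._bb)
            if self.rho_fixed is not None:
                if self.rho_fixed >= 1.0:
                    e_logit_rho = np.full(K, np.inf)
                else:
                    e_logit_rho = np.full(
                        K, np.log(self.rho_fixed) - np.log1p(-self.rho_fixed)
                    )
            else:
                e_logit_rho = digamma(self._ar) - digamma(self._br)

            # loadings (spike-and-slab, one component row at a time)
            for k in range(K):
                mk = self._M[:, k]
                Rk = R + np.outer(mk, self._EB[k])
                sum_a2 = float(mk @ mk) + N * self._v[k]
                s2 = 1.0 / (e_beta[k] + e_lam * sum_a2)
                mu = s2 * e_lam * (mk @ Rk)
                if it >= self.warmup_iters:
                    u = (
                        e_logit_rho[k]
                        + 0.5 * (e_log_beta[k] + np.log(s2))
                        + mu**2 / (2.0 * s2)
                    )
                    with np.errstate(over="ignore"):
                        gam = 1.0 / (1.0 + np.exp(-u))
                else:
                    # warm-up: PIPs stay at 0.5 while scores and slab means
                    # alternate, so weak components can grow into structure
                    # instead of decaying through the spike
                    gam = self._gamma[k]
                self._s2[k] = s2
                self._mu[k] = mu
                self._gamma[k] = gam
                self._EB[k] = gam * mu
                self._EB2[k] = gam * (mu**2 + s2)
                R = Rk - np.outer(mk, self._EB[k])

            # cell scores
            for k in range(K):
                Rk = R + np.outer(self._M[:, k], self._EB[k])
                tau = 1.0 + float(e_lam @ self._EB2[k])
                self._M[:, k] = (Rk @ (e_lam * self._EB[k])) / tau
                self._v[k] = 1.0 / tau
                R = Rk - np.outer(self._M[:, k], self._EB[k])

            # conjugate blocks; rho and beta stay at initialization during
            # warm-up so components cannot lock into the spike before the
            # score/loading alternation has separated the structure (each
            # sweep remains exact coordinate ascent, so the ELBO is still
            # monotone through the transition)
            if it >= self.warmup_iters:
                gsum = self._gamma.sum(axis=1)
                if self.rho_fixed is None:
                    self._ar = self.a_rho + gsum
                    self._br = self.b_rho + G - gsum
                self._ab = self.a_beta + 0.5 * gsum
                self._bb = self.b_beta + 0.5 * (
                    self._gamma * (self._mu**2 + self._s2)
                ).sum(axis=1)
            q = self._expected_sq_residual(R)
            self._al = np.full(G, self.a_lambda + N / 2.0)
            self._bl = self.b_lambda + 0.5 * q

            elbo = self._elbo(R)
            if not np.isfinite(elbo):
                raise FloatingPointError(f"non-finite ELBO at iteration {it}")
            if elbo_trace:
                drop = elbo_trace[-1] - elbo
                if drop > self.elbo_tol * max(abs(elbo), 1.0) and drop > 1e-6 * max(
                    abs(elbo), 1.0
                ):
                    raise RuntimeError(
                        f"ELBO decreased at iteration {it}: "
                        f"{elbo_trace[-1]:.8g} -> {elbo:.8g}"
                    )
            elbo_trace.append(elbo)

            pip_now = self._gamma > 0.5
            pip_change = np.mean(pip_now != prev_pip)
            prev_pip = pip_now
            if len(elbo_trace) >= 2 and it > self.warmup_iters:
                rel = abs(elbo_trace[-1] - elbo_trace[-2]) / max(abs(elbo_trace[-1]), 1.0)
                if rel < self.elbo_tol and pip_change < self.pip_change_tol:
                    self.converged_ = True
                    break

        self.cell_scores_ = self._M
        self.cell_score_var_ = self._v.copy()
        self.loadings_ = self._EB
        self.pip_ = self._gamma
        self.loading_slab_mean_ = self._mu
        self.loading_slab_var_ = self._s2
        self.rho_ = (
            np.full(K, self.rho_fixed)
            if self.rho_fixed is not None
            else self._ar / (self._ar + self._br)
        )
        self.beta_ = self._ab / self._bb
        self.lambda_ = self._al / self._bl
        self.elbo_trace_ = np.asarray(elbo_trace)
        self.n_iter_ = len(elbo_trace)
        self._residual = R
        return self

    def elbo(self, X) -> float:
        """Recompute the variational lower bound at the fitted posterior.

        Matches the tail of ``elbo_trace_`` when evaluated on the training
        matrix.
        """
        check_is_fitted(self, "loadings_")
        X = _as_matrix(X)
        if X.shape != (self._N, self._G):
            raise ValueError("shape mismatch with the fitted model")
        R = X - self._M @ self._EB
        return self._elbo(R)

    def transform(self, X) -> np.ndarray:
        """Posterior-mean scores for (new) cells given the fitted loadings."""
        check_is_fitted(self, "loadings_")
        X = _as_matrix(X)
        lam = self.lambda_
        B = self.loadings_
        prec = np.eye(self.n_components) + (B * lam) @ B.T
        return np.linalg.solve(prec, (B * lam) @ X.T).T

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.cell_scores_

    def impute(self, exclude_components: Iterable[int] = ()) -> np.ndarray:
        """Model-imputed expression A @ E[B], optionally dropping components."""
        check_is_fitted(self, "loadings_")
        keep = np.ones(self.n_components, dtype=bool)
        for k in exclude_components:
            keep[k] = False
        return self.cell_scores_[:, keep] @ self.loadings_[keep]


def fit_sda(
    x,
    k: int = 50,
    max_iter: int = 10000,
    elbo_tol: float = 1e-6,
    pip_change_tol: float = 1e-4,
    seed: int = 0,
    n_restarts: int = 1,
    **kwargs,
) -> SDA:
    """Fit the spike-and-slab factor model; thin wrapper over :class:`SDA`.

    With ``n_restarts`` > 1, fits from that many score initializations
    (seeds derived from ``seed``) and returns the run with the highest
    final ELBO — variational coordinate ascent has local optima, and the
    bound itself is the model's own ranking of them.
    """
    best = None
    seeds = [seed] if n_restarts <= 1 else [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n_restarts)
    ]
    for s in seeds:
        model = SDA(
            n_components=k,
            max_iter=max_iter,
            elbo_tol=elbo_tol,
            pip_change_tol=pip_change_tol,
            random_state=s,
            **kwargs,
        ).fit(x)
        if best is None or model.elbo_trace_[-1] > best.elbo_trace_[-1]:
            best = model
    return best


def sparsify(model: SDA, pip_threshold: float = 0.5) -> np.ndarray:
    """Loading matrix with entries of PIP below the threshold set to zero."""
    if not (0.0 <= pip_threshold <= 1.0):
        raise ValueError("pip_threshold must be in [0, 1]")
    check_is_fitted(model, "loadings_")
    return np.where(model.pip_ >= pip_threshold, model.loadings_, 0.0)


def sparsity_profile(
    loadings: np.ndarray, threshold_fracs: Sequence[float]
) -> np.ndarray:
    """Fraction of absolute loadings exceeding each threshold, thresholds
    given as fractions of the maximum absolute loading; strictly a
    non-increasing curve."""
    loadings = np.asarray(loadings, dtype=float)
    if loadings.size == 0:
        raise ValueError("empty loading matrix")
    m = np.abs(loadings).max()
    if m == 0:
        warnings.warn("all-zero loading matrix", stacklevel=2)
        return np.zeros(len(threshold_fracs))
    absl = np.abs(loadings).ravel()
    return np.array([np.mean(absl > f * m) for f in threshold_fracs])


def _abs_corr_matrix(l1: np.ndarray, l2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson correlations between rows; zero-variance rows get 0."""
    a = l1 - l1.mean(axis=1, keepdims=True)
    b = l2 - l2.mean(axis=1, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (a @ b.T) / np.outer(sa, sb)
    corr[~np.isfinite(corr)] = 0.0
    return corr, np.abs(corr)


def match_components(l1: np.ndarray, l2: np.ndarray):
    """Match the rows of two loading matrices up to permutation and sign.

    Solves the linear assignment problem on the absolute Pearson
    correlation matrix; signs are chosen so matched correlations are
    positive.  Returns (permutation, signs, matched correlations), where
    ``permutation[i]`` is the row of ``l2`` matched to row i of ``l1``.
    """
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    if l1.shape[1] != l2.shape[1]:
        raise ValueError("gene dimensions differ")
    corr, acorr = _abs_corr_matrix(l1, l2)
    rows, cols = optimize.linear_sum_assignment(-acorr)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    signed = corr[rows, perm[rows]]
    signs = np.where(signed >= 0, 1, -1)
    return perm, signs, np.abs(signed)


def procrustes_compare(
    l_source: np.ndarray, l_target: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal (Procrustes) rotation of one loading matrix onto another.

    Finds the K x K orthogonal R minimizing ||R l_source - l_target||_F
    (SVD-based, so rank-deficient inputs are handled by the pseudo-inverse
    structure of the SVD) and returns (rotated source, per-component
    Pearson correlation with the target).
    """
    l_source = np.asarray(l_source, dtype=float)
    l_target = np.asarray(l_target, dtype=float)
    if l_source.shape != l_target.shape:
        raise ValueError("loading matrices must have equal shapes")
    rt, _ = sla.orthogonal_procrustes(l_source.T, l_target.T)
    rotated = (l_source.T @ rt).T
    corr, _ = _abs_corr_matrix(rotated, l_target)
    return rotated, np.diag(corr)


def flag_single_cell_components(
    model: SDA,
    dominance_ratio: float = 5.0,
    min_cells: int = 5,
    activity_fraction: float = 0.25,
) -> list[int]:
    """Flag components driven by one (or very few) cells.

    A component is flagged when its largest absolute cell score exceeds
    ``dominance_ratio`` times the second largest, or when fewer than
    ``min_cells`` cells have absolute scores above ``activity_fraction``
    of the component maximum.
    """
    check_is_fitted(model, "cell_scores_")
    flagged = []
    scores = np.abs(model.cell_scores_)
    for k in range(scores.shape[1]):
        s = np.sort(scores[:, k])[::-1]
        if s[0] == 0:
            continue
        if len(s) > 1 and s[1] > 0 and s[0] / s[1] > dominance_ratio:
            flagged.append(k)
            continue
        if (scores[:, k] > activity_fraction * s[0]).sum() < min_cells:
            flagged.append(k)
    return flagged


def flag_technical_components(
    model: SDA,
    batch_labels: Sequence,
    strain_labels: Sequence,
    gene_classes: Sequence | None = None,
    effect_size: float = 1.0,
    top_n: int = 20,
    technical_classes: frozenset = frozenset({"ribosomal", "pseudogene"}),
) -> dict[int, list[str]]:
    """Flag batch-effect and housekeeping-artifact components.

    A component is 'batch' when two batches of the same strain have mean
    cell scores differing by more than ``effect_size`` pooled standard
    deviations (Cohen's d), and 'gene-class' when a majority of its top
    ``top_n`` genes by absolute loading fall in ``technical_classes``.
    """
    check_is_fitted(model, "cell_scores_")
    batch = np.asarray(batch_labels)
    strain = np.asarray(strain_labels)
    if len(batch) != model.cell_scores_.shape[0]:
        raise ValueError("label length mismatch")
    flags: dict[int, list[str]] = {}

    multi_batch = False
    for s in np.unique(strain):
        if len(np.unique(batch[strain == s])) > 1:
            multi_batch = True
    if not multi_batch:
        warnings.warn("no strain has multiple batches; batch rule skipped",
                      stacklevel=2)

    for k in range(model.cell_scores_.shape[1]):
        sc = model.cell_scores_[:, k]
        reasons = []
        if multi_batch:
            for s in np.unique(strain):
                mask = strain == s
                bs = np.unique(batch[mask])
                if len(bs) < 2:
                    continue
                means = [sc[mask & (batch == b)].mean() for b in bs]
                pooled = sc[mask].std(ddof=1)
                if pooled > 0 and (max(means) - min(means)) / pooled > effect_size:
                    reasons.append("batch")
                    break
        if gene_classes is not None:
            classes = np.asarray(gene_classes)
            top = np.argsort(-np.abs(model.loadings_[k]))[:top_n]
            frac = np.isin(classes[top], list(technical_classes)).mean()
            if frac > 0.5:
                reasons.append("gene-class")
        if reasons:
            flags[k] = reasons
    return flags
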