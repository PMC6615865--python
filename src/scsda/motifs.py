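"""Promoter motif discovery with a collapsed ZOOPS Gibbs sampler.

The model is zero-or-one occurrence per sequence (ZOOPS): each promoter
either contains one motif instance at an unknown position or none.  Motif
columns carry symmetric Dirichlet priors that are integrated out, so the
sampler operates on the per-sequence occurrence states alone (collapsed
Gibbs); the background is a fixed 0-order model estimated from the input.
Discovery seeds from random 6-mers drawn from the data and may extend the
motif by informative flanking columns.  A fixed-PWM expectation-maximization
scan converts any PWM into per-sequence presence probabilities, which are
then correlated with component gene loadings.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PWM",
    "PromoterSet",
    "MotifFit",
    "extract_promoter_windows",
    "filter_masked",
    "GibbsMotifSampler",
    "scan_fixed_pwm",
    "motif_loading_association",
    "cpg_pseudo_motif",
    "pwm_summaries",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

WINDOW_SPECS = (
    "up150", "up200", "up250",
    "down150", "down200", "down250",
    "cent200", "cent300", "cent400", "cent800",
)


@dataclass
class PWM:
    """Position weight matrix over A/C/G/T.

    ``probs`` has one row per motif position; each row is a probability
    distribution over the four bases.
    """

    probs: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probs must be (L, 4)")
        if np.any(self.probs < 0):
            raise ValueError("PWM probabilities must be nonnegative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.5) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(counts / counts.sum(axis=1, keepdims=True), pseudocount)

    @classmethod
    def from_consensus(cls, consensus: str, match: float = 1.0) -> "PWM":
        """PWM putting probability ``match`` on each consensus base."""
        off = (1.0 - match) / 3.0
        probs = np.full((len(consensus), 4), off)
        for i, b in enumerate(consensus.upper()):
            probs[i, _CODE[b]] = match
        return cls(probs)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))


@dataclass
class PromoterSet:
    """Promoter windows: one uppercase A/C/G/T/N sequence per gene."""

    gene_ids: list[str]
    sequences: list[str]
    window: str
    masked_fraction: np.ndarray
    truncated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sequences = [s.upper() for s in self.sequences]
        self.masked_fraction = np.asarray(self.masked_fraction, dtype=float)
        if len(self.gene_ids) != len(self.sequences):
            raise ValueError("gene_ids and sequences length mismatch")

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class MotifFit:
    """Result of one discovery chain: the PWM, ZOOPS presence prior, per-
    sequence presence posteriors/positions, and the motif-proportion trace."""

    pwm: PWM
    presence_prior: float
    presence_posterior: np.ndarray
    positions: np.ndarray            # sampled occurrence start, -1 = absent
    trace: np.ndarray                # motif proportion per iteration
    log_likelihood: float            # ZOOPS term, background factored out
    converged: bool
    seed: int
    width: int = field(init=False)

    def __post_init__(self) -> None:
        self.width = self.pwm.length


# ---------------------------------------------------------------------------
# promoter windows


def _parse_window(spec: str) -> tuple[str, int]:
    m = re.fullmatch(r"(up|down|cent)(\d+)", spec)
    if not m:
        raise ValueError(
            f"unknown window spec {spec!r}; expected one of {WINDOW_SPECS}"
        )
    return m.group(1), int(m.group(2))


def _contig_seq(genome: Mapping[str, object], chrom: str, start: int, end: int) -> tuple[str, bool]:
    """Fetch [start, end) clamped to the contig; returns (seq, truncated)."""
    record = genome[chrom]
    clen = len(record)
    lo, hi = max(start, 0), min(end, clen)
    truncated = lo != start or hi != end
    if lo >= hi:
        return "", True
    piece = record[lo:hi]
    seq = piece if isinstance(piece, str) else str(piece)
    return seq, truncated


def extract_promoter_windows(
    tss_table: pd.DataFrame | str,
    genome: Mapping[str, object],
    window_spec: str,
) -> PromoterSet:
    """Cut promoter windows around transcription start sites.

    ``tss_table`` is BED-like (chrom, start, end, gene, score, strand;
    0-based half-open).  The TSS is ``start`` on '+' and ``end``-1 on '-'.
    Windows are half-open: upstream-w is the w bases 5' of the TSS,
    downstream-w the w bases starting at the TSS, centered-w is split
    symmetrically.  Minus-strand windows are reverse-complemented so the
    returned sequence always reads 5'→3' along the gene.  Windows running
    off a contig end are truncated and flagged.
    """
    kind, w = _parse_window(window_spec)
    if isinstance(tss_table, str):
        tss_table = pd.read_csv(
            tss_table, sep="\t", header=None,
            names=["chrom", "start", "end", "gene", "score", "strand"],
        )
    gene_ids, seqs, masked, trunc = [], [], [], []
    for row in tss_table.itertuples(index=False):
        if row.strand == "+":
            tss = int(row.start)
            if kind == "up":
                lo, hi = tss - w, tss
            elif kind == "down":
                lo, hi = tss, tss + w
            else:
                lo, hi = tss - w // 2, tss + w // 2
        elif row.strand == "-":
            tss = int(row.end) - 1
            if kind == "up":
                lo, hi = tss + 1, tss + 1 + w
            elif kind == "down":
                lo, hi = tss + 1 - w, tss + 1
            else:
                lo, hi = tss + 1 - w // 2, tss + 1 + w // 2
        else:
            raise ValueError(f"invalid strand {row.strand!r} for {row.gene}")
        seq, was_trunc = _contig_seq(genome, row.chrom, lo, hi)
        if row.strand == "-":
            seq = seq.translate(_RC)[::-1]
        if was_trunc:
            warnings.warn(
                f"window {window_spec} for {row.gene} truncated at contig edge",
                stacklevel=2,
            )
        n_masked = sum(1 for ch in seq if ch == "N" or ch.islower())
        gene_ids.append(str(row.gene))
        seqs.append(seq)
        masked.append(n_masked / len(seq) if seq else 1.0)
        trunc.append(was_trunc)
    return PromoterSet(
        gene_ids=gene_ids,
        sequences=seqs,
        window=window_spec,
        masked_fraction=np.array(masked),
        truncated=np.array(trunc, dtype=bool),
    )


def filter_masked(seqs: PromoterSet, max_masked: float = 0.10) -> PromoterSet:
    """Drop sequences with a masked-base (N or soft-masked) fraction
    strictly greater than ``max_masked``."""
    keep = seqs.masked_fraction <= max_masked
    if not keep.any():
        raise ValueError("all sequences exceed the masked-base threshold")
    return PromoterSet(
        gene_ids=[g for g, k in zip(seqs.gene_ids, keep) if k],
        sequences=[s for s, k in zip(seqs.sequences, keep) if k],
        window=seqs.window,
        masked_fraction=seqs.masked_fraction[keep],
        truncated=None if seqs.truncated is None else seqs.truncated[keep],
    )


# ---------------------------------------------------------------------------
# collapsed ZOOPS Gibbs machinery


def _encode(sequences: Sequence[str]) -> list[np.ndarray]:
    out = []
    for s in sequences:
        codes = np.full(len(s), 4, dtype=np.int64)
        for b, c in _CODE.items():
            codes[np.frombuffer(s.encode(), dtype=np.uint8) == ord(b)] = c
        out.append(codes)
    return out


def _windows(codes: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """All length-w windows of one sequence and a validity mask (no N)."""
    if len(codes) < w:
        return np.empty((0, w), dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, w)
    return win, (win < 4).all(axis=1)


def estimate_background(sequences: Sequence[str]) -> np.ndarray:
    """0-order base frequencies of the input set (N excluded)."""
    counts = np.zeros(4)
    for codes in _encode(sequences):
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no unmasked bases in input")
    return counts / counts.sum()


class _ChainState:
    """Occurrence assignments and collapsed column counts for one chain."""

    def __init__(self, seqs: list[np.ndarray], width: int, pseudocount: float,
                 log_bg: np.ndarray):
        self.seqs = seqs
        self.width = width
        self.alpha = pseudocount
        self.log_bg = log_bg
        self.z = np.full(len(seqs), -1, dtype=np.int64)
        self.counts = np.zeros((width, 4))
        self.n_sites = 0
        self.win: list[np.ndarray] = []
        self.valid: list[np.ndarray] = []
        self._build_windows()

    def _build_windows(self) -> None:
        self.win, self.valid = [], []
        for codes in self.seqs:
            w, v = _windows(codes, self.width)
            self.win.append(w)
            self.valid.append(v)

    def site(self, i: int) -> np.ndarray:
        return self.seqs[i][self.z[i] : self.z[i] + self.width]

    def remove(self, i: int) -> None:
        if self.z[i] >= 0:
            self.counts[np.arange(self.width), self.site(i)] -= 1.0
            self.n_sites -= 1
            self.z[i] = -1

    def add(self, i: int, pos: int) -> None:
        self.z[i] = pos
        if pos >= 0:
            self.counts[np.arange(self.width), self.site(i)] += 1.0
            self.n_sites += 1

    def log_odds(self) -> np.ndarray:
        """Predictive motif-vs-background log odds per column/base."""
        pred = np.log(self.counts + self.alpha) - np.log(
            self.n_sites + 4.0 * self.alpha
        )
        return pred - self.log_bg[None, :]

    def position_scores(self, i: int, delta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-position log odds for sequence i and valid-position indices."""
        win, valid = self.win[i], self.valid[i]
        if win.shape[0] == 0 or not valid.any():
            return np.empty(0), np.empty(0, dtype=np.int64)
        idx = np.where(valid)[0]
        s = delta[np.arange(self.width)[None, :], win[idx]].sum(axis=1)
        return s, idx

    def sweep(self, pi: float, rng: np.random.Generator,
              delta_override: np.ndarray | None = None) -> None:
        """One Gibbs sweep over all sequences."""
        log_pi, log_not = np.log(pi), np.log1p(-pi)
        for i in range(len(self.seqs)):
            self.remove(i)
            delta = self.log_odds() if delta_override is None else delta_override
            s, idx = self.position_scores(i, delta)
            if s.size == 0:
                continue
            logw = np.concatenate(
                [[log_not], log_pi - np.log(s.size) + s]
            )
            logw -= logsumexp(logw)
            choice = rng.choice(logw.size, p=np.exp(logw))
            self.add(i, -1 if choice == 0 else int(idx[choice - 1]))

    def zoops_log_likelihood(self, pi: float) -> float:
        """Σ_i log[(1-π) + (π/P_i)·Σ_p odds_p] under the current predictive
        PWM; the whole-sequence background factor is omitted (common to all
        models)."""
        delta = self.log_odds()
        total = 0.0
        for i in range(len(self.seqs)):
            s, _ = self.position_scores(i, delta)
            if s.size == 0:
                total += np.log1p(-pi)
                continue
            total += logsumexp(
                np.concatenate([[np.log1p(-pi)], np.log(pi) - np.log(s.size) + s])
            )
        return float(total)

    def presence_posterior(self, pi: float) -> np.ndarray:
        """Rao-Blackwellized per-sequence presence probability under the
        current predictive PWM and prior."""
        delta = self.log_odds()
        post = np.zeros(len(self.seqs))
        for i in range(len(self.seqs)):
            s, _ = self.position_scores(i, delta)
            if s.size == 0:
                continue
            lp = np.log(pi) - np.log(s.size) + logsumexp(s)
            post[i] = 1.0 / (1.0 + np.exp(np.log1p(-pi) - lp))
        return post


def collapsed_gibbs_chain(
    sequences: Sequence[str],
    width: int,
    n_sweeps: int,
    presence_prior: float,
    pseudocount: float = 0.5,
    seed: int = 0,
    background: np.ndarray | None = None,
    record_states: bool = False,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Run a plain collapsed ZOOPS chain with fixed prior and width.

    Targets the exact posterior over occurrence configurations with the
    Dirichlet-multinomial motif marginal and a fixed 0-order background.
    Returns the motif-proportion trace and (optionally) the z state after
    every sweep.  This is the kernel the full sampler builds on and is used
    directly for exactness checks against brute-force enumeration.
    """
    rng = np.random.default_rng(seed)
    seqs = _encode(sequences)
    bg = estimate_background(sequences) if background is None else np.asarray(background)
    state = _ChainState(seqs, width, pseudocount, np.log(bg))
    trace = np.zeros(n_sweeps)
    states: list[np.ndarray] = []
    for it in range(n_sweeps):
        state.sweep(presence_prior, rng)
        trace[it] = state.n_sites / len(seqs)
        if record_states:
            states.append(state.z.copy())
    return trace, states


def _column_ic(counts: np.ndarray, alpha: float) -> float:
    p = (counts + alpha) / (counts.sum() + 4 * alpha)
    return float(2.0 + (p * np.log2(p)).sum())


class GibbsMotifSampler(BaseEstimator):
    """De novo ZOOPS motif discovery by collapsed Gibbs sampling.

    Each restart seeds from a random 6-mer drawn from the input sequences,
    samples occurrence states until the motif proportion stabilizes
    (standard deviation of the trailing trace below ``conv_sd``) or
    ``max_iter`` sweeps, optionally extends the motif by informative
    flanking columns up to ``max_width``, and the best restart by ZOOPS
    likelihood is kept.

    Parameters
    ----------
    seed_length : initial motif width (6-mer seeds).
    n_restarts : independent chains from different random seed motifs.
    max_iter : Gibbs sweeps per restart.
    conv_sd : convergence threshold on the SD of the motif-proportion trace.
    conv_window : trailing window length for the SD test.
    pseudocount : symmetric Dirichlet pseudocount on motif columns.
    max_width, extend, ic_min : flanking-column extension control; a flank
        is added while its information content exceeds ``ic_min`` bits.
    update_prior : re-estimate the ZOOPS presence prior each sweep
        (stochastic EM); fix it for exact-posterior work.
    """

    def __init__(
        self,
        seed_length: int = 6,
        n_restarts: int = 9,
        max_iter: int = 1000,
        conv_sd: float = 0.05,
        conv_window: int = 50,
        pseudocount: float = 0.5,
        max_width: int = 12,
        extend: bool = True,
        ic_min: float = 0.25,
        presence_prior: float = 0.5,
        update_prior: bool = True,
        random_state: int | None = 0,
    ):
        self.seed_length = seed_length
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.conv_sd = conv_sd
        self.conv_window = conv_window
        self.pseudocount = pseudocount
        self.max_width = max_width
        self.extend = extend
        self.ic_min = ic_min
        self.presence_prior = presence_prior
        self.update_prior = update_prior
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _run_until_converged(self, state: _ChainState, pi: float,
                             rng: np.random.Generator, budget: int,
                             trace: list[float],
                             delta0: np.ndarray | None) -> tuple[float, bool]:
        converged = False
        for it in range(budget):
            state.sweep(pi, rng, delta_override=delta0 if it == 0 else None)
            prop = state.n_sites / len(state.seqs)
            trace.append(prop)
            if self.update_prior:
                pi = float(np.clip(prop, 1e-3, 1 - 1e-3))
            if len(trace) >= self.conv_window:
                if np.std(trace[-self.conv_window:]) < self.conv_sd:
                    converged = True
                    break
        return pi, converged

    def _try_extend(self, state: _ChainState) -> _ChainState | None:
        """Add the more informative qualifying flank column, if any."""
        if state.width >= self.max_width or state.n_sites < 5:
            return None
        left = np.zeros(4)
        right = np.zeros(4)
        n_left = n_right = 0
        for i, z in enumerate(state.z):
            if z > 0:
                b = state.seqs[i][z - 1]
                if b < 4:
                    left[b] += 1
                    n_left += 1
            if 0 <= z <= len(state.seqs[i]) - state.width - 1:
                b = state.seqs[i][z + state.width]
                if b < 4:
                    right[b] += 1
                    n_right += 1
        cands = []
        if n_left >= max(5, state.n_sites // 2):
            cands.append(("L", _column_ic(left, self.pseudocount)))
        if n_right >= max(5, state.n_sites // 2):
            cands.append(("R", _column_ic(right, self.pseudocount)))
        cands = [c for c in cands if c[1] > self.ic_min]
        if not cands:
            return None
        side = max(cands, key=lambda c: c[1])[0]
        new = _ChainState(state.seqs, state.width + 1, self.alpha_, state.log_bg)
        for i, z in enumerate(state.z):
            if z < 0:
                continue
            pos = z - 1 if side == "L" else z
            if 0 <= pos <= len(state.seqs[i]) - new.width and (
                state.seqs[i][pos : pos + new.width] < 4
            ).all():
                new.add(i, pos)
        return new

    def _one_restart(self, sequences: Sequence[str], seqs: list[np.ndarray],
                     log_bg: np.ndarray, seed: int) -> MotifFit:
        rng = np.random.default_rng(seed)
        w = self.seed_length
        # random 6-mer seed from the data -> soft initial PWM
        lengths = np.array([len(s) for s in seqs])
        ok = np.where(lengths >= w)[0]
        for _ in range(100):
            i = int(rng.choice(ok))
            p = int(rng.integers(0, lengths[i] - w + 1))
            kmer = seqs[i][p : p + w]
            if (kmer < 4).all():
                break
        seed_pwm = np.full((w, 4), 0.1)
        seed_pwm[np.arange(w), kmer] = 0.7
        delta0 = np.log(seed_pwm) - log_bg[None, :]

        state = _ChainState(seqs, w, self.alpha_, log_bg)
        pi = self.presence_prior
        trace: list[float] = []
        pi, converged = self._run_until_converged(
            state, pi, rng, self.max_iter, trace, delta0
        )
        if self.extend:
            budget = self.max_iter // 2
            while budget > self.conv_window:
                new = self._try_extend(state)
                if new is None:
                    break
                state = new
                pi, converged = self._run_until_converged(
                    state, pi, rng, budget, trace, None
                )
                budget //= 2
        pwm = PWM.from_counts(state.counts, self.alpha_)
        return MotifFit(
            pwm=pwm,
            presence_prior=pi,
            presence_posterior=state.presence_posterior(pi),
            positions=state.z.copy(),
            trace=np.asarray(trace),
            log_likelihood=state.zoops_log_likelihood(pi),
            converged=converged,
            seed=seed,
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X: PromoterSet | Sequence[str], y=None) -> "GibbsMotifSampler":
        sequences = X.sequences if isinstance(X, PromoterSet) else list(X)
        if len(sequences) < 10:
            raise ValueError("need at least 10 sequences")
        if min(len(s) for s in sequences) < self.seed_length:
            raise ValueError("all sequences must be at least seed_length long")
        self.alpha_ = float(self.pseudocount)
        seqs = _encode(sequences)
        self.background_ = estimate_background(sequences)
        log_bg = np.log(self.background_)
        ss = np.random.SeedSequence(self.random_state)
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                       ss.spawn(self.n_restarts)]
        fits: list[MotifFit] = []
        for cs in child_seeds:
            try:
                fits.append(self._one_restart(sequences, seqs, log_bg, cs))
            except FloatingPointError:  # pragma: no cover - defensive
                warnings.warn(f"restart with seed {cs} aborted", stacklevel=2)
        if not fits:
            raise RuntimeError("all restarts failed")
        self.restarts_ = fits
        best = max(fits, key=lambda f: f.log_likelihood)
        self.best_fit_ = best
        self.pwm_ = best.pwm
        self.presence_prior_ = best.presence_prior
        self.presence_posterior_ = best.presence_posterior
        self.positions_ = best.positions
        self.trace_ = best.trace
        self.converged_ = best.converged
        return self

    def transform(self, X: PromoterSet | Sequence[str]) -> np.ndarray:
        """Presence probabilities for new sequences under the fitted PWM."""
        check_is_fitted(self, "pwm_")
        return scan_fixed_pwm(X, self.pwm_, presence_prior=self.presence_prior_)


def scan_fixed_pwm(
    seqs: PromoterSet | Sequence[str],
    pwm: PWM,
    n_iter: int = 20,
    presence_prior: float = 0.5,
    background: np.ndarray | None = None,
    return_trace: bool = False,
):
    """Per-sequence motif presence probability with the PWM held fixed.

    EM over the ZOOPS presence prior: the E-step computes each sequence's
    presence posterior under the fixed PWM, the M-step sets the prior to the
    mean posterior; run for ``n_iter`` iterations.  Deterministic.
    """
    sequences = seqs.sequences if isinstance(seqs, PromoterSet) else list(seqs)
    codes = _encode(sequences)
    if min(len(c) for c in codes) < pwm.length:
        raise ValueError("PWM longer than the shortest sequence")
    bg = estimate_background(sequences) if background is None else np.asarray(background)
    delta = np.log(np.clip(pwm.probs, 1e-12, None)) - np.log(bg)[None, :]
    w = pwm.length
    # precompute per-sequence position log odds
    seq_scores = []
    for c in codes:
        win, valid = _windows(c, w)
        if win.shape[0] == 0 or not valid.any():
            seq_scores.append(None)
            continue
        s = delta[np.arange(w)[None, :], win[valid]].sum(axis=1)
        seq_scores.append(logsumexp(s) - np.log(s.size))
    pi = float(presence_prior)
    trace = []
    post = np.zeros(len(sequences))
    for _ in range(n_iter):
        for i, ls in enumerate(seq_scores):
            if ls is None:
                post[i] = 0.0
            else:
                post[i] = 1.0 / (1.0 + np.exp(np.log1p(-pi) - np.log(pi) - ls))
        pi = float(np.clip(post.mean(), 1e-6, 1 - 1e-6))
        trace.append(pi)
    if return_trace:
        return post, np.asarray(trace)
    return post


def motif_loading_association(
    gene_loadings: np.ndarray, motif_probs: np.ndarray
) -> tuple[float, float, float]:
    """Correlation test between one component side's gene loadings and
    per-gene motif presence probabilities.

    Returns (Pearson r, Fisher-transform Z, two-sided p).  Z is
    atanh(r)·sqrt(n-3), standard normal under independence.
    """
    x = np.asarray(gene_loadings, dtype=float)
    y = np.asarray(motif_probs, dtype=float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 paired genes")
    if np.std(x) == 0 or np.std(y) == 0:
        return (np.nan, np.nan, np.nan)
    r = float(np.corrcoef(x, y)[0, 1])
    r_c = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    z = float(np.arctanh(r_c) * np.sqrt(n - 3))
    p = float(2.0 * norm.sf(abs(z)))
    return (r, z, p)


def cpg_pseudo_motif(seqs: PromoterSet | Sequence[str]) -> np.ndarray:
    """Count of CpG dinucleotides per sequence (a pseudo-motif: CpG-island
    promoters score high without any PWM)."""
    sequences = seqs.sequences if isinstance(seqs, PromoterSet) else list(seqs)
    return np.array([s.upper().count("CG") for s in sequences])


def pwm_summaries(pwm: PWM, cpg_flag_threshold: float = 0.3) -> tuple[float, float, bool]:
    """Total information content (bits) and the maximum probability of a CpG
    at any adjacent position pair, with a flag at the stated threshold."""
    p = np.clip(pwm.probs, 1e-300, None)
    ic = float(np.sum(2.0 + (pwm.probs * np.log2(p)).sum(axis=1)))
    if pwm.length < 2:
        cpg = 0.0
    else:
        cpg = float(np.max(pwm.probs[:-1, _CODE["C"]] * pwm.probs[1:, _CODE["G"]]))
    return ic, cpg, cpg > cpg_flag_threshold
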