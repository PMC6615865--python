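# Methods

`scsda` reimplements, as a tested pipeline, a single-cell analysis workflow
for spermatogenesis Drop-seq data: quality control and normalization of a
UMI count matrix, sparse Bayesian factor decomposition with a
spike-and-slab prior (SDA), model-based imputation evaluated by
held-out-read cross-validation, principal-curve pseudotime over a 2-D
embedding of cell scores, component annotation with exact enrichment
statistics, and de novo promoter-motif discovery by collapsed ZOOPS Gibbs
sampling.  This note records the models, the parameters that matter, the
synthetic data the package is validated on, and the design choices made
where the design was genuinely open.

## The factor model and its inference

The decomposition models the normalized expression matrix `X` (cells ×
genes) as

    X_cg = Σ_k A_ck B_kg + ε_cg,     ε_cg ~ N(0, 1/λ_g)

with standard-normal cell scores `A_ck`, and gene loadings under a
spike-and-slab prior: `B_kg = S_kg · W_kg`, `S_kg ~ Bernoulli(ρ_k)`,
`W_kg ~ N(0, 1/β_k)`.  Conjugate hyperpriors close the model:
`ρ_k ~ Beta(1, 1)`, `β_k, λ_g ~ Gamma(10⁻³, 10⁻³)`.  The posterior
inclusion probability `PIP_kg = q(S_kg = 1)` quantifies how confidently a
gene loads on a component; loadings with PIP below 0.5 are zeroed by
`sparsify`.

Inference is mean-field variational coordinate ascent.  Every update —
one component's loadings across genes (the joint spike/slab block), one
component's scores across cells, then the conjugate ρ/β/λ blocks — is the
exact conditional maximizer of the evidence lower bound (ELBO), so the
ELBO is non-decreasing; the fit asserts this at every sweep (relative
tolerance 10⁻⁶), which doubles as a continuous check of the update
algebra.  An independent Monte-Carlo estimate of `E_q[log p − log q]` on a
tiny instance verifies the analytic bound in the test suite.

Two initialization details matter and are deliberate:

- **Precision posteriors start at E = 1 with O(1) shape.**  Starting the
  Gamma posteriors at the diffuse prior shape makes `E[log β] ≈ −10³`,
  which collapses every PIP into the spike on the first sweep.
- **Warm-up (default 25 sweeps, 50 in the benchmarks).**  PIPs are held at
  0.5 and ρ/β are not updated while scores and slab means alternate.
  Without this, the PIP factor sits inside the score↔loading feedback
  loop: a component that has not yet found structure has small PIPs, hence
  a loop gain below one, and decays to an absorbing zero state before it
  can grow.  Warm-up is still exact coordinate ascent on the same bound
  (a subset of blocks is simply not updated), so monotonicity is
  preserved; convergence checks are gated to the post-warm-up phase.

Within a sweep, loadings are updated before scores: scores are initialized
randomly and loadings at zero, so the reverse order would overwrite the
random initialization with the prior mean (exactly zero) before the
loadings ever saw data.

Coordinate ascent has local optima in which two planted components mix.
`fit_sda(..., n_restarts=n)` fits from several score initializations and
keeps the run with the highest final ELBO; in the benchmarks the bound
reliably ranks the unmixed solution first.

Convergence: relative ELBO change below `elbo_tol` (10⁻⁶) *and* the
fraction of PIPs crossing 0.5 between sweeps below `pip_change_tol`
(10⁻⁴).  Defaults K = 50 components and 10,000 iterations mirror the
workflow the package reimplements; the synthetic benchmarks use K = 8–12
and converge within a few hundred sweeps.

## QC and normalization

Cells with fewer than 200 UMIs or fewer than 50 expressed genes are
removed, optionally together with cells more than one standard deviation
below their batch's mean on either statistic (applied per batch; globally
with a warning when batch labels are missing).  An elevated normalized
mitochondrial-rRNA marker (threshold 2 on the unit-variance scale) removes
presumptively apoptotic cells; the threshold is applied to the marker
normalized by `count / sqrt(library size)` scaled to unit variance, since
the workflow's published description does not pin the scale.  All rules
are evaluated on the original matrix in one pass, so the filter is
idempotent by construction.  Genes in the lower third of mean expression
are dropped (count = ⌊G/3⌋, ties broken by stable gene order).

Normalization divides each cell by the square root of its total UMI count
— the reading of "square root transformation of total transcript counts"
consistent with a subsequent per-gene step; the alternative (square root
of each entry) is available via `cell_transform="sqrt_counts"` — then
divides each gene by its sample standard deviation *without centering*
(zeros must stay zeros: the reference matrix is 93.8% sparse after
normalization, which is impossible with mean-centering), and caps values
at 10.

## Imputation evaluation (RPAC)

Reads are assigned to a test set with probability 0.2; because read
assignment is exchangeable this is exact per-entry binomial thinning, and
`train + test` reproduces the source matrix entry-wise.  A predictor is
scored per cell by the rank prediction accuracy curve: genes sorted by
predicted expression (high to low), cumulative fraction of the cell's test
reads against cumulative rank fraction, integrated by the trapezoidal rule
with endpoints (0,0) and (1,1).  Tied predictions contribute the average
of their test reads per tied rank — the expected curve under a random tie
order, hence deterministic and permutation-invariant (this matters for
the Unimputed baseline, whose many zero counts are all tied).  Cells with
no test reads are skipped and logged.  A uniformly random predictor
averages AUC 0.5; the oracle (true simulated rates) bounds all others from
above on synthetic data.  Negative imputed values are ranked as-is.
Built-in predictors: `Unimputed` (training counts scaled by cell totals;
empty training rows fall back to the mean-cell ranking), `MeanCell`
(per-gene training sums, identical for every cell), and the factorization
product `A·B` with optional component exclusion.  External predictors
plug in as matrices; the baseline methods themselves (NNMF, ICA, PCA,
MAGIC) are out of scope.

## Pseudotime

Cells are embedded in 2-D by t-SNE on the component-score matrix
(perplexity 50, 1000 iterations, random initialization, no PCA step),
after dropping flagged technical/batch components and excluding cells that
trip any somatic score rule (|score| above a per-component threshold, or
mitochondrial marker above 3); excluded cells are assigned pseudotime
post hoc by the same projection rule, flagged.

A principal curve is fitted by alternating projection (exact
nearest-point projection onto the discretized curve, ties resolved to the
lower arc length) and smoothing (per-coordinate least-squares cubic
regression splines with `df` degrees of freedom = `df − 4` interior knots
at arc-length quantiles), over the schedule df = 4…9, each stage
warm-started from the previous.  The inner loop reverts a step that would
increase the total squared projection distance, so the recorded trace is
non-increasing within each df stage (a stage change re-knots the spline
and may raise it).  The curve is discretized at `max(100, n/10)` points.

One robustness problem is intrinsic to this construction: a 2-D embedding
of a one-dimensional trajectory frequently places the trajectory's ends
near each other, and a curve fitted through such a shape can fold across
the gap — the folded curve often has *lower* projection error, so no
fit statistic can reject it.  The pipeline entry point
`trajectory_pseudotime` therefore (i) initializes the arc parameter from
a k-nearest-neighbor-graph geodesic ordering of the embedding (a global
ordering that cannot fold), (ii) repeats the embedding under several
t-SNE seeds, and (iii) selects among all (seed, df-stage) candidates by
the absolute Spearman agreement between the candidate's arc-length
positions and the geodesic ordering of its own embedding.  The selection
is purely internal; no ground truth enters it.  Orientation and origin of
the arc length are arbitrary; `orient_pseudotime` fixes them against a
configured early-marker cell set, and all downstream contracts are
rank-based.

Components are placed in time by the |score|-weighted mean pseudotime of
cells with |score| > 2.  The X:autosome ratio divides each cell's summed
imputed X-gene expression by its autosomal sum (X, Y, MT excluded from
the denominator), optionally smoothed by a centered rolling mean along
pseudotime.

## Enrichment statistics

`fisher_2x2` reports the sample odds ratio `ad/bc`, the conditional
maximum-likelihood odds ratio, and the two-sided minimum-likelihood exact
p.  Published analyses are ambiguous about which odds-ratio estimator
they print, so both are reported.  The conditional MLE solves the
noncentral-hypergeometric score equation with the root found on an
inverse scale at the conventional tolerance — the procedure of the
standard exact-test implementation — so odds ratios published by that
tool reproduce to their printed precision; a root solved to machine
precision differs in the third significant digit for extreme tables.  The test suite checks the p-value against
brute-force enumeration over fixed margins for tables up to N = 30.
Gene-set enrichment tests each component's top-n genes per loading side
against each set within the analysis universe, with Benjamini–Hochberg or
Bonferroni control; one-sided components (cell-score range ratio > 5)
have their minor side skipped.  Strain enrichment compares the strain
composition of a component's strongly loading cells (|score| > 2, the
threshold used for temporal ordering; configurable) with the overall cell
fractions.

## Motif discovery

The ZOOPS model gives each promoter at most one motif occurrence.  Motif
columns carry symmetric Dirichlet(0.5) pseudocounts that are integrated
out, so the sampler is a collapsed Gibbs chain over per-sequence
occurrence states; the background is a fixed 0-order model estimated from
the input set.  On a 3-sequence toy instance the chain's empirical
occurrence marginals match brute-force enumeration of the collapsed
posterior within 2% (tested), confirming the kernel targets the exact
posterior.  Discovery runs 9 restarts from random 6-mers sampled from the
data, up to 1000 sweeps each or convergence (SD of the motif-proportion
trace over a trailing window of 50 sweeps below 0.05 — the window length
is this package's choice), re-estimating the presence prior each sweep
(stochastic EM); the best restart by ZOOPS likelihood wins.  After
convergence the motif may grow by flanking columns whose information
content exceeds 0.25 bits, up to width 12 — the extension rule is an
explicit assumption, since the protocol being emulated does not describe
one.  Presence posteriors are Rao-Blackwellized under the final PWM.
Fixed-PWM scanning is plain EM over the presence prior (20 iterations,
deterministic).  Motif–loading association uses the Fisher-transform Z,
`atanh(r)·√(n−3)`, verified standard normal under permutation.

Promoter windows follow the 10-window scheme (150/200/250 bp upstream and
downstream, 200/300/400/800 bp centered on the TSS), half-open, with
minus-strand windows reverse-complemented; sequences with more than 10%
masked bases (N or soft-masked) are removed, boundary inclusive.

## The synthetic data

The generator emulates the statistical structure the pipeline consumes,
not the biology of raw reads.  A cell's latent rate is
`scale_c · softplus(Σ_k score_ck·loading_kg + baseline_g + batch_bg +
noise)`, where `scale_c` normalizes the cell's total softplus mass to a
log-normal library size (median ≈ 1300 UMIs), and counts are Poisson.
Gene baselines are N(−7, 3.5) on the linear-predictor scale, putting the
default 3,000 × 2,000 matrix at ≈ 87% zeros — Drop-seq-like dropout at
this gene count; the reference dataset's 93.8% sparsity arises at ~19k
genes and is not reachable at a 10× smaller gene panel without
concentrating essentially all reads on a handful of genes.

Temporal structure: each of the 8 default components is a Gaussian bump in
pseudotime `t ∈ [0, 1]`, centers evenly spaced, widths cycling through
`0.7/k·{1, 1.5, 2.2}` — wide enough that consecutive components overlap
strongly and the cell population forms a connected trajectory.  Three
strains draw `t ~ Uniform(0, arrest)` with arrest quantiles 1.0 / 0.62 /
0.45, mirroring a wild type and two progressively earlier meiotic-arrest
mutants; the earliest-arresting strain carries a pathology component
active only in its cells past 60% of its arrest point.  Batch effects are
dense mean-zero Gaussian loading vectors (SD 0.3) added per batch.  A
configurable fraction of cells (3%) is "apoptotic", with mitochondrial
gene rates boosted 12×.  X-linked genes (6%) are silenced inside a
pseudotime window (0.55–0.78, floor 0.03) with partial recovery (0.5)
afterwards, emulating meiotic sex chromosome inactivation.  Promoters are
i.i.d. background sequences with at most one planted motif occurrence per
sequence per motif, position uniform, truth recorded in BED-like form.

`recovery_benchmark_config()` defines the conditions under which factor
recovery is measured: 500 × 400, five planted separable components,
observation noise SD 0.5, a single complete-trajectory strain, baselines
N(3, 0.6) (the near-linear region of the softplus link, so planted
loadings enter the observed matrix linearly rather than
exponentially distorted), nonzero loadings with a minimum magnitude of
0.4 (so membership in a component is detectable in principle for every
support gene), and signed multi-timescale activations — component k is a
train of k+2 alternating-sign bumps — which makes the activation
functions mutually near-orthogonal and none of them collinear with the
constant mean-expression direction.  With single nonnegative bumps the
five activations sum to a near-constant, and one planted direction
becomes unidentifiable against the dense mean component that any
intercept-free factor model must devote to nonnegative data; the
benchmark would then measure an identifiability artifact rather than the
fitter.

What passing these tests does *not* show: the generator has no ambient
RNA, no doublets, no UMI collisions, no gene–gene correlation beyond the
planted components, Poisson (not over-dispersed) counts, and a single
unbranched trajectory.  Performance on real Drop-seq data depends on all
of these.

## Problem sizes

The test suite and acceptance computations run at desk scale, chosen as
the smallest sizes at which each recovery statistic is stable: factor
recovery at 500 × 400 with K = 8 and 3 restarts; the trajectory pipeline
at the default 3,000 × 2,000 with K = 12, 300 sweeps, and three t-SNE
seeds; motif recovery at 200 sequences × 200 bp with 9 restarts; RPAC
calibration over 500 cells × 2,000 genes with ~1,000 held-out reads per
cell.
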