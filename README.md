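# scsda

Sparse Bayesian factor decomposition and trajectory analysis for
single-cell spermatogenesis data.

Single-cell Drop-seq profiles of the testis capture the full continuum of
male germ cell development, but the count matrix is ~94% zeros and every
cell sits at a different point of a smooth developmental trajectory.
`scsda` addresses this with a *model-based decomposition*: instead of hard
clustering, the expression matrix is factorized into latent components
with a sparsity-inducing prior, and cells are ordered in continuous
pseudotime along a principal curve.  The package is aimed at
computational biologists analysing germ-cell (or other
single-trajectory) scRNA-seq data, and at methodologists who want a
tested, self-contained reference implementation of the workflow.

## The model

The normalized expression matrix X (cells × genes) is decomposed as

    X = A·B + E,   E_cg ~ N(0, λ_g⁻¹)

with cell scores A_ck ~ N(0, 1) and a spike-and-slab prior on each gene
loading: B_kg = S_kg·W_kg, where S_kg ~ Bernoulli(ρ_k) is a point mass at
zero (the spike) and W_kg ~ N(0, β_k⁻¹) the slab.  The posterior
inclusion probability PIP_kg = q(S_kg = 1) says how confidently gene g
participates in component k.  Inference is mean-field variational Bayes;
the evidence lower bound is non-decreasing by construction and asserted
at every sweep.

Around the decomposition the package provides:

- **`scsda.qc`** — the QC/normalization recipe the factorization expects
  (UMI/gene-count filters, per-batch 1-SD rule, lower-third gene filter,
  cell ÷ √library-size, gene ÷ SD without centering, cap at 10);
- **`scsda.imputation`** — held-out-read cross-validation: binomial read
  splitting and the rank prediction accuracy curve (RPAC), whose AUC is
  0.5 for a random predictor;
- **`scsda.pseudotime`** — t-SNE embedding of cell scores, somatic-cell
  exclusion by score thresholds, an iterative principal curve
  (df 4→9 schedule), arc-length pseudotime, component temporal ordering,
  and the X:autosome ratio that quantifies meiotic sex chromosome
  inactivation;
- **`scsda.annotation`** — exact 2×2 tests (sample and conditional-MLE
  odds ratios), gene-set/GO-style enrichment with BH or Bonferroni
  control, one-sidedness, and strain enrichment of component-loading
  cells;
- **`scsda.motifs`** — de novo promoter-motif discovery with a collapsed
  ZOOPS Gibbs sampler (9 restarts from random 6-mer seeds), fixed-PWM
  presence scanning, motif–loading correlation tests, and the CpG
  pseudo-motif;
- **`scsda.datasets`** — a synthetic-data generator with planted ground
  truth (overlapping temporal components, strain-specific meiotic arrest,
  batch effects, apoptotic cells, X silencing, planted promoter motifs)
  so every stage is testable without downloads.

## Worked example

```python
import numpy as np
import scsda
from scsda import annotation, qc, pseudotime as pt
from scsda.sda import flag_technical_components

# a testis-like dataset with planted truth: 3,000 cells x 2,000 genes,
# three strains (WT and two meiotic-arrest mutants), batch effects
truth = scsda.simulate_true_model(seed=1)
data = scsda.simulate_counts(truth, seed=2)

norm = qc.normalize(qc.filter_genes(qc.filter_cells(data.counts)))
print(norm.shape)
# (3000, 1334)

model = scsda.fit_sda(norm, k=12, max_iter=300, seed=0, warmup_iters=50)
print(len(model.elbo_trace_), float(model.pip_.mean().round(3)))
# 299 0.219

# flag batch/housekeeping components, exclude pathological cells
# (components private to a minority strain), then order cells in time
gene_classes = np.where(norm.gene_meta["mitochondrial"], "mito",
                        norm.gene_meta["gene_class"])
tech = flag_technical_components(
    model, norm.cell_meta["batch"], norm.cell_meta["strain"], gene_classes,
    technical_classes=frozenset({"ribosomal", "pseudogene", "mito"}),
)
print(tech)
# {8: ['batch']}

f, p, _ = annotation.strain_enrichment(model.cell_scores_,
                                       norm.cell_meta["strain"])
rules = [(k, 2.0) for k in range(12)
         if f.loc[k].max() >= 0.95 and p[f.loc[k].idxmax()] < 1 / p.size]
germ = ~pt.exclude_somatic(model.cell_scores_, rules)
print(rules, int((~germ).sum()))
# [(7, 2.0)] 310

traj = pt.trajectory_pseudotime(model.cell_scores_[germ],
                                excluded_components=sorted(tech),
                                seeds=(0, 1, 2))
print(traj.df, round(traj.agreement, 3))
# 4 0.969
```

`norm.shape` is the post-QC matrix (the lower third of genes dropped).
The mean PIP of ~0.22 says the fitted loadings are sparse: roughly a
fifth of (component, gene) pairs are credibly nonzero.  The flagging step
identifies the planted batch-effect component (8), and the
strain-enrichment rule isolates the planted pathology component (7),
whose 310 strongly loading mutant cells are excluded from curve fitting.
`traj.agreement` is the internal consistency score of the chosen
principal-curve run (Spearman agreement between arc-length pseudotime
and the embedding's graph-geodesic ordering); values near 1 indicate an
unfolded, well-ordered trajectory.  On this dataset the recovered
pseudotime correlates with the planted developmental time at
|Spearman ρ| ≈ 0.94, and the mutant strains' pseudotime distributions
truncate in the planted arrest order (median/90th-percentile pseudotime
WT 114/169 > MutLate 81/121 > MutEarly 46/76) — these checks run in
`tests/test_acceptance.py`.

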