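"""Shared fixtures: small hand-built count matrices and the three expensive
session-scoped pipeline runs (factor recovery, trajectory, motif recovery)."""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import scsda
from scsda import imputation as imp
from scsda import qc
from scsda.datasets import recovery_benchmark_config
from scsda.motifs import PWM, GibbsMotifSampler
from scsda.sda import fit_sda


def make_counts(
    x: np.ndarray,
    strain: list | None = None,
    batch: list | None = None,
    chromosome: list | None = None,
    mito: list | None = None,
) -> ad.AnnData:
    """AnnData from a dense integer array with optional metadata."""
    x = np.asarray(x)
    n, g = x.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    if strain is not None:
        obs["strain"] = strain
    if batch is not None:
        obs["batch"] = batch
    var = pd.DataFrame(index=[f"g{j}" for j in range(g)])
    if chromosome is not None:
        var["chromosome"] = chromosome
    if mito is not None:
        var["mitochondrial"] = mito
    return ad.AnnData(X=sparse.csr_matrix(x.astype(np.int64)), obs=obs, var=var)


@pytest.fixture(scope="session")
def recovery_instance():
    """The 500x400 factor-recovery benchmark: planted truth, counts, fit."""
    cfg = recovery_benchmark_config()
    truth = scsda.simulate_true_model(cfg, seed=11)
    data = scsda.simulate_counts(truth, seed=12)
    filtered = qc.filter_cells(data.counts, min_umi=50, min_genes=20)
    nm = qc.normalize(filtered)
    model = fit_sda(
        nm, k=8, max_iter=2000, seed=0, n_restarts=3, warmup_iters=50
    )
    return {"truth": truth, "data": data, "normalized": nm, "model": model}


@pytest.fixture(scope="session")
def imputation_split(recovery_instance):
    """80/20 read split of the benchmark counts with an SDA fit on the
    training half."""
    counts = recovery_instance["data"].counts
    split = imp.split_reads(counts, p_test=0.2, seed=13)
    filtered = qc.filter_cells(split.train, min_umi=20, min_genes=10)
    nm = qc.normalize(filtered)
    model = fit_sda(nm, k=8, max_iter=1500, seed=0, warmup_iters=50)
    kept = [split.train.obs_names.get_loc(c) for c in nm.cell_ids]
    aligned = imp.SplitCounts(
        train=split.train[kept].copy(),
        test=split.test[kept].copy(),
        p_test=split.p_test,
        seed=split.seed,
    )
    return {"split": aligned, "model": model, "normalized": nm}


@pytest.fixture(scope="session")
def trajectory_run():
    """Default testis-like dataset taken through QC, SDA, component
    flagging, somatic-style exclusion and principal-curve pseudotime."""
    from scsda import annotation, pseudotime as pt
    from scsda.sda import flag_technical_components

    truth = scsda.simulate_true_model(seed=1)
    data = scsda.simulate_counts(truth, seed=2)
    filtered = qc.filter_genes(qc.filter_cells(data.counts))
    nm = qc.normalize(filtered)
    model = fit_sda(nm, k=12, max_iter=300, seed=0, warmup_iters=50)
    obs = nm.cell_meta
    strain = obs["strain"].to_numpy()
    batch = obs["batch"].to_numpy()
    gene_classes = np.where(
        nm.gene_meta["mitochondrial"].to_numpy(),
        "mito",
        nm.gene_meta["gene_class"].to_numpy(),
    )
    tech = flag_technical_components(
        model, batch, strain, gene_classes,
        technical_classes=frozenset({"ribosomal", "pseudogene", "mito"}),
    )
    # components private to a minority strain mark pathological cell
    # populations (majority-strain privacy can be a legitimate late-stage
    # signature, since only the unarrested strain reaches late pseudotime)
    f, p, _ = annotation.strain_enrichment(model.cell_scores_, strain)
    rules = [
        (k, 2.0)
        for k in range(model.cell_scores_.shape[1])
        if (f.loc[k].max() >= 0.95 and p[f.loc[k].idxmax()] < 1.0 / p.size)
        or "gene-class" in tech.get(k, [])
    ]
    excluded_cells = pt.exclude_somatic(model.cell_scores_, rules)
    keep = ~excluded_cells
    traj = pt.trajectory_pseudotime(
        model.cell_scores_[keep],
        excluded_components=sorted(tech),
        seeds=(0, 1, 2),
    )
    return {
        "truth": truth,
        "data": data,
        "normalized": nm,
        "model": model,
        "technical_flags": tech,
        "somatic_rules": rules,
        "keep": keep,
        "trajectory": traj,
    }


@pytest.fixture(scope="session")
def planted_motif_instance():
    """200 synthetic promoters with a width-8 motif planted in 60%."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    consensus = "TGACGTCA"
    probs = np.full((8, 4), 0.05 / 3 * 3)
    probs[:] = (1 - 0.95) / 3
    for i, b in enumerate(consensus):
        probs[i, code[b]] = 0.95
    pwm = PWM(probs)
    pset, truth = scsda.simulate_promoters([(pwm, 0.6)], n_seq=200, length=200, seed=5)
    planted = np.zeros(len(pset), dtype=bool)
    planted[[pset.gene_ids.index(g) for g in truth["seq_id"]]] = True
    sampler = GibbsMotifSampler(n_restarts=9, max_iter=1000, random_state=0).fit(pset)
    return {"pwm": pwm, "promoters": pset, "truth": truth, "planted": planted,
            "sampler": sampler}
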