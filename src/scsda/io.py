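"""Plain-text interchange: Matrix Market counts with TSV sidecars, FASTA
promoters, GMT-like gene sets, and minimal MEME motif output."""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .motifs import PWM, PromoterSet

__all__ = [
    "write_counts",
    "read_counts",
    "write_promoters",
    "read_promoters",
    "read_gene_sets",
    "write_gene_sets",
    "write_pwm_meme",
    "write_qc_report",
]


def write_counts(adata: ad.AnnData, out_dir: str | Path) -> None:
    """Write counts as matrix.mtx (cells x genes) + cells.tsv + genes.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(out / "matrix.mtx", x.astype(np.int64))
    adata.obs.rename_axis("cell_id").to_csv(out / "cells.tsv", sep="\t")
    adata.var.rename_axis("gene_id").to_csv(out / "genes.tsv", sep="\t")
    meta = {"seed": adata.uns.get("seed")} if adata.uns else {}
    (out / "meta.json").write_text(json.dumps(meta))


def read_counts(in_dir: str | Path) -> ad.AnnData:
    inp = Path(in_dir)
    x = sparse.csr_matrix(spio.mmread(inp / "matrix.mtx"))
    obs = pd.read_csv(inp / "cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(inp / "genes.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    adata = ad.AnnData(X=x.astype(np.int64), obs=obs, var=var)
    meta_path = inp / "meta.json"
    if meta_path.exists():
        adata.uns.update(json.loads(meta_path.read_text()))
    return adata


def write_promoters(pset: PromoterSet, fasta_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for gid, seq in zip(pset.gene_ids, pset.sequences):
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_promoters(fasta_path: str | Path, window: str = "file") -> PromoterSet:
    from Bio import SeqIO

    ids, seqs = [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    masked = np.array(
        [sum(1 for ch in s if ch == "N" or ch.islower()) / max(len(s), 1)
         for s in seqs]
    )
    return PromoterSet(gene_ids=ids, sequences=seqs, window=window,
                       masked_fraction=masked)


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """GMT-like TSV: set id, description, then tab-separated gene ids."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gene_sets(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def write_pwm_meme(pwm: PWM, name: str, path: str | Path,
                   background: np.ndarray | None = None) -> None:
    """Minimal MEME motif format."""
    bg = background if background is not None else np.full(4, 0.25)
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: +", "",
        "Background letter frequencies",
        f"A {bg[0]:.3f} C {bg[1]:.3f} G {bg[2]:.3f} T {bg[3]:.3f}", "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pwm.length}",
    ]
    for row in pwm.probs:
        lines.append(" ".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_qc_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)
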