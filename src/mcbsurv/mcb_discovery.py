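"""Partition ordered CpGs into methylation-correlated blocks (MCBs).

An MCB is a maximal run of adjacent CpGs on one chromosome in which every
consecutive probe pair is both physically close (gap ≤ ``max_gap`` bases)
and tightly co-methylated (squared Pearson correlation of β values across
samples ≥ ``r2_cutoff``).  A boundary — a transition spot between two
adjacent markers — is declared wherever either condition fails; runs not
broken by a boundary and holding at least ``min_cpgs`` probes become blocks.

This mirrors how haplotype blocks are called from linkage disequilibrium,
with the co-methylation r² playing the role of LD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import MCB, BetaMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartitionParams:
    """Block-calling thresholds.

    r2_cutoff : squared Pearson correlation below which adjacent probes are
        declared uncorrelated (boundary).  Default 0.8.
    max_gap : maximum base-pair distance between adjacent member CpGs.
        Default 1000 (one kilobase).
    min_cpgs : minimum number of probes a run needs to be reported.
        Default 2.
    """

    r2_cutoff: float = 0.8
    max_gap: int = 1000
    min_cpgs: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.r2_cutoff <= 1):
            raise ValueError("r2_cutoff must be in (0, 1]")
        if self.max_gap < 1:
            raise ValueError("max_gap must be ≥ 1")
        if self.min_cpgs < 2:
            raise ValueError("min_cpgs must be ≥ 2")


def _adjacent_r(vals: np.ndarray) -> np.ndarray:
    """Pearson r between each consecutive row pair; NaN where undefined."""
    x = vals - vals.mean(axis=1, keepdims=True)
    sd = np.sqrt((x**2).sum(axis=1))
    num = (x[:-1] * x[1:]).sum(axis=1)
    den = sd[:-1] * sd[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return r


def partition_mcbs(
    beta: BetaMatrix,
    ann: pd.DataFrame,
    params: PartitionParams = PartitionParams(),
) -> list[MCB]:
    """Call MCBs chromosome by chromosome.

    Probes are sorted by position within each chromosome; a boundary is
    declared between adjacent probes when the gap exceeds ``max_gap`` or the
    squared correlation falls below ``r2_cutoff``.  A zero-variance probe has
    undefined correlation with its neighbours and conservatively induces a
    boundary on both sides.  Block IDs are assigned sequentially in genomic
    order (chromosomes in sorted label order).
    """
    if beta.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate Pearson correlation")
    if beta.values.isna().any().any():
        raise ValueError("β matrix must be imputed (no missing values) before partitioning")
    shared = set(beta.probe_ids.intersection(ann.index))
    if not shared:
        raise ValueError("no probes shared between β matrix and annotation")

    ann_sub = ann.loc[[p for p in ann.index if p in shared]]
    mcbs: list[MCB] = []
    next_id = 1
    n_zero_var = 0
    for chrom in sorted(ann_sub["chrom"].unique()):
        sub = ann_sub[ann_sub["chrom"] == chrom].sort_values("pos", kind="mergesort")
        probes = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        if len(probes) < 2:
            continue
        vals = beta.values.loc[probes].to_numpy(dtype=float)
        r = _adjacent_r(vals)
        n_zero_var += int(np.isnan(r).sum())
        gap = np.diff(pos)
        linked = (gap <= params.max_gap) & (np.nan_to_num(r, nan=0.0) ** 2 >= params.r2_cutoff)
        linked &= ~np.isnan(r)

        run_start = 0
        for i in range(len(probes)):
            boundary_after = i == len(probes) - 1 or not linked[i]
            if boundary_after:
                run = slice(run_start, i + 1)
                if i + 1 - run_start >= params.min_cpgs:
                    mcbs.append(
                        MCB(
                            mcb_id=next_id,
                            chrom=chrom,
                            start=int(pos[run][0]),
                            end=int(pos[run][-1]),
                            probes=list(probes[run]),
                        )
                    )
                    next_id += 1
                run_start = i + 1
    if n_zero_var:
        logger.info("partition: %d adjacent pairs had undefined correlation (zero variance)", n_zero_var)
    return mcbs


def mcb_mean(beta: BetaMatrix, mcb: MCB) -> pd.Series:
    """Per-sample unweighted arithmetic mean of the block's member-probe β."""
    missing = [p for p in mcb.probes if p not in beta.probe_ids]
    if missing:
        raise KeyError(f"probes not in β matrix: {missing[:5]}")
    return beta.values.loc[mcb.probes].mean(axis=0)


def mcb_mean_matrix(beta: BetaMatrix, mcbs: list[MCB]) -> pd.DataFrame:
    """Stack per-sample block means into an (MCB × sample) DataFrame."""
    rows = {m.mcb_id: mcb_mean(beta, m) for m in mcbs}
    out = pd.DataFrame(rows).T
    out.index.name = "mcb_id"
    return out


def mcb_summaries(mcbs: list[MCB], beta: BetaMatrix) -> pd.DataFrame:
    """Per-block summary statistics.

    Columns: chrom, start, end, length_bp, n_cpgs, mean_beta (grand mean
    over member CpGs and samples) and sd_cpg_means — the standard deviation
    (n−1 convention) of the per-CpG mean β values within the block, a
    measure of how much the methylation level varies along the block.
    """
    rows = []
    for m in mcbs:
        missing = [p for p in m.probes if p not in beta.probe_ids]
        if missing:
            raise KeyError(f"MCB {m.mcb_id}: probes not in β matrix: {missing[:5]}")
        block = beta.values.loc[m.probes]
        cpg_means = block.mean(axis=1)
        rows.append(
            {
                "mcb_id": m.mcb_id,
                "chrom": m.chrom,
                "start": m.start,
                "end": m.end,
                "length_bp": m.length_bp,
                "n_cpgs": m.n_cpgs,
                "mean_beta": float(block.to_numpy().mean()),
                "sd_cpg_means": float(cpg_means.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows).set_index("mcb_id")


def chromosome_counts(mcbs: list[MCB]) -> pd.Series:
    """Number of blocks per chromosome, sorted by chromosome label."""
    counts = pd.Series([m.chrom for m in mcbs], dtype=object).value_counts().sort_index()
    counts.name = "n_mcbs"
    return counts


def link_genes(
    mcbs: list[MCB],
    expr: pd.DataFrame,
    ann: pd.DataFrame,
    beta: BetaMatrix,
) -> list[MCB]:
    """Assign each block the gene whose expression tracks it most strongly.

    Raw counts (genes × samples) are transformed as log2(count + 1).  A
    block's candidate genes are the union of the gene symbols annotated to
    its member probes; for each candidate, the Pearson correlation between
    the block's per-sample mean β and the gene's transformed expression is
    computed over the shared samples, and the candidate with the greatest
    absolute correlation wins.  Blocks with no annotated candidate, or whose
    candidates have no expression data, keep ``gene=None``.
    """
    shared = beta.sample_ids.intersection(expr.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 samples shared between β and expression")
    log_expr = np.log2(expr.loc[:, shared].astype(float) + 1.0)

    out: list[MCB] = []
    for m in mcbs:
        candidates: list[str] = []
        for p in m.probes:
            if p in ann.index:
                for g in ann.loc[p, "genes"]:
                    if g not in candidates:
                        candidates.append(g)
        candidates = [g for g in candidates if g in log_expr.index]
        gene, gene_r = None, None
        if candidates:
            mean_beta = mcb_mean(beta, m).loc[shared].to_numpy(dtype=float)
            best_abs = -1.0
            for g in candidates:
                e = log_expr.loc[g].to_numpy(dtype=float)
                if np.std(e) == 0 or np.std(mean_beta) == 0:
                    continue
                r = float(np.corrcoef(mean_beta, e)[0, 1])
                if abs(r) > best_abs:
                    best_abs, gene, gene_r = abs(r), g, r
        out.append(
            MCB(
                mcb_id=m.mcb_id,
                chrom=m.chrom,
                start=m.start,
                end=m.end,
                probes=list(m.probes),
                gene=gene,
                gene_r=gene_r,
            )
        )
    return out
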