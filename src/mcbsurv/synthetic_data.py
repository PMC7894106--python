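"""Synthetic 450K-like fixtures: correlated CpG blocks, planted prognostic
effects, right-censored survival, and optionally correlated expression.

Methylation is generated from a latent Gaussian with exchangeable
intra-block correlation ρ pushed through a logistic link around each
block's mean β level, so the partitioning statistic (Pearson r on β) is
controlled directly.  Noise CpGs are independent and placed far apart so
they can never merge into blocks.  Event times follow an exponential
proportional-hazards model driven by the causal block's per-sample mean β;
censoring is the minimum of an independent exponential and an
administrative cutoff.  Every generator is deterministic given the design
seed and emits objects the I/O layer round-trips unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data_io import (
    MCB,
    BetaMatrix,
    SurvivalTable,
    write_beta_matrix,
    write_clinical,
    write_manifest,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlockSpec:
    """Geometry and correlation of one planted CpG block."""

    chrom: str
    start: int
    n_cpgs: int
    spacing: int = 100
    rho: float = 0.95
    mean_beta: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if not (0 < self.mean_beta < 1):
            raise ValueError("mean_beta must be in (0, 1)")
        if self.n_cpgs < 1 or self.spacing < 1 or self.start < 1:
            raise ValueError("counts and coordinates must be positive")

    @property
    def end(self) -> int:
        return self.start + (self.n_cpgs - 1) * self.spacing


@dataclass(frozen=True)
class SimDesign:
    """Full study design for one synthetic cohort.

    effect_size is the log hazard ratio per unit of (centered) causal-block
    mean β; baseline_hazard and censor_rate are exponential rates per day;
    latent_scale sets the spread of β around each block's mean level (0.6
    gives a per-CpG β standard deviation of roughly 0.15 at mid methylation
    levels, comparable to variable array probes).
    """

    n_samples: int = 300
    blocks: tuple[BlockSpec, ...] = ()
    n_noise_cpgs: int = 100
    causal_block_index: int | None = None
    effect_size: float = float(np.log(2) / 0.1)
    baseline_hazard: float = 1.0 / 1500.0
    censor_rate: float = 1.0 / 3000.0
    admin_censor_days: float = 3650.0
    seed: int = 0
    latent_scale: float = 0.6

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_noise_cpgs < 0:
            raise ValueError("counts must be positive")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if self.causal_block_index is not None and not (
            0 <= self.causal_block_index < len(self.blocks)
        ):
            raise ValueError("causal_block_index out of range")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for b in self.blocks:
            for s, e in by_chrom.get(b.chrom, []):
                if b.start <= e and s <= b.end:
                    raise ValueError(f"overlapping blocks on {b.chrom}")
            by_chrom.setdefault(b.chrom, []).append((b.start, b.end))


def default_design(
    seed: int,
    n_samples: int = 300,
    n_blocks: int = 21,
    causal_block_index: int | None = 0,
    n_cpgs_per_block: int = 5,
    rho: float = 0.95,
    n_noise_cpgs: int = 100,
) -> SimDesign:
    """Standard fixture design: one (optional) causal block among nulls.

    Blocks carry 5 CpGs at 100 bp spacing with ρ = 0.95 and cycle through
    low / mid / high mean β levels, mirroring the trimodal β landscape of
    array data; the causal block sits at a mid methylation level so its
    mean β varies enough to carry signal.
    """
    levels = (0.5, 0.15, 0.85)
    blocks = tuple(
        BlockSpec(
            chrom=f"chr{(i % 8) + 1}",
            start=10_000 + (i // 8) * 100_000,
            n_cpgs=n_cpgs_per_block,
            spacing=100,
            rho=rho,
            mean_beta=levels[i % 3] if i != (causal_block_index or 0) else 0.5,
        )
        for i in range(n_blocks)
    )
    return SimDesign(
        n_samples=n_samples,
        blocks=blocks,
        n_noise_cpgs=n_noise_cpgs,
        causal_block_index=causal_block_index,
        seed=seed,
    )


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def block_probe_ids(design: SimDesign, block_index: int) -> list[str]:
    b = design.blocks[block_index]
    return [f"cg_b{block_index:03d}_{j:02d}" for j in range(b.n_cpgs)]


def simulate_methylation(design: SimDesign) -> tuple[BetaMatrix, pd.DataFrame]:
    """Draw the β matrix and matching probe annotation for a design.

    Each block's latent field is sqrt(ρ)·shared + sqrt(1−ρ)·idiosyncratic,
    giving exchangeable pairwise correlation ρ, then mapped through the
    logistic link around logit(mean β).  Noise CpGs are independent, drawn
    around low/mid/high levels, and spaced 2 kb apart on a dedicated
    chromosome so the partitioner can never link them.
    """
    rng = np.random.default_rng([design.seed, 101])
    n = design.n_samples
    samples = _sample_ids(n)

    rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    ann_rows: list[dict] = []
    for bi, b in enumerate(design.blocks):
        shared = rng.normal(size=n)
        idio = rng.normal(size=(b.n_cpgs, n))
        z = np.sqrt(b.rho) * shared[None, :] + np.sqrt(1.0 - b.rho) * idio
        beta = expit(logit(b.mean_beta) + design.latent_scale * z)
        for j in range(b.n_cpgs):
            pid = f"cg_b{bi:03d}_{j:02d}"
            probe_ids.append(pid)
            rows.append(beta[j])
            ann_rows.append(
                {
                    "probe_id": pid,
                    "chrom": b.chrom,
                    "pos": b.start + j * b.spacing,
                    "genes": (f"GENE{bi:03d}",),
                    "snp_flag": False,
                }
            )
    levels = np.array([0.1, 0.5, 0.85])
    for j in range(design.n_noise_cpgs):
        mu = levels[rng.integers(0, 3)]
        z = rng.normal(size=n)
        rows.append(expit(logit(mu) + design.latent_scale * z))
        pid = f"cg_noise_{j:04d}"
        probe_ids.append(pid)
        ann_rows.append(
            {
                "probe_id": pid,
                "chrom": "chrU",
                "pos": 10_000 + j * 2_000,
                "genes": (),
                "snp_flag": False,
            }
        )
    values = pd.DataFrame(np.vstack(rows), index=probe_ids, columns=samples)
    # guard against exact 1.0 from extreme latent draws (float rounding)
    values = values.clip(upper=np.nextafter(1.0, 0.0))
    ann = pd.DataFrame(ann_rows).set_index("probe_id")
    return BetaMatrix(values), ann


def _causal_mean(
    beta: BetaMatrix, mcbs: list[MCB] | None, design: SimDesign
) -> pd.Series:
    idx = design.causal_block_index
    assert idx is not None
    probes = set(block_probe_ids(design, idx))
    if mcbs is not None:
        hits = [m for m in mcbs if probes & set(m.probes)]
        if not hits:
            raise ValueError("causal block not present in the provided MCB collection")
        member = hits[0].probes
    else:
        member = sorted(probes)
    return beta.values.loc[list(member)].mean(axis=0)


def simulate_survival(
    beta: BetaMatrix, mcbs: list[MCB] | None, design: SimDesign
) -> SurvivalTable:
    """Exponential proportional-hazards event times driven by the causal block.

    hazard_i = baseline_hazard · exp(effect_size · centered mean β of the
    causal block); with no causal block the hazard is the baseline for
    everyone (null simulation).  Observed time is the minimum of the event
    time, an independent exponential censoring time and the administrative
    cutoff.
    """
    rng = np.random.default_rng([design.seed, 202])
    n = design.n_samples
    samples = list(beta.sample_ids)
    if len(samples) != n:
        raise ValueError("β matrix does not match the design's sample count")

    if design.causal_block_index is None:
        lin = np.zeros(n)
    else:
        m = _causal_mean(beta, mcbs, design).to_numpy(dtype=float)
        lin = design.effect_size * (m - m.mean())
    rate = design.baseline_hazard * np.exp(lin)
    t_event = rng.exponential(1.0 / rate)
    if design.censor_rate > 0:
        t_cens = rng.exponential(1.0 / design.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, design.admin_censor_days)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if event.sum() == 0:
        logger.warning("simulate_survival: all samples censored")
    df = pd.DataFrame({"time_days": time, "event": event}, index=pd.Index(samples, name="sample"))
    return SurvivalTable(df)


def simulate_expression(
    beta: BetaMatrix,
    mcbs: list[MCB],
    target_r: float,
    seed: int,
    ann: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Raw-count expression whose log2(count+1) correlates with block means.

    For each block with an annotated gene, the log-scale expression is a
    Gaussian mixture a·z + b·noise of the standardized block mean β chosen
    so the realized Pearson correlation approximates ``target_r``; counts
    are recovered by inverting the log2(·+1) transform.
    """
    if not (-1.0 <= target_r <= 1.0):
        raise ValueError("target_r must be in [-1, 1]")
    rng = np.random.default_rng([seed, 303])
    samples = list(beta.sample_ids)
    rows = {}
    for m in mcbs:
        gene = m.gene
        if gene is None and ann is not None:
            for p in m.probes:
                if p in ann.index and ann.loc[p, "genes"]:
                    gene = ann.loc[p, "genes"][0]
                    break
        if gene is None:
            gene = f"GENE_MCB{m.mcb_id}"
        z = beta.values.loc[m.probes].mean(axis=0).to_numpy(dtype=float)
        z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
        e = target_r * z + np.sqrt(max(0.0, 1.0 - target_r**2)) * rng.normal(size=len(z))
        log_expr = 6.0 + 1.5 * e
        rows[gene] = np.maximum(np.exp2(log_expr) - 1.0, 0.0)
    expr = pd.DataFrame(rows, index=samples).T
    expr.index.name = "gene"
    return expr


def write_fixture_set(design: SimDesign, out_dir, expression_r: float = -0.7) -> dict:
    """Materialize a full fixture set (β, manifest, clinical, expression,
    ground truth) as plain-text files readable by the I/O layer."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    beta, ann = simulate_methylation(design)
    truth_mcbs = [
        MCB(
            mcb_id=i + 1,
            chrom=b.chrom,
            start=b.start,
            end=b.end,
            probes=block_probe_ids(design, i),
        )
        for i, b in enumerate(design.blocks)
    ]
    surv = simulate_survival(beta, truth_mcbs, design) if design.causal_block_index is not None \
        else simulate_survival(beta, None, design)
    expr = simulate_expression(beta, truth_mcbs, expression_r, design.seed, ann=ann)

    write_beta_matrix(beta, out / "beta.tsv")
    write_manifest(ann, out / "manifest.csv")
    write_clinical(surv, out / "clinical.tsv")
    expr.to_csv(out / "expression.tsv", sep="\t", index_label="gene", lineterminator="\n")
    truth = {
        "design": {
            **{k: v for k, v in asdict(design).items() if k != "blocks"},
            "blocks": [asdict(b) for b in design.blocks],
        },
        "causal_probes": (
            block_probe_ids(design, design.causal_block_index)
            if design.causal_block_index is not None
            else []
        ),
    }
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
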