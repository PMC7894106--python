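"""β-value computation from allele intensities and CpG-level filtering.

The methylation fraction at a probe is computed from normalized methylated
and unmethylated intensities with a constant offset in the denominator, the
convention recommended by the array vendor:

    β = max(y_methy, 0) / (max(y_methy, 0) + max(y_unmethy, 0) + ε)

with ε = 100 by default, so β always falls in [0, 1).  Filtering removes
SNP-overlapping probes and probes with too much missingness, then mean
imputes the remaining gaps per probe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_io import BetaMatrix

logger = logging.getLogger(__name__)


def compute_beta(y_methy, y_unmethy, epsilon: float = 100.0):
    """Methylation fraction from (possibly negative) allele intensities.

    Negative intensities, which arise after background normalization, are
    clipped to zero before forming the ratio.  Accepts scalars or arrays.

    Parameters
    ----------
    y_methy, y_unmethy
        Normalized methylated / unmethylated allele intensities.
    epsilon
        Constant offset added to the denominator; must be positive.  The
        offset guarantees β < 1 and stabilises low-intensity probes.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    m = np.maximum(np.asarray(y_methy, dtype=float), 0.0)
    u = np.maximum(np.asarray(y_unmethy, dtype=float), 0.0)
    beta = m / (m + u + epsilon)
    return beta if beta.ndim else float(beta)


def compute_beta_matrix(
    methy: pd.DataFrame, unmethy: pd.DataFrame, epsilon: float = 100.0
) -> BetaMatrix:
    """Apply :func:`compute_beta` elementwise to paired intensity matrices."""
    if not methy.index.equals(unmethy.index) or not methy.columns.equals(unmethy.columns):
        raise ValueError("methylated/unmethylated matrices must share probes and samples")
    vals = compute_beta(methy.to_numpy(float), unmethy.to_numpy(float), epsilon)
    return BetaMatrix(pd.DataFrame(vals, index=methy.index, columns=methy.columns))


def filter_cpgs(
    beta: BetaMatrix,
    ann: pd.DataFrame,
    missing_threshold: float = 0.30,
) -> BetaMatrix:
    """Drop SNP-overlapping and high-missingness probes; mean-impute the rest.

    Probes flagged as overlapping a known SNP are removed.  Probes whose
    fraction of missing samples is at or above ``missing_threshold`` are
    removed (a probe with *a few* gaps, strictly below the threshold, is
    imputable).  Surviving gaps are filled with the probe's mean over its
    non-missing samples, so the output contains no missing values.  Values
    that were observed are never altered.
    """
    shared = beta.probe_ids.intersection(ann.index)
    if len(shared) == 0:
        raise ValueError("β matrix and annotation share no probes")
    order = [p for p in beta.probe_ids if p in set(shared)]
    vals = beta.values.loc[order]
    snp = ann.loc[order, "snp_flag"].astype(bool)

    miss_frac = vals.isna().mean(axis=1)
    keep = (~snp) & (miss_frac < missing_threshold)
    n_snp = int(snp.sum())
    n_miss = int(((~snp) & (miss_frac >= missing_threshold)).sum())
    logger.info(
        "filter_cpgs: removed %d SNP probes, %d high-missingness probes; %d remain",
        n_snp, n_miss, int(keep.sum()),
    )
    if not keep.any():
        raise ValueError("no probes survive filtering")

    out = vals.loc[keep].copy()
    row_means = out.mean(axis=1, skipna=True)
    out = out.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    return BetaMatrix(out)
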