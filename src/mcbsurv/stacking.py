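"""Feature-weighted linear stacking (FWLS) of base-model risk scores.

The blended score is d(x) = Σ_i w_i(x) g_i(x), where g_i are the base-model
scores and the weights are themselves linear in a set of meta-features
f_j(x): w_i(x) = Σ_j v_ij f_j(x).  Substituting gives a plain linear model

    d(x) = Σ_{i,j} v_ij f_j(x) g_i(x)

over the product columns f_j·g_i, so the v_ij are found by (minimum-norm)
least squares against a training target y(x).  With only the constant
meta-feature f_1 ≡ 1 this reduces to classical linear stacking.  On
censored data the default target is the event indicator; an alternative is
the martingale residual from a covariate-free Cox (Nelson–Aalen) fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .base_learners import RiskScoreVector
from .data_io import SurvivalTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StackingSpec:
    """Configuration of the FWLS meta-learner.

    meta_features : names of the meta-feature columns; "constant" (always
        first when present) is the intercept-like feature f ≡ 1, any other
        name must be a column of the provided meta matrix.
    target_mode : "event" regresses on the 0/1 event indicator;
        "martingale" on martingale residuals from a null Cox model.
    nonneg : constrain all v_ij ≥ 0 (nonnegative least squares).
    """

    meta_features: tuple[str, ...] = ("constant",)
    target_mode: str = "event"
    nonneg: bool = False

    def __post_init__(self) -> None:
        if len(self.meta_features) < 1:
            raise ValueError("need at least one meta-feature")
        if "constant" in self.meta_features and self.meta_features[0] != "constant":
            raise ValueError("the constant meta-feature must come first")
        if self.target_mode not in ("event", "martingale"):
            raise ValueError(f"unknown target_mode {self.target_mode!r}")


@dataclass
class StackedModel:
    """Learned FWLS weights v (base models × meta-features)."""

    v: np.ndarray
    base_tags: tuple[str, ...]
    spec: StackingSpec = field(default_factory=StackingSpec)

    def __post_init__(self) -> None:
        if not np.isfinite(self.v).all():
            raise ValueError("stacking weights must be finite")
        if self.v.shape != (len(self.base_tags), len(self.spec.meta_features)):
            raise ValueError("weight matrix shape inconsistent with spec")


def _meta_matrix(meta: pd.DataFrame | None, spec: StackingSpec, index: pd.Index) -> np.ndarray:
    cols = []
    for name in spec.meta_features:
        if name == "constant":
            cols.append(np.ones(len(index)))
        else:
            if meta is None or name not in meta.columns:
                raise KeyError(f"meta-feature {name!r} not provided")
            cols.append(meta.loc[index, name].to_numpy(dtype=float))
    return np.column_stack(cols)


def _product_design(base: np.ndarray, meta: np.ndarray) -> np.ndarray:
    """Columns f_j(x)·g_i(x), ordered (i, j) row-major over (model, feature)."""
    n, m = base.shape
    p = meta.shape[1]
    return (base[:, :, None] * meta[:, None, :]).reshape(n, m * p)


def fit_fwls(
    base_scores: pd.DataFrame,
    y: np.ndarray | pd.Series,
    meta: pd.DataFrame | None = None,
    spec: StackingSpec = StackingSpec(),
) -> StackedModel:
    """Solve the FWLS least-squares problem for the weights v_ij.

    ``base_scores`` is samples × base models (column names become the base
    tags).  Rank-deficient designs resolve to the minimum-norm solution with
    a logged warning; with ``spec.nonneg`` the nonnegative least-squares
    variant is solved instead.
    """
    if base_scores.isna().any().any():
        raise ValueError("base scores contain missing values")
    m, p = base_scores.shape[1], len(spec.meta_features)
    if base_scores.shape[0] < m * p + 1:
        raise ValueError("need more samples than stacking weights")
    B = base_scores.to_numpy(dtype=float)
    F = _meta_matrix(meta, spec, base_scores.index)
    X = _product_design(B, F)
    yv = np.asarray(y, dtype=float)
    if spec.nonneg:
        flat, _ = nnls(X, yv)
    else:
        flat, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
        if rank < X.shape[1]:
            logger.warning(
                "fit_fwls: rank-deficient design (rank %d < %d); minimum-norm solution",
                rank, X.shape[1],
            )
    v = flat.reshape(m, p)
    return StackedModel(v=v, base_tags=tuple(base_scores.columns), spec=spec)


def predict_fwls(
    model: StackedModel,
    base_scores: pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> RiskScoreVector:
    """Blended score d(x) = Σ_{i,j} v_ij f_j(x) g_i(x)."""
    if tuple(base_scores.columns) != model.base_tags:
        raise ValueError(
            f"base model columns {tuple(base_scores.columns)} do not match "
            f"fitted tags {model.base_tags}"
        )
    B = base_scores.to_numpy(dtype=float)
    F = _meta_matrix(meta, model.spec, base_scores.index)
    X = _product_design(B, F)
    d = X @ model.v.reshape(-1)
    return RiskScoreVector(
        scores=pd.Series(d, index=base_scores.index), source="ensemble"
    )


def martingale_residuals(surv: SurvivalTable) -> pd.Series:
    """Martingale residuals from a covariate-free (null) Cox model.

    Under the null model the residual is event − H0(time), with H0 the
    Nelson–Aalen cumulative hazard estimate.
    """
    from lifelines import NelsonAalenFitter

    naf = NelsonAalenFitter()
    naf.fit(surv.time.to_numpy(dtype=float), surv.event.to_numpy(dtype=int))
    h0 = naf.cumulative_hazard_at_times(surv.time.to_numpy(dtype=float)).to_numpy()
    return pd.Series(surv.event.to_numpy(dtype=float) - h0, index=surv.sample_ids)


def stacking_target(surv: SurvivalTable, spec: StackingSpec) -> pd.Series:
    if spec.target_mode == "event":
        return surv.event.astype(float)
    return martingale_residuals(surv)


def ensemble_cv_scores(
    base_oof: dict[str, RiskScoreVector],
    surv: SurvivalTable,
    meta: pd.DataFrame | None = None,
    spec: StackingSpec = StackingSpec(),
) -> RiskScoreVector:
    """Out-of-fold ensemble scores from already-out-of-fold base scores.

    Within each fold of the shared CV split, stacking weights are fitted on
    the other folds' base scores and applied to the held-out fold, so the
    ensemble score of every sample comes from weights it did not influence.
    All base vectors must carry identical fold assignments.
    """
    tags = list(base_oof)
    folds = None
    for tag, rs in base_oof.items():
        if rs.fold_assignment is None:
            raise ValueError(f"base scores {tag!r} lack fold assignments")
        if folds is None:
            folds = rs.fold_assignment
        elif not folds.equals(rs.fold_assignment):
            raise ValueError("base score vectors have inconsistent fold assignments")
    assert folds is not None
    base = pd.DataFrame({t: base_oof[t].scores for t in tags}).loc[surv.sample_ids]
    y = stacking_target(surv, spec).loc[surv.sample_ids]

    out = pd.Series(np.nan, index=surv.sample_ids, dtype=float)
    for f in sorted(folds.unique()):
        test_ids = folds.index[folds == f]
        train_ids = folds.index[folds != f]
        model = fit_fwls(base.loc[train_ids], y.loc[train_ids], meta=meta, spec=spec)
        out.loc[test_ids] = predict_fwls(
            model, base.loc[test_ids], meta=meta
        ).scores.to_numpy()
    return RiskScoreVector(scores=out, source="ensemble", fold_assignment=folds)
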