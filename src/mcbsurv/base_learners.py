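"""Per-block survival base learners and out-of-fold risk scoring.

Three models are fitted on the member-CpG β values of a single block:

* a classic Cox proportional-hazards model (risk = linear predictor),
* a linear-kernel epsilon-SVR regressing observed follow-up time
  (predictions are negated so that higher score = worse prognosis), and
* an elastic-net penalized Cox model whose coefficients are taken at the
  smallest penalty on a glmnet-style decreasing path.

Block-level feature selection fits an L1 (lasso) Cox model over block mean
β features along a penalty path and retains the blocks with a nonzero
coefficient at a fixed penalty value.  Risk scores on training data come
from stratified k-fold cross-validation so every score is out-of-fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVR
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .data_io import MCB, SurvivalTable

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """A base learner failed to converge or the fit is degenerate."""


def _surv_array(surv: SurvivalTable):
    return Surv.from_arrays(
        event=surv.event.to_numpy(dtype=bool), time=surv.time.to_numpy(dtype=float)
    )


def _design(block_beta: pd.DataFrame, surv: SurvivalTable) -> pd.DataFrame:
    """Samples × CpGs design aligned to the survival table's sample order."""
    missing = [s for s in surv.sample_ids if s not in block_beta.columns]
    if missing:
        raise KeyError(f"samples missing from β block: {missing[:5]}")
    return block_beta.loc[:, surv.sample_ids].T


@dataclass
class RiskScoreVector:
    """Risk scores (higher = worse prognosis) with provenance."""

    scores: pd.Series
    source: str
    fold_assignment: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("risk scores must be finite")


@dataclass
class CoxModel:
    coefs: pd.Series
    dropped: list[str] = field(default_factory=list)
    tag: str = "cox"

    def predict(self, block_beta: pd.DataFrame) -> pd.Series:
        X = block_beta.loc[self.coefs.index].T
        return pd.Series(X.to_numpy(float) @ self.coefs.to_numpy(float), index=X.index)


@dataclass
class SVRModel:
    estimator: SVR
    probe_ids: list[str]
    target: str = "time"
    constant_value: float | None = None
    tag: str = "svr"

    def predict(self, block_beta: pd.DataFrame) -> pd.Series:
        X = block_beta.loc[self.probe_ids].T
        if self.constant_value is not None:
            pred = np.full(len(X), self.constant_value)
        else:
            pred = self.estimator.predict(X.to_numpy(float))
        # longer predicted survival = lower risk
        return pd.Series(-pred, index=X.index)

    def predict_time(self, block_beta: pd.DataFrame) -> pd.Series:
        """Predicted regression target (time scale), unnegated."""
        X = block_beta.loc[self.probe_ids].T
        if self.constant_value is not None:
            return pd.Series(np.full(len(X), self.constant_value), index=X.index)
        return pd.Series(self.estimator.predict(X.to_numpy(float)), index=X.index)


@dataclass
class EnetModel:
    coefs: pd.Series
    penalty: float
    alpha_mix: float
    tag: str = "enet"

    def predict(self, block_beta: pd.DataFrame) -> pd.Series:
        X = block_beta.loc[self.coefs.index].T
        return pd.Series(X.to_numpy(float) @ self.coefs.to_numpy(float), index=X.index)


def fit_cox(
    block_beta: pd.DataFrame,
    surv: SurvivalTable,
    max_feature_frac: float = 0.5,
) -> CoxModel:
    """Cox proportional-hazards fit on a block's member-CpG β values.

    Zero-variance CpG columns are dropped before fitting (their coefficient
    is reported as 0); the number of CpGs may not exceed
    ``max_feature_frac`` times the sample count, which guards against wildly
    overparameterized fits on small cohorts.
    """
    if int(surv.event.sum()) < 2:
        raise FitError("need at least 2 events to fit a Cox model")
    X = _design(block_beta, surv)
    if X.shape[1] > max_feature_frac * X.shape[0]:
        raise FitError(
            f"{X.shape[1]} CpGs exceeds cap of {max_feature_frac:.0%} of {X.shape[0]} samples"
        )
    variances = X.var(axis=0, ddof=0)
    dropped = list(variances.index[variances == 0])
    if dropped:
        logger.warning("fit_cox: dropped %d zero-variance CpGs", len(dropped))
    kept = [c for c in X.columns if c not in set(dropped)]
    coefs = pd.Series(0.0, index=block_beta.index)
    if kept:
        est = CoxPHSurvivalAnalysis(alpha=1e-9, n_iter=200)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X[kept].to_numpy(float), _surv_array(surv))
        except Exception as exc:  # pragma: no cover - depends on data pathology
            raise FitError(f"Cox fit failed: {exc}") from exc
        if not np.isfinite(est.coef_).all():
            raise FitError("Cox fit produced non-finite coefficients")
        coefs.loc[kept] = est.coef_
    return CoxModel(coefs=coefs, dropped=dropped)


def fit_svr(
    block_beta: pd.DataFrame,
    surv: SurvivalTable,
    target: str = "time",
    C: float = 1.0,
    epsilon: float = 0.1,
) -> SVRModel:
    """Linear-kernel epsilon-SVR of a survival target on block β values.

    ``target`` is either observed follow-up time ("time") or its log
    transform ("log_time", log(time + 1)); censoring is ignored at fit time,
    a documented simplification.  Risk scores are the negated predictions.
    """
    if len(surv.sample_ids) < 3:
        raise FitError("need at least 3 samples for SVR")
    X = _design(block_beta, surv)
    if target == "time":
        y = surv.time.to_numpy(dtype=float)
    elif target == "log_time":
        y = np.log(surv.time.to_numpy(dtype=float) + 1.0)
    else:
        raise ValueError(f"unknown SVR target {target!r}")
    if np.ptp(y) == 0:
        logger.warning("fit_svr: degenerate constant target; constant-score model")
        return SVRModel(
            estimator=SVR(), probe_ids=list(block_beta.index),
            target=target, constant_value=float(y[0]),
        )
    est = SVR(kernel="linear", C=C, epsilon=epsilon)
    est.fit(X.to_numpy(float), y)
    return SVRModel(estimator=est, probe_ids=list(block_beta.index), target=target)


def fit_enet_cox(
    block_beta: pd.DataFrame,
    surv: SurvivalTable,
    alpha_mix: float = 0.5,
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.01,
    ridge_alpha: float = 0.01,
) -> EnetModel:
    """Elastic-net penalized Cox fit, coefficients at the path's minimum penalty.

    A decreasing log-spaced penalty path of ``n_alphas`` values is computed
    from the data-derived maximum down to ``alpha_min_ratio`` times that
    maximum (glmnet convention, features standardized internally); the model
    keeps the coefficients at the smallest penalty, which prunes only the
    weakest-effect CpGs.  ``alpha_mix`` is the lasso/ridge mixing fraction
    (1 = pure lasso); ``alpha_mix = 0`` falls back to a ridge-penalized Cox
    fit at penalty ``ridge_alpha``.
    """
    if int(surv.event.sum()) < 2:
        raise FitError("need at least 2 events to fit a penalized Cox model")
    if not (0 <= alpha_mix <= 1):
        raise ValueError("alpha_mix must be in [0, 1]")
    X = _design(block_beta, surv)
    coefs = pd.Series(0.0, index=block_beta.index)
    if alpha_mix == 0:
        est = CoxPHSurvivalAnalysis(alpha=ridge_alpha, n_iter=200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X.to_numpy(float), _surv_array(surv))
        coefs.loc[X.columns] = est.coef_
        return EnetModel(coefs=coefs, penalty=ridge_alpha, alpha_mix=0.0)
    est = CoxnetSurvivalAnalysis(
        l1_ratio=alpha_mix,
        n_alphas=n_alphas,
        alpha_min_ratio=alpha_min_ratio,
        normalize=True,
        fit_baseline_model=False,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X.to_numpy(float), _surv_array(surv))
    except Exception as exc:  # pragma: no cover
        raise FitError(f"elastic-net Cox fit failed: {exc}") from exc
    coefs.loc[X.columns] = est.coef_[:, -1]
    return EnetModel(coefs=coefs, penalty=float(est.alphas_[-1]), alpha_mix=alpha_mix)


def select_mcbs_l1(
    mcb_means: pd.DataFrame,
    surv: SurvivalTable,
    mcbs: Sequence[MCB],
    lambda_threshold: float = 0.01,
    min_cpgs: int = 5,
) -> list[int]:
    """Embedded L1-Cox feature selection over block mean β features.

    Blocks with fewer than ``min_cpgs`` member CpGs are dropped first.  A
    lasso-penalized Cox model (features standardized internally) is then fit
    along a decreasing penalty path augmented with ``lambda_threshold``, and
    the block IDs with a nonzero coefficient at that fixed penalty are
    returned.  A threshold above the path maximum shrinks everything to
    zero and yields an empty selection.
    """
    if int(surv.event.sum()) < 2:
        raise ValueError("need at least 2 events for L1-Cox selection")
    size_ok = [m.mcb_id for m in mcbs if m.n_cpgs >= min_cpgs]
    candidates = [mid for mid in mcb_means.index if mid in set(size_ok)]
    if not candidates:
        logger.info("select_mcbs_l1: no blocks with ≥ %d CpGs", min_cpgs)
        return []
    X = mcb_means.loc[candidates, surv.sample_ids].T.to_numpy(dtype=float)
    y = _surv_array(surv)

    base = CoxnetSurvivalAnalysis(l1_ratio=1.0, normalize=True, alpha_min_ratio=0.01)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base.fit(X, y)
        path = np.unique(np.concatenate([base.alphas_, [lambda_threshold]]))[::-1]
        est = CoxnetSurvivalAnalysis(l1_ratio=1.0, normalize=True, alphas=list(path))
        est.fit(X, y)
    idx = int(np.argmin(np.abs(est.alphas_ - lambda_threshold)))
    nonzero = np.flatnonzero(est.coef_[:, idx] != 0)
    selected = [candidates[i] for i in nonzero]
    logger.info(
        "select_mcbs_l1: %d of %d blocks selected at λ=%g", len(selected), len(candidates),
        lambda_threshold,
    )
    return selected


def cv_risk_scores(
    fitter: Callable[[pd.DataFrame, SurvivalTable], object],
    block_beta: pd.DataFrame,
    surv: SurvivalTable,
    k: int = 10,
    seed: int = 42,
    max_retries: int = 10,
) -> RiskScoreVector:
    """Out-of-fold risk scores from k-fold CV stratified by event status.

    Each sample's score comes from a model fitted on the other k−1 folds.
    Folds are redrawn (up to ``max_retries`` reseedings) until every
    training split contains at least two events; ``k = n`` degenerates to
    leave-one-out.  Deterministic given ``seed``.
    """
    n = len(surv.sample_ids)
    if n < k:
        raise ValueError(f"k={k} exceeds sample count {n}")
    events = surv.event.to_numpy(dtype=int)
    sample_ids = np.asarray(surv.sample_ids)

    for retry in range(max_retries):
        if k == n:
            splits = list(LeaveOneOut().split(sample_ids))
        else:
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + 1000 * retry)
            splits = list(skf.split(sample_ids, events))
        if all(events[train].sum() >= 2 for train, _ in splits):
            break
    else:
        raise ValueError(
            f"could not draw {k} folds whose training splits all contain ≥2 events; "
            "use a smaller k"
        )

    scores = pd.Series(np.nan, index=surv.sample_ids, dtype=float)
    folds = pd.Series(-1, index=surv.sample_ids, dtype=int)
    tag = "model"
    for f, (train, test) in enumerate(splits):
        surv_train = surv.subset(sample_ids[train])
        model = fitter(block_beta.loc[:, sample_ids[train]], surv_train)
        tag = getattr(model, "tag", tag)
        pred = model.predict(block_beta.loc[:, sample_ids[test]])
        scores.loc[sample_ids[test]] = pred.to_numpy(dtype=float)
        folds.loc[sample_ids[test]] = f
    return RiskScoreVector(scores=scores, source=tag, fold_assignment=folds)
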