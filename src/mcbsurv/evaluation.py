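"""Prognostic performance metrics and survival-comparison statistics.

Scores are evaluated with the cumulative-case / dynamic-control
time-dependent AUC at a fixed horizon (default 5 years) using inverse
probability of censoring weights from the Kaplan–Meier censoring estimator,
and with Harrell's concordance index.  Blocks are ranked across models and
datasets by the rank-product statistic RP_i = Σ_j ln R_ij where R_ij is the
block's rank (1 = best AUC) in column j; a small RP marks a consistently
good block.  Group survival differences use Kaplan–Meier curves with a
log-rank test at the training-median risk cutoff, AUC differences use a
bootstrap percentile method, model columns are compared with paired t-tests
under Benjamini–Hochberg adjustment, and the risk score's independence from
clinical covariates is assessed with a multivariate Cox model.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .base_learners import RiskScoreVector
from .data_io import SurvivalTable

logger = logging.getLogger(__name__)

#: Five years expressed in days.
FIVE_YEARS_DAYS = 1826


def _scores_series(scores) -> pd.Series:
    if isinstance(scores, RiskScoreVector):
        return scores.scores
    return pd.Series(scores)


def _km_censoring(time: np.ndarray, event: np.ndarray):
    """Kaplan–Meier estimate of the censoring survival function G(t).

    Events are treated as censored observations of the censoring time; the
    returned step function is right-continuous with G(0) = 1.
    """
    order = np.argsort(time, kind="mergesort")
    t, d = time[order], 1 - event[order]
    uniq = np.unique(t)
    at_risk = np.searchsorted(t, uniq, side="left")
    n = len(t)
    surv = []
    g = 1.0
    for u in uniq:
        n_risk = n - np.searchsorted(t, u, side="left")
        n_cens = int(((t == u) & (d == 1)).sum())
        if n_risk > 0:
            g *= 1.0 - n_cens / n_risk
        surv.append(g)
    return uniq, np.asarray(surv)


def _step(times: np.ndarray, values: np.ndarray, t: float, left: bool = False) -> float:
    side = "left" if left else "right"
    i = np.searchsorted(times, t, side=side) - 1
    return 1.0 if i < 0 else float(values[i])


def time_dependent_auc(
    scores,
    surv: SurvivalTable,
    horizon_days: float = FIVE_YEARS_DAYS,
) -> float:
    """Cumulative/dynamic AUC at ``horizon_days`` with IPCW.

    Cases are samples with an observed event at or before the horizon,
    controls are samples still under observation beyond it.  Each case i is
    weighted 1/G(t_i−) and each control 1/G(horizon), with G the
    Kaplan–Meier censoring-survival estimate, which de-biases the AUC for
    right censoring.  Tied scores count 0.5.  Returns NaN when there are no
    cases or no controls.
    """
    s = _scores_series(scores).loc[surv.sample_ids].to_numpy(dtype=float)
    time = surv.time.to_numpy(dtype=float)
    event = surv.event.to_numpy(dtype=int)

    case = (event == 1) & (time <= horizon_days)
    ctrl = time > horizon_days
    if not case.any() or not ctrl.any():
        logger.warning("time_dependent_auc: no cases or no controls at horizon; undefined")
        return float("nan")

    kt, kv = _km_censoring(time, event)
    w_case = np.array([_step(kt, kv, t, left=True) for t in time[case]])
    g_h = _step(kt, kv, horizon_days)
    if (w_case <= 0).any() or g_h <= 0:
        keep = w_case > 0
        if g_h <= 0:
            logger.warning("time_dependent_auc: censoring KM reaches 0 at horizon; undefined")
            return float("nan")
        logger.warning(
            "time_dependent_auc: excluded %d cases with zero censoring weight",
            int((~keep).sum()),
        )
        w_case = w_case[keep]
        s_case = s[case][keep]
    else:
        s_case = s[case]
    if len(s_case) == 0:
        return float("nan")
    wi = 1.0 / w_case
    wj = np.full(int(ctrl.sum()), 1.0 / g_h)
    s_ctrl = s[ctrl]

    diff = s_case[:, None] - s_ctrl[None, :]
    conc = (diff > 0) + 0.5 * (diff == 0)
    num = float((wi[:, None] * wj[None, :] * conc).sum())
    den = float(wi.sum() * wj.sum())
    return num / den


def concordance_index(scores, surv: SurvivalTable) -> float:
    """Harrell's C over comparable pairs, tied scores counting 0.5.

    Higher risk scores are expected for samples with earlier events.
    Returns NaN when no pair is comparable.
    """
    s = _scores_series(scores).loc[surv.sample_ids].to_numpy(dtype=float)
    try:
        return float(
            _lifelines_cindex(
                surv.time.to_numpy(dtype=float), -s, surv.event.to_numpy(dtype=int)
            )
        )
    except ZeroDivisionError:
        logger.warning("concordance_index: no comparable pairs; undefined")
        return float("nan")


def rank_product(auc_table: pd.DataFrame) -> pd.Series:
    """Rank-product score per block from an (MCB × column) AUC table.

    Within each column, blocks are ranked by AUC descending (rank 1 = best,
    ties receive average ranks); RP_i = Σ_j ln R_ij.  Blocks with a missing
    AUC in any ranked column are excluded with a logged count.  Smaller RP
    is better; a block ranked first everywhere scores exactly 0.
    """
    if auc_table.shape[1] < 1:
        raise ValueError("need at least one column to rank")
    complete = auc_table.dropna()
    n_dropped = len(auc_table) - len(complete)
    if n_dropped:
        logger.info("rank_product: excluded %d blocks with missing AUCs", n_dropped)
    ranks = complete.rank(ascending=False, method="average", axis=0)
    rp = np.log(ranks).sum(axis=1)
    rp.name = "rank_product"
    return rp


@dataclass
class KMResult:
    labels: pd.Series  # True = high risk
    statistic: float
    p_value: float
    curves: dict[str, pd.DataFrame]


def km_logrank(scores, surv: SurvivalTable, cutoff: float) -> KMResult:
    """Kaplan–Meier comparison of high- vs low-risk groups at a score cutoff.

    Samples with score strictly above ``cutoff`` (typically the training-set
    median risk score) form the high-risk group; the two groups are compared
    with the two-sample log-rank test.
    """
    s = _scores_series(scores).loc[surv.sample_ids]
    high = s > cutoff
    if high.all() or (~high).all():
        raise ValueError(
            "cutoff puts every sample in one risk group; choose a different cutoff"
        )
    t = surv.time.to_numpy(dtype=float)
    e = surv.event.to_numpy(dtype=int)
    hi = high.to_numpy()
    res = logrank_test(t[hi], t[~hi], event_observed_A=e[hi], event_observed_B=e[~hi])
    curves = {}
    for name, mask in (("high", hi), ("low", ~hi)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=name)
        curves[name] = kmf.survival_function_
    return KMResult(
        labels=high, statistic=float(res.test_statistic), p_value=float(res.p_value),
        curves=curves,
    )


@dataclass
class BootstrapAUCResult:
    auc_a: float
    auc_b: float
    diff: float
    ci_low: float
    ci_high: float
    p_value: float
    n_redrawn: int


def bootstrap_auc_compare(
    scores_a,
    scores_b,
    surv: SurvivalTable,
    horizon_days: float = FIVE_YEARS_DAYS,
    n_boot: int = 1000,
    seed: int = 42,
) -> BootstrapAUCResult:
    """Percentile-bootstrap comparison of two models' horizon AUCs.

    Samples are resampled with replacement; both AUCs are recomputed per
    replicate and the percentile CI of their difference is reported with a
    two-sided p-value 2·min(P(diff ≤ 0), P(diff ≥ 0)) clipped to
    (1/n_boot, 1).  Replicates where either AUC is undefined (no cases or
    controls) are redrawn, up to a cap.
    """
    sa = _scores_series(scores_a).loc[surv.sample_ids]
    sb = _scores_series(scores_b).loc[surv.sample_ids]
    rng = np.random.default_rng(seed)
    ids = np.asarray(surv.sample_ids)
    n = len(ids)

    diffs = np.empty(n_boot)
    n_redrawn = 0
    max_total_redraws = 50 * n_boot
    b = 0
    while b < n_boot:
        take = rng.integers(0, n, size=n)
        sub_ids = [f"b{i}" for i in range(n)]
        sub_surv = SurvivalTable(
            pd.DataFrame(
                {
                    "time_days": surv.time.to_numpy()[take],
                    "event": surv.event.to_numpy()[take],
                },
                index=sub_ids,
            )
        )
        a = time_dependent_auc(pd.Series(sa.to_numpy()[take], index=sub_ids), sub_surv, horizon_days)
        c = time_dependent_auc(pd.Series(sb.to_numpy()[take], index=sub_ids), sub_surv, horizon_days)
        if np.isnan(a) or np.isnan(c):
            n_redrawn += 1
            if n_redrawn > max_total_redraws:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        diffs[b] = a - c
        b += 1
    if n_redrawn:
        logger.info("bootstrap_auc_compare: redrew %d degenerate replicates", n_redrawn)

    auc_a = time_dependent_auc(sa, surv, horizon_days)
    auc_b = time_dependent_auc(sb, surv, horizon_days)
    ci_low, ci_high = np.percentile(diffs, [2.5, 97.5])
    p = 2.0 * min(float((diffs <= 0).mean()), float((diffs >= 0).mean()))
    p = float(np.clip(p, 1.0 / n_boot, 1.0))
    return BootstrapAUCResult(
        auc_a=auc_a, auc_b=auc_b, diff=auc_a - auc_b,
        ci_low=float(ci_low), ci_high=float(ci_high), p_value=p, n_redrawn=n_redrawn,
    )


def compare_models_paired(auc_matrix: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests between model columns across blocks, BH-adjusted.

    Each pair of model columns is compared with a paired t-test over the
    block rows; p-values are adjusted across all pairs with the
    Benjamini–Hochberg step-up procedure.  Zero-variance differences (e.g.
    identical columns or a constant shift) yield t = 0, p = 1 with a
    warning.
    """
    if len(auc_matrix) < 2:
        raise ValueError("need at least 2 block rows for a paired comparison")
    rows = []
    for a, b in itertools.combinations(auc_matrix.columns, 2):
        d = (auc_matrix[a] - auc_matrix[b]).dropna().to_numpy(dtype=float)
        # a constant shift leaves differences equal up to float cancellation
        if len(d) < 2 or np.allclose(d, d[0], rtol=0.0, atol=1e-12):
            logger.warning("compare_models_paired: zero-variance differences for %s vs %s", a, b)
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(
                auc_matrix[a].dropna(), auc_matrix[b].dropna()
            )
        rows.append({"model_a": a, "model_b": b, "t": float(t), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    out["significant"] = out["p_adjusted"] < 0.05
    return out


@dataclass
class MultivariateResult:
    table: pd.DataFrame | None
    n_dropped: int
    flagged: bool
    message: str = ""


def multivariate_adjustment(
    risk,
    surv: SurvivalTable,
    cutoff: float | None = None,
    dichotomize: bool = True,
) -> MultivariateResult:
    """Multivariate Cox model of survival on the risk score plus covariates.

    By default the score is dichotomized at ``cutoff`` (the training median
    when None), matching how the classifier assigns risk groups; with
    ``dichotomize=False`` the continuous score enters directly.  Rows with
    any missing covariate are dropped (complete case) and counted.  Returns
    a table of hazard ratios with 95% CIs and Wald p-values; separation or
    collinearity problems flag the result instead of raising.
    """
    s = _scores_series(risk).loc[surv.sample_ids]
    if dichotomize:
        if cutoff is None:
            cutoff = float(s.median())
        risk_col = (s > cutoff).astype(float)
        risk_name = "risk_group"
    else:
        risk_col = s.astype(float)
        risk_name = "risk_score"
    df = pd.concat(
        [surv.time.rename("time_days"), surv.event.rename("event"),
         risk_col.rename(risk_name), surv.covariates],
        axis=1,
    )
    n0 = len(df)
    df = df.dropna()
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("multivariate_adjustment: dropped %d incomplete rows", n_dropped)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            cph.fit(df, duration_col="time_days", event_col="event")
    except Exception as exc:
        logger.warning("multivariate_adjustment: flagged fit (%s)", exc)
        return MultivariateResult(table=None, n_dropped=n_dropped, flagged=True,
                                  message=str(exc))
    summ = cph.summary
    table = pd.DataFrame(
        {
            "HR": summ["exp(coef)"],
            "CI_low": summ["exp(coef) lower 95%"],
            "CI_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    return MultivariateResult(table=table, n_dropped=n_dropped, flagged=False)
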