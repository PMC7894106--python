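"""Time-dependent AUC, concordance, rank product and survival statistics."""

import numpy as np
import pandas as pd
import pytest

from mcbsurv.evaluation import (
    bootstrap_auc_compare,
    compare_models_paired,
    concordance_index,
    km_logrank,
    multivariate_adjustment,
    rank_product,
    time_dependent_auc,
)

from conftest import make_surv, simulate_ph_cohort


def _ids(n):
    return [f"s{i}" for i in range(n)]


class TestTimeDependentAuc:
    def test_perfect_separation_gives_one(self):
        # uncensored; every event-before-horizon sample outranks every survivor
        time = np.array([100, 200, 300, 2000, 2500, 3000], dtype=float)
        surv = make_surv(time, np.ones(6, int), _ids(6))
        scores = pd.Series([5.0, 4.0, 3.0, 0.3, 0.2, 0.1], index=_ids(6))
        assert time_dependent_auc(scores, surv, 1826) == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        time = np.array([100, 200, 2000, 3000], dtype=float)
        surv = make_surv(time, np.ones(4, int), _ids(4))
        scores = pd.Series(0.7, index=_ids(4))
        assert time_dependent_auc(scores, surv, 1826) == pytest.approx(0.5)

    def test_no_cases_reported_missing(self):
        surv = make_surv([3000, 4000], [1, 1], _ids(2))
        scores = pd.Series([1.0, 2.0], index=_ids(2))
        assert np.isnan(time_dependent_auc(scores, surv, 1826))

    def test_uncensored_equals_pairwise_fraction(self):
        # small printed cohort; oracle = exhaustive case/control pair count
        time = np.array([50, 120, 400, 800, 900, 1200, 1900, 2100, 2500, 2600, 3100, 4000], dtype=float)
        scores = pd.Series(
            [2.1, 1.4, 1.9, 0.8, 1.1, 0.7, 0.9, 0.5, 1.0, 0.2, 0.4, 0.3],
            index=_ids(12),
        )
        surv = make_surv(time, np.ones(12, int), _ids(12))
        horizon = 1826
        case = time <= horizon
        ctrl = time > horizon
        d = scores.to_numpy()[case][:, None] - scores.to_numpy()[ctrl][None, :]
        oracle = float(((d > 0) + 0.5 * (d == 0)).mean())
        assert time_dependent_auc(scores, surv, horizon) == pytest.approx(oracle)

    def test_matches_ipcw_reference_under_censoring(self, rng):
        # independent estimator: scikit-survival's cumulative/dynamic AUC
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        n = 150
        time = rng.exponential(1200, n)
        event = (rng.random(n) < 0.7).astype(int)
        scores = pd.Series(rng.normal(size=n), index=_ids(n))
        surv = make_surv(time, event, _ids(n))
        y = Surv.from_arrays(event=event.astype(bool), time=time)
        ref, _ = cumulative_dynamic_auc(y, y, scores.to_numpy(), [800.0])
        assert time_dependent_auc(scores, surv, 800.0) == pytest.approx(ref[0], abs=1e-10)

    def test_invariant_under_monotone_score_transform(self, rng):
        n = 80
        time = rng.exponential(1000, n)
        event = (rng.random(n) < 0.8).astype(int)
        scores = pd.Series(rng.normal(size=n), index=_ids(n))
        surv = make_surv(time, event, _ids(n))
        a = time_dependent_auc(scores, surv, 900)
        b = time_dependent_auc(np.exp(scores * 2), surv, 900)
        assert a == pytest.approx(b, abs=1e-12)


class TestConcordance:
    def test_perfect_scores_give_one(self):
        time = np.array([10.0, 20, 30, 40, 50])
        surv = make_surv(time, np.ones(5, int), _ids(5))
        assert concordance_index(pd.Series(-time, index=_ids(5)), surv) == pytest.approx(1.0)

    def test_toy_with_censoring_matches_pair_count(self):
        # n = 5, one censored: exhaustive comparable-pair oracle
        time = np.array([5.0, 10, 15, 20, 25])
        event = np.array([1, 1, 0, 1, 1])
        scores = pd.Series([3.0, 2.5, 1.0, 2.7, 0.5], index=_ids(5))
        surv = make_surv(time, event, _ids(5))
        conc = total = 0.0
        for i in range(5):
            for j in range(5):
                if time[i] < time[j] and event[i] == 1:
                    total += 1
                    if scores.iloc[i] > scores.iloc[j]:
                        conc += 1
                    elif scores.iloc[i] == scores.iloc[j]:
                        conc += 0.5
        assert concordance_index(scores, surv) == pytest.approx(conc / total)

    def test_random_scores_near_half(self):
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 400
            time = r.exponential(1000, n)
            event = (r.random(n) < 0.7).astype(int)
            surv = make_surv(time, event, _ids(n))
            vals.append(concordance_index(pd.Series(r.normal(size=n), index=_ids(n)), surv))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_no_comparable_pairs_missing(self):
        surv = make_surv([100.0, 100.0], [0, 0], _ids(2))
        assert np.isnan(concordance_index(pd.Series([1.0, 2.0], index=_ids(2)), surv))


class TestRankProduct:
    def test_rank_one_everywhere_gives_zero(self):
        tbl = pd.DataFrame({"a": [0.9, 0.5, 0.4], "b": [0.8, 0.6, 0.5]}, index=[1, 2, 3])
        rp = rank_product(tbl)
        assert rp[1] == pytest.approx(0.0)

    def test_natural_log_convention(self):
        tbl = pd.DataFrame({"a": [0.9, 0.8, 0.7], "b": [0.9, 0.8, 0.7]}, index=[1, 2, 3])
        # block 2 has ranks (2, 2) -> RP = ln 2 + ln 2; ranks (2, 3) -> ln 6
        assert rank_product(tbl)[2] == pytest.approx(2 * np.log(2))
        tbl2 = pd.DataFrame({"a": [0.9, 0.8], "b": [0.9, 0.7]}, index=[1, 2])
        tbl2.loc[3] = [0.95, 0.8]
        # block 2: rank 3 in a (0.8 < 0.9 < 0.95), rank 2 in b? construct directly:
        tbl3 = pd.DataFrame({"a": [0.9, 0.8, 0.95], "b": [0.9, 0.75, 0.8]}, index=[1, 2, 3])
        assert rank_product(tbl3)[2] == pytest.approx(np.log(3) + np.log(3))

    def test_ties_get_average_ranks(self):
        tbl = pd.DataFrame({"a": [0.9, 0.9, 0.5]}, index=[1, 2, 3])
        rp = rank_product(tbl)
        assert rp[1] == rp[2] == pytest.approx(np.log(1.5))

    def test_matches_brute_force_and_monotone_invariance(self, rng):
        tbl = pd.DataFrame(
            rng.uniform(0.3, 0.9, size=(12, 4)), index=range(1, 13),
            columns=["c1", "c2", "c3", "c4"],
        )
        rp = rank_product(tbl)
        # brute-force oracle: sort each column descending, positional ranks
        expected = pd.Series(0.0, index=tbl.index)
        for c in tbl.columns:
            order = tbl[c].sort_values(ascending=False)
            ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
            expected += np.log(ranks)
        pd.testing.assert_series_equal(rp, expected.rename("rank_product"))
        # strictly monotone per-column transforms leave RP unchanged
        transformed = tbl.copy()
        transformed["c1"] = np.exp(tbl["c1"])
        transformed["c2"] = tbl["c2"] ** 3
        transformed["c3"] = 10 * tbl["c3"] - 2
        pd.testing.assert_series_equal(rank_product(transformed), rp)

    def test_missing_rows_excluded(self, rng, caplog):
        tbl = pd.DataFrame({"a": [0.9, np.nan, 0.5], "b": [0.8, 0.7, 0.6]}, index=[1, 2, 3])
        with caplog.at_level("INFO"):
            rp = rank_product(tbl)
        assert list(rp.index) == [1, 3]


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        time = np.array([5.0, 10, 15, 20] * 2)
        event = np.array([1, 0, 1, 1] * 2)
        scores = pd.Series([1.0] * 4 + [0.0] * 4, index=_ids(8))
        surv = make_surv(time, event, _ids(8))
        res = km_logrank(scores, surv, 0.5)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_one_sided_cutoff_rejected(self, rng):
        surv = make_surv(rng.uniform(1, 100, 6), np.ones(6, int), _ids(6))
        scores = pd.Series(np.arange(6, dtype=float), index=_ids(6))
        with pytest.raises(ValueError, match="cutoff"):
            km_logrank(scores, surv, 100.0)

    def test_median_cutoff_balances_groups(self, rng):
        n = 31
        scores = pd.Series(rng.normal(size=n), index=_ids(n))
        surv = make_surv(rng.uniform(1, 1000, n), rng.integers(0, 2, n), _ids(n))
        res = km_logrank(scores, surv, float(scores.median()))
        n_high = int(res.labels.sum())
        assert abs(n_high - (n - n_high)) <= 1

    def test_power_under_strong_group_effect(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 200
            group = r.random(n) < 0.5
            rate = np.where(group, 3e-3, 1e-3)  # hazard ratio 3
            time = r.exponential(1.0 / rate)
            event = np.ones(n, int)
            surv = make_surv(time, event, _ids(n))
            scores = pd.Series(group.astype(float), index=_ids(n))
            hits += km_logrank(scores, surv, 0.5).p_value < 0.05
        assert hits >= 18


class TestBootstrapAuc:
    def _cohort(self, rng, n=120):
        x = rng.normal(0.5, 0.1, n)
        time, event = simulate_ph_cohort(rng, x, 6.0)
        surv = make_surv(time, event, _ids(n))
        return pd.Series(x, index=_ids(n)), surv

    def test_self_comparison_centered_at_zero(self, rng):
        s, surv = self._cohort(rng)
        res = bootstrap_auc_compare(s, s, surv, n_boot=100, seed=0)
        assert res.ci_low == res.ci_high == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_deterministic_given_seed(self, rng):
        s, surv = self._cohort(rng)
        noise = pd.Series(np.random.default_rng(5).normal(size=len(s)), index=s.index)
        r1 = bootstrap_auc_compare(s, noise, surv, n_boot=80, seed=11)
        r2 = bootstrap_auc_compare(s, noise, surv, n_boot=80, seed=11)
        assert (r1.ci_low, r1.ci_high, r1.p_value) == (r2.ci_low, r2.ci_high, r2.p_value)

    def test_detects_dominant_model(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 400
            x = r.normal(0.5, 0.1, n)
            time, event = simulate_ph_cohort(r, x, 12.0, censor_frac=0.0)
            surv = make_surv(time, event, _ids(n))
            good = pd.Series(x, index=_ids(n))
            bad = pd.Series(r.normal(size=n), index=_ids(n))
            res = bootstrap_auc_compare(good, bad, surv, n_boot=200, seed=seed)
            hits += res.p_value < 0.05
        assert hits >= 9


class TestComparePaired:
    def test_identical_columns_give_p_one(self, caplog):
        tbl = pd.DataFrame({"a": [0.5, 0.6, 0.7], "b": [0.5, 0.6, 0.7]})
        with caplog.at_level("WARNING"):
            out = compare_models_paired(tbl)
        assert out.loc[0, "t"] == 0.0 and out.loc[0, "p_raw"] == 1.0

    def test_constant_shift_is_degenerate(self, rng):
        a = rng.uniform(0.4, 0.7, 10)
        tbl = pd.DataFrame({"a": a, "b": a + 0.05})
        out = compare_models_paired(tbl)
        assert out.loc[0, "p_raw"] == 1.0  # zero-variance differences convention

    def test_bh_adjustment_matches_step_up_oracle(self, rng):
        cols = {f"m{i}": rng.uniform(0.3, 0.8, 30) + i * 0.01 for i in range(4)}
        out = compare_models_paired(pd.DataFrame(cols))
        p = out["p_raw"].to_numpy()
        # independent step-up oracle
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        prev = 1.0
        for rank_pos in range(m, 0, -1):
            i = order[rank_pos - 1]
            prev = min(prev, p[i] * m / rank_pos)
            adj[i] = prev
        np.testing.assert_allclose(out["p_adjusted"].to_numpy(), adj, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            compare_models_paired(pd.DataFrame({"a": [0.5], "b": [0.6]}))


class TestMultivariate:
    def test_null_covariate_ci_covers_one(self):
        covered = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 500
            x = r.normal(0.5, 0.1, n)
            time, event = simulate_ph_cohort(r, x, 5.0)
            noise = r.normal(size=n)
            surv = make_surv(time, event, _ids(n), covariates={"noise": noise})
            res = multivariate_adjustment(pd.Series(x, index=_ids(n)), surv)
            assert not res.flagged
            row = res.table.loc["noise"]
            covered += row["CI_low"] <= 1.0 <= row["CI_high"]
        assert covered >= 18

    def test_binary_hr2_recovered(self):
        hrs = []
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            n = 500
            g = (r.random(n) < 0.5).astype(float)
            rate = 1e-3 * np.exp(np.log(2) * g)
            time = r.exponential(1.0 / rate)
            event = np.ones(n, int)
            score = r.normal(size=n)  # uninformative risk score alongside
            surv = make_surv(time, event, _ids(n), covariates={"grp": g})
            res = multivariate_adjustment(pd.Series(score, index=_ids(n)), surv)
            hrs.append(res.table.loc["grp", "HR"])
        assert 1.5 < np.median(hrs) < 2.7

    def test_duplicated_covariate_flagged(self, rng):
        n = 100
        x = rng.normal(size=n)
        surv = make_surv(
            rng.exponential(1000, n), rng.integers(0, 2, n), _ids(n),
            covariates={"a": x, "b": x},
        )
        res = multivariate_adjustment(pd.Series(rng.normal(size=n), index=_ids(n)), surv)
        assert res.flagged

    def test_incomplete_covariates_dropped_and_counted(self, rng):
        n = 50
        cov = rng.normal(size=n)
        cov[:5] = np.nan
        surv = make_surv(rng.exponential(1000, n), np.ones(n, int), _ids(n),
                         covariates={"c": cov})
        res = multivariate_adjustment(pd.Series(rng.normal(size=n), index=_ids(n)), surv)
        assert res.n_dropped == 5
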