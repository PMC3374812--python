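import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as ll_logrank

from amplimark.io import validate_clinical
from amplimark.outliers import OutlierConfig, OutlierMatrixPair
from amplimark.survival import (
    cox_binary,
    cox_binary_many,
    cox_fit,
    km_estimate,
    log_rank_test,
    logrank_many,
    outlier_survival_screen,
)


def _clin(times, events, **extra):
    df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(times))],
                       "time": times, "event": events, **extra})
    return validate_clinical(df)


class TestKaplanMeier:
    def test_product_limit_hand_example(self):
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_no_events_gives_flat_curve(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.survival_at(3) == 1.0

    def test_unity_before_first_event(self):
        km = km_estimate([5, 6, 7], [1, 1, 1])
        assert km.survival_at(1) == 1.0

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 200)
        km = km_estimate(t, np.ones_like(t, dtype=int))
        for q in (1.0, 3.0, 7.0):
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_ci_brackets_estimate_and_survival_non_increasing(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 100)
        e = rng.integers(0, 2, 100)
        km = km_estimate(t, e)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert (km.ci_lower <= km.survival + 1e-12).all()
        assert (km.survival <= km.ci_upper + 1e-12).all()

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_give_zero(self):
        stat, p = log_rank_test([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_enumerated_example(self):
        # A: events at 1, 2; B: events at 3, 4 -> chi-square 49/17
        stat, p = log_rank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert stat == pytest.approx(49 / 17, rel=1e-12)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(3, 30), rng.exponential(5, 25)
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 25)
        s1, p1 = log_rank_test(ta, ea, tb, eb)
        s2, p2 = log_rank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_censoring_position_within_event_gap_is_irrelevant(self):
        # a subject censored anywhere strictly between the same two event
        # times sits in exactly the same risk sets
        tb, eb = [3.0, 5.0], [1, 1]
        s1, _ = log_rank_test([1.0, 2.0, 3.5], [1, 1, 0], tb, eb)
        s2, _ = log_rank_test([1.0, 2.0, 4.9], [1, 1, 0], tb, eb)
        assert s1 == pytest.approx(s2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_lifelines_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        ta = np.round(rng.exponential(3, 40), 1)  # rounding creates ties
        tb = np.round(rng.exponential(5, 35), 1)
        ea = rng.integers(0, 2, 40)
        eb = rng.integers(0, 2, 35)
        stat, p = log_rank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            log_rank_test([], [], [1], [1])


class TestCoxBinary:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_lifelines_efron(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        x = rng.integers(0, 2, n)
        t = np.round(rng.exponential(1.0 / (0.1 * np.exp(0.7 * x))), 1) + 0.1
        e = rng.integers(0, 2, n)
        if e.sum() < 5 or x.min() == x.max():
            pytest.skip("degenerate draw")
        res = cox_binary(t, e, x)
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert res["coef"] == pytest.approx(cph.summary.loc["x", "coef"], abs=1e-6)
        assert res["p"] == pytest.approx(cph.summary.loc["x", "p"], rel=1e-4)

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(10)
        n = 1000
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.05 * np.exp(np.log(2) * x)))
        res = cox_binary(t, np.ones(n, dtype=int), x)
        assert 1.8 <= res["hazard_ratio"] <= 2.2

    def test_constant_indicator_raises(self):
        with pytest.raises(ValueError, match="constant"):
            cox_binary([1, 2, 3], [1, 1, 1], [1, 1, 1])

    def test_vectorised_columns_agree_with_single_fits(self):
        rng = np.random.default_rng(4)
        n = 80
        t = rng.exponential(5, n)
        e = rng.integers(0, 2, n)
        member = rng.integers(0, 2, (n, 6))
        beta, se, ll, ll0 = cox_binary_many(t, e, member)
        for j in range(6):
            single = cox_binary(t, e, member[:, j])
            assert single["coef"] == pytest.approx(beta[j], abs=1e-8)


class TestMultivariateCox:
    def test_null_covariate_near_unity(self):
        rng = np.random.default_rng(6)
        n = 1000
        clin = _clin(rng.exponential(10, n), np.ones(n, dtype=int),
                     age=rng.normal(60, 8, n))
        res = cox_fit(clin, ["age"])
        assert res.summary.loc["age", "hazard_ratio"] == pytest.approx(1.0, abs=0.02)

    def test_grade_expands_to_two_indicators(self):
        rng = np.random.default_rng(7)
        n = 300
        grade = rng.choice(["low", "intermediate", "high"], n)
        clin = _clin(rng.exponential(10, n), rng.integers(0, 2, n), grade=grade)
        res = cox_fit(clin, ["grade"])
        assert {"grade_low", "grade_high"} == set(res.summary.index)

    def test_constant_covariate_raises_naming_it(self):
        clin = _clin([1, 2, 3, 4], [1, 1, 1, 0], age=[50, 50, 50, 50])
        with pytest.raises(ValueError, match="age"):
            cox_fit(clin, ["age"])

    def test_hazard_ratio_equals_exp_coef(self):
        rng = np.random.default_rng(8)
        n = 200
        clin = _clin(rng.exponential(10, n), rng.integers(0, 2, n),
                     age=rng.normal(60, 8, n))
        res = cox_fit(clin, ["age"])
        assert res.summary["hazard_ratio"].iloc[0] == pytest.approx(
            np.exp(res.summary["coef"].iloc[0]))


class TestOutlierScreen:
    @staticmethod
    def _pair_from_rows(rows, samples):
        b = pd.DataFrame(rows, columns=samples).astype(np.int8)
        b.index = [f"g{i}" for i in range(len(rows))]
        return OutlierMatrixPair(b_high=b, b_low=b * 0, config=OutlierConfig())

    def test_planted_hazard_gene_retained(self):
        rng = np.random.default_rng(9)
        n = 200
        samples = [f"s{i}" for i in range(n)]
        carriers = np.zeros(n, dtype=int)
        carriers[:30] = 1
        t = rng.exponential(1.0 / (0.05 * np.exp(np.log(5) * carriers)))
        clin = _clin(t, np.ones(n, dtype=int))
        pair = self._pair_from_rows([carriers], samples)
        res = outlier_survival_screen(pair, clin.set_index(pd.Index(samples, name="sample_id")))
        assert len(res) == 1
        assert res.iloc[0]["hazard_ratio"] > 1
        assert res.iloc[0]["p_value"] < 0.05
        assert res.iloc[0]["n_outlier"] == 30

    def test_below_min_outliers_never_tested(self):
        rng = np.random.default_rng(12)
        n = 100
        samples = [f"s{i}" for i in range(n)]
        nine = np.zeros(n, dtype=int)
        nine[:9] = 1  # strong but under-supported signal
        t = rng.exponential(1.0 / (0.05 * np.exp(np.log(50) * nine)))
        clin = _clin(t, np.ones(n, dtype=int)).set_index(pd.Index(samples, name="sample_id"))
        pair = self._pair_from_rows([nine], samples)
        assert outlier_survival_screen(pair, clin).empty

    def test_null_gene_mostly_excluded(self):
        kept = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = 150
            samples = [f"s{i}" for i in range(n)]
            flag = np.zeros(n, dtype=int)
            flag[rng.choice(n, 20, replace=False)] = 1
            clin = _clin(rng.exponential(10, n), np.ones(n, dtype=int))
            clin.index = pd.Index(samples, name="sample_id")
            pair = self._pair_from_rows([flag], samples)
            kept += len(outlier_survival_screen(pair, clin))
        assert kept <= 4  # ~5% type-I rate over 40 null screens

    def test_alignment_mismatch_raises(self):
        clin = _clin([1, 2], [1, 1])
        pair = self._pair_from_rows([[1] * 6 + [0] * 6], [f"x{i}" for i in range(12)])
        with pytest.raises(ValueError, match="missing"):
            outlier_survival_screen(pair, clin, min_outliers=3)
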