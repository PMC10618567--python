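import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from hrdscar.stats import (
    bh_adjust,
    compare_scores_by_alteration,
    component_relation,
    cox_fit,
    cox_univariate_then_multivariable,
    fisher_cooccurrence,
    km_estimate,
    logrank_test,
    roc_auc,
)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.01]) == pytest.approx([0.01])

    def test_step_up_arithmetic(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1)

    def test_order_invariance(self):
        p = [0.001, 0.2, 0.04, 0.9, 0.03]
        perm = [3, 0, 4, 1, 2]
        direct = bh_adjust(p)
        permuted = bh_adjust([p[i] for i in perm])
        assert permuted == pytest.approx([direct[i] for i in perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestGroupComparison:
    def test_pooled_t_matches_textbook_formula(self):
        scores = pd.Series([10, 12, 14, 1, 2, 3], index=list("abcdef"), dtype=float)
        alt = pd.DataFrame({"G": [1, 1, 1, 0, 0, 0]}, index=list("abcdef"))
        res = compare_scores_by_alteration(scores, alt)[0]
        a, w = np.array([10.0, 12, 14]), np.array([1.0, 2, 3])
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(w) - 1) * w.var(ddof=1)) / (len(a) + len(w) - 2)
        t_hand = (a.mean() - w.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(w)))
        assert res.t_stat == pytest.approx(t_hand)
        assert res.direction == "positive"

    def test_identical_groups_give_p_one(self):
        scores = pd.Series([1.0, 2, 3, 1, 2, 3], index=list("abcdef"))
        alt = pd.DataFrame({"G": [1, 1, 1, 0, 0, 0]}, index=list("abcdef"))
        res = compare_scores_by_alteration(scores, alt)[0]
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_small_group_skipped(self):
        scores = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        alt = pd.DataFrame({"G": [1, 0, 0, 0]}, index=list("abcd"))
        assert compare_scores_by_alteration(scores, alt) == []

    def test_null_simulation_false_positive_control(self):
        rng = np.random.default_rng(8)
        n_sig = 0
        n_reps = 40
        for _ in range(n_reps):
            scores = pd.Series(rng.normal(size=60))
            alt = pd.DataFrame(rng.integers(0, 2, size=(60, 20)), columns=[f"g{i}" for i in range(20)])
            results = compare_scores_by_alteration(scores, alt)
            n_sig += sum(r.p_adjusted < 0.05 for r in results)
        assert n_sig / n_reps <= 1.0  # BH keeps expected false positives <= 1 per screen


def fisher_two_sided_exact(a, b, c, d):
    """Point-probability two-sided Fisher p by exact hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, r1)
    probs = {
        k: Fraction(math.comb(c1, k) * math.comb(n - c1, r1 - k), denom)
        for k in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisher:
    def test_perfect_cooccurrence_pair(self):
        alt = pd.DataFrame({"A": [1] * 10 + [0] * 10, "B": [1] * 10 + [0] * 10})
        res = fisher_cooccurrence(alt)[0]
        assert res.direction == "co_occurrence"
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_matches_exact_enumeration_small_margins(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            a, b, c, d = rng.integers(0, 8, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            col1 = [1] * (a + b) + [0] * (c + d)
            col2 = [1] * a + [0] * b + [1] * c + [0] * d
            alt = pd.DataFrame({"A": col1, "B": col2})
            res = fisher_cooccurrence(alt)
            if not res:
                continue
            assert res[0].p_value == pytest.approx(
                fisher_two_sided_exact(int(a), int(b), int(c), int(d)), rel=1e-8
            )

    def test_constant_column_skipped(self):
        alt = pd.DataFrame({"A": [0, 0, 0, 0], "B": [1, 0, 1, 0]})
        assert fisher_cooccurrence(alt) == []

    def test_independent_columns_mostly_null(self):
        rng = np.random.default_rng(10)
        alt = pd.DataFrame(rng.integers(0, 2, size=(80, 8)), columns=[f"g{i}" for i in range(8)])
        res = fisher_cooccurrence(alt)
        assert np.median([r.p_adjusted for r in res]) > 0.5


class TestComponentRelation:
    def test_loh_only_cohort_slope_one(self):
        df = pd.DataFrame({"loh": [0, 1, 2, 3], "tai": 0, "lst": 0})
        df["gi_score"] = df[["loh", "tai", "lst"]].sum(axis=1)
        res = component_relation(df).set_index("component")
        assert res.loc["loh", "slope"] == pytest.approx(1.0)
        assert res.loc["loh", "r_squared"] == pytest.approx(1.0)
        assert "tai" not in res.index  # zero-variance component skipped

    def test_constructed_slope_two(self):
        x = np.arange(10)
        df = pd.DataFrame({"loh": x, "tai": x, "lst": 0})
        df["gi_score"] = df[["loh", "tai", "lst"]].sum(axis=1)
        res = component_relation(df).set_index("component")
        assert res.loc["loh", "slope"] == pytest.approx(2.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"loh": [1], "tai": [0], "lst": [0], "gi_score": [1]})
        with pytest.raises(ValueError, match="at least 3"):
            component_relation(df)


def auc_brute_force(labels, scores):
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        auc, _ = roc_auc([1, 1, 0, 0], [4, 3, 2, 1])
        assert auc == 1.0

    def test_partial_ranking(self):
        # pair counting: pairs (4,3), (4,1), (2,3), (2,1) -> 3 of 4 won
        auc, _ = roc_auc([1, 1, 0, 0], [4, 2, 3, 1])
        assert auc == pytest.approx(auc_brute_force([1, 1, 0, 0], [4, 2, 3, 1])) == 0.75

    def test_matches_pair_counting_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 10, size=40)  # integer scores force ties
            auc, _ = roc_auc(labels, scores)
            assert auc == pytest.approx(auc_brute_force(labels, scores))

    def test_null_is_near_half(self):
        rng = np.random.default_rng(12)
        labels = rng.integers(0, 2, size=1000)
        auc, _ = roc_auc(labels, rng.normal(size=1000))
        assert abs(auc - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1, 1], [1, 2, 3])


def hand_logrank(times_a, times_b):
    """Observed-minus-expected log-rank chi-square, no censoring, from first principles."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    O = E = V = 0.0
    for t in np.unique(np.concatenate([ta, tb])):
        n1, n2 = (ta >= t).sum(), (tb >= t).sum()
        d1, d2 = (ta == t).sum(), (tb == t).sum()
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestSurvival:
    def test_km_equals_empirical_survivor_without_censoring(self):
        rng = np.random.default_rng(13)
        times = rng.exponential(10, size=50).round(1)
        km = km_estimate(times, np.ones_like(times, dtype=int))
        for _, row in km.iterrows():
            assert row["survival"] == pytest.approx((times > row["time"]).mean())

    def test_km_starts_at_one_and_never_increases(self):
        rng = np.random.default_rng(14)
        times = rng.exponential(10, size=50)
        events = rng.integers(0, 2, size=50)
        km = km_estimate(times, events)
        surv = km["survival"].to_numpy()
        assert surv[0] <= 1.0 + 1e-12
        assert np.all(np.diff(surv) <= 1e-12)

    def test_identical_groups_give_zero_statistic(self):
        times = [3.0, 5, 8, 10]
        stat, p = logrank_test(times + times, [1, 1, 1, 1] * 2, [0] * 4 + [1] * 4)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_group_toy_matches_hand_table(self):
        a = [6, 7, 10, 15, 19, 25]
        b = [1, 3, 5, 8, 12, 14]
        stat, _ = logrank_test(a + b, [1] * 12, ["A"] * 6 + ["B"] * 6)
        assert stat == pytest.approx(hand_logrank(a, b), rel=1e-6)


def simulate_ph(rng, n, beta, baseline=0.05, horizon=60.0):
    x = rng.integers(0, 2, size=n)
    t = rng.exponential(1.0 / (baseline * np.exp(beta * x)))
    return pd.DataFrame(
        {"time": np.minimum(t, horizon), "event": (t <= horizon).astype(int), "x": x}
    )


class TestCox:
    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(15)
        df = simulate_ph(rng, 500, beta=0.0)
        fit = cox_fit(df, "time", "event", ["x"]).iloc[0]
        assert abs(fit["coef"]) < 0.2
        assert fit["hr_lower95"] < 1.0 < fit["hr_upper95"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(16)
        df = simulate_ph(rng, 300, beta=0.7)
        fit = cox_fit(df, "time", "event", ["x"]).iloc[0]
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = cox_fit(shuffled, "time", "event", ["x"]).iloc[0]
        assert fit["coef"] == pytest.approx(fit2["coef"], rel=1e-6)

    def test_no_events_is_a_stage_error(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0], "x": [0, 1, 0]})
        with pytest.raises(ValueError, match="no events"):
            cox_fit(df, "time", "event", ["x"])

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 0], "x": [1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, "time", "event", ["x"])

    def test_univariate_screen_feeds_multivariable(self):
        rng = np.random.default_rng(17)
        df = simulate_ph(rng, 600, beta=0.9)
        df["noise"] = rng.normal(size=len(df))
        uni, multi = cox_univariate_then_multivariable(df, "time", "event", ["x", "noise"])
        assert set(uni["variable"]) == {"x", "noise"}
        assert "x" in set(multi["variable"])  # the real effect survives the screen
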