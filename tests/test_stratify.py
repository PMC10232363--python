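import numpy as np
import pandas as pd
import pytest

from nutriscreen import (
    DataError,
    DegenerateSplitError,
    differential_expression,
    km_estimate,
    logrank,
    split_by_score,
    welch_t,
)


class TestSplit:
    def test_median_split_upper_pair_high(self):
        out = split_by_score(list("abcd"), [1, 2, 3, 4]).set_index("sample")["group"]
        assert set(out[out == "high"].index) == {"c", "d"}
        assert set(out[out == "low"].index) == {"a", "b"}

    def test_cohort_of_145_halves_into_72_low_73_high(self):
        rng = np.random.default_rng(0)
        out = split_by_score([f"T{i}" for i in range(145)], rng.normal(size=145),
                             scheme="halves")
        counts = out["group"].value_counts()
        assert counts["high"] == 73 and counts["low"] == 72

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(21)]
        scores = rng.normal(size=21)
        base = split_by_score(samples, scores, scheme="halves").set_index("sample")["group"]
        perm = rng.permutation(21)
        shuffled = split_by_score(
            [samples[i] for i in perm], scores[perm], scheme="halves"
        ).set_index("sample")["group"]
        pd.testing.assert_series_equal(base.sort_index(), shuffled.sort_index())

    def test_median_ties_go_low_by_default_and_high_on_request(self):
        samples = list("abcde")
        scores = [1, 2, 3, 3, 5]  # median = 3
        low_tie = split_by_score(samples, scores).set_index("sample")["group"]
        assert list(low_tie) == ["low", "low", "low", "low", "high"]
        high_tie = split_by_score(samples, scores, tie="high").set_index("sample")["group"]
        assert list(high_tie) == ["low", "low", "high", "high", "high"]

    def test_constant_scores_rejected(self):
        with pytest.raises(DegenerateSplitError):
            split_by_score(list("abcd"), [2, 2, 2, 2])


class TestWelch:
    def test_hand_computed_toy(self):
        t, p = welch_t([1, 2, 3], [4, 5, 6])
        # means 2 vs 5, each variance 1: t = -3 / sqrt(2/3), Welch df = 4
        assert t == pytest.approx(-3.674, abs=1e-3)
        from scipy.stats import t as t_dist

        assert p == pytest.approx(2 * t_dist.sf(3.0 / np.sqrt(2 / 3), 4), rel=1e-9)

    def test_degenerate_zero_variance(self):
        assert welch_t([1, 1], [1, 1]) == (0.0, 1.0)
        t, p = welch_t([1, 1], [2, 2])
        assert t == -np.inf and p < 1e-300


class TestDifferentialExpression:
    @staticmethod
    def groups_for(samples):
        half = len(samples) // 2
        return pd.DataFrame(
            {"sample": samples, "score": 0.0,
             "group": ["high"] * half + ["low"] * (len(samples) - half)}
        )

    def test_identical_groups_are_flat_null(self):
        rng = np.random.default_rng(0)
        block = rng.normal(8, 1, (10, 4))
        expr = pd.DataFrame(np.hstack([block, block]), index=[f"g{i}" for i in range(10)],
                            columns=[f"s{i}" for i in range(8)])
        res = differential_expression(expr, self.groups_for(list(expr.columns)))
        assert np.allclose(res["delta"], 0.0)
        assert np.allclose(res["p_value"], 1.0)

    def test_sign_of_delta_matches_t(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(8, 1, (50, 12)),
                            index=[f"g{i}" for i in range(50)],
                            columns=[f"s{i}" for i in range(12)])
        res = differential_expression(expr, self.groups_for(list(expr.columns)))
        nz = res[res["t_stat"] != 0]
        assert (np.sign(nz["delta"]) == np.sign(nz["t_stat"])).all()

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(8, 1, (30, 10)),
                            index=[f"g{i}" for i in range(30)],
                            columns=[f"s{i}" for i in range(10)])
        groups = self.groups_for(list(expr.columns))
        flipped = groups.assign(group=groups["group"].map({"high": "low", "low": "high"}))
        a = differential_expression(expr, groups).set_index("gene")
        b = differential_expression(expr, flipped).set_index("gene")
        np.testing.assert_allclose(a["delta"], -b.loc[a.index, "delta"], atol=1e-12)
        np.testing.assert_allclose(a["t_stat"], -b.loc[a.index, "t_stat"], atol=1e-12)
        np.testing.assert_allclose(a["p_value"], b.loc[a.index, "p_value"], atol=1e-12)

    def test_shifted_gene_detected_with_power(self):
        """+2 log2 shift at SD 0.5, 8 vs 8: the shifted gene wins nearly always."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(rng.normal(8, 0.5, (50, 16)),
                                index=[f"g{i}" for i in range(50)],
                                columns=[f"s{i}" for i in range(16)])
            expr.iloc[0, :8] += 2.0
            res = differential_expression(expr, self.groups_for(list(expr.columns)))
            top = res.iloc[0]
            if top["gene"] == "g0" and top["q_value"] < 0.01:
                wins += 1
        assert wins >= 95

    def test_small_groups_rejected(self):
        expr = pd.DataFrame(np.zeros((2, 3)), columns=["a", "b", "c"])
        groups = pd.DataFrame({"sample": ["a", "b", "c"], "score": 0,
                               "group": ["high", "low", "low"]})
        with pytest.raises(DataError):
            differential_expression(expr, groups)


def manual_product_limit(times, events):
    """Independent hand-rolled product-limit table for the oracle."""
    order = np.argsort(times)
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    out, s, at_risk = {}, 1.0, len(times)
    for t in np.unique(times):
        d = int(((times == t) & (events == 1)).sum())
        n = int((times >= t).sum())
        if d:
            s *= 1 - d / n
        out[t] = s
    return out


class TestKaplanMeier:
    def test_four_subjects_one_death(self):
        km = km_estimate([1, 2, 3, 4], [1, 0, 0, 0])
        assert km.survival_at(1.0) == pytest.approx(0.75)
        assert km.survival_at(0.5) == pytest.approx(1.0)

    def test_all_censored_curve_is_one(self):
        km = km_estimate([3, 5, 7], [0, 0, 0])
        np.testing.assert_allclose(km.survival, 1.0)

    def test_mixed_six_subject_table_matches_manual_oracle(self):
        times = [1, 2, 2, 3, 5, 6]
        events = [1, 1, 0, 1, 0, 1]
        km = km_estimate(times, events)
        for t, s in manual_product_limit(times, events).items():
            assert km.survival_at(t) == pytest.approx(s, abs=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(10, 40)
        km = km_estimate(times, np.ones(40, int))
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert km.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(DataError):
            km_estimate([-1, 2], [1, 1])


def manual_logrank(times, events, group):
    """Hand-computed O-E and hypergeometric variance tables."""
    times, events = np.asarray(times, float), np.asarray(events, int)
    in_a = np.asarray(group) == "a"
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n, n_a = at_risk.sum(), (at_risk & in_a).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & in_a).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_null(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1] * 2
        group = ["a"] * 4 + ["b"] * 4
        chi2, p = logrank(times, events, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_matches_manual_tables(self):
        rng = np.random.default_rng(11)
        times = np.concatenate([rng.exponential(5, 10), rng.exponential(15, 10)])
        events = (rng.uniform(size=20) < 0.8).astype(int)
        group = np.array(["a"] * 10 + ["b"] * 10)
        chi2, _ = logrank(times, events, group)
        assert chi2 == pytest.approx(manual_logrank(times, events, group), rel=1e-9)

    def test_invariant_under_monotone_time_rescaling(self):
        rng = np.random.default_rng(13)
        times = rng.exponential(10, 30)
        events = (rng.uniform(size=30) < 0.7).astype(int)
        group = np.array(["a", "b"] * 15)
        base = logrank(times, events, group)
        rescaled = logrank(np.sqrt(times), events, group)
        assert base == pytest.approx(rescaled, rel=1e-9)

    def test_zero_events_rejected(self):
        with pytest.raises(DataError):
            logrank([1, 2], [0, 0], ["a", "b"])
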