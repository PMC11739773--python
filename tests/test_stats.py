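"""Statistics: enumeration oracles, Cox recovery, cutoffs, Kaplan-Meier."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from reentry_scout import (
    compare_groups,
    cox_fit,
    kaplan_meier,
    roc_cutoff_at_sensitivity,
    select_multivariable,
)


def _table(values, events, times=None):
    df = pd.DataFrame({"x": values, "event": events})
    df["time_years"] = times if times is not None else np.arange(1.0, len(df) + 1)
    return df


# ---------------------------------------------------------------------
# independent oracles (brute-force enumeration at tiny n)


def mannwhitney_exact_p(g1, g0):
    """Two-sided exact Mann-Whitney p by enumerating all rank splits."""
    pooled = list(g1) + list(g0)
    n1 = len(g1)

    def u_stat(sample1, sample0):
        return sum(
            (a > b) + 0.5 * (a == b) for a in sample1 for b in sample0
        )

    u_obs = u_stat(g1, g0)
    mu = n1 * len(g0) / 2.0
    dev_obs = abs(u_obs - mu)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        s1 = [pooled[i] for i in comb]
        s0 = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if abs(u_stat(s1, s0) - mu) >= dev_obs - 1e-12:
            count += 1
    return count / total


def fisher_exact_p(table):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(a_):
        return (
            math.comb(r1, a_) * math.comb(r2, c1 - a_) / math.comb(n, c1)
        )

    p_obs = prob(a)
    return sum(
        prob(a_)
        for a_ in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(a_) <= p_obs + 1e-12
    )


class TestGroupComparisons:
    def test_mannwhitney_exact_example(self):
        df = _table([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0])
        res = compare_groups(df, "x", "continuous")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.100, abs=1e-9)
        assert res.p_value == pytest.approx(mannwhitney_exact_p([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize("seed", range(6))
    def test_mannwhitney_matches_enumeration_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(2, 5, 2)
        vals = rng.permutation(np.arange(1.0, n1 + n0 + 1))  # distinct ranks
        df = _table(vals, [1] * n1 + [0] * n0)
        res = compare_groups(df, "x", "continuous")
        assert res.p_value == pytest.approx(
            mannwhitney_exact_p(vals[:n1], vals[n1:]), abs=1e-9
        )

    def test_identical_groups_p_one(self):
        df = _table([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        res = compare_groups(df, "x", "continuous")
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_fisher_exact_example(self):
        df = _table([1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0])
        res = compare_groups(df, "x", "categorical")
        assert res.p_value == pytest.approx(0.100, abs=1e-9)
        assert res.p_value == pytest.approx(fisher_exact_p([[3, 0], [0, 3]]))

    @pytest.mark.parametrize(
        "tab", [[[3, 5], [6, 2]], [[1, 9], [4, 4]], [[7, 3], [2, 8]], [[5, 5], [5, 5]]]
    )
    def test_fisher_matches_enumeration(self, tab):
        values = [1] * tab[0][0] + [0] * tab[0][1] + [1] * tab[1][0] + [0] * tab[1][1]
        events = [1] * sum(tab[0]) + [0] * sum(tab[1])
        df = _table(values, events)
        res = compare_groups(df, "x", "categorical")
        assert res.p_value == pytest.approx(fisher_exact_p(tab), abs=1e-9)

    def test_empty_group_rejected(self):
        df = _table([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError):
            compare_groups(df, "x", "continuous")


class TestCox:
    def test_null_covariate_flagged_with_unit_hr(self):
        df = _table([5.0] * 30, [1] * 15 + [0] * 15)
        r = cox_fit(df, ["x"])[0]
        assert r.hazard_ratio == 1.0
        assert r.p_value == 1.0
        assert r.flag == "degenerate"

    def test_two_group_exponential_recovery(self):
        # true HR 2.0, no censoring; closed-form oracle: the rate ratio
        rng = np.random.default_rng(7)
        n = 2000
        grp = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.1 * np.exp(np.log(2.0) * grp)))
        df = pd.DataFrame({"x": grp, "event": 1, "time_years": t})
        r = cox_fit(df, ["x"])[0]
        assert 1.8 <= r.hazard_ratio <= 2.2
        assert r.ci_low <= r.hazard_ratio <= r.ci_high
        rate_ratio = t[grp == 0].mean() / t[grp == 1].mean()
        assert r.hazard_ratio == pytest.approx(rate_ratio, rel=0.10)

    def test_per_ten_rescaling_is_exact_power(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "x": rng.normal(50, 10, 300),
                "event": rng.integers(0, 2, 300),
                "time_years": rng.exponential(2, 300),
            }
        )
        r1 = cox_fit(df, ["x"])[0]
        r10 = cox_fit(df, ["x"], scales={"x": 10.0})[0]
        assert r10.hazard_ratio == pytest.approx(r1.hazard_ratio**10, rel=1e-6)

    def test_multivariable_selection_includes_clinical_covariates(self):
        rng = np.random.default_rng(5)
        n = 300
        strong = rng.normal(size=n)
        noise = rng.normal(size=n)
        lam = 0.2 * np.exp(0.9 * strong)
        df = pd.DataFrame(
            {
                "strong": strong,
                "noise": noise,
                "lvef_pct": rng.normal(32, 8, n),
                "lvedv_ml": rng.normal(220, 50, n),
                "event": 1,
                "time_years": rng.exponential(1 / lam),
            }
        )
        uni, keep = select_multivariable(df, ["strong", "noise"])
        assert "strong" in keep
        assert "lvef_pct" in keep and "lvedv_ml" in keep
        multi = cox_fit(df, keep, mode="multivariable")
        assert {r.variable for r in multi} == set(keep)


class TestRocCutoff:
    def test_ninety_percent_sensitivity_on_ladder(self):
        # events at 1..10; largest t with >= 90% of events above is t = 1
        df = _table(
            list(range(1, 11)) + [0, 0], [1] * 10 + [0, 0]
        )
        assert roc_cutoff_at_sensitivity(df, "x", 0.90) == 1.0

    def test_full_sensitivity_sits_below_min_event(self):
        df = _table([3, 5, 8, 1, 2], [1, 1, 1, 0, 0])
        cut = roc_cutoff_at_sensitivity(df, "x", 1.0)
        assert cut < 3
        ev = df.loc[df.event == 1, "x"]
        assert (ev > cut).mean() == 1.0

    def test_tied_event_values(self):
        df = _table([4, 4, 4, 1, 2], [1, 1, 1, 0, 0])
        cut = roc_cutoff_at_sensitivity(df, "x", 0.90)
        assert cut < 4
        assert (df.loc[df.event == 1, "x"] > cut).mean() == 1.0

    def test_brute_force_largest_valid_threshold(self):
        rng = np.random.default_rng(11)
        vals = rng.integers(0, 20, 30).astype(float)
        ev = rng.integers(0, 2, 30)
        ev[0] = 1
        df = _table(vals, ev)
        cut = roc_cutoff_at_sensitivity(df, "x", 0.80)
        ev_vals = vals[ev == 1]
        assert (ev_vals > cut).mean() >= 0.80
        higher = [t for t in np.unique(vals) if t > cut]
        for t in higher:
            assert (ev_vals > t).mean() < 0.80

    def test_no_events_rejected(self):
        df = _table([1, 2], [0, 0])
        with pytest.raises(ValueError):
            roc_cutoff_at_sensitivity(df, "x", 0.9)


class TestKaplanMeier:
    def test_product_limit_arithmetic(self):
        df = pd.DataFrame(
            {
                "g": [0, 0, 0, 0, 1, 1, 1, 1],
                "event": [1, 1, 0, 0, 1, 1, 0, 0],
                "time_years": [1.0, 2.0, 3.0, 4.0] * 2,
            }
        )
        km = kaplan_meier(df, "g")
        for lab in (0, 1):
            assert km.survival_at(lab, 1.0) == pytest.approx(0.75)
            assert km.survival_at(lab, 2.5) == pytest.approx(0.50)

    def test_identical_groups_logrank_p_one(self):
        df = pd.DataFrame(
            {
                "g": [0] * 4 + [1] * 4,
                "event": [1, 0, 1, 0] * 2,
                "time_years": [1.0, 2.0, 3.0, 4.0] * 2,
            }
        )
        km = kaplan_meier(df, "g")
        assert km.p_value == pytest.approx(1.0, abs=1e-9)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(2.0, 50)
        df = pd.DataFrame(
            {"g": [0] * 50 + [1] * 50, "event": 1,
             "time_years": np.concatenate([t, t])}
        )
        km = kaplan_meier(df, "g")
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            emp = (t > q).mean()
            assert km.survival_at(0, q) == pytest.approx(emp, abs=1e-9)

    def test_logrank_power_under_threefold_hazard(self):
        # groups generated with HR = 3 at n = 200/arm: log-rank should
        # reject at 5% in nearly every replicate
        rng = np.random.default_rng(31)
        hits = 0
        for _ in range(100):
            t0 = rng.exponential(1.0 / 0.2, 200)
            t1 = rng.exponential(1.0 / 0.6, 200)
            c = rng.uniform(0, 8, 400)
            t = np.concatenate([t0, t1])
            df = pd.DataFrame(
                {
                    "g": [0] * 200 + [1] * 200,
                    "event": (t <= c).astype(int),
                    "time_years": np.minimum(t, c),
                }
            )
            if kaplan_meier(df, "g").p_value < 0.05:
                hits += 1
        assert hits >= 95

    def test_single_group_rejected(self):
        df = pd.DataFrame({"g": [0, 0], "event": [1, 0], "time_years": [1.0, 2.0]})
        with pytest.raises(ValueError):
            kaplan_meier(df, "g")
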