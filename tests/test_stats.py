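import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from copulamri import (
    bh_adjust,
    cox_fit,
    kaplan_meier,
    kruskal_wallis,
    logrank_test,
    subtype_indicators,
)

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def kw_oracle(groups):
    """Rank-formula Kruskal-Wallis H with tie correction, written from scratch."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    n = pooled.size
    ranks = np.empty(n)
    s = pooled[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2 + 1
        i = j + 1
    h = 12 / (n * (n + 1)) * sum(
        ranks[k].sum() ** 2 / len(g)
        for k, g in zip(np.split(np.arange(n), np.cumsum([len(g) for g in groups])[:-1]), groups)
    ) - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


def logrank_oracle(time, event, groups):
    """Brute-force observed-minus-expected tally over pooled event times."""
    time, event, groups = map(np.asarray, (time, event, groups))
    levels = sorted(set(groups))
    o_minus_e = np.zeros(len(levels))
    var = np.zeros((len(levels), len(levels)))
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        d = ((time == t) & (event == 1)).sum()
        n = at_risk.sum()
        for a, ga in enumerate(levels):
            na = (at_risk & (groups == ga)).sum()
            da = ((time == t) & (event == 1) & (groups == ga)).sum()
            o_minus_e[a] += da - d * na / n
            for b, gb in enumerate(levels):
                nb = (at_risk & (groups == gb)).sum()
                same = 1.0 if a == b else 0.0
                if n > 1:
                    var[a, b] += d * (na / n) * (same - nb / n) * (n - d) / (n - 1)
    v = o_minus_e[:-1]
    chi2 = float(v @ np.linalg.solve(var[:-1, :-1], v))
    return chi2


def breslow_partial_loglik(beta, time, event, x):
    """Closed-form Breslow partial log-likelihood for a single covariate."""
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        d_idx = np.flatnonzero((time == t) & (event == 1))
        risk = np.flatnonzero(time >= t)
        ll += beta * x[d_idx].sum() - len(d_idx) * math.log(
            np.exp(beta * x[risk]).sum()
        )
    return ll


def simulate_cox(n, true_hr, censor_frac, seed):
    """Exponential survival with a binary covariate of known hazard ratio."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    lam = 0.01 * true_hr**x
    t = rng.exponential(1 / lam)
    c = rng.exponential(1 / (0.01 * censor_frac / (1 - censor_frac))) if censor_frac else np.inf
    c = np.broadcast_to(c, t.shape) if np.isscalar(c) else c
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return pd.DataFrame({"time_days": time, "event": event, "x": x})


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


class TestKruskalWallis:
    def test_identical_groups_null(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_rank_formula_oracle(self):
        groups = [np.array([1.0, 2, 3]), np.array([10.0, 11, 12]), np.array([20.0, 21, 22])]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kw_oracle(groups), abs=1e-10)

    def test_tie_correction_matches_oracle(self, rng):
        groups = [rng.integers(0, 5, 12).astype(float) for _ in range(3)]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kw_oracle(groups), abs=1e-10)

    def test_all_identical_values(self):
        assert kruskal_wallis([[2, 2], [2, 2, 2]]) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestBHAdjust:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_hand_worked_mixed(self):
        # m=4: sorted (0.005,0.01,0.02,0.1) -> (0.02, 0.02, 0.0267, 0.1)
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.1, 0.005, 0.02]),
            [0.02, 0.1, 0.02, 4 * 0.02 / 3],
        )

    def test_single_and_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_never_decreases_and_top_rank_raw(self, rng):
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert adj[np.argmax(p)] == pytest.approx(p.max())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestKaplanMeier:
    def test_no_censoring_product_limit(self):
        curves = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1], ["g"] * 4)
        c = curves["g"]
        np.testing.assert_allclose(c.survival[1:], [0.75, 0.5, 0.25, 0.0])
        assert c.median == 2

    def test_all_censored_flat_curve(self):
        curves = kaplan_meier([5, 6, 7], [0, 0, 0], ["g"] * 3)
        assert (curves["g"].survival == 1.0).all()
        assert math.isnan(curves["g"].median)

    def test_mixed_toy_matches_hand_table(self):
        # times 1,2+,3,4+,5,6 ; events at 1,3,5,6
        # S: t=1 5/6; t=3 5/6*3/4; t=5 5/6*3/4*1/2; t=6 0
        curves = kaplan_meier([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1], ["g"] * 6)
        c = curves["g"]
        s_at = dict(zip(c.times, c.survival))
        assert s_at[1.0] == pytest.approx(5 / 6)
        assert s_at[3.0] == pytest.approx(5 / 6 * 3 / 4)
        assert s_at[5.0] == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)
        assert s_at[6.0] == pytest.approx(0.0)
        assert c.median == 5


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1] * 2
        g = ["a"] * 4 + ["b"] * 4
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_group_toy_matches_tally_oracle(self):
        t = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        e = [1, 1, 1, 1, 0, 1, 1, 1, 1]
        g = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        chi2, _ = logrank_test(t, e, g)
        assert chi2 == pytest.approx(logrank_oracle(t, e, g), abs=1e-10)

    def test_two_group_toy_matches_tally_oracle(self):
        t = [2, 4, 6, 1, 3, 5]
        e = [1, 1, 0, 1, 1, 1]
        g = ["a", "a", "a", "b", "b", "b"]
        chi2, _ = logrank_test(t, e, g)
        assert chi2 == pytest.approx(logrank_oracle(t, e, g), abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1, 2], [0, 0], ["a", "b"])


class TestCoxFit:
    def test_four_subject_toy_matches_1d_partial_likelihood(self):
        df = pd.DataFrame(
            {"time_days": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1],
             "x": [1.0, 0.0, 1.0, 0.0]}
        )
        res = cox_fit(df, ["x"], ties="breslow")
        beta_hat = math.log(res["hazard_ratio"].iloc[0])
        opt = minimize_scalar(
            lambda b: -breslow_partial_loglik(
                b, df["time_days"].to_numpy(), df["event"].to_numpy(), df["x"].to_numpy()
            ),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert beta_hat == pytest.approx(opt.x, abs=1e-6)

    def test_null_covariate_recovery(self):
        df = simulate_cox(500, true_hr=1.0, censor_frac=0.0, seed=42)
        res = cox_fit(df, ["x"])
        assert abs(math.log(res["hazard_ratio"].iloc[0])) < 0.1

    def test_hr2_recovery_with_censoring(self):
        df = simulate_cox(500, true_hr=2.0, censor_frac=0.3, seed=7)
        hr = cox_fit(df, ["x"])["hazard_ratio"].iloc[0]
        assert 1.6 < hr < 2.5

    def test_shift_invariance_of_hr(self):
        df = simulate_cox(200, true_hr=2.0, censor_frac=0.2, seed=3)
        hr1 = cox_fit(df, ["x"])["hazard_ratio"].iloc[0]
        df2 = df.assign(x=df["x"] + 100.0)
        hr2 = cox_fit(df2, ["x"])["hazard_ratio"].iloc[0]
        assert hr1 == pytest.approx(hr2, rel=1e-6)

    def test_time_rescale_invariance_of_hr(self):
        df = simulate_cox(200, true_hr=2.0, censor_frac=0.2, seed=3)
        hr1 = cox_fit(df, ["x"])["hazard_ratio"].iloc[0]
        df2 = df.assign(time_days=df["time_days"] * 365.25)
        hr2 = cox_fit(df2, ["x"])["hazard_ratio"].iloc[0]
        assert hr1 == pytest.approx(hr2, rel=1e-6)

    def test_ci_brackets_hr(self):
        df = simulate_cox(300, true_hr=2.0, censor_frac=0.2, seed=11)
        row = cox_fit(df, ["x"]).iloc[0]
        assert row["ci_low"] <= row["hazard_ratio"] <= row["ci_high"]
        assert row["hazard_ratio"] > 0

    def test_constant_covariate_rejected(self):
        df = simulate_cox(50, 1.0, 0.0, 1).assign(z=1.0)
        with pytest.raises(ValueError, match="constant covariate"):
            cox_fit(df, ["z"])

    def test_univariate_mode_one_model_per_covariate(self):
        df = simulate_cox(100, 2.0, 0.2, 5)
        df["y"] = np.random.default_rng(0).normal(size=100)
        res = cox_fit(df, ["x", "y"], model_type="univariate")
        assert len(res) == 2
        assert (res["model_type"] == "univariate").all()

    def test_missing_covariates_dropped(self):
        df = simulate_cox(100, 2.0, 0.2, 5)
        df.loc[:4, "x"] = np.nan
        res = cox_fit(df, ["x"])
        assert res["n"].iloc[0] == 95


class TestSubtypeIndicators:
    def test_reference_excluded(self):
        labels = pd.Series([1, 2, 3, 2], index=list("abcd"))
        ind = subtype_indicators(labels, reference=2)
        assert list(ind.columns) == ["subtype_1", "subtype_3"]
        assert ind.loc["a", "subtype_1"] == 1
        assert ind.loc["b"].sum() == 0

    def test_bad_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            subtype_indicators(pd.Series([1, 2]), reference=9)
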