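"""Cox screens, tertile dichotomization, KM/log-rank and paired Wilcoxon."""

import itertools

import numpy as np
import pandas as pd
import pytest

from serialdex import (
    cox_fit,
    dichotomize_tertile,
    km_estimate,
    logrank_test,
    rfs_screen_matrix,
    screen_rfs,
    wilcoxon_signed_rank,
)


# --------------------------- Cox proportional hazards ----------------------

def breslow_loglik(beta, x, time, event):
    """Independent O(n^2) Breslow partial log-likelihood for one covariate."""
    x, time, event = map(np.asarray, (x, time, event))
    ll = float(beta * x[event == 1].sum())
    for tt in np.unique(time[event == 1]):
        d = int(((time == tt) & (event == 1)).sum())
        ll -= d * np.log(np.exp(beta * x[time >= tt]).sum())
    return ll


def grid_maximizer(x, time, event, lo=-5, hi=5, step=1e-4):
    grid = np.arange(lo, hi + step, step)
    ll = np.array([breslow_loglik(b, x, time, event) for b in grid])
    return grid[np.argmax(ll)]


@pytest.mark.parametrize("seed", [0, 1])
def test_cox_matches_grid_search_oracle(seed):
    """Newton-Raphson maximizer agrees with a brute-force grid search, n <= 8."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(8)
    time = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])  # includes a tie
    event = np.array([1, 1, 1, 0, 1, 0, 1, 1])
    res = cox_fit(x, time, event, min_n=5, min_events=2)
    beta_grid = grid_maximizer(x, time, event)
    assert abs(res.beta - beta_grid) <= 1e-3
    # LR statistic recomputed from the oracle likelihood
    lr = 2 * (breslow_loglik(res.beta, x, time, event) - breslow_loglik(0.0, x, time, event))
    assert res.lr_statistic == pytest.approx(lr, abs=1e-6)


def test_cox_matches_lifelines_without_ties(rng):
    """On tie-free data Breslow equals Efron, so lifelines is an independent check."""
    from lifelines import CoxPHFitter

    n = 60
    x = rng.standard_normal(n)
    time = rng.exponential(scale=np.exp(-0.5 * x)) + rng.uniform(0, 1e-6, n)
    event = (rng.random(n) < 0.7).astype(int)
    event[:3] = 1
    res = cox_fit(x, time, event)
    cph = CoxPHFitter().fit(pd.DataFrame({"x": x, "T": time, "E": event}), "T", "E")
    assert res.beta == pytest.approx(float(cph.params_["x"]), abs=1e-4)
    assert res.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)


def test_cox_degenerate_contracts():
    t = np.arange(1.0, 11.0)
    e = np.ones(10)
    res = cox_fit(np.ones(10), t, e)
    assert (res.beta, res.lr_statistic, res.lr_p) == (0.0, 0.0, 1.0)
    assert res.degenerate
    res = cox_fit(np.arange(10.0), t, np.zeros(10))  # no events
    assert res.beta == 0.0 and res.degenerate


def test_cox_adjustment_changes_the_nested_comparison(rng):
    """The LR test compares nested models that both keep the adjustment term."""
    n = 80
    hr = (rng.random(n) < 0.5).astype(float)
    x = rng.standard_normal(n) + hr
    time = rng.exponential(scale=np.exp(-0.8 * hr - 0.0 * x))
    event = np.ones(n)
    adj = pd.DataFrame({"hr_positive": hr})
    res_adj = cox_fit(x, time, event, adjust=adj)
    res_raw = cox_fit(x, time, event)
    assert res_adj.adjusted_for == ("hr_positive",)
    # x only proxies hr; adjusting for hr should shrink the LR statistic
    assert res_adj.lr_statistic < res_raw.lr_statistic


def test_screen_rfs_continues_past_failures(cohort, rng):
    expr, meta, truth, norm = cohort
    values, t, e, hrdf = rfs_screen_matrix(norm, meta, "ts")
    values = values.iloc[:10].copy()
    values.iloc[0] = 1.0  # constant feature -> degenerate row, not a crash
    out = screen_rfs(values, t, e)
    assert out.loc[values.index[0], "lr_p"] == 1.0
    assert out["lr_p"].notna().sum() >= 9


def test_ts_screens_exclude_patients_without_residual_disease(cohort):
    expr, meta, truth, norm = cohort
    from serialdex.cohort import residual_disease_patients

    eligible = set(residual_disease_patients(meta))
    for mode in ("ts", "delta_ts"):
        values, t, e, hrdf = rfs_screen_matrix(norm, meta, mode)
        assert set(values.columns) <= eligible
    values, _, _, _ = rfs_screen_matrix(norm, meta, "t1")
    assert not set(values.columns) <= eligible  # T1 screen keeps responders


# --------------------------- tertiles, KM, log-rank ------------------------

def test_tertile_examples():
    v = pd.Series(range(1, 10), index=list("abcdefghi"))
    top = dichotomize_tertile(v, "top_vs_rest")
    assert set(v[top == "high"]) == {7, 8, 9}
    low = dichotomize_tertile(v, "bottom_vs_rest")
    assert set(v[low == "low"]) == {1, 2, 3}


def test_tertile_ties_are_deterministic():
    v = pd.Series([1, 2, 2, 2, 3, 4])
    top = dichotomize_tertile(v, "top_vs_rest")  # cut at 2.33: ties below stay in rest
    assert list(v[top == "high"]) == [3, 4]
    with pytest.raises(ValueError, match="distinct"):
        dichotomize_tertile(pd.Series([5.0, 5.0, 5.0]))


def test_km_without_censoring_is_one_minus_ecdf(rng):
    curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
    np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
    t = rng.exponential(size=25)
    curve = km_estimate(t, np.ones(25))
    ecdf = np.searchsorted(np.sort(t), curve.times, side="right") / t.size
    np.testing.assert_allclose(curve.survival, 1 - ecdf, atol=1e-12)


def logrank_oracle(time, event, group):
    """Hand computation over the 2x2 tables at each event time: (O-E)^2/V."""
    time, event, group = map(np.asarray, (time, event, group))
    O = E = V = 0.0
    for tt in np.unique(time[event == 1]):
        at_risk = time >= tt
        n, n1 = at_risk.sum(), (at_risk & (group == 1)).sum()
        d = ((time == tt) & (event == 1)).sum()
        d1 = ((time == tt) & (event == 1) & (group == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def test_logrank_identical_groups_is_null():
    chi2, p = logrank_test([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1], list("aaabbb"))
    assert (chi2, p) == (0.0, 1.0)


def test_logrank_matches_hand_oracle_on_six_subjects():
    time = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
    event = [1, 1, 1, 1, 0, 1]
    group = [0, 0, 0, 1, 1, 1]
    chi2, p = logrank_test(time, event, group)
    assert chi2 == pytest.approx(logrank_oracle(time, event, group), abs=1e-10)


def test_logrank_input_contracts():
    with pytest.raises(ValueError, match="2 groups"):
        logrank_test([1, 2], [1, 1], ["a", "a"])
    with pytest.raises(ValueError, match="event"):
        logrank_test([1, 2], [0, 0], ["a", "b"])


# --------------------------- Wilcoxon signed-rank --------------------------

def signed_rank_brute_force_p(d):
    """Enumerate the 2^n sign vectors of the rank sum (handles ties)."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = np.array([
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product([-1, 1], repeat=d.size)
    ], dtype=float)
    p_ge = (sums >= w_obs - 1e-12).mean()
    p_le = (sums <= w_obs + 1e-12).mean()
    return min(1.0, 2 * min(p_ge, p_le))


def test_wilcoxon_examples_and_symmetry():
    assert wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)
    w, p = wilcoxon_signed_rank(np.zeros(5), [1.0, 2.0, 3.0, 4.0, 5.0])
    assert (w, p) == (15.0, pytest.approx(2 / 32))
    _, p_swapped = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0], np.zeros(5))
    assert p_swapped == pytest.approx(p)


@pytest.mark.parametrize("d", [(1.0, 1.0, 2.0), (1.0, -2.0, 3.0, 3.0, -0.5, 4.0)])
def test_wilcoxon_exact_null_matches_enumeration(d):
    _, p = wilcoxon_signed_rank(np.zeros(len(d)), d)
    assert p == pytest.approx(signed_rank_brute_force_p(np.asarray(d)))
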