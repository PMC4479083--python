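"""Paired and two-group permutation tests and the BH step-up."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from serialdex import (
    ExpressionMatrix,
    bh_adjust,
    paired_permutation_test,
    run_contrast,
    two_group_permutation_test,
    validate_sample_meta,
)


def _paired_t(d):
    d = np.asarray(d, dtype=float)
    return d.mean() / (d.std(ddof=1) / np.sqrt(d.size))


def brute_force_paired_p(d):
    """Enumerate all 2^n sign assignments of the differences (oracle)."""
    d = np.asarray(d, dtype=float)
    t_obs = abs(_paired_t(d))
    hits = total = 0
    for signs in itertools.product([-1, 1], repeat=d.size):
        total += 1
        if abs(_paired_t(np.array(signs) * d)) >= t_obs - 1e-12:
            hits += 1
    return hits / total


def _welch(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return (x.mean() - y.mean()) / np.sqrt(x.var(ddof=1) / x.size + y.var(ddof=1) / y.size)


def brute_force_two_group_p(values, n1):
    """Enumerate all C(n, n1) group-1 index sets (oracle)."""
    values = np.asarray(values, dtype=float)
    idx = set(range(n1))
    t_obs = abs(_welch(values[list(idx)], values[[i for i in range(values.size) if i not in idx]]))
    hits = total = 0
    for comb in itertools.combinations(range(values.size), n1):
        rest = [i for i in range(values.size) if i not in comb]
        total += 1
        if abs(_welch(values[list(comb)], values[rest])) >= t_obs - 1e-12:
            hits += 1
    return hits / total


def test_paired_degenerate_all_zero_differences():
    res = paired_permutation_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert (res.t, res.p) == (0.0, 1.0)


def test_paired_exhaustive_small_example():
    """d = (1,2,3): only the all-plus and all-minus sign vectors reach |t_obs|."""
    res = paired_permutation_test([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], n_perm=10_000)
    assert res.exhaustive and res.n_perm_total == 8
    assert res.p == pytest.approx(2 / 8)
    assert res.t == pytest.approx(_paired_t([1, 2, 3]))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_paired_exhaustive_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    d = rng.standard_normal(9)
    res = paired_permutation_test(np.zeros(9), d, n_perm=4096)
    assert res.exhaustive
    assert res.p == pytest.approx(brute_force_paired_p(d))


def test_paired_monte_carlo_close_to_exhaustive():
    rng = np.random.default_rng(5)
    d = rng.standard_normal(11) + 0.5
    exact = paired_permutation_test(np.zeros(11), d, n_perm=4096).p
    mc = paired_permutation_test(np.zeros(11), d, n_perm=2000, seed=7)
    assert not mc.exhaustive
    assert abs(mc.p - exact) < 2 / math.sqrt(2000)


def test_paired_requires_three_pairs_and_drops_missing():
    with pytest.raises(ValueError, match=">= 3"):
        paired_permutation_test([1.0, 2.0], [2.0, 3.0])
    res = paired_permutation_test([0, 0, 0, np.nan], [1.0, 2.0, 3.0, 9.0])
    assert res.n == 3 and res.n_perm_total == 8


@given(st.lists(st.floats(-5, 5), min_size=4, max_size=10))
@settings(max_examples=40, deadline=None)
def test_paired_sign_symmetry_and_granularity(diffs):
    """Negating the data negates t, leaves p unchanged; p*total is an integer >= 1."""
    d = np.asarray(diffs)
    a = np.zeros_like(d)
    r1 = paired_permutation_test(a, d, n_perm=512, seed=3)
    r2 = paired_permutation_test(a, -d, n_perm=512, seed=3)
    assert r1.p == r2.p
    assert r1.t == pytest.approx(-r2.t, nan_ok=True)
    k = r1.p * r1.n_perm_total
    assert k >= 1 and k == pytest.approx(round(k))


def test_two_group_degenerate_identical_groups():
    res = two_group_permutation_test([1.0, 2.0, 1.0, 2.0], ["A", "A", "B", "B"])
    assert (res.t, res.p) == (0.0, 1.0)


def test_two_group_exhaustive_small_example():
    """(0,0) vs (5,5): 2 of the 6 label splits reach |t_obs|."""
    res = two_group_permutation_test([0.0, 0.0, 5.0, 5.0], ["A", "A", "B", "B"], n_perm=100)
    assert res.exhaustive and res.n_perm_total == 6
    assert res.p == pytest.approx(2 / 6)


@pytest.mark.parametrize("seed", [3, 4])
def test_two_group_exhaustive_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    values = rng.standard_normal(9)
    labels = ["A"] * 4 + ["B"] * 5
    res = two_group_permutation_test(values, labels, n_perm=200)
    assert res.exhaustive
    assert res.p == pytest.approx(brute_force_two_group_p(values, 4))


def test_two_group_requires_two_per_group():
    with pytest.raises(ValueError, match=">= 2"):
        two_group_permutation_test([1.0, 2.0, 3.0], ["A", "B", "B"])


def test_bh_matches_hand_step_up_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])


def step_up_oracle(p):
    """Direct BH step-up: q_(i) = p_(i) m/i, then cumulative min from the right."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


@pytest.mark.parametrize("seed", range(5))
def test_bh_equals_oracle_on_random_vectors(seed, rng):
    rng = np.random.default_rng(seed)
    p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 200))
    np.testing.assert_allclose(bh_adjust(p), step_up_oracle(p), atol=1e-12)


def test_bh_order_equivariance_missing_and_validation(rng):
    p = rng.uniform(0.001, 1.0, size=50)
    perm = rng.permutation(50)
    np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))
    with_na = np.r_[p[:10], np.nan]
    out = bh_adjust(with_na)
    assert np.isnan(out[-1]) and not np.isnan(out[:10]).any()
    np.testing.assert_allclose(out[:10], bh_adjust(p[:10]))  # NaN excluded from m
    with pytest.raises(ValueError):
        bh_adjust([0.0, 0.5])
    with pytest.raises(ValueError):
        bh_adjust([1.5])


def test_bh_threshold_recovers_step_up_rejection_set(rng):
    """Thresholding adjusted p at q rejects exactly the BH step-up set."""
    p = rng.uniform(0.0001, 1.0, size=300) ** 2
    q = 0.05
    adj = bh_adjust(p)
    m = p.size
    srt = np.sort(p)
    ks = np.nonzero(srt <= q * np.arange(1, m + 1) / m)[0]
    cutoff = srt[ks.max()] if ks.size else 0.0
    assert set(np.nonzero(adj <= q)[0]) == set(np.nonzero(p <= cutoff)[0])


def _tiny_cohort(delta_by_group):
    """Six patients with T1/T2 pairs; RCB 0/0/0 vs II/II/II."""
    rows, cols = [], {}
    rng = np.random.default_rng(0)
    base = rng.standard_normal((5, 6))
    for i in range(6):
        rcb = "0" if i < 3 else "II"
        for tp in ("T1", "T2"):
            sid = f"P{i}_{tp}"
            rows.append({"sample_id": sid, "patient_id": f"P{i}", "timepoint": tp, "batch": "B1", "rcb": rcb})
            shift = 0.0 if tp == "T1" else delta_by_group[rcb]
            cols[sid] = base[:, i] + shift
    meta = validate_sample_meta(pd.DataFrame(rows))
    expr = ExpressionMatrix(pd.DataFrame(cols, index=[f"g{j}" for j in range(5)]), level="gene")
    return expr, meta


def test_delta_contrast_identical_shift_in_both_groups_is_null():
    """If every patient changes by the same amount, the delta contrast calls nothing."""
    expr, meta = _tiny_cohort({"0": 2.0, "II": 2.0})
    res = run_contrast(expr, meta, "rcb_delta_t2", n_perm=200, seed=0)
    assert len(res.significant) == 0
    assert (res.table["raw_p"] == 1.0).all()  # deltas are constant across patients


def test_run_contrast_errors_and_metadata():
    expr, meta = _tiny_cohort({"0": 0.0, "II": 0.0})
    with pytest.raises(ValueError, match="unknown contrast"):
        run_contrast(expr, meta, "nope")
    res = run_contrast(expr, meta, "t1_vs_t2", n_perm=100, seed=1)
    assert res.threshold_rule.startswith("adjusted")
    assert {"t", "raw_p", "adjusted_p", "direction", "n"} <= set(res.table.columns)
    assert (res.table["n"] == 6).all()


def test_ts_contrasts_restricted_to_residual_disease(cohort):
    """Patients without residual disease (RCB 0) never enter TS-based contrasts."""
    expr, meta, truth, norm = cohort
    res = run_contrast(norm, meta, "t1_vs_ts", n_perm=50, seed=0)
    from serialdex.cohort import residual_disease_patients

    n_eligible_pairs = len(
        set(residual_disease_patients(meta))
        & set(meta.loc[meta["timepoint"] == "TS", "patient_id"])
        & set(meta.loc[meta["timepoint"] == "T1", "patient_id"])
    )
    assert (res.table["n"] == n_eligible_pairs).all()
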