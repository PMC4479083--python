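"""Per-feature association with recurrence-free survival.

The screen fits, for every feature, a Cox proportional-hazards model with
the feature's expression (or its change between two time points) as a
continuous covariate, optionally adjusted for hormone-receptor status.  The
partial likelihood is maximized by Newton-Raphson with Breslow tie handling
(Efron selectable), and the reported p-value is the likelihood-ratio test of
the feature against the nested model without it (adjustment covariates
retained in both) on 1 degree of freedom.  Screens of the surgical time
point (TS, TS - T1) include only patients with residual disease.

Also provided: tertile dichotomization for illustrating associations with
Kaplan-Meier curves, the product-limit estimator and two-group log-rank test
(via lifelines), and the paired Wilcoxon signed-rank test with an exact
sign-enumeration null for small samples.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .cohort import patient_table, residual_disease_patients, timepoint_matrix, delta_matrix
from .datamodel import ExpressionMatrix


@dataclasses.dataclass
class SurvResult:
    """Cox fit of one feature: log hazard ratio per expression unit + LR test."""

    feature_id: str
    beta: float
    se: float
    lr_statistic: float
    lr_p: float
    n: int
    n_events: int
    adjusted_for: tuple[str, ...] = ()
    converged: bool = True
    degenerate: bool = False


@dataclasses.dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    label: str
    times: np.ndarray         # event/censor times in the step function
    survival: np.ndarray      # S(t) just after each time
    at_risk: np.ndarray       # numbers at risk just before each time
    n: int
    n_events: int


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow / Efron), Newton-Raphson
# ---------------------------------------------------------------------------

def _cox_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray, ties: str):
    """Partial log-likelihood, gradient and information at ``beta``.

    Rows must be sorted by ascending time.  Tied event times form one group;
    Breslow uses the full risk-set sum for every tied event, Efron
    downweights the tied events' own contributions progressively.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -700, 700)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # suffix sums over the risk set {j : time_j >= t}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        dead = [k for k in range(i, j) if event[k] == 1]
        d = len(dead)
        if d:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            if ties == "breslow":
                ll += eta[dead].sum() - d * np.log(s0)
                U += X[dead].sum(axis=0) - d * s1 / s0
                I += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
            else:  # efron
                wd = w[dead].sum()
                wxd = wx[dead].sum(axis=0)
                wxxd = wxx[dead].sum(axis=0)
                ll += eta[dead].sum()
                U += X[dead].sum(axis=0)
                for r in range(d):
                    f = r / d
                    s0r = s0 - f * wd
                    s1r = s1 - f * wxd
                    s2r = s2 - f * wxxd
                    ll -= np.log(s0r)
                    U -= s1r / s0r
                    I += s2r / s0r - np.outer(s1r, s1r) / s0r**2
        i = j
    return ll, U, I


def _cox_newton(X, time, event, ties="breslow", max_iter=100, tol=1e-9):
    """Newton-Raphson with step halving; returns (beta, cov, ll, converged)."""
    order = np.argsort(time, kind="stable")
    X, time, event = X[order], time[order], event[order]
    p = X.shape[1]
    beta = np.zeros(p)
    ll, U, I = _cox_loglik(beta, X, time, event, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll, new_U, new_I = _cox_loglik(new_beta, X, time, event, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step /= 2
            new_beta = beta + step
            new_ll, new_U, new_I = _cox_loglik(new_beta, X, time, event, ties)
            halvings += 1
        if not np.isfinite(new_ll):
            break
        improved = new_ll - ll
        beta, ll, U, I = new_beta, new_ll, new_U, new_I
        if abs(improved) < tol and np.abs(U).max() < 1e-6:
            converged = True
            break
        if np.abs(beta).max() > 50:  # monotone likelihood / separation
            break
    try:
        cov = np.linalg.inv(I)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, ll, converged


def cox_fit(
    x: Sequence[float],
    rfs_time: Sequence[float],
    rfs_event: Sequence[int],
    adjust: pd.DataFrame | np.ndarray | None = None,
    ties: str = "breslow",
    feature_id: str = "",
    min_n: int = 10,
    min_events: int = 3,
    max_iter: int = 100,
) -> SurvResult:
    """Cox PH fit of one continuous covariate with a likelihood-ratio test.

    The LR statistic compares the model with the covariate to the nested
    model without it; ``adjust`` covariates (e.g. an HR-status indicator)
    are retained in both models.  Rows with missing values are dropped.
    Degenerate inputs follow the stated contracts: a constant covariate or a
    dataset with no events gives ``beta = 0, lr_p = 1`` flagged degenerate;
    non-convergence yields a flagged result with missing ``beta``.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(rfs_time, dtype=float)
    event = np.asarray(rfs_event, dtype=float)
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    adj_names: tuple[str, ...] = ()
    if adjust is not None:
        adjust = pd.DataFrame(adjust)
        adj_names = tuple(str(c) for c in adjust.columns)
        A = adjust.to_numpy(dtype=float)
    else:
        A = np.empty((x.size, 0))
    keep = ~(np.isnan(x) | np.isnan(time) | np.isnan(event) | np.isnan(A).any(axis=1))
    x, time, event, A = x[keep], time[keep], event[keep], A[keep]
    n, n_events = int(x.size), int(event.sum())
    if n < min_n:
        raise ValueError(f"need >= {min_n} complete observations, got {n}")
    if n_events == 0 or np.ptp(x) == 0:
        return SurvResult(feature_id, 0.0, np.nan, 0.0, 1.0, n, n_events, adj_names, True, True)
    if n_events < min_events:
        raise ValueError(f"need >= {min_events} events, got {n_events}")

    X_full = np.column_stack([x, A])
    beta_f, cov_f, ll_f, conv_f = _cox_newton(X_full, time, event, ties, max_iter)
    if A.shape[1]:
        _, _, ll_r, conv_r = _cox_newton(A, time, event, ties, max_iter)
    else:
        order = np.argsort(time, kind="stable")
        ll_r, _, _ = _cox_loglik(np.zeros(1), X_full[order][:, :1], time[order], event[order], ties)
        conv_r = True
    if not (conv_f and conv_r):
        return SurvResult(feature_id, np.nan, np.nan, np.nan, np.nan, n, n_events, adj_names, False, False)
    lr = max(0.0, 2.0 * (ll_f - ll_r))
    lr_p = float(stats.chi2.sf(lr, df=1))
    lr_p = min(max(lr_p, np.nextafter(0, 1)), 1.0)
    return SurvResult(
        feature_id=feature_id,
        beta=float(beta_f[0]),
        se=float(np.sqrt(cov_f[0, 0])) if np.isfinite(cov_f[0, 0]) else np.nan,
        lr_statistic=float(lr),
        lr_p=lr_p,
        n=n,
        n_events=n_events,
        adjusted_for=adj_names,
        converged=True,
    )


def screen_rfs(
    values: pd.DataFrame,
    rfs_time: pd.Series,
    rfs_event: pd.Series,
    adjust: pd.DataFrame | None = None,
    threshold: float = 0.005,
    ties: str = "breslow",
    min_n: int = 10,
    min_events: int = 3,
) -> pd.DataFrame:
    """Per-feature Cox screen at a relaxed raw threshold (default p < 0.005).

    ``values`` is features x patients; ``rfs_time`` / ``rfs_event`` are
    patient-indexed.  Returns a DataFrame with one row per feature (beta,
    se, lr_statistic, lr_p, n, n_events, significant, direction); rows whose
    fit fails carry NaN and the screen continues.  ``direction`` is
    ``"reduced_rfs"`` when high expression increases hazard (beta > 0).
    """
    patients = list(values.columns)
    t = rfs_time[patients].to_numpy(dtype=float)
    e = rfs_event[patients].to_numpy(dtype=float)
    A = adjust.loc[patients] if adjust is not None else None
    rows = []
    for fid, row in values.iterrows():
        try:
            res = cox_fit(
                row.to_numpy(dtype=float), t, e, adjust=A, ties=ties,
                feature_id=str(fid), min_n=min_n, min_events=min_events,
            )
            rows.append(
                {
                    "feature_id": fid, "beta": res.beta, "se": res.se,
                    "lr_statistic": res.lr_statistic, "lr_p": res.lr_p,
                    "n": res.n, "n_events": res.n_events,
                    "converged": res.converged, "degenerate": res.degenerate,
                }
            )
        except (ValueError, np.linalg.LinAlgError):
            rows.append(
                {
                    "feature_id": fid, "beta": np.nan, "se": np.nan,
                    "lr_statistic": np.nan, "lr_p": np.nan,
                    "n": 0, "n_events": 0, "converged": False, "degenerate": False,
                }
            )
    out = pd.DataFrame(rows).set_index("feature_id")
    out["significant"] = out["lr_p"] < threshold
    out["direction"] = np.where(
        out["beta"].isna(), "", np.where(out["beta"] > 0, "reduced_rfs", "improved_rfs")
    )
    return out


def rfs_screen_matrix(
    expr: ExpressionMatrix, meta: pd.DataFrame, mode: str
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Assemble the patient-level inputs of one RFS screen.

    ``mode``: ``"t1"`` (pretreatment expression), ``"ts"`` (residual tumor)
    or ``"delta_ts"`` (TS - T1 change).  TS-based modes include only
    patients with residual disease.  Returns (values, rfs_time, rfs_event,
    hr_indicator) aligned on patients with RFS data.
    """
    if mode not in ("t1", "ts", "delta_ts"):
        raise ValueError(f"mode must be 't1', 'ts' or 'delta_ts', got {mode!r}")
    if mode == "t1":
        mat = timepoint_matrix(expr, meta, "T1")
    elif mode == "ts":
        mat = timepoint_matrix(expr, meta, "TS")
    else:
        mat = delta_matrix(expr, meta, "T1", "TS")
    if mode != "t1":
        eligible = set(residual_disease_patients(meta))
        mat = mat.loc[:, [p for p in mat.columns if p in eligible]]
    per = patient_table(meta)
    per = per.loc[[p for p in mat.columns if p in per.index]]
    has_rfs = ~(per["rfs_time"].isna() | per["rfs_event"].isna())
    patients = per.index[has_rfs.to_numpy(dtype=bool)].tolist()
    mat = mat.loc[:, patients]
    hr = pd.DataFrame(
        {"hr_positive": (per.loc[patients, "hr_status"] == "positive").astype(float)},
        index=patients,
    )
    return mat, per.loc[patients, "rfs_time"], per.loc[patients, "rfs_event"], hr


# ---------------------------------------------------------------------------
# Dichotomization and Kaplan-Meier machinery
# ---------------------------------------------------------------------------

def dichotomize_tertile(values: Sequence[float], direction: str = "top_vs_rest") -> pd.Series:
    """Split values at an empirical tertile for survival illustration.

    ``top_vs_rest`` labels values >= the 2/3 linear-interpolated quantile
    ``"high"`` and the rest ``"rest"``; ``bottom_vs_rest`` labels values <=
    the 1/3 quantile ``"low"``.  Ties with the cutoff all fall on the
    extreme-group side (deterministic).  All-equal input has no tertile and
    is an error.
    """
    if direction not in ("top_vs_rest", "bottom_vs_rest"):
        raise ValueError(f"direction must be 'top_vs_rest' or 'bottom_vs_rest', got {direction!r}")
    v = pd.Series(values, dtype=float)
    finite = v.dropna()
    if finite.nunique() < 3:
        raise ValueError("need >= 3 distinct values to form tertiles")
    if direction == "top_vs_rest":
        cut = float(np.quantile(finite, 2 / 3, method="linear"))
        labels = np.where(v >= cut, "high", "rest")
    else:
        cut = float(np.quantile(finite, 1 / 3, method="linear"))
        labels = np.where(v <= cut, "low", "rest")
    out = pd.Series(labels, index=v.index)
    out[v.isna()] = np.nan
    return out


def km_estimate(rfs_time: Sequence[float], rfs_event: Sequence[int], label: str = "") -> KMCurve:
    """Product-limit (Kaplan-Meier) estimate of the survival function."""
    t = np.asarray(rfs_time, dtype=float)
    e = np.asarray(rfs_event, dtype=float)
    if t.size == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and kmf.event_table["observed"].iloc[0] == 0 and kmf.event_table["censored"].iloc[0] == 0 else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        label=label,
        times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=float),
        n=int(t.size),
        n_events=int(e.sum()),
    )


def logrank_test(rfs_time: Sequence[float], rfs_event: Sequence[int], groups: Sequence) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    t = np.asarray(rfs_time, dtype=float)
    e = np.asarray(rfs_event, dtype=float)
    g = np.asarray(groups)
    uniq = sorted(pd.unique(g).tolist())
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    m0, m1 = g == uniq[0], g == uniq[1]
    if m0.sum() == 0 or m1.sum() == 0:
        raise ValueError("empty group")
    if e.sum() == 0:
        raise ValueError("log-rank test needs >= 1 event")
    res = _ll_logrank(t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank (exact for small n)
# ---------------------------------------------------------------------------

def _exact_signed_rank_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank statistic by sign enumeration.

    ``ranks2`` are the doubled (hence integer) ranks of |d|; ``w2`` the
    doubled observed positive-rank sum.  The null distribution of W+ over
    the 2^n equiprobable sign vectors is built by dynamic-programming
    convolution, which handles averaged tie-ranks exactly.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    dist /= 2.0 ** len(ranks2)
    w2 = int(round(w2))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test of ``b - a``; returns (W+, two-sided p).

    Zero differences are dropped (the classical convention); tied |d| get
    averaged ranks.  The null is enumerated exactly for up to 20 nonzero
    differences; larger samples use the normal approximation with tie
    correction (via scipy).  All differences zero gives p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    d = (b - a)[keep]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 20:
        p = _exact_signed_rank_p(np.round(ranks * 2), w_plus * 2)
    else:
        p = float(stats.wilcoxon(d, zero_method="wilcox", correction=False, method="approx").pvalue)
    return w_plus, p
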