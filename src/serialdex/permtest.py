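"""Permutation-null differential expression with BH adjustment.

Two tests are provided, matching the two kinds of contrasts in a serial
neoadjuvant design:

* a **paired sample permutation test based on the t-statistic** for
  time-point contrasts (T1 vs T2, T1 vs TS): the null is generated by
  independently flipping the sign of each within-patient difference;
* a **two-group permutation test** on the Welch t-statistic for
  responder/nonresponder contrasts at a static time point or on a
  per-patient change: the null reassigns group labels preserving sizes.

Both enumerate the null exhaustively when the permutation space fits in the
requested budget (2^n sign vectors, or C(n, n1) label splits) and otherwise
sample ``n_perm`` random permutations *plus the identity*, so the reported
p-value is never 0 and is permutation-granular: ``p * total`` is an integer
>= 1.  Two-sided p-values count permutations with ``|t| >= |t_obs|``.

Per the study design, time-point contrasts are thresholded on
Benjamini-Hochberg adjusted p < 0.05, while outcome (RCB) contrasts use the
relaxed raw p < 0.005 without multiplicity correction.
"""

from __future__ import annotations

import dataclasses
import math
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import delta_matrix, paired_matrices, patient_table, residual_disease_patients, timepoint_matrix
from .datamodel import ExpressionMatrix

_REL_TOL = 1e-12  # relative slack when comparing |t_perm| with |t_obs|
_CHUNK = 512      # permutations per block in the vectorized kernels


@dataclasses.dataclass
class PermResult:
    """Outcome of a single permutation test."""

    t: float
    p: float
    n: int
    exhaustive: bool
    n_perm_total: int


@dataclasses.dataclass
class DEResult:
    """Per-feature results of one differential-expression contrast.

    ``table`` is indexed by feature id with columns ``t``, ``mean_diff``,
    ``n``, ``raw_p`` and (for BH-thresholded contrasts) ``adjusted_p``, plus
    ``direction`` ("up"/"down" with respect to the contrast's stated
    reference).  ``threshold_rule`` records how significance was decided.
    """

    contrast: str
    table: pd.DataFrame
    n_perm: int
    exhaustive: bool
    seed: int | None
    threshold_rule: str
    alpha: float

    @property
    def significant(self) -> pd.Index:
        col = "adjusted_p" if self.threshold_rule.startswith("adjusted") else "raw_p"
        mask = self.table[col] < self.alpha
        return self.table.index[mask.fillna(False)]

    @property
    def n_up(self) -> int:
        return int((self.table.loc[self.significant, "direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table.loc[self.significant, "direction"] == "down").sum())

    def summary(self) -> dict:
        return {
            "contrast": self.contrast,
            "n_features": int(len(self.table)),
            "n_significant": int(len(self.significant)),
            "n_up": self.n_up,
            "n_down": self.n_down,
            "threshold_rule": self.threshold_rule,
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "exhaustive": self.exhaustive,
        }


# ---------------------------------------------------------------------------
# Paired test: sign-flip null on within-pair differences
# ---------------------------------------------------------------------------

def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator | None) -> tuple[np.ndarray, bool]:
    """All 2^n sign vectors if they fit in n_perm, else n_perm random + identity."""
    if 2**n <= n_perm:
        bits = np.arange(2**n, dtype=np.int64)[:, None] >> np.arange(n)[None, :]
        return (1 - 2 * (bits & 1)).astype(np.float64), True
    if rng is None:
        rng = np.random.default_rng()
    signs = rng.integers(0, 2, size=(n_perm, n)).astype(np.float64) * 2 - 1
    return np.vstack([np.ones((1, n)), signs]), False


def _paired_t(mean: np.ndarray, ss: np.ndarray, n: int) -> np.ndarray:
    """t = mean / (sd/sqrt(n)) given per-row means and total sums of squares.

    Under sign flips the sum of squares is invariant, so only the flipped
    mean is needed.  Degenerate rows: sd == 0 with zero mean -> t = 0; sd ==
    0 with nonzero mean -> t = +/- inf (all mass at one sign).
    """
    var = (ss - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
        t = np.where(var > 0, t, np.where(mean == 0, 0.0, np.sign(mean) * np.inf))
    return t


def _paired_perm_matrix(
    D: np.ndarray, n_perm: int, rng: np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Vectorized paired permutation test on rows of D (features x pairs)."""
    G, n = D.shape
    S, exhaustive = _sign_matrix(n, n_perm, rng)
    total = S.shape[0]
    ss = (D**2).sum(axis=1)
    t_obs = _paired_t(D.mean(axis=1), ss, n)
    thresh = np.abs(t_obs) * (1 - _REL_TOL)
    counts = np.zeros(G, dtype=np.int64)
    for start in range(0, total, _CHUNK):
        block = S[start : start + _CHUNK]
        means = block @ D.T / n                     # (chunk, G)
        t_perm = _paired_t(means, ss[None, :], n)
        counts += (np.abs(t_perm) >= thresh[None, :]).sum(axis=0)
    p = counts / total
    # all-zero rows: t = 0 and every permutation ties; contract p = 1
    p[ss == 0] = 1.0
    return t_obs, p, exhaustive, total


def paired_permutation_test(
    a: Sequence[float], b: Sequence[float], n_perm: int = 10_000, seed: int | None = None
) -> PermResult:
    """Paired permutation test based on the t-statistic for ``b - a``.

    Pairs with a missing member are dropped; at least 3 complete pairs are
    required.  ``t = mean(d) / (sd(d)/sqrt(n))`` with the n-1 sample sd; the
    null independently flips the sign of each difference.  If all
    differences are 0 the degenerate contract ``t = 0, p = 1`` applies.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = (b - a)[keep]
    n = d.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    rng = np.random.default_rng(seed) if seed is not None else np.random.default_rng()
    t, p, exhaustive, total = _paired_perm_matrix(d[None, :], n_perm, rng)
    return PermResult(float(t[0]), float(p[0]), n, exhaustive, total)


# ---------------------------------------------------------------------------
# Two-group test: label-permutation null on the Welch t-statistic
# ---------------------------------------------------------------------------

def _welch_t(s1, q1, s2, q2, n1: int, n2: int) -> np.ndarray:
    """Welch t from group sums (s) and sums of squares (q)."""
    m1, m2 = s1 / n1, s2 / n2
    v1 = np.maximum((q1 - n1 * m1**2) / (n1 - 1), 0.0)
    v2 = np.maximum((q2 - n2 * m2**2) / (n2 - 1), 0.0)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        t = np.where(denom > 0, t, np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    return t


def _group_masks(n: int, n1: int, n_perm: int, rng: np.random.Generator | None, identity: np.ndarray):
    """Membership masks for group 1: exhaustive C(n, n1) splits or random + identity."""
    if math.comb(n, n1) <= n_perm:
        masks = np.zeros((math.comb(n, n1), n), dtype=np.float64)
        for row, idx in enumerate(combinations(range(n), n1)):
            masks[row, list(idx)] = 1.0
        return masks, True
    if rng is None:
        rng = np.random.default_rng()
    masks = np.zeros((n_perm + 1, n), dtype=np.float64)
    masks[0] = identity
    for row in range(1, n_perm + 1):
        masks[row, rng.choice(n, size=n1, replace=False)] = 1.0
    return masks, False


def _two_group_perm_matrix(
    X: np.ndarray, in_group1: np.ndarray, n_perm: int, rng: np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Vectorized two-group permutation test on rows of X (features x samples)."""
    G, n = X.shape
    n1 = int(in_group1.sum())
    n2 = n - n1
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples, got {n1} and {n2}")
    masks, exhaustive = _group_masks(n, n1, n_perm, rng, in_group1.astype(np.float64))
    total = masks.shape[0]
    tot_s = X.sum(axis=1)
    tot_q = (X**2).sum(axis=1)
    s1_obs = X @ in_group1.astype(np.float64)
    q1_obs = (X**2) @ in_group1.astype(np.float64)
    t_obs = _welch_t(s1_obs, q1_obs, tot_s - s1_obs, tot_q - q1_obs, n1, n2)
    thresh = np.abs(t_obs) * (1 - _REL_TOL)
    counts = np.zeros(G, dtype=np.int64)
    for start in range(0, total, _CHUNK):
        block = masks[start : start + _CHUNK]
        s1 = X @ block.T                            # (G, chunk)
        q1 = (X**2) @ block.T
        t_perm = _welch_t(s1, q1, tot_s[:, None] - s1, tot_q[:, None] - q1, n1, n2)
        counts += (np.abs(t_perm) >= thresh[:, None]).sum(axis=1)
    p = counts / total
    constant = tot_q - tot_s**2 / n <= 0
    p[constant] = 1.0  # identical values in both groups: every split ties
    return t_obs, p, exhaustive, total


def two_group_permutation_test(
    values: Sequence[float],
    group_labels: Sequence,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermResult:
    """Two-group permutation test on the Welch t-statistic.

    ``group_labels`` must take exactly two values; group 1 is the label that
    sorts first (its mean enters the statistic positively).  Missing values
    are removed with their labels; each group then needs >= 2 samples.  The
    null reassigns labels preserving group sizes, enumerated exhaustively
    when C(n, n1) <= n_perm.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValueError("values and group_labels must have equal length")
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    in_group1 = labels == uniq[0]
    rng = np.random.default_rng(seed) if seed is not None else np.random.default_rng()
    t, p, exhaustive, total = _two_group_perm_matrix(values[None, :], in_group1, n_perm, rng)
    return PermResult(float(t[0]), float(p[0]), int(values.size), exhaustive, total)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up
# ---------------------------------------------------------------------------

def bh_adjust(raw_p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Missing entries pass through as NaN and are excluded from the number of
    tests m.  Entries outside (0, 1] are an error.
    """
    p = np.asarray(raw_p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] <= 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Cohort-level contrasts
# ---------------------------------------------------------------------------

#: contrast name -> (kind, parameters). Paired contrasts compare two time
#: points within patients; "static" and "delta" contrasts compare responder
#: vs nonresponder (RCB 0/I vs II/III) groups. TS-based contrasts include
#: only patients with residual disease (RCB I/II/III).
CONTRASTS: dict[str, dict] = {
    "t1_vs_t2": {"kind": "paired", "tp": ("T1", "T2"), "rule": "adjusted"},
    "t1_vs_ts": {"kind": "paired", "tp": ("T1", "TS"), "rule": "adjusted", "restrict_ts": True},
    "rcb_t1": {"kind": "static", "tp": "T1", "rule": "raw"},
    "rcb_t2": {"kind": "static", "tp": "T2", "rule": "raw"},
    "rcb_delta_t2": {"kind": "delta", "tp": ("T1", "T2"), "rule": "raw"},
    "rcb_delta_ts": {"kind": "delta", "tp": ("T1", "TS"), "rule": "raw", "restrict_ts": True},
}


def run_contrast(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    contrast: str,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    raw_alpha: float = 0.005,
) -> DEResult:
    """Run one named contrast over every feature of the matrix.

    Time-point contrasts (``t1_vs_t2``, ``t1_vs_ts``) use the paired
    sign-flip test, BH adjustment and the adjusted p < ``alpha`` rule;
    outcome contrasts (``rcb_*``) use the two-group label-permutation test
    and the raw p < ``raw_alpha`` rule with no multiplicity correction.
    TS-based contrasts are restricted to patients with residual disease.

    Features whose complete-pair count falls below the per-test minimum get
    NaN statistics (and are excluded from the BH m); the contrast itself
    errors only when *no* feature has enough complete data.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRASTS)}")
    spec = CONTRASTS[contrast]
    rng = np.random.default_rng(seed)
    per = patient_table(meta)

    if spec["kind"] == "paired":
        tp_a, tp_b = spec["tp"]
        a, b = paired_matrices(expr, meta, tp_a, tp_b)
        if spec.get("restrict_ts"):
            keep = [p for p in a.columns if p in set(residual_disease_patients(meta))]
            a, b = a.loc[:, keep], b.loc[:, keep]
        if a.shape[1] < 3:
            raise ValueError(
                f"contrast {contrast!r}: only {a.shape[1]} complete pairs "
                f"({list(a.columns)}); need >= 3"
            )
        D = (b.to_numpy() - a.to_numpy())
        complete = ~np.isnan(D).any(axis=1)
        G = D.shape[0]
        t = np.full(G, np.nan)
        raw_p = np.full(G, np.nan)
        n_used = np.full(G, 0, dtype=int)
        exhaustive = False
        if complete.any():
            t_c, p_c, exhaustive, _ = _paired_perm_matrix(D[complete], n_perm, rng)
            t[complete], raw_p[complete] = t_c, p_c
            n_used[complete] = D.shape[1]
        for i in np.flatnonzero(~complete):
            d = D[i][~np.isnan(D[i])]
            if d.size >= 3:
                t_i, p_i, _, _ = _paired_perm_matrix(d[None, :], n_perm, rng)
                t[i], raw_p[i], n_used[i] = t_i[0], p_i[0], d.size
        mean_diff = np.nanmean(D, axis=1)
        reference = f"{tp_b} relative to {tp_a}"
    else:
        if spec["kind"] == "static":
            mat = timepoint_matrix(expr, meta, spec["tp"])
        else:
            mat = delta_matrix(expr, meta, *spec["tp"])
        groups = per.loc[mat.columns, "rcb_group"]
        keep_pat = groups.isin(["responder", "nonresponder"]).to_numpy()
        if spec.get("restrict_ts"):
            keep_pat &= mat.columns.isin(residual_disease_patients(meta))
        mat = mat.loc[:, keep_pat]
        groups = groups[keep_pat]
        in_nonresp = (groups == "nonresponder").to_numpy()
        n1, n2 = int(in_nonresp.sum()), int((~in_nonresp).sum())
        if n1 < 2 or n2 < 2:
            raise ValueError(
                f"contrast {contrast!r}: group sizes {n1} nonresponders / {n2} responders; "
                f"need >= 2 each (usable patients: {list(mat.columns)})"
            )
        X = mat.to_numpy()
        complete = ~np.isnan(X).any(axis=1)
        G = X.shape[0]
        t = np.full(G, np.nan)
        raw_p = np.full(G, np.nan)
        n_used = np.full(G, 0, dtype=int)
        exhaustive = False
        if complete.any():
            t_c, p_c, exhaustive, _ = _two_group_perm_matrix(X[complete], in_nonresp, n_perm, rng)
            t[complete], raw_p[complete] = t_c, p_c
            n_used[complete] = X.shape[1]
        for i in np.flatnonzero(~complete):
            keep = ~np.isnan(X[i])
            g1 = in_nonresp[keep]
            if g1.sum() >= 2 and (~g1).sum() >= 2:
                t_i, p_i, _, _ = _two_group_perm_matrix(X[i, keep][None, :], g1, n_perm, rng)
                t[i], raw_p[i], n_used[i] = t_i[0], p_i[0], int(keep.sum())
        with np.errstate(invalid="ignore"):
            mean_diff = np.nanmean(np.where(in_nonresp[None, :], X, np.nan), axis=1) - np.nanmean(
                np.where(~in_nonresp[None, :], X, np.nan), axis=1
            )
        mean_diff[~complete & (n_used == 0)] = np.nan
        reference = "nonresponder (RCB II/III) relative to responder (RCB 0/I)"

    table = pd.DataFrame(
        {
            "t": t,
            "mean_diff": mean_diff,
            "n": n_used,
            "raw_p": raw_p,
            "direction": np.where(np.isnan(mean_diff), "", np.where(mean_diff > 0, "up", "down")),
        },
        index=expr.feature_ids,
    )
    if spec["rule"] == "adjusted":
        table["adjusted_p"] = bh_adjust(table["raw_p"].to_numpy())
        rule, level = "adjusted_p<alpha", alpha
    else:
        rule, level = "raw_p<alpha (no multiplicity correction)", raw_alpha
    table.attrs["reference"] = reference
    return DEResult(
        contrast=contrast,
        table=table,
        n_perm=n_perm,
        exhaustive=exhaustive,
        seed=seed,
        threshold_rule=rule,
        alpha=level,
    )
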