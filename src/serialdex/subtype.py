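"""Nearest-centroid molecular subtype assignment and paired concordance.

A sample is assigned the subtype whose centroid profile correlates best with
the sample's expression over the panel genes (Spearman by default, Pearson
selectable).  This is a generic nearest-centroid classifier over a
user-supplied panel: the full PAM50 preprocessing (reference-population gene
centering, risk-of-relapse scores) is intentionally not reproduced, because
the published centroid values and calibration data are external inputs.

Concordance between two time points is the fraction of matched patient
pairs with an identical assignment, reported as a percentage rounded to the
nearest integer (half away from zero — the convention forced by printed
rates such as 24/39 -> 62 %).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CentroidPanel, ExpressionMatrix, normalize_symbol, percent_rounded

_TIE_TOL = 1e-12


@dataclasses.dataclass
class SubtypeCall:
    sample_id: str
    label: str
    correlations: pd.Series  # one correlation per centroid, panel order
    n_genes_used: int
    tie: bool = False


def assign_subtype(
    profile: pd.Series,
    panel: CentroidPanel,
    metric: str = "spearman",
    min_genes: int = 30,
    sample_id: str = "",
) -> SubtypeCall:
    """Assign one sample to its nearest centroid.

    ``profile`` maps gene symbols to expression values; correlation is
    computed over the panel genes present and non-missing in the profile
    (at least ``min_genes`` required).  Ties are broken by panel column
    order and flagged.
    """
    if metric not in ("spearman", "pearson"):
        raise ValueError(f"metric must be 'spearman' or 'pearson', got {metric!r}")
    prof = profile.copy()
    prof.index = prof.index.map(normalize_symbol)
    panel_genes = panel.gene_ids.map(normalize_symbol)
    shared = [g for g in panel_genes if g in prof.index and not np.isnan(prof[g])]
    if len(shared) < min_genes:
        raise ValueError(
            f"only {len(shared)} shared non-missing panel genes for sample "
            f"{sample_id or '<unnamed>'!r}; need >= {min_genes}"
        )
    x = prof[shared].to_numpy(dtype=float)
    cents = panel.centroids.set_axis(panel_genes, axis=0).loc[shared]
    if metric == "spearman":
        x = stats.rankdata(x)
        mat = np.apply_along_axis(stats.rankdata, 0, cents.to_numpy())
    else:
        mat = cents.to_numpy()
    xc = x - x.mean()
    mc = mat - mat.mean(axis=0)
    denom = np.sqrt((xc**2).sum() * (mc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc @ mc) / denom
    corr = np.where(denom > 0, corr, np.nan)
    corrs = pd.Series(corr, index=panel.subtype_labels)
    best = int(np.nanargmax(corr))
    tie = bool((np.abs(corr - corr[best]) < _TIE_TOL).sum() > 1)
    return SubtypeCall(
        sample_id=sample_id,
        label=str(panel.subtype_labels[best]),
        correlations=corrs,
        n_genes_used=len(shared),
        tie=tie,
    )


def assign_subtypes(
    expr: ExpressionMatrix,
    panel: CentroidPanel,
    metric: str = "spearman",
    min_genes: int = 30,
) -> pd.DataFrame:
    """Call every sample of a matrix; returns one row per sample.

    Columns: ``label``, ``n_genes_used``, ``tie`` and one correlation column
    per subtype (prefixed ``corr_``).
    """
    rows = []
    for sid in expr.sample_ids:
        call = assign_subtype(expr.data[sid], panel, metric=metric, min_genes=min_genes, sample_id=sid)
        row = {"sample_id": sid, "label": call.label, "n_genes_used": call.n_genes_used, "tie": call.tie}
        row.update({f"corr_{k}": v for k, v in call.correlations.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


@dataclasses.dataclass
class ConcordanceResult:
    n_pairs: int
    n_identical: int
    n_changed: int
    rate_percent: int
    transitions: pd.DataFrame  # rows: call at A, columns: call at B

    def summary(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_identical": self.n_identical,
            "n_changed": self.n_changed,
            "rate_percent": self.rate_percent,
            "transitions": {a: dict(row) for a, row in self.transitions.iterrows()},
        }


def concordance(calls_a: pd.Series, calls_b: pd.Series) -> ConcordanceResult:
    """Subtype concordance between two call vectors paired by patient id.

    ``calls_a`` / ``calls_b`` map patient id -> subtype label at each time
    point; only patients present in both contribute.  The concordance rate
    is ``100 * identical / pairs`` rounded to the nearest integer, and the
    transition table counts label -> label changes.
    """
    common = [p for p in calls_a.index if p in set(calls_b.index)]
    if not common:
        raise ValueError("no matched pairs between the two call vectors")
    a = calls_a[common].astype(str)
    b = calls_b[common].astype(str)
    labels = sorted(set(a) | set(b))
    trans = pd.DataFrame(0, index=pd.Index(labels, name="from"), columns=pd.Index(labels, name="to"))
    for la, lb in zip(a, b):
        trans.loc[la, lb] += 1
    n_pairs = len(common)
    n_identical = int((a.to_numpy() == b.to_numpy()).sum())
    return ConcordanceResult(
        n_pairs=n_pairs,
        n_identical=n_identical,
        n_changed=n_pairs - n_identical,
        rate_percent=percent_rounded(n_identical, n_pairs),
        transitions=trans,
    )


def paired_calls(calls: pd.DataFrame, meta: pd.DataFrame, tp_a: str, tp_b: str) -> tuple[pd.Series, pd.Series]:
    """Split per-sample calls into two patient-indexed label vectors."""
    joined = calls.join(meta[["patient_id", "timepoint"]])
    a = joined[joined["timepoint"] == tp_a].set_index("patient_id")["label"]
    b = joined[joined["timepoint"] == tp_b].set_index("patient_id")["label"]
    return a, b
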