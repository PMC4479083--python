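"""Core data containers for serial tumor expression cohorts.

A cohort is described by two tables: a features x samples matrix of log2
expression ratios (:class:`ExpressionMatrix`) and a per-sample clinical /
technical annotation sheet (a validated :class:`pandas.DataFrame`, see
:func:`validate_sample_meta`).  Samples are serial biopsies taken at up to
three time points per patient:

* ``T1`` — pretreatment core biopsy,
* ``T2`` — 24–96 h after the first chemotherapy dose,
* ``TS`` — residual tumor at surgery.

Response to neoadjuvant chemotherapy is graded by residual cancer burden
(RCB); classes 0/I form the responder group and II/III the nonresponder
group.  Analyses of the surgical time point are restricted to patients with
residual disease (RCB I/II/III) — note that RCB I patients count as
responders for the group split yet still carry residual tumor.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TIMEPOINTS = ("T1", "T2", "TS")

RCB_LEVELS = ("0", "I", "II", "III", "undetermined")

#: RCB class -> dichotomized response group.
RCB_GROUP_MAP = {
    "0": "responder",
    "I": "responder",
    "II": "nonresponder",
    "III": "nonresponder",
    "undetermined": "NA",
}

HR_LEVELS = ("positive", "negative", "NA")

#: Canonical column order of a sample sheet.
META_COLUMNS = (
    "sample_id",
    "patient_id",
    "timepoint",
    "batch",
    "rcb",
    "rcb_group",
    "hr_status",
    "rfs_time",
    "rfs_event",
)


class FormatError(ValueError):
    """A tabular input violates its declared format contract."""


def normalize_symbol(symbol: str) -> str:
    """Case-fold a gene symbol to upper case (declared matching normalization)."""
    return str(symbol).strip().upper()


def rcb_group(rcb) -> str:
    """Map an RCB class to its response group.

    ``0``/``I`` -> ``responder``; ``II``/``III`` -> ``nonresponder``;
    missing or ``undetermined`` -> ``NA``.  Total on all levels.
    """
    if rcb is None or (isinstance(rcb, float) and np.isnan(rcb)):
        return "NA"
    key = str(rcb).strip()
    if key in ("", "NA", "nan"):
        return "NA"
    if key not in RCB_GROUP_MAP:
        raise FormatError(f"unknown RCB class {rcb!r}; expected one of {RCB_LEVELS}")
    return RCB_GROUP_MAP[key]


def has_residual_disease(rcb) -> bool:
    """True for RCB I/II/III — the inclusion rule for surgical (TS) analyses.

    RCB I patients belong to the responder group of the 0/I vs II/III split
    but do carry residual tumor, so they are eligible for TS analyses.
    """
    if rcb is None or (isinstance(rcb, float) and np.isnan(rcb)):
        return False
    return str(rcb).strip() in ("I", "II", "III")


@dataclasses.dataclass
class ExpressionMatrix:
    """Features x samples matrix of log2 expression ratios.

    Parameters
    ----------
    data
        DataFrame with feature identifiers as index (probe ids or gene
        symbols) and sample identifiers as columns.  Values are floats;
        ``NaN`` encodes a missing measurement and is distinct from 0.
    level
        ``"probe"`` or ``"gene"`` — the feature level of the index.
    """

    data: pd.DataFrame
    level: str = "gene"

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValueError(f"level must be 'probe' or 'gene', got {self.level!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], level=self.level)


def validate_sample_meta(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet and derive the ``rcb_group`` column.

    Required columns: ``sample_id``, ``patient_id``, ``timepoint``, ``batch``.
    Optional: ``rcb``, ``hr_status``, ``rfs_time``, ``rfs_event``; absent
    optional columns are added filled with missing values.  Returns a copy in
    canonical column order, indexed by ``sample_id``.

    Raises
    ------
    FormatError
        On duplicate sample ids or (patient, timepoint) pairs, unknown
        timepoints, an ``rfs_event`` column without ``rfs_time``, or a
        positive event at time 0.
    """
    df = df.copy()
    for col in ("sample_id", "patient_id", "timepoint", "batch"):
        if col not in df.columns:
            raise FormatError(f"sample sheet lacks required column {col!r}")
    if "rfs_event" in df.columns and "rfs_time" not in df.columns:
        raise FormatError("rfs_event present without rfs_time")

    df["sample_id"] = df["sample_id"].astype(str)
    df["patient_id"] = df["patient_id"].astype(str)
    df["timepoint"] = df["timepoint"].astype(str)
    df["batch"] = df["batch"].astype(str)

    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate sample id {dup.iloc[0]!r}")
    bad_tp = sorted(set(df["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise FormatError(f"unknown timepoint {bad_tp[0]!r}; expected one of {TIMEPOINTS}")
    pairs = df[["patient_id", "timepoint"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        offender = pairs[pairs.duplicated()].iloc[0]
        raise FormatError(f"duplicate (patient, timepoint) pair {offender!r}")

    if "rcb" not in df.columns:
        df["rcb"] = pd.NA
    df["rcb"] = df["rcb"].map(
        lambda v: pd.NA
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() in ("", "NA", "nan", "<NA>")
        else str(v).strip()
    )
    bad_rcb = sorted(set(df["rcb"].dropna()) - set(RCB_LEVELS))
    if bad_rcb:
        raise FormatError(f"unknown RCB class {bad_rcb[0]!r}; expected one of {RCB_LEVELS}")
    df["rcb_group"] = df["rcb"].map(lambda v: rcb_group(None if v is pd.NA else v))

    if "hr_status" not in df.columns:
        df["hr_status"] = "NA"
    df["hr_status"] = df["hr_status"].map(
        lambda v: "NA"
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() in ("", "NA", "nan", "<NA>")
        else str(v).strip()
    )
    bad_hr = sorted(set(df["hr_status"]) - set(HR_LEVELS))
    if bad_hr:
        raise FormatError(f"unknown hr_status {bad_hr[0]!r}; expected one of {HR_LEVELS}")

    for col in ("rfs_time", "rfs_event"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="raise")
    bad_event = ~df["rfs_event"].isna() & ~df["rfs_event"].isin([0, 1])
    if bad_event.any():
        raise FormatError("rfs_event must be 0 (censored) or 1 (recurrence)")
    neg = df["rfs_time"] < 0
    if neg.any():
        raise FormatError("rfs_time must be nonnegative")
    zero_event = (df["rfs_event"] == 1) & ~(df["rfs_time"] > 0)
    if zero_event.any():
        raise FormatError("rfs_event=1 requires rfs_time > 0")

    out = df.loc[:, list(META_COLUMNS)]
    out.index = pd.Index(out["sample_id"], name="sample_id")
    return out


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (e.g. parsed from a Broad-dialect GMT file)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclasses.dataclass
class CentroidPanel:
    """Genes x subtypes centroid matrix for nearest-centroid subtyping.

    The subtype (column) order is significant: correlation ties are broken
    in favor of the earlier column.
    """

    centroids: pd.DataFrame

    def __post_init__(self) -> None:
        cols = self.centroids.columns
        if cols.has_duplicates:
            raise FormatError("duplicate subtype labels in centroid panel")
        if len(cols) < 2:
            raise FormatError(f"centroid panel needs >=2 subtypes, got {len(cols)}")
        if len(self.centroids.index) < 2:
            raise FormatError(f"centroid panel needs >=2 genes, got {len(self.centroids.index)}")
        if self.centroids.index.has_duplicates:
            raise FormatError("duplicate gene ids in centroid panel")
        self.centroids = self.centroids.astype(float)

    @property
    def subtype_labels(self) -> pd.Index:
        return self.centroids.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.centroids.index


def percent_rounded(numerator: float, denominator: float) -> int:
    """``round(100 * numerator / denominator)`` with half away from zero.

    Used for concordance and cohort percentages; half-away-from-zero is
    forced by 24/39 = 61.5... printing as 62.
    """
    if denominator == 0:
        raise ValueError("denominator is zero")
    x = 100.0 * numerator / denominator
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))
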