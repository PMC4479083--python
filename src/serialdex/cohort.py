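"""Helpers that resolve samples to patients and time points.

Patients contribute up to one sample per time point; pairing across time
points is resolved through ``patient_id``.  These helpers return
patient-indexed matrices so paired tests, deltas and survival screens all
operate on aligned columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, has_residual_disease


def timepoint_matrix(expr: ExpressionMatrix, meta: pd.DataFrame, timepoint: str) -> pd.DataFrame:
    """Features x patients matrix of one time point (columns = patient ids)."""
    rows = meta[meta["timepoint"] == timepoint]
    sub = expr.data.loc[:, rows.index]
    sub.columns = rows["patient_id"].to_numpy()
    return sub

def paired_matrices(
    expr: ExpressionMatrix, meta: pd.DataFrame, tp_a: str, tp_b: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aligned features x patients matrices for patients with both time points."""
    a = timepoint_matrix(expr, meta, tp_a)
    b = timepoint_matrix(expr, meta, tp_b)
    common = [p for p in a.columns if p in set(b.columns)]
    return a.loc[:, common], b.loc[:, common]

def delta_matrix(expr: ExpressionMatrix, meta: pd.DataFrame, tp_a: str, tp_b: str) -> pd.DataFrame:
    """Per-patient change ``tp_b - tp_a`` for patients with both time points."""
    a, b = paired_matrices(expr, meta, tp_a, tp_b)
    return b - a


def patient_table(meta: pd.DataFrame) -> pd.DataFrame:
    """One row per patient with the patient-level annotations.

    Raises if a patient carries inconsistent clinical values across samples.
    """
    cols = ["patient_id", "rcb", "rcb_group", "hr_status", "rfs_time", "rfs_event"]
    per = meta[cols].drop_duplicates()
    if per["patient_id"].duplicated().any():
        dup = per["patient_id"][per["patient_id"].duplicated()].iloc[0]
        raise ValueError(f"patient {dup!r} has inconsistent clinical annotations")
    return per.set_index("patient_id")


def residual_disease_patients(meta: pd.DataFrame) -> list[str]:
    """Patients eligible for surgical-specimen (TS) analyses: RCB I/II/III."""
    per = patient_table(meta)
    keep = per["rcb"].map(lambda r: has_residual_disease(None if pd.isna(r) else r))
    return per.index[keep.to_numpy(dtype=bool)].tolist()
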