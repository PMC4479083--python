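"""Probe collapse and print-batch residualization.

Two-color spotted arrays are printed in batches; each print run induces an
additive per-gene offset on the log2 ratio.  The batch effect is removed by
fitting, per gene, the one-way linear model ``value ~ batch`` (categorical)
and keeping the residuals.  Because the design is a one-way layout, the
least-squares residuals are exactly the values minus their batch means, so
the fit is implemented in closed form rather than iteratively — identical
result, exact and fast.  Replicate probes of a gene are collapsed by
arithmetic mean, ignoring missing values.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, normalize_symbol

logger = logging.getLogger(__name__)


def collapse_probes(matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Average replicate probes of each gene into one gene-level row.

    Probes absent from ``probe_to_gene`` are dropped (a count is logged).
    Per gene and sample the value is the mean of the gene's probes over
    non-missing entries; if all probes are missing the gene value stays
    missing.  Output rows follow the order of first probe occurrence.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene mapping is empty")
    mapping = {str(p): normalize_symbol(g) for p, g in probe_to_gene.items()}
    probes = matrix.data.index
    mapped = probes.map(mapping)
    n_unmapped = int(mapped.isna().sum())
    if n_unmapped:
        logger.info("collapse_probes: dropping %d unmapped probes", n_unmapped)
    keep = ~mapped.isna()
    data = matrix.data.loc[keep]
    genes = mapped[keep]
    # groupby(sort=False) preserves first-occurrence order; mean skips NaN.
    collapsed = data.groupby(genes.to_numpy(), sort=False).mean()
    collapsed.index.name = matrix.data.index.name
    return ExpressionMatrix(collapsed, level="gene")


def residualize_batch(matrix: ExpressionMatrix, meta: pd.DataFrame) -> ExpressionMatrix:
    """Remove print-batch effects: per gene, subtract the batch-specific mean.

    Equivalent to the residuals of the one-way fit ``value ~ batch``.  Genes
    observed in a single batch are simply mean-centered.  Missing values are
    excluded from the batch means and remain missing; a (gene, batch) cell
    that is entirely missing stays missing.  Idempotent.
    """
    samples = matrix.sample_ids
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise ValueError(f"sample {missing[0]!r} has no metadata row / batch label")
    batch = meta.loc[samples, "batch"]
    if batch.isna().any():
        offender = samples[batch.isna().to_numpy()][0]
        raise ValueError(f"sample {offender!r} is missing a batch label")
    out = matrix.data.copy()
    for _, cols in out.columns.groupby(batch.to_numpy()).items():
        block = out.loc[:, cols]
        out.loc[:, cols] = block.sub(block.mean(axis=1, skipna=True), axis=0)
    return ExpressionMatrix(out, level=matrix.level)
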