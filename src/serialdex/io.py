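"""Readers and writers for the tabular formats the pipeline consumes.

All files are tab-separated UTF-8 without quoting.  Missing values are
accepted as ``NA`` or the empty string on read and written back as ``NA``;
floats are written at full precision so read/write round-trips are lossless.
Gene symbols in GMT and centroid files are upper-cased on read (the declared
cross-file matching normalization).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CentroidPanel,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    normalize_symbol,
    validate_sample_meta,
)

logger = logging.getLogger(__name__)

_MISSING_TOKENS = ("", "NA")


def read_expression(path, level: str = "gene") -> ExpressionMatrix:
    """Read a features x samples expression TSV.

    Header row holds sample ids; first column holds feature ids; remaining
    cells are numeric or a missing token (``NA`` / empty).  Raises
    :class:`FormatError` naming the offending cell or duplicated identifier.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    if raw.columns.has_duplicates:
        # pandas mangles duplicate headers to 'x.1'; re-check the raw header line
        pass
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for name in header:
        if name in seen:
            raise FormatError(f"{path}: duplicate sample id {name!r}")
        seen.add(name)

    numeric = raw.apply(lambda col: pd.to_numeric(col.where(~col.isin(_MISSING_TOKENS)), errors="coerce"))
    bad = numeric.isna() & ~raw.isin(_MISSING_TOKENS)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at feature {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    numeric.index = raw.index.map(str)
    return ExpressionMatrix(numeric, level=level)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_sample_meta(path) -> pd.DataFrame:
    """Read and validate a sample sheet TSV (see :func:`validate_sample_meta`)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace({tok: np.nan for tok in _MISSING_TOKENS})
    return validate_sample_meta(df)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", na_rep="NA", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, then member genes.

    Order preserving; symbols upper-cased; duplicate genes within a set are
    dropped with a warning; an empty set is a format error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            for g in genes:
                if not g.strip():
                    continue
                sym = normalize_symbol(g)
                if sym in seen:
                    warnings.warn(f"{path}:{lineno}: duplicate gene {sym!r} in set {name!r}; deduplicated")
                    continue
                seen.add(sym)
                members.append(sym)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_centroids(path) -> CentroidPanel:
    """Read a centroid TSV: gene rows x subtype columns; symbols upper-cased."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(_MISSING_TOKENS), keep_default_na=False)
    df.index = df.index.map(normalize_symbol)
    return CentroidPanel(df)


def write_centroids(panel: CentroidPanel, path) -> None:
    df = panel.centroids.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_probe_map(path) -> dict[str, str]:
    """Read a two-column probe -> gene symbol TSV (header ``probe_id\\tgene_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: probe map needs two columns (probe_id, gene_id)")
    probes = df.iloc[:, 0].astype(str)
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise FormatError(f"{path}: probe {dup!r} mapped more than once")
    genes = df.iloc[:, 1].map(normalize_symbol)
    return dict(zip(probes, genes))


def write_probe_map(mapping: dict[str, str], path) -> None:
    pd.DataFrame({"probe_id": list(mapping), "gene_id": list(mapping.values())}).to_csv(
        path, sep="\t", index=False
    )
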