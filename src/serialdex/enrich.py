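"""Gene-set overrepresentation by Fisher's exact test.

Each gene set is crossed with the significant-gene list in a 2x2 table over
the analysis universe — all features tested in the upstream contrast, the
standard microarray background (not the genome).  The one-sided enrichment
p-value is the hypergeometric upper-tail sum; sets with p < 0.05 are
conventionally called overrepresented.  No multiplicity correction is
applied by default; an optional BH column can be requested and is clearly
marked as an extension of the convention.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneSetCollection, normalize_symbol
from .permtest import bh_adjust


@dataclasses.dataclass
class EnrichmentResult:
    set_name: str
    odds_ratio: float
    p: float
    n_overlap: int
    table: np.ndarray        # 2x2: rows in-set/out-set, cols significant/not
    overlap_genes: list[str]


def overrepresentation_test(
    significant_genes: Iterable[str], universe: Iterable[str], gene_set: Iterable[str], set_name: str = ""
) -> EnrichmentResult:
    """One-sided Fisher exact test for enrichment of a set among significant genes.

    ``significant_genes`` must be a subset of ``universe``; the set is
    intersected with the universe before testing.  A set disjoint from the
    universe returns p = 1 with overlap 0 (nothing to enrich).
    """
    sig = {normalize_symbol(g) for g in significant_genes}
    uni = {normalize_symbol(g) for g in universe}
    if not uni:
        raise ValueError("empty universe")
    if not sig:
        raise ValueError("empty significant gene list")
    if not sig <= uni:
        raise ValueError("significant genes must be a subset of the universe")
    members = {normalize_symbol(g) for g in gene_set} & uni
    overlap = sorted(members & sig)
    a = len(overlap)                      # in set & significant
    b = len(members) - a                  # in set & not significant
    c = len(sig) - a                      # not in set & significant
    d = len(uni) - len(members) - c       # not in set & not significant
    table = np.array([[a, b], [c, d]])
    if not members:
        return EnrichmentResult(set_name, np.nan, 1.0, 0, table, [])
    odds, p = stats.fisher_exact(table, alternative="greater")
    return EnrichmentResult(set_name, float(odds), float(p), a, table, overlap)


def enrich_all(
    significant_genes: Iterable[str],
    universe: Iterable[str],
    gene_sets: GeneSetCollection,
    alpha: float = 0.05,
    add_bh: bool = False,
) -> pd.DataFrame:
    """Test every set of a collection; returns a table ranked by raw p.

    Columns: ``n_set`` (members in the universe), ``n_overlap``,
    ``odds_ratio``, ``p``, ``significant`` (raw p < ``alpha``, the
    convention used here) and ``overlap_genes``.  With ``add_bh=True`` an
    ``adjusted_p_bh`` column is appended as a clearly-marked extension; the
    significance call still uses the raw p.
    """
    uni = {normalize_symbol(g) for g in universe}
    rows = []
    for name, genes in gene_sets:
        res = overrepresentation_test(significant_genes, uni, genes, set_name=name)
        rows.append(
            {
                "set": name,
                "n_set": int(res.table[0].sum()),
                "n_overlap": res.n_overlap,
                "odds_ratio": res.odds_ratio,
                "p": res.p,
                "overlap_genes": ",".join(res.overlap_genes),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["significant"] = out["p"] < alpha
    if add_bh:
        out["adjusted_p_bh"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "n_set"], kind="stable")
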