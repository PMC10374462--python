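"""Hypergeometric over-representation of gene signatures with BH FDR.

The universe is the set of genes measured in the dataset after filtering;
each collection gene set is intersected with the universe before testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(query: set, collection: dict[str, set],
                              universe: set) -> pd.DataFrame:
    """Upper-tail hypergeometric test of ``query`` against each named set.

    For a universe of size U, a gene set of size K (after restriction to the
    universe) and a query of size n with overlap k, p = P(X >= k) for
    X ~ Hypergeom(U, K, n). Returns one row per set, sorted by p, with a
    BH-adjusted q column.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise InputError("empty universe")
    if not query:
        raise InputError("empty query set")
    stray = query - universe
    if stray:
        raise InputError(f"query genes outside the universe: "
                         f"{sorted(stray)[:10]}")
    U, n = len(universe), len(query)
    rows = []
    for name, genes in collection.items():
        members = set(genes) & universe
        K = len(members)
        overlap = sorted(query & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, U, K, n))
        rows.append({"set_name": name, "universe": U, "set_size": K,
                     "query_size": n, "overlap": k,
                     "p": min(p, 1.0), "overlap_genes": overlap})
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_fdr(result["p"].to_numpy())
        result = result.sort_values("p", kind="stable").reset_index(drop=True)
    return result
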