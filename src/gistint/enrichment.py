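"""Hypergeometric gene-set over-representation with BH correction.

A query gene list (e.g. genes with copy-number gain) is tested against each
gene set inside a finite universe: with ``N`` universe genes, ``K`` of them
in the set, and ``n`` in the query, the p-value is the one-sided upper tail
``P(X >= k)`` of the hypergeometric law for the observed overlap ``k``.
"""
from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .models import GeneSet


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(query: Iterable[str], sets: Iterable[GeneSet],
                     universe: Iterable[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    The query must be a subset of the universe; each set is intersected
    with the universe before testing.  Returns one row per set with the
    overlap ``k``, the parameters ``(N, K, n)``, the upper-tail p-value and
    the BH-adjusted q-value, sorted by p then set id.
    """
    universe = set(universe)
    if not universe:
        raise DomainError("universe is empty")
    query = set(query)
    stray = query - universe
    if stray:
        raise DomainError(f"query genes outside universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for gs in sets:
        genes = gs.genes & universe
        K = len(genes)
        k = len(genes & query)
        # P(X >= k); survival function is P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set_id": gs.set_id, "description": gs.description,
                     "k": k, "n": n, "K": K, "N": N,
                     "p_value": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["set_id", "description", "k", "n",
                                         "K", "N", "p_value"])
    result["q_value"] = bh_adjust(result["p_value"]) if len(result) else []
    return (result.sort_values(["p_value", "set_id"])
            .reset_index(drop=True))
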