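"""Hypergeometric over-representation analysis of DE symbols against gene sets.

A plain one-sided hypergeometric test per gene set (upper tail,
P[X >= k] for k overlap symbols out of n query draws from a universe of N
with K set members), BH-adjusted across terms, with fold enrichment
(k/n)/(K/N).  The universe defaults to the assayed, post-QC proteins — the
measured background — rather than the whole genome.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .differential_expression import bh_adjust
from .io_model import GeneSetCollection

logger = logging.getLogger("sendotype")

__all__ = ["ora", "de_to_query"]


def ora(
    query: set[str] | frozenset[str],
    sets: GeneSetCollection,
    universe: set[str] | frozenset[str],
) -> pd.DataFrame:
    """Hypergeometric ORA of a query symbol set against each gene set.

    Symbols outside the universe are ignored (both in the query and in the
    sets); terms with no universe overlap are skipped.  Returns one row per
    term sorted by p-value with overlap counts, fold enrichment, p and BH
    adjusted p.
    """
    universe = frozenset(universe)
    dropped = set(query) - universe
    if dropped:
        logger.info("ora: %d query symbols outside the universe ignored", len(dropped))
    query = frozenset(query) & universe
    if not query:
        raise ValueError("query is empty (after restriction to the universe)")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for term, (desc, members) in sets.items():
        members_in = members & universe
        if not members_in:
            logger.info("ora: term %s has no overlap with the universe; skipped", term)
            continue
        k = len(query & members_in)
        big_k = len(members_in)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_query))
        rows.append({
            "term_id": term,
            "description": desc,
            "overlap": k,
            "set_size": big_k,
            "query_size": n_query,
            "universe_size": n_universe,
            "fold_enrichment": (k / n_query) / (big_k / n_universe),
            "p_value": min(p, 1.0),
        })
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    table = pd.DataFrame(rows).set_index("term_id")
    table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
    return table.sort_values(["p_value", "term_id"], kind="mergesort")


def de_to_query(
    de: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> frozenset[str]:
    """Significant DE symbols: (adjusted) p below ``alpha``."""
    col = "adj_p" if use_adjusted else "p_value"
    return frozenset(de.index[de[col] < alpha])
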