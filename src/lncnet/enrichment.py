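"""Over-representation analysis of a DE gene list against GMT term collections.

Plain hypergeometric upper-tail ORA with Benjamini-Hochberg adjustment across
terms. GO/KEGG-style collections are just GMT inputs here; no modified
Fisher (EASE) score is applied. The default universe is the set of all genes
that entered DE testing.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .io import GeneSetCollection
from .stats import bh_adjust, hypergeom_sf

__all__ = ["ora"]


def ora(
    de_genes: set[str],
    terms: GeneSetCollection,
    universe: set[str],
    adj_p_threshold: float = 0.05,
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``de_genes`` in each term.

    Each term is intersected with the universe before testing (terms that
    vanish are skipped); p-values are BH-adjusted across tested terms. Rows
    are sorted by (adj_p, p, term_name) and carry the overlap members plus,
    when ``directions`` maps gene -> {up, down}, the up/down breakdown of the
    members. ``significant`` flags adj_p < adj_p_threshold.

    Raises on an empty universe or empty DE list, and when de_genes is not a
    subset of the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    if not de_genes:
        raise ValueError("empty DE gene list")
    if not de_genes <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    N = len(universe)
    n = len(de_genes)
    rows = []
    for name in sorted(terms):
        members = terms[name] & universe
        if not members:
            continue
        overlap = sorted(de_genes & members)
        p = hypergeom_sf(N, len(members), n, len(overlap))
        row = {
            "term_name": name,
            "N": N,
            "K": len(members),
            "n": n,
            "k": len(overlap),
            "p": p,
            "member_genes": ",".join(overlap),
        }
        if directions is not None:
            row["n_up"] = sum(1 for g in overlap if directions.get(g) == "up")
            row["n_down"] = sum(1 for g in overlap if directions.get(g) == "down")
        rows.append(row)
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["adj_p"] = bh_adjust(res["p"].to_numpy())
    res["significant"] = res["adj_p"] < adj_p_threshold
    res = res.sort_values(["adj_p", "p", "term_name"], kind="mergesort").reset_index(drop=True)
    return res
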