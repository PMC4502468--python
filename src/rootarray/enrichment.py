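"""Hypergeometric over-representation analysis of gene sets.

Any probe set produced by the pipeline (a temporal cluster, a specificity
class) can be tested against user-supplied flat term sets.  For a universe
of N genes of which K carry a term, and a query set of n genes of which k
carry it, the enrichment p-value is the upper tail
``P(X >= k)`` of Hypergeometric(N, K, n).  Only over-representation is
tested, and the raw p-values are compared with the threshold by default;
Benjamini–Hochberg correction is available via ``adjust="bh"``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["enrich"]


def enrich(gene_set, universe, terms: dict, p_threshold=0.01,
           adjust="none") -> pd.DataFrame:
    """Over-representation of ``gene_set`` within ``universe`` per term.

    Parameters
    ----------
    gene_set, universe : iterables of gene ids
        Genes outside the universe are dropped with a warning.
    terms : dict of :class:`~rootarray.io.TermSet`
        Term sets; members are intersected with the universe before
        testing, and terms with zero overlap with the universe are kept
        in the output (p = 1) but can never be significant.
    p_threshold : float
        Flagging threshold (strict: ``p < p_threshold``).

    Returns a DataFrame sorted by p-value (term id breaking ties), with
    columns term_id, term_name, k, n, K, N, p, optional p_adj, enriched.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if p_threshold <= 0:
        raise ValueError("p_threshold must be positive")
    gene_set = set(gene_set)
    outside = gene_set - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
        gene_set &= universe

    N, n = len(universe), len(gene_set)
    rows = []
    for term in terms.values():
        members = term.genes & universe
        K = len(members)
        k = len(gene_set & members)
        # upper tail P(X >= k); sf(k-1) includes the point mass at k
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append(
            {"term_id": term.term_id, "term_name": term.name,
             "k": k, "n": n, "K": K, "N": N, "p": p}
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "p"]
    )
    if len(out) == 0:
        out["enriched"] = pd.Series(dtype=bool)
        return out
    p_for_gate = out["p"]
    if adjust == "bh":
        out["p_adj"] = stats.false_discovery_control(out["p"].to_numpy(),
                                                     method="bh")
        p_for_gate = out["p_adj"]
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["enriched"] = p_for_gate < p_threshold
    return out.sort_values(["p", "term_id"]).reset_index(drop=True)
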