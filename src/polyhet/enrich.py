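"""Hypergeometric over-representation analysis of gene sets.

For a gene set of size n drawn from a universe of N genes, a term annotating
K universe genes and k set genes gets the upper-tail probability
P(X >= k) for X ~ Hypergeometric(N, K, n), followed by Benjamini-Hochberg
correction across the tested terms of one namespace.  The universe should be
the genes actually tested for differential expression, not the whole genome,
to avoid expression-bias inflation.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy import stats as sps

from .de import bh_adjust
from .io import TermAnnotation

RESULT_COLUMNS = ["term_id", "term_name", "k", "K", "n", "N", "fold",
                  "p_raw", "q_fdr"]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed through the survival function of the scipy hypergeometric
    distribution (stable in log space); k = 0 returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("need 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def enrich(gene_set: Iterable[str], annotation: TermAnnotation,
           universe: Iterable[str], min_term_size: int = 3) -> pd.DataFrame:
    """Over-representation of ``gene_set`` terms against ``universe``.

    Terms are restricted to the universe first; terms annotating fewer than
    ``min_term_size`` universe genes are not tested.  Results are BH-corrected
    within this call (one namespace) and sorted by raw p.
    """
    uni = frozenset(str(g) for g in universe)
    if not uni:
        raise ValueError("empty universe")
    genes = frozenset(str(g) for g in gene_set)
    outside = genes - uni
    if outside:
        raise ValueError(
            f"{len(outside)} query genes outside the universe "
            f"(e.g. {sorted(outside)[:3]})")
    restricted = annotation.restrict(uni)
    N, n = len(uni), len(genes)
    rows = []
    for term, members in restricted.terms.items():
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & genes)
        expected = n * K / N
        rows.append({
            "term_id": term,
            "term_name": restricted.term_names.get(term, ""),
            "k": k, "K": K, "n": n, "N": N,
            "fold": (k / expected) if expected > 0 else float("nan"),
            "p_raw": hypergeom_upper(k, K, n, N),
        })
    result = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if result.empty:
        result["q_fdr"] = []
        return result[RESULT_COLUMNS]
    result["q_fdr"] = bh_adjust(result["p_raw"])
    return (result.sort_values(["p_raw", "term_id"])
            .reset_index(drop=True)[RESULT_COLUMNS])
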