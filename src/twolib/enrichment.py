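"""Hypergeometric term enrichment of DEGs with Bonferroni correction.

For each annotated term, with N the number of genes carrying at least
one annotation of that term type (the annotated universe), n the DEGs
within N, M the genes annotated to the term and m the DEGs among them,
the enrichment p-value is the upper tail

    P(X >= m),  X ~ Hypergeometric(N, M, n)

i.e. 1 - sum_{i<m} C(M,i) C(N-M, n-i) / C(N,n). GO terms and pathways
are tested as separate families: each family's Bonferroni multiplier is
the number of terms tested within it, and a term is enriched when the
corrected p is at most alpha (default 0.05).
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["hypergeom_enrich", "enrich_all"]

logger = logging.getLogger("twolib")

DEFAULT_ALPHA = 0.05


def hypergeom_enrich(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= m)."""
    if min(N, n, M, m) < 0:
        raise ValueError("tallies must be non-negative")
    if M > N or n > N:
        raise ValueError(f"inconsistent tallies: M={M}, n={n} must not exceed N={N}")
    if m > min(n, M):
        raise ValueError(f"inconsistent tallies: m={m} exceeds min(n, M)={min(n, M)}")
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, M, n))


def enrich_all(
    deg_ids: set[str],
    annotations: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Test every annotated term for DEG over-representation.

    ``annotations`` has columns gene_id, term_id, term_type. DEG ids
    absent from the annotated universe of a term type are logged and do
    not contribute to n for that family. Results are sorted by raw p
    (ties broken by term_id) within term type.
    """
    if annotations.empty:
        raise ValueError("annotation table is empty")
    required = {"gene_id", "term_id", "term_type"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    deg_ids = set(deg_ids)
    out_rows = []
    for term_type, group in annotations.groupby("term_type", sort=True):
        universe = set(group["gene_id"])
        degs_in = deg_ids & universe
        dropped = len(deg_ids) - len(degs_in)
        if dropped:
            logger.info("enrich_all[%s]: %d DEG ids outside the annotated universe ignored",
                        term_type, dropped)
        N, n = len(universe), len(degs_in)
        terms = group.groupby("term_id")["gene_id"].apply(set)
        T = len(terms)
        for term_id, members in terms.items():
            M = len(members)
            m = len(members & degs_in)
            p_raw = hypergeom_enrich(N, n, M, m)
            p_bonf = min(1.0, p_raw * T)
            out_rows.append(
                {
                    "term_id": term_id,
                    "term_type": term_type,
                    "N": N,
                    "n": n,
                    "M": M,
                    "m": m,
                    "annotation_rate_pct": 100.0 * m / n if n else 0.0,
                    "p_raw": p_raw,
                    "p_bonferroni": p_bonf,
                    "enriched": p_bonf <= alpha,
                }
            )
    df = pd.DataFrame(out_rows)
    df = df.sort_values(["term_type", "p_raw", "term_id"], kind="mergesort")
    return df.reset_index(drop=True)
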