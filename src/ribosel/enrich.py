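"""Gene-set over-representation analysis (hypergeometric / one-sided Fisher).

Generic ORA over user-supplied GMT collections.  The universe should be the
expressed genes of the relevant comparison, not the whole genome, so the test
asks whether a pathway is over-represented among, say, differential genes
relative to everything that could have been called.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def hypergeometric_enrichment(
    query: set[str],
    universe: set[str],
    collection: Mapping[str, Mapping],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric P(X ≥ k) per term, BH-adjusted across terms.

    N = |universe|, K = |term ∩ universe|, n = |query|, k = |term ∩ query|.
    Terms with no gene in the universe are not tested.  Output is sorted by
    (q, p, term_id); ``enriched`` marks q ≤ alpha.
    """
    if not query:
        logger.warning("hypergeometric_enrichment: empty query; returning no terms")
        return pd.DataFrame(
            columns=["term_id", "description", "k", "K", "n", "N", "fold_enrichment", "p_raw", "q_value", "enriched"]
        )
    extra = query - universe
    if extra:
        raise ValueError(f"query genes outside the universe: {sorted(extra)[:5]}")
    N = len(universe)
    n = len(query)
    rows = []
    for term_id in sorted(collection):
        entry = collection[term_id]
        genes = set(entry["genes"]) & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        expected = K * n / N
        rows.append(
            {
                "term_id": term_id,
                "description": entry.get("description", ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fold_enrichment": k / expected if expected > 0 else float("nan"),
                "p_raw": p,
            }
        )
    df = pd.DataFrame.from_records(rows)
    if df.empty:
        df["q_value"] = []
        df["enriched"] = []
        return df
    df["q_value"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    df["enriched"] = df["q_value"] <= alpha
    return df.sort_values(["q_value", "p_raw", "term_id"], kind="mergesort").reset_index(drop=True)


def top_terms(result: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """First n rows of the sorted enrichment table."""
    if n <= 0:
        raise ValueError("n must be positive")
    return result.head(n).reset_index(drop=True)
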