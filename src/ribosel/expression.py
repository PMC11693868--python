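"""Gene-level expression summaries and DEG/DTG calling.

The comparison design has one library per condition within a fraction, so the
differential test is a per-gene Fisher exact test of the gene's count against
the remainder of its library, across the two libraries — the replicate-free
analogue of a count-based test.  Benjamini–Hochberg adjustment is applied over
the expression-filtered gene family, and a gene is flagged only when all three
criteria hold: |log2 fold change| ≥ 1, FPKM ≥ 1 in at least one condition, and
adjusted P ≤ 0.001 (all configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class DifferentialThresholds:
    min_abs_log2fc: float = 1.0
    min_fpkm: float = 1.0
    max_p_adj: float = 0.001


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series, totals: pd.Series) -> pd.DataFrame:
    """FPKM = count × 10⁹ / (transcript length [nt] × total mapped reads)."""
    if not counts.index.equals(lengths.reindex(counts.index).index):
        raise ValueError("length index does not match count rows")
    lens = lengths.reindex(counts.index)
    if lens.isna().any():
        raise ValueError("missing transcript lengths")
    if (lens < 1).any():
        raise ValueError("transcript lengths must be ≥ 1 nt")
    tot = totals.reindex(counts.columns)
    if tot.isna().any() or (tot < 1).any():
        raise ValueError("library totals must be ≥ 1 and cover every column")
    return counts * 1e9 / np.outer(lens.to_numpy(), tot.to_numpy())


def fisher_count_test(count_a: float, total_a: int, count_b: float, total_b: int) -> float:
    """Two-sided Fisher exact p for one gene's counts against the library remainders."""
    ca, cb = int(round(count_a)), int(round(count_b))
    table = [[ca, int(total_a) - ca], [cb, int(total_b) - cb]]
    if min(table[0][1], table[1][1]) < 0:
        raise ValueError("gene count exceeds library total")
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def call_differential(
    gene_counts_A: pd.Series,
    gene_counts_B: pd.Series,
    gene_fpkm_A: pd.Series,
    gene_fpkm_B: pd.Series,
    total_A: int,
    total_B: int,
    thresholds: DifferentialThresholds = DifferentialThresholds(),
    pseudocount: float = 0.25,
) -> pd.DataFrame:
    """Per-gene differential calls for one comparison (one library per condition).

    The pseudocount enters the fold change only, never the test.  Genes below
    the expression filter are excluded from the multiple-testing family (their
    p columns are NaN) and flagged ``ns``.
    """
    if total_A < 1 or total_B < 1:
        raise ValueError("library totals must be positive")
    if not gene_counts_A.index.equals(gene_counts_B.index):
        raise ValueError("count vectors must share the gene index")
    genes = gene_counts_A.index
    fa = gene_fpkm_A.reindex(genes)
    fb = gene_fpkm_B.reindex(genes)
    log2fc = np.log2((fb + pseudocount) / (fa + pseudocount))
    expressed = (fa >= thresholds.min_fpkm) | (fb >= thresholds.min_fpkm)

    p_raw = pd.Series(np.nan, index=genes)
    tested = genes[expressed]
    p_raw.loc[tested] = [
        fisher_count_test(gene_counts_A[g], total_A, gene_counts_B[g], total_B) for g in tested
    ]
    p_adj = pd.Series(np.nan, index=genes)
    if len(tested):
        p_adj.loc[tested] = multipletests(p_raw.loc[tested].to_numpy(), method="fdr_bh")[1]

    flag = pd.Series("ns", index=genes, dtype=object)
    sig = expressed & (p_adj <= thresholds.max_p_adj) & (log2fc.abs() >= thresholds.min_abs_log2fc)
    flag[sig & (log2fc > 0)] = "up_B"
    flag[sig & (log2fc < 0)] = "up_A"
    return pd.DataFrame(
        {
            "gene_id": genes,
            "count_A": gene_counts_A.to_numpy(),
            "count_B": gene_counts_B.to_numpy(),
            "fpkm_A": fa.to_numpy(),
            "fpkm_B": fb.to_numpy(),
            "log2fc": log2fc.to_numpy(),
            "expressed": expressed.to_numpy(),
            "p_raw": p_raw.to_numpy(),
            "p_adj": p_adj.to_numpy(),
            "flag": flag.to_numpy(),
        }
    ).set_index("gene_id", drop=False)


def differential_gene_set(calls: pd.DataFrame) -> set[str]:
    """Genes flagged in either direction."""
    return set(calls.loc[calls["flag"] != "ns", "gene_id"])


def overlap_calls(deg: set[str], dtg: set[str]) -> dict[str, float]:
    """Exact overlap statistics between DEG and DTG sets."""
    shared = deg & dtg
    return {
        "n_deg": len(deg),
        "n_dtg": len(dtg),
        "n_shared": len(shared),
        "frac_of_deg": len(shared) / len(deg) if deg else float("nan"),
        "frac_of_dtg": len(shared) / len(dtg) if dtg else float("nan"),
    }
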