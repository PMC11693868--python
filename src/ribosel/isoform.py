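"""Ribosome-selective isoform usage within one condition.

For every multi-isoform gene the isoform composition of the cytosolic fraction
is compared with the ribosome-associated fraction:

* a per-gene chi-square homogeneity test on the 2×k table of isoform counts
  (cytosolic row vs ribosome row), with two small-sample modifications — a
  per-cell pseudocount and merging of low-expectation isoforms into an "other"
  bin — both configurable and both recorded in output metadata;
* the per-isoform selection score Diff_CP = CP_ribo − CP_cyto, where CP is an
  isoform's share of its gene's counts within one fraction (positive Diff_CP:
  the ribosome preferentially engages that isoform);
* the extreme pair (maximally positively / maximally negatively selected
  isoforms) and the mRNA structural elements (5'UTR, 3'UTR, CDS) in which the
  two differ;
* dominant-transcript calls per fraction and switch detection between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable, TranscriptCatalog

STRUCTURAL_ELEMENTS = ("utr5", "utr3", "cds")


@dataclass(frozen=True)
class IsoformUsage:
    """Per-gene isoform counts and composition proportions in both fractions.

    ``transcript_ids`` is the union of isoforms passing the expression filter
    in either fraction; CP vectors are renormalized within each fraction over
    the isoforms expressed there (absent isoforms carry CP 0), so each vector
    sums to 1 whenever the fraction has any expressed isoform.
    """

    gene_id: str
    transcript_ids: tuple[str, ...]
    counts_cyto: np.ndarray
    counts_ribo: np.ndarray
    cp_cyto: np.ndarray
    cp_ribo: np.ndarray

    @property
    def k(self) -> int:
        return len(self.transcript_ids)


@dataclass(frozen=True)
class ChiSquareResult:
    chi2_stat: float
    df: int
    p_raw: float
    k_merged: int


def _proportions(counts: np.ndarray, expressed: np.ndarray) -> np.ndarray:
    cp = np.zeros_like(counts, dtype=float)
    total = counts[expressed].sum()
    if total > 0:
        cp[expressed] = counts[expressed] / total
    return cp


def _make_usage(
    gene_id: str,
    tx_ids: np.ndarray,
    counts_c: np.ndarray,
    counts_r: np.ndarray,
    expr_c: np.ndarray,
    expr_r: np.ndarray,
) -> IsoformUsage | None:
    keep = expr_c | expr_r
    if not keep.any():
        return None
    order = np.argsort(tx_ids[keep])
    ids = tuple(tx_ids[keep][order])
    return IsoformUsage(
        gene_id=gene_id,
        transcript_ids=ids,
        counts_cyto=counts_c[keep][order],
        counts_ribo=counts_r[keep][order],
        cp_cyto=_proportions(counts_c[keep][order], expr_c[keep][order]),
        cp_ribo=_proportions(counts_r[keep][order], expr_r[keep][order]),
    )


def build_isoform_usage(
    table: AbundanceTable,
    gene_id: str,
    condition: str,
    min_tx_fpkm: float = 1.0,
) -> IsoformUsage | None:
    """Assemble the usage record for one gene in one condition.

    Returns None when no isoform passes the expression filter in either
    fraction (the gene is skipped and excluded from every family).
    """
    cyto = table.library_id(condition, "cytosolic")
    ribo = table.library_id(condition, "ribosome")
    txs = table.tx2gene.index[table.tx2gene == gene_id]
    return _make_usage(
        gene_id,
        np.asarray(txs, dtype=object),
        table.counts.loc[txs, cyto].to_numpy(dtype=float),
        table.counts.loc[txs, ribo].to_numpy(dtype=float),
        table.fpkm.loc[txs, cyto].to_numpy() >= min_tx_fpkm,
        table.fpkm.loc[txs, ribo].to_numpy() >= min_tx_fpkm,
    )


def isoform_proportions(
    table: AbundanceTable,
    gene_id: str,
    condition: str,
    fraction: str,
    min_tx_fpkm: float = 1.0,
) -> pd.Series:
    """CP_i = count_i / Σ counts over isoforms with FPKM ≥ min_tx_fpkm in that fraction."""
    lib = table.library_id(condition, fraction)
    txs = table.tx2gene.index[table.tx2gene == gene_id]
    counts = table.counts.loc[txs, lib]
    expressed = table.fpkm.loc[txs, lib] >= min_tx_fpkm
    counts = counts[expressed]
    total = counts.sum()
    if len(counts) == 0 or total <= 0:
        return pd.Series(dtype=float)
    return (counts / total).sort_index()


def selective_usage_test(
    usage: IsoformUsage,
    min_expected: float = 5.0,
    pseudocount: float = 0.5,
) -> ChiSquareResult | None:
    """Chi-square homogeneity test of isoform composition between fractions.

    Modifications to the textbook Pearson test: (i) ``pseudocount`` is added
    to every cell; (ii) while any expected cell count stays below
    ``min_expected`` and more than two isoform bins remain, the two
    lowest-usage bins are merged into one "other" bin.  With pseudocount 0 and
    ``min_expected`` 0 the statistic is the unmodified Pearson chi-square on
    the 2×k table.  Returns None for genes that are not testable (fewer than
    two expressed isoforms, or an empty fraction).
    """
    if usage.k < 2:
        return None
    obs = np.vstack([usage.counts_cyto, usage.counts_ribo]).astype(float) + pseudocount
    if obs.sum(axis=1).min() <= 0:
        return None
    while obs.shape[1] > 2:
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        if expected.min() >= min_expected:
            break
        order = np.argsort(obs.sum(axis=0))
        merged = obs[:, order[0]] + obs[:, order[1]]
        obs = np.column_stack([np.delete(obs, order[:2], axis=1), merged])
    k = obs.shape[1]
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if expected.min() <= 0:
        return None
    chi2, _p, _df, _ = stats.chi2_contingency(obs, correction=False)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return ChiSquareResult(chi2_stat=float(chi2), df=df, p_raw=p, k_merged=k)


def adjust_selection_pvalues(p_raw: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini–Hochberg q-values and selection flags over the testable family."""
    if len(p_raw) == 0:
        return pd.DataFrame(columns=["q_value", "selected"])
    q = multipletests(p_raw.to_numpy(), method="fdr_bh")[1]
    return pd.DataFrame({"q_value": q, "selected": q <= alpha}, index=p_raw.index)


def diff_cp(usage: IsoformUsage) -> pd.Series:
    """Diff_CP_i = CP_ribo_i − CP_cyto_i over the union isoform set (sums to 0)."""
    return pd.Series(usage.cp_ribo - usage.cp_cyto, index=list(usage.transcript_ids))


def extreme_isoforms(dcp: pd.Series, cp_cyto: pd.Series | None = None) -> tuple[str, str]:
    """Maximally positively and negatively selected isoforms.

    Ties are broken by higher cytosolic CP, then lexicographic transcript id;
    in the fully degenerate all-equal case the two returned isoforms are the
    first two under the tie ordering.
    """
    if len(dcp) < 2:
        raise ValueError("extreme_isoforms needs at least 2 isoforms")
    cp = cp_cyto.reindex(dcp.index) if cp_cyto is not None else pd.Series(0.0, index=dcp.index)
    pos = sorted(dcp.index, key=lambda t: (-dcp[t], -cp[t], t))
    neg = sorted(dcp.index, key=lambda t: (dcp[t], -cp[t], t))
    max_pos = pos[0]
    max_neg = neg[0] if neg[0] != max_pos else neg[1]
    return max_pos, max_neg


def compare_structural_elements(
    tx_a: str,
    tx_b: str,
    catalog: TranscriptCatalog,
) -> set[str]:
    """mRNA structural elements whose genomic interval sets differ between two isoforms.

    A coding/non-coding pair reports every element present in either
    transcript, since the element decomposition itself is undefined for the
    non-coding partner.
    """
    a = catalog.transcripts[tx_a]
    b = catalog.transcripts[tx_b]
    if a.gene_id != b.gene_id:
        raise ValueError(f"{tx_a} and {tx_b} belong to different genes")
    if a.is_coding != b.is_coding:
        return {
            e for e in STRUCTURAL_ELEMENTS if getattr(a, e) or getattr(b, e)
        }
    return {e for e in STRUCTURAL_ELEMENTS if getattr(a, e) != getattr(b, e)}


def multi_isoform_stats(
    table: AbundanceTable,
    condition: str,
    fraction: str,
    min_tx_fpkm: float = 1.0,
) -> dict[str, float]:
    """Fraction of genes using ≥2 isoforms above the expression filter in one fraction."""
    lib = table.library_id(condition, fraction)
    expressed = table.fpkm[lib] >= min_tx_fpkm
    per_gene = expressed.groupby(table.tx2gene.reindex(table.fpkm.index)).sum()
    n_total = len(per_gene)
    n_ge2 = int((per_gene >= 2).sum())
    return {
        "n_genes_ge2_expressed": n_ge2,
        "n_genes_total": n_total,
        "proportion": n_ge2 / n_total if n_total else float("nan"),
    }


def proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided two-sample proportion test (chi-square with Yates correction)."""
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("sample size must be ≥ 1")
        if not 0 <= x <= n:
            raise ValueError("successes must lie in [0, n]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table.sum(axis=0).min() == 0:  # all successes or all failures: no difference testable
        return 1.0
    _, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(p)


def call_dominant_transcript(
    cp: pd.Series,
    cp_min: float = 0.5,
    ratio_min: float = 2.0,
) -> str | None:
    """Dominant isoform: CP ≥ cp_min and ≥ ratio_min × the runner-up CP.

    Single-isoform genes are dominant by definition.  Ties at the top are
    broken lexicographically for determinism.
    """
    if len(cp) == 0:
        raise ValueError("empty CP vector")
    order = sorted(cp.index, key=lambda t: (-cp[t], t))
    if len(cp) == 1:
        return order[0]
    top, second = cp[order[0]], cp[order[1]]
    if top >= cp_min and top >= ratio_min * second:
        return order[0]
    return None


def detect_dominant_switch(dom_cyto: str | None, dom_ribo: str | None) -> str:
    """unchanged / switched when both fractions have a dominant isoform; else undefined."""
    if dom_cyto is None or dom_ribo is None:
        return "undefined"
    return "unchanged" if dom_cyto == dom_ribo else "switched"


def analyze_condition(
    table: AbundanceTable,
    catalog: TranscriptCatalog | None,
    condition: str,
    alpha: float = 0.05,
    min_expected: float = 5.0,
    pseudocount: float = 0.5,
    min_tx_fpkm: float = 1.0,
    dominant_cp_min: float = 0.5,
    dominant_ratio_min: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-gene isoform-selection analysis for one condition.

    Returns (gene table, per-isoform Diff_CP table).  The gene table carries
    the chi-square test, BH q-values over the testable family, extreme
    isoforms, structural differences (when a catalog is given), dominant
    calls and switch status.
    """
    cyto = table.library_id(condition, "cytosolic")
    ribo = table.library_id(condition, "ribosome")
    tx_index = np.asarray(table.counts.index, dtype=object)
    tx2gene = table.tx2gene.reindex(table.counts.index)
    counts_c = table.counts[cyto].to_numpy(dtype=float)
    counts_r = table.counts[ribo].to_numpy(dtype=float)
    expr_c = table.fpkm[cyto].to_numpy() >= min_tx_fpkm
    expr_r = table.fpkm[ribo].to_numpy() >= min_tx_fpkm
    gene_positions = tx2gene.reset_index(drop=True).groupby(tx2gene.values, sort=True).indices

    gene_rows = []
    iso_rows = []
    for gene_id in sorted(gene_positions):
        ix = gene_positions[gene_id]
        usage = _make_usage(
            gene_id, tx_index[ix], counts_c[ix], counts_r[ix], expr_c[ix], expr_r[ix]
        )
        row: dict = {
            "gene_id": gene_id,
            "n_isoforms_expressed": 0 if usage is None else usage.k,
            "chi2_stat": np.nan,
            "df": 0,
            "p_raw": np.nan,
            "testable": False,
            "max_pos_tx": "",
            "max_neg_tx": "",
            "structural_diff": "",
            "dominant_cyto": "",
            "dominant_ribo": "",
            "dominant_switch": "undefined",
        }
        if usage is not None:
            res = selective_usage_test(usage, min_expected=min_expected, pseudocount=pseudocount)
            if res is not None:
                row.update(
                    chi2_stat=res.chi2_stat, df=res.df, p_raw=res.p_raw, testable=True
                )
            if usage.k >= 2:
                dcp = diff_cp(usage)
                cps = pd.Series(usage.cp_cyto, index=list(usage.transcript_ids))
                max_pos, max_neg = extreme_isoforms(dcp, cps)
                row["max_pos_tx"] = max_pos
                row["max_neg_tx"] = max_neg
                if catalog is not None:
                    diff = compare_structural_elements(max_pos, max_neg, catalog)
                    row["structural_diff"] = ",".join(sorted(diff))
                for tx, d in dcp.items():
                    iso_rows.append(
                        {
                            "gene_id": gene_id,
                            "transcript_id": tx,
                            "cp_cyto": float(cps[tx]),
                            "cp_ribo": float(cps[tx] + d),
                            "diff_cp": float(d),
                        }
                    )
            dom_c = _dominant_from_cp(usage.cp_cyto, usage.transcript_ids, dominant_cp_min, dominant_ratio_min)
            dom_r = _dominant_from_cp(usage.cp_ribo, usage.transcript_ids, dominant_cp_min, dominant_ratio_min)
            row["dominant_cyto"] = dom_c or ""
            row["dominant_ribo"] = dom_r or ""
            row["dominant_switch"] = detect_dominant_switch(dom_c, dom_r)
        gene_rows.append(row)
    genes = pd.DataFrame.from_records(gene_rows).set_index("gene_id", drop=False)
    genes["q_value"] = np.nan
    genes["selected"] = False
    testable = genes.index[genes["testable"]]
    if len(testable):
        adj = adjust_selection_pvalues(genes.loc[testable, "p_raw"], alpha=alpha)
        genes.loc[testable, "q_value"] = adj["q_value"]
        genes.loc[testable, "selected"] = adj["selected"]
    iso = pd.DataFrame.from_records(iso_rows, columns=["gene_id", "transcript_id", "cp_cyto", "cp_ribo", "diff_cp"])
    return genes, iso


def _dominant_from_cp(
    cp: np.ndarray,
    tx_ids: tuple[str, ...],
    cp_min: float,
    ratio_min: float,
) -> str | None:
    s = pd.Series(cp, index=list(tx_ids))
    s = s[s > 0]
    if len(s) == 0:
        return None
    return call_dominant_transcript(s, cp_min=cp_min, ratio_min=ratio_min)
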