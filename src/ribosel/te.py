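"""Translational efficiency: computation, [0,1] normalization, differential calls.

TE is the gene-level ratio of ribosome-associated to cytosolic FPKM within one
condition.  Before comparing conditions the TE vectors are normalized to
[0, 1] over the common-gene set; the default is the empirical quantile (rank)
transform, which is robust to the heavy right tail of abundance ratios —
min–max scaling is available but a single outlier compresses every other gene
into a narrow band.  A gene is differentially translated when the normalized
TEs differ by more than ``delta_threshold`` (default 0.5).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


def compute_te(cyto_fpkm: pd.Series, ribo_fpkm: pd.Series, min_fpkm: float = 1.0) -> pd.Series:
    """Per-gene TE = ribo FPKM / cyto FPKM for genes with cytosolic FPKM ≥ min_fpkm.

    Genes failing the cytosolic filter (including zero denominators) are
    absent from the output.
    """
    eligible = cyto_fpkm.index[(cyto_fpkm >= min_fpkm) & (cyto_fpkm > 0)]
    dropped = len(cyto_fpkm) - len(eligible)
    if dropped:
        logger.info("compute_te: %d genes below cytosolic FPKM %.3g excluded", dropped, min_fpkm)
    te = ribo_fpkm.reindex(eligible) / cyto_fpkm.reindex(eligible)
    te.name = "te"
    return te


def normalize_te(te: pd.Series, method: str = "rank") -> pd.Series:
    """Map TE values onto [0, 1].

    rank:   (rank − 1)/(n − 1) with average ranks for ties (n = 1 maps to 0.5).
    minmax: (x − min)/(max − min); an all-constant vector maps to 0.5 with a
            warning, since no ordering information exists.
    """
    x = te.to_numpy(dtype=float)
    if method == "rank":
        if len(x) == 0:
            return pd.Series(dtype=float, index=te.index)
        if len(x) == 1:
            return pd.Series([0.5], index=te.index)
        norm = (rankdata(x, method="average") - 1.0) / (len(x) - 1.0)
    elif method == "minmax":
        if len(x) < 2:
            raise ValueError("minmax normalization needs at least 2 values")
        lo, hi = x.min(), x.max()
        if hi == lo:
            logger.warning("normalize_te: all TE values identical; mapping to 0.5")
            norm = np.full_like(x, 0.5)
        else:
            norm = (x - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return pd.Series(norm, index=te.index)


def call_differential_te(
    te_norm_A: pd.Series,
    te_norm_B: pd.Series,
    delta_threshold: float = 0.5,
) -> pd.DataFrame:
    """Flag genes whose normalized TE differs by more than the threshold.

    ``delta`` is condition A minus condition B; ``up_A`` means higher relative
    TE in condition A.
    """
    if not te_norm_A.index.equals(te_norm_B.index):
        raise ValueError("normalized TE vectors must share the same gene index")
    if not 0 < delta_threshold <= 1:
        raise ValueError("delta_threshold must be in (0, 1]")
    delta = te_norm_A - te_norm_B
    flag = pd.Series("ns", index=delta.index, dtype=object)
    flag[delta > delta_threshold] = "up_A"
    flag[delta < -delta_threshold] = "up_B"
    return pd.DataFrame(
        {
            "gene_id": delta.index,
            "te_norm_A": te_norm_A.to_numpy(),
            "te_norm_B": te_norm_B.to_numpy(),
            "delta": delta.to_numpy(),
            "flag": flag.to_numpy(),
        }
    ).set_index("gene_id", drop=False)


def joint_te_table(
    te_A: pd.Series,
    te_B: pd.Series,
    method: str = "rank",
    delta_threshold: float = 0.5,
) -> pd.DataFrame:
    """Common-gene joint analysis: intersect eligible sets, normalize, call.

    Mirrors the two-condition workflow: TE is first computed per condition
    over that condition's eligible genes, then restricted to the intersection
    before normalization so both normalized vectors describe the same family.
    """
    common = te_A.index.intersection(te_B.index).sort_values()
    na = normalize_te(te_A.reindex(common), method=method)
    nb = normalize_te(te_B.reindex(common), method=method)
    out = call_differential_te(na, nb, delta_threshold=delta_threshold)
    out.insert(1, "te_A", te_A.reindex(common).to_numpy())
    out.insert(2, "te_B", te_B.reindex(common).to_numpy())
    return out
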