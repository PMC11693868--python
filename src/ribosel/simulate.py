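"""Synthetic transcript catalogs and four-library counts with planted effects.

The generator emulates a two-condition (A = embryo-like, B = cell-line-like)
polysome-profiling experiment: for each condition one cytosolic and one
ribosome-associated library, quantified at transcript level.  Effects planted
on top of a null model — differential expression, translational-efficiency
shifts, ribosome-selective isoform usage, dominant-transcript switches — are
recorded per gene in :class:`TruthRecord` so that every downstream caller can
be scored against ground truth.

Counts are negative-binomial around depth-scaled expectations.  The default
dispersion is small: with one library per condition × fraction the experiment
has no biological replicates, so the noise being modelled is the technical
sampling of a fixed mRNA pool, which is close to Poisson.  Larger dispersions
are accepted for sensitivity studies of how overdispersion breaks
replicate-free tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import compute_fpkm
from .io import (
    AbundanceTable,
    LibrarySpec,
    TranscriptCatalog,
    build_transcript,
)
from .isoform import call_dominant_transcript

STRUCTURE_ELEMENTS = {
    "base": frozenset(),
    "utr5": frozenset({"utr5"}),
    "utr3": frozenset({"utr3"}),
    # moving the stop codon changes both the CDS and the 3'UTR interval sets
    "cds": frozenset({"cds", "utr3"}),
}


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic experiment.

    ``isoform_count_weights`` are probabilities for 1..5 isoforms per gene;
    the default mean is ≈1.9 isoforms/gene, matching a typical multi-isoform
    assembly.  Expression baselines are log-normal (``mean_expression_log2``,
    ``sd_expression_log2`` in log2 units); per-gene baseline translational
    efficiency is log-normal with spread ``te_log2_sd`` and is shared between
    conditions, so under the null the two conditions rank genes identically up
    to sampling noise.
    """

    n_genes: int = 500
    isoform_count_weights: tuple[float, ...] = (0.45, 0.30, 0.15, 0.07, 0.03)
    mean_expression_log2: float = 5.0
    sd_expression_log2: float = 1.5
    nb_dispersion: float = 1e-6
    te_log2_sd: float = 1.0
    dirichlet_alpha: float = 2.0
    frac_de_genes: float = 0.1
    de_log2fc: float = 2.0
    frac_te_shift_genes: float = 0.1
    te_shift_log2: float = 3.0
    frac_selection_genes: float = 0.1
    selection_cp_shift: float = 0.3
    frac_dominant_switch: float = 0.1
    library_depth: int = 2_000_000
    n_replicates: int = 1
    structure_variant_probs: tuple[tuple[str, float], ...] = (
        ("utr5", 0.45),
        ("utr3", 0.45),
        ("cds", 0.10),
    )
    minus_strand_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be ≥ 1")
        if len(self.isoform_count_weights) != 5 or abs(sum(self.isoform_count_weights) - 1) > 1e-9:
            raise ValueError("isoform_count_weights must be 5 probabilities summing to 1")
        for name in ("frac_de_genes", "frac_te_shift_genes", "frac_selection_genes", "frac_dominant_switch"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 < self.selection_cp_shift <= 0.5:
            raise ValueError("selection_cp_shift must be in (0, 0.5]")
        if self.library_depth < 1:
            raise ValueError("library_depth must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be ≥ 1")
        vp = dict(self.structure_variant_probs)
        if set(vp) - {"utr5", "utr3", "cds"} or abs(sum(vp.values()) - 1) > 1e-9:
            raise ValueError("structure_variant_probs must cover utr5/utr3/cds and sum to 1")


@dataclass(frozen=True)
class TruthRecord:
    """Per-gene ground truth for the planted effects.

    ``is_selected`` is true whenever the ribosome-fraction isoform composition
    was planted away from the cytosolic one — by a CP-shift draw
    (``selection_planted``), a dominant-switch draw (``switch_planted``) or
    both — since any of these makes the gene a true positive for the
    selective-usage test.
    """

    gene_id: str
    is_de: bool
    de_direction: str  # up_A / up_B / none
    is_te_shifted: bool
    te_direction: str
    is_selected: bool
    selection_planted: bool
    switch_planted: bool
    planted_cp_shift: dict[str, float]  # transcript_id -> ribo CP − cyto CP, sums to 0
    dominant_cyto: str | None
    dominant_ribo: str | None


# ---------------------------------------------------------------------------
# catalog generation
# ---------------------------------------------------------------------------

_GENE_SPACING = 10_000
_VARIANT_STEP = 40


def _oriented_structure(variant: str, j: int) -> tuple[list, list]:
    """Exon/CDS intervals for isoform variant ``variant`` at offset rank ``j``,
    in oriented (plus-strand) coordinates relative to the gene origin."""
    d = _VARIANT_STEP * j
    exons = [[200, 800], [1100, 2300]]
    cds = [[400, 800], [1100, 1900]]
    if variant == "utr5":
        exons[0][0] = 200 + d  # shorter 5'UTR
    elif variant == "utr3":
        exons[1][1] = 2300 + d  # longer 3'UTR
    elif variant == "cds":
        cds[1][1] = 1900 - d  # earlier stop codon; 3'UTR grows accordingly
    elif variant != "base":
        raise ValueError(f"unknown variant {variant}")
    return exons, cds


def generate_catalog_with_truth(params: SimulationParams) -> tuple[TranscriptCatalog, pd.DataFrame]:
    """Build the synthetic catalog plus a per-transcript structure-truth table.

    Isoforms of a gene share a CDS core and differ from the gene's base
    isoform in 5'UTR, 3'UTR or CDS extent; each isoform gets a distinct
    coordinate offset, so any two isoforms of a gene differ exactly in the
    union of their planted element sets.  The truth table records that set.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    variants, variant_probs = zip(*params.structure_variant_probs)
    models = []
    records = []
    for gi in range(params.n_genes):
        gene_id = f"G{gi + 1:05d}"
        k = int(rng.choice(np.arange(1, 6), p=np.asarray(params.isoform_count_weights)))
        strand = "-" if rng.random() < params.minus_strand_prob else "+"
        origin = _GENE_SPACING * gi
        reflect = 2 * origin + 2_500  # keeps minus-strand genes inside their block
        for j in range(k):
            variant = "base" if j == 0 else str(rng.choice(variants, p=np.asarray(variant_probs)))
            exons, cds = _oriented_structure(variant, j)
            if strand == "+":
                exon_iv = [(origin + a, origin + b) for a, b in exons]
                cds_iv = [(origin + a, origin + b) for a, b in cds]
            else:
                exon_iv = [(reflect - origin - b, reflect - origin - a) for a, b in exons]
                cds_iv = [(reflect - origin - b, reflect - origin - a) for a, b in cds]
            tx_id = f"{gene_id}.t{j + 1}"
            models.append(build_transcript(tx_id, gene_id, "chrS", strand, exon_iv, cds_iv))
            records.append(
                {
                    "transcript_id": tx_id,
                    "gene_id": gene_id,
                    "variant": variant,
                    "variant_elements": ",".join(sorted(STRUCTURE_ELEMENTS[variant])),
                }
            )
    catalog = TranscriptCatalog.from_transcripts(models)
    return catalog, pd.DataFrame.from_records(records)


def generate_catalog(params: SimulationParams) -> TranscriptCatalog:
    catalog, _ = generate_catalog_with_truth(params)
    return catalog


def expected_structural_difference(structure_truth: pd.DataFrame, tx_a: str, tx_b: str) -> set[str]:
    """Elements in which two simulated isoforms differ, from the construction rule."""
    s = structure_truth.set_index("transcript_id")["variant_elements"]
    ea = set(s[tx_a].split(",")) - {""}
    eb = set(s[tx_b].split(",")) - {""}
    return ea | eb if tx_a != tx_b else set()


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _apply_cp_shift(cp: np.ndarray, shift: float) -> np.ndarray:
    """Move CP mass ``shift`` onto one isoform, rescaling the others.

    The target is the highest-CP isoform that can absorb +shift without
    exceeding 1; if none can, the highest-CP isoform loses ``shift`` instead.
    """
    out = cp.astype(float).copy()
    order = np.argsort(-out)
    target = next((i for i in order if out[i] + shift <= 1.0), None)
    if target is not None:
        rest = 1.0 - out[target]
        out[np.arange(len(out)) != target] *= (rest - shift) / max(rest, 1e-12)
        out[target] += shift
    else:
        target = order[0]
        rest = 1.0 - out[target]
        out[np.arange(len(out)) != target] *= (rest + shift) / max(rest, 1e-12)
        out[target] -= shift
    return out


def _swap_top_two(cp: np.ndarray) -> np.ndarray:
    out = cp.astype(float).copy()
    if len(out) >= 2:
        order = np.argsort(-out)
        i, j = order[0], order[1]
        out[i], out[j] = out[j], out[i]
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 0.0))
    return rng.negative_binomial(r, p).astype(float)


@dataclass
class _PlantedModel:
    gene_ids: list[str]
    mu: np.ndarray
    is_de: np.ndarray
    de_sign: np.ndarray
    is_te: np.ndarray
    te_sign: np.ndarray
    is_sel: np.ndarray
    is_switch: np.ndarray
    cp_cyto: list[np.ndarray]
    cp_ribo: list[np.ndarray]
    w: dict[tuple[str, str], np.ndarray]


def _planted_model(catalog: TranscriptCatalog, params: SimulationParams) -> _PlantedModel:
    """Draw all planted effects (deterministic in params.seed; no count noise)."""
    rng = np.random.default_rng([params.seed, 0])
    gene_ids = sorted(catalog.genes)
    G = len(gene_ids)
    k_per_gene = np.array([len(catalog.genes[g]) for g in gene_ids])
    multi = k_per_gene >= 2

    base_log2 = rng.normal(params.mean_expression_log2, params.sd_expression_log2, G)
    te_base = 2.0 ** rng.normal(0.0, params.te_log2_sd, G)
    is_de = rng.random(G) < params.frac_de_genes
    de_sign = rng.choice([-1.0, 1.0], G)
    is_te = rng.random(G) < params.frac_te_shift_genes
    te_sign = rng.choice([-1.0, 1.0], G)
    is_sel = (rng.random(G) < params.frac_selection_genes) & multi
    is_switch = (rng.random(G) < params.frac_dominant_switch) & multi

    mu = 2.0 ** base_log2
    de_mult = np.where(is_de, 2.0 ** (de_sign * params.de_log2fc), 1.0)
    te_mult = np.where(is_te, 2.0 ** (te_sign * params.te_shift_log2), 1.0)

    cp_cyto: list[np.ndarray] = []
    cp_ribo: list[np.ndarray] = []
    for gi in range(G):
        k = int(k_per_gene[gi])
        cp = rng.dirichlet(np.full(k, params.dirichlet_alpha)) if k > 1 else np.array([1.0])
        ribo = cp
        if is_sel[gi]:
            ribo = _apply_cp_shift(ribo, params.selection_cp_shift)
        if is_switch[gi]:
            ribo = _swap_top_two(ribo)
        cp_cyto.append(cp)
        cp_ribo.append(ribo)

    w = {
        ("A", "cytosolic"): mu,
        ("A", "ribosome"): mu * te_base,
        ("B", "cytosolic"): mu * de_mult,
        ("B", "ribosome"): mu * de_mult * te_base * te_mult,
    }
    return _PlantedModel(gene_ids, mu, is_de, de_sign, is_te, te_sign, is_sel, is_switch, cp_cyto, cp_ribo, w)


def _expected_matrix(catalog: TranscriptCatalog, params: SimulationParams, model: _PlantedModel) -> pd.DataFrame:
    tx_ids = [tx for g in model.gene_ids for tx in sorted(catalog.genes[g])]
    cols = {}
    for cond in ("A", "B"):
        for frac, short in (("cytosolic", "cyto"), ("ribosome", "ribo")):
            expected = np.concatenate(
                [
                    model.w[(cond, frac)][gi]
                    * (model.cp_cyto[gi] if frac == "cytosolic" else model.cp_ribo[gi])
                    for gi in range(len(model.gene_ids))
                ]
            )
            cols[f"{cond}_{short}"] = params.library_depth * expected / expected.sum()
    return pd.DataFrame(cols, index=pd.Index(tx_ids, name="transcript_id"))


def expected_mean_counts(catalog: TranscriptCatalog, params: SimulationParams) -> pd.DataFrame:
    """Depth-scaled expected transcript counts per library, before count noise."""
    params.validate()
    return _expected_matrix(catalog, params, _planted_model(catalog, params))


def simulate_counts(
    catalog: TranscriptCatalog,
    params: SimulationParams,
    noise_seed: int | None = None,
) -> tuple[AbundanceTable, list[TruthRecord]]:
    """Draw the four-library count matrix with planted effects.

    Per gene g the relative abundance is log-normal; condition B multiplies it
    by 2^±de_log2fc for DE genes; the ribosome fraction multiplies it by the
    gene's baseline TE and, for TE-shifted genes, by an extra 2^±te_shift_log2
    in condition B.  Isoform proportions are Dirichlet in the cytosolic
    fraction; selected genes get a CP shift and switch genes a top-two swap in
    the ribosome fraction.  Transcript counts are negative binomial around the
    depth-scaled expectation; FPKM is computed from realized library sizes.

    ``noise_seed`` reseeds only the count noise, leaving the planted effects
    fixed — the handle for Monte-Carlo studies of the same planted experiment.
    """
    params.validate()
    model = _planted_model(catalog, params)
    expected_df = _expected_matrix(catalog, params, model)
    rng = np.random.default_rng([params.seed if noise_seed is None else noise_seed, 1])

    specs: list[LibrarySpec] = []
    counts = {}
    for base_id in expected_df.columns:
        cond, short = base_id.split("_")
        frac = "cytosolic" if short == "cyto" else "ribosome"
        for rep in range(1, params.n_replicates + 1):
            lib_id = base_id if params.n_replicates == 1 else f"{base_id}_rep{rep}"
            drawn = _nb_draw(rng, expected_df[base_id].to_numpy(), params.nb_dispersion)
            counts[lib_id] = drawn
            specs.append(
                LibrarySpec(
                    library_id=lib_id,
                    condition=cond,
                    fraction=frac,
                    total_mapped_reads=max(int(drawn.sum()), 1),
                )
            )

    tx_ids = list(expected_df.index)
    lengths = pd.Series({t: catalog.transcripts[t].length for t in tx_ids}, dtype=float)
    counts_df = pd.DataFrame(counts, index=expected_df.index)
    totals = pd.Series({s.library_id: float(s.total_mapped_reads) for s in specs})
    fpkm_df = compute_fpkm(counts_df, lengths, totals)
    tx_gene = pd.Series({t: catalog.transcripts[t].gene_id for t in tx_ids}, dtype=object)
    table = AbundanceTable(
        counts=counts_df.sort_index(),
        fpkm=fpkm_df.sort_index(),
        tx2gene=tx_gene.sort_index(),
        lengths=lengths.sort_index(),
        specs=tuple(specs),
    )

    truth: list[TruthRecord] = []
    for gi, g in enumerate(model.gene_ids):
        txs = sorted(catalog.genes[g])
        shift = {t: float(model.cp_ribo[gi][i] - model.cp_cyto[gi][i]) for i, t in enumerate(txs)}
        dom_c = call_dominant_transcript(pd.Series(model.cp_cyto[gi], index=txs))
        dom_r = call_dominant_transcript(pd.Series(model.cp_ribo[gi], index=txs))
        truth.append(
            TruthRecord(
                gene_id=g,
                is_de=bool(model.is_de[gi]),
                de_direction=("up_B" if model.de_sign[gi] > 0 else "up_A") if model.is_de[gi] else "none",
                is_te_shifted=bool(model.is_te[gi]),
                te_direction=("up_B" if model.te_sign[gi] > 0 else "up_A") if model.is_te[gi] else "none",
                is_selected=bool(model.is_sel[gi] or model.is_switch[gi]),
                selection_planted=bool(model.is_sel[gi]),
                switch_planted=bool(model.is_switch[gi]),
                planted_cp_shift=shift,
                dominant_cyto=dom_c,
                dominant_ribo=dom_r,
            )
        )
    return table, truth


def simulate_experiment(
    params: SimulationParams,
) -> tuple[TranscriptCatalog, pd.DataFrame, AbundanceTable, list[TruthRecord]]:
    """Catalog + structure truth + counts + per-gene truth in one call."""
    catalog, structure = generate_catalog_with_truth(params)
    table, truth = simulate_counts(catalog, params)
    return catalog, structure, table, truth


def truth_frames(truth: Sequence[TruthRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten truth records into a per-gene and a per-isoform table for TSV output."""
    gene_rows = []
    iso_rows = []
    for r in truth:
        gene_rows.append(
            {
                "gene_id": r.gene_id,
                "is_de": r.is_de,
                "de_direction": r.de_direction,
                "is_te_shifted": r.is_te_shifted,
                "te_direction": r.te_direction,
                "is_selected": r.is_selected,
                "selection_planted": r.selection_planted,
                "switch_planted": r.switch_planted,
                "dominant_cyto": r.dominant_cyto or "",
                "dominant_ribo": r.dominant_ribo or "",
            }
        )
        for tx, s in r.planted_cp_shift.items():
            iso_rows.append({"gene_id": r.gene_id, "transcript_id": tx, "planted_cp_shift": s})
    return pd.DataFrame.from_records(gene_rows), pd.DataFrame.from_records(iso_rows)
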