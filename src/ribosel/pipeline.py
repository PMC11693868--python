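"""End-to-end orchestration: simulate/load → expression → TE → isoform → enrich.

One :class:`RunConfig` drives the whole run.  Every stage writes its TSV into
the output directory, a ``summary.tsv`` collects the headline statistics, and
a ``MANIFEST`` lists each completed output with its SHA-256 checksum, so two
runs with the same inputs, config and seed are byte-identical (the log file,
which carries timestamps, is excluded from the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import expression, te
from . import isoform as iso_mod
from .enrich import hypergeometric_enrichment
from .io import (
    AbundanceTable,
    LibrarySpec,
    check_library_design,
    parse_gtf,
    read_gmt,
    read_quantification,
    write_gtf,
    write_quantification,
    write_results_table,
)
from .simulate import SimulationParams, simulate_experiment, truth_frames

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run.

    When ``gtf``/``quant`` are unset the bundled simulator provides the data
    (``sim_n_genes`` genes at ``seed``).  Threshold defaults: |log2FC| ≥ 1,
    FPKM ≥ 1 in at least one condition and adjusted P ≤ 0.001 for DEG/DTG
    calls; normalized-TE difference > 0.5 for differential TE; BH q ≤ 0.05
    for selective isoform usage.
    """

    outdir: str = "ribosel_run"
    gtf: str | None = None
    quant: str | None = None
    gmt: str | None = None
    libraries: dict = field(
        default_factory=lambda: {
            "A_cyto": {"condition": "A", "fraction": "cytosolic"},
            "A_ribo": {"condition": "A", "fraction": "ribosome"},
            "B_cyto": {"condition": "B", "fraction": "cytosolic"},
            "B_ribo": {"condition": "B", "fraction": "ribosome"},
        }
    )
    min_abs_log2fc: float = 1.0
    min_fpkm: float = 1.0
    max_p_adj: float = 0.001
    fc_pseudocount: float = 0.25
    delta_te: float = 0.5
    te_norm: str = "rank"
    alpha: float = 0.05
    min_expected: float = 5.0
    chi_pseudocount: float = 0.5
    min_tx_fpkm: float = 1.0
    dominant_cp_min: float = 0.5
    dominant_ratio_min: float = 2.0
    sim_n_genes: int = 200
    sim_overrides: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of human-readable constraint violations (empty iff valid)."""
    v: list[str] = []
    if not 0 < config.delta_te <= 1:
        v.append("delta_te: must be in (0,1]")
    if not 0 < config.alpha < 1:
        v.append("alpha: must be in (0,1)")
    if config.max_p_adj <= 0 or config.max_p_adj > 1:
        v.append("max_p_adj: must be in (0,1]")
    if config.min_abs_log2fc < 0:
        v.append("min_abs_log2fc: must be ≥ 0")
    if config.min_fpkm < 0:
        v.append("min_fpkm: must be ≥ 0")
    if config.fc_pseudocount < 0:
        v.append("fc_pseudocount: must be ≥ 0")
    if config.chi_pseudocount < 0:
        v.append("chi_pseudocount: must be ≥ 0")
    if config.min_expected < 0:
        v.append("min_expected: must be ≥ 0")
    if config.dominant_cp_min <= 0 or config.dominant_cp_min > 1:
        v.append("dominant_cp_min: must be in (0,1]")
    if config.dominant_ratio_min < 1:
        v.append("dominant_ratio_min: must be ≥ 1")
    if config.te_norm not in {"rank", "minmax"}:
        v.append("te_norm: must be 'rank' or 'minmax'")
    if config.sim_n_genes < 1:
        v.append("sim_n_genes: must be ≥ 1")
    needed = {("A", "cytosolic"), ("A", "ribosome"), ("B", "cytosolic"), ("B", "ribosome")}
    have = {(d.get("condition"), d.get("fraction")) for d in config.libraries.values()}
    for cond, frac in sorted(needed - have):
        v.append(f"libraries: missing library for condition {cond}, fraction {frac}")
    if (config.gtf is None) != (config.quant is None):
        v.append("gtf/quant: provide both (real data) or neither (simulation)")
    return v


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig, outdir: Path):
    if config.gtf is None:
        params = SimulationParams(
            n_genes=config.sim_n_genes, seed=config.seed, **config.sim_overrides
        )
        catalog, structure, table, truth = simulate_experiment(params)
        write_gtf(catalog, outdir / "catalog.gtf")
        write_quantification(table, outdir / "quantification.tsv")
        tg, ti = truth_frames(truth)
        write_results_table(tg, outdir / "truth_genes.tsv")
        write_results_table(ti, outdir / "truth_isoforms.tsv")
        write_results_table(structure, outdir / "truth_structure.tsv")
        sim_outputs = [
            "catalog.gtf",
            "quantification.tsv",
            "truth_genes.tsv",
            "truth_isoforms.tsv",
            "truth_structure.tsv",
        ]
        return catalog, table, sim_outputs
    catalog = parse_gtf(config.gtf)
    specs = [
        LibrarySpec(library_id=lid, condition=d["condition"], fraction=d["fraction"], total_mapped_reads=1)
        for lid, d in sorted(config.libraries.items())
    ]
    table = read_quantification(config.quant, specs, catalog=catalog)
    # totals from realized library sizes
    specs = [
        dataclasses.replace(s, total_mapped_reads=max(int(table.counts[s.library_id].sum()), 1))
        for s in specs
    ]
    table = AbundanceTable(
        counts=table.counts, fpkm=table.fpkm, tx2gene=table.tx2gene, lengths=table.lengths, specs=tuple(specs)
    )
    check_library_design(table.specs)
    return catalog, table, []


def run_full_pipeline(config: RunConfig) -> dict[str, float]:
    """Run every stage, write all outputs under ``config.outdir``, return the summary."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    completed: list[str] = ["config.yaml"]
    summary: dict[str, float] = {}
    try:
        catalog, table, sim_outputs = _load_inputs(config, outdir)
        completed += sim_outputs
        logger.info("inputs ready: %d genes, %d transcripts", catalog.n_genes, catalog.n_transcripts)

        # --- expression: DEG (transcriptome) and DTG (translatome) ---
        gene_counts = table.gene_counts()
        gene_fpkm = table.gene_fpkm()
        thresholds = expression.DifferentialThresholds(
            min_abs_log2fc=config.min_abs_log2fc,
            min_fpkm=config.min_fpkm,
            max_p_adj=config.max_p_adj,
        )
        calls = {}
        for label, fraction in (("transcriptome", "cytosolic"), ("translatome", "ribosome")):
            lib_a = table.library_id("A", fraction)
            lib_b = table.library_id("B", fraction)
            calls[label] = expression.call_differential(
                gene_counts[lib_a],
                gene_counts[lib_b],
                gene_fpkm[lib_a],
                gene_fpkm[lib_b],
                table.spec(lib_a).total_mapped_reads,
                table.spec(lib_b).total_mapped_reads,
                thresholds=thresholds,
                pseudocount=config.fc_pseudocount,
            )
            logger.info(
                "%s: %d tested, %d differential",
                label,
                int(calls[label]["expressed"].sum()),
                int((calls[label]["flag"] != "ns").sum()),
            )
        merged = calls["transcriptome"].add_suffix("_transcriptome").join(
            calls["translatome"].add_suffix("_translatome")
        )
        merged.insert(0, "gene_id", merged.index)
        merged = merged.drop(columns=["gene_id_transcriptome", "gene_id_translatome"])
        write_results_table(merged, outdir / "gene_calls.tsv")
        completed.append("gene_calls.tsv")

        deg = expression.differential_gene_set(calls["transcriptome"])
        dtg = expression.differential_gene_set(calls["translatome"])
        ov = expression.overlap_calls(deg, dtg)
        for label in ("transcriptome", "translatome"):
            key = "deg" if label == "transcriptome" else "dtg"
            c = calls[label]
            summary[f"n_tested_{label}"] = int(c["expressed"].sum())
            summary[f"n_{key}"] = int((c["flag"] != "ns").sum())
            summary[f"n_{key}_up_A"] = int((c["flag"] == "up_A").sum())
            summary[f"n_{key}_up_B"] = int((c["flag"] == "up_B").sum())
        summary["n_deg_dtg_shared"] = ov["n_shared"]
        summary["frac_deg_shared"] = ov["frac_of_deg"]
        summary["frac_dtg_shared"] = ov["frac_of_dtg"]

        # --- translational efficiency ---
        te_by_cond = {}
        for cond in ("A", "B"):
            cyto = gene_fpkm[table.library_id(cond, "cytosolic")]
            ribo = gene_fpkm[table.library_id(cond, "ribosome")]
            te_by_cond[cond] = te.compute_te(cyto, ribo, min_fpkm=config.min_fpkm)
            summary[f"n_te_eligible_{cond}"] = len(te_by_cond[cond])
        te_table = te.joint_te_table(
            te_by_cond["A"], te_by_cond["B"], method=config.te_norm, delta_threshold=config.delta_te
        )
        write_results_table(te_table, outdir / "te_calls.tsv")
        completed.append("te_calls.tsv")
        summary["n_te_common"] = len(te_table)
        summary["n_diff_te"] = int((te_table["flag"] != "ns").sum())
        summary["n_diff_te_up_A"] = int((te_table["flag"] == "up_A").sum())
        summary["n_diff_te_up_B"] = int((te_table["flag"] == "up_B").sum())
        logger.info("TE: %d common genes, %d differential", len(te_table), summary["n_diff_te"])

        # --- isoform selection per condition ---
        selected_sets = {}
        for cond in ("A", "B"):
            genes_df, iso_df = iso_mod.analyze_condition(
                table,
                catalog,
                cond,
                alpha=config.alpha,
                min_expected=config.min_expected,
                pseudocount=config.chi_pseudocount,
                min_tx_fpkm=config.min_tx_fpkm,
                dominant_cp_min=config.dominant_cp_min,
                dominant_ratio_min=config.dominant_ratio_min,
            )
            write_results_table(genes_df, outdir / f"isoform_selection_{cond}.tsv")
            write_results_table(iso_df, outdir / f"isoform_diffcp_{cond}.tsv")
            completed += [f"isoform_selection_{cond}.tsv", f"isoform_diffcp_{cond}.tsv"]
            testable = genes_df[genes_df["testable"]]
            sel = genes_df[genes_df["selected"]]
            selected_sets[cond] = set(sel["gene_id"])
            summary[f"n_testable_{cond}"] = len(testable)
            summary[f"n_selected_{cond}"] = len(sel)
            dom = genes_df[genes_df["n_isoforms_expressed"] >= 2]["dominant_switch"]
            n_dom = len(dom)
            for status in ("unchanged", "switched", "undefined"):
                summary[f"frac_dominant_{status}_{cond}"] = (
                    float((dom == status).mean()) if n_dom else float("nan")
                )
            sel_multi = sel[sel["structural_diff"] != ""]
            n_struct = len(sel_multi)
            utr_hits = sel_multi["structural_diff"].str.contains("utr").sum() if n_struct else 0
            cds_hits = sel_multi["structural_diff"].str.contains("cds").sum() if n_struct else 0
            summary[f"frac_selected_utr_diff_{cond}"] = utr_hits / n_struct if n_struct else float("nan")
            summary[f"frac_selected_cds_diff_{cond}"] = cds_hits / n_struct if n_struct else float("nan")
            for fraction, short in (("cytosolic", "cyto"), ("ribosome", "ribo")):
                ms = iso_mod.multi_isoform_stats(
                    table, cond, fraction, min_tx_fpkm=config.min_tx_fpkm
                )
                summary[f"prop_multi_isoform_{short}_{cond}"] = ms["proportion"]
            mc = iso_mod.multi_isoform_stats(table, cond, "cytosolic", min_tx_fpkm=config.min_tx_fpkm)
            mr = iso_mod.multi_isoform_stats(table, cond, "ribosome", min_tx_fpkm=config.min_tx_fpkm)
            summary[f"p_prop_multi_isoform_{cond}"] = iso_mod.proportion_test(
                mc["n_genes_ge2_expressed"], mc["n_genes_total"], mr["n_genes_ge2_expressed"], mr["n_genes_total"]
            )
            logger.info(
                "isoform selection %s: %d testable, %d selected", cond, len(testable), len(sel)
            )
        shared_sel = selected_sets["A"] & selected_sets["B"]
        summary["n_selected_shared"] = len(shared_sel)

        # --- enrichment (optional) ---
        if config.gmt is not None:
            collection = read_gmt(config.gmt)
            universe = set(calls["transcriptome"].loc[calls["transcriptome"]["expressed"], "gene_id"])
            result = hypergeometric_enrichment(deg & universe, universe, collection, alpha=config.alpha)
            write_results_table(result, outdir / "enrichment.tsv")
            completed.append("enrichment.tsv")
            summary["n_terms_tested"] = len(result)
            summary["n_terms_enriched"] = int(result["enriched"].sum()) if len(result) else 0

        summary_df = pd.DataFrame(
            {"statistic": sorted(summary), "value": [summary[k] for k in sorted(summary)]}
        )
        write_results_table(summary_df, outdir / "summary.tsv")
        completed.append("summary.tsv")
    finally:
        manifest = "".join(
            f"{_sha256(outdir / name)}  {name}\n" for name in sorted(set(completed))
        )
        (outdir / "MANIFEST").write_text(manifest)
    return summary
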