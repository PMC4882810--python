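"""End-to-end orchestration and report generation.

Runs depletion -> ORF annotation -> SNP markers -> differential expression
-> sex-chromosome scan from a single :class:`PipelineConfig`, either on
user-supplied files (FASTA + counts TSV + VCF + gene-map BED + sample
sheet) or on a freshly simulated dataset, and writes a machine-readable
JSON report plus a human Markdown summary. Every threshold actually
applied is echoed into the report; in synthetic mode the report also
carries truth-recovery metrics (diagnostic-SNP precision/recall, PAR
boundary error, region overlap).
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from zwscan import depletion, diffexpr, io, orf, sexscan, simdata, snpmarkers


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; exactly one input mode.

    Synthetic mode: set ``sim``. Real mode: set the five input paths.
    """

    outdir: str = "zwscan_out"
    sim: simdata.SimConfig | None = None
    fasta: str | None = None
    counts: str | None = None
    vcf: str | None = None
    genemap: str | None = None
    samples: str | None = None
    thresholds: snpmarkers.Thresholds = field(default_factory=snpmarkers.Thresholds)
    hemoglobin_threshold: float = 0.20
    hemoglobin_ids: list[str] | None = None  # known globins, merged with share flags
    target_pairs: int | None = None
    de_level: float = 0.05
    min_fold: float = 2.0
    min_aa: int = 100
    chrom: str = "Z"
    window: int = 10
    tau_expr: float = 0.5
    tau_dens: float = 1.5
    min_run: int = 5
    het_band: tuple[float, float] = (0.2, 0.8)
    het_min_depth: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        real = [self.fasta, self.counts, self.vcf, self.genemap, self.samples]
        if self.sim is None:
            missing = [
                name
                for name, value in zip(
                    ("fasta", "counts", "vcf", "genemap", "samples"), real
                )
                if value is None
            ]
            if missing:
                raise ValueError(f"real-mode config missing fields: {missing}")
        elif any(v is not None for v in real):
            raise ValueError("supply either sim or real input paths, not both")


def snp_read_correlation(snp_counts, read_totals) -> float:
    """Pearson correlation of per-individual SNP counts vs read totals.

    Guards the degenerate cases a correlation is undefined for (fewer than
    three individuals, zero variance).
    """
    x = np.asarray(snp_counts, dtype=float)
    y = np.asarray(read_totals, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage tagging
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


@_stage("inputs")
def _load_inputs(cfg: PipelineConfig) -> dict:
    if cfg.sim is not None:
        bundle = simdata.simulate_dataset(cfg.sim)
        return {
            "sequences": bundle.sequences,
            "counts": bundle.counts,
            "variants": bundle.variants,
            "gene_map": bundle.gene_map,
            "sheet": bundle.sheet,
            "truth": bundle.truth,
            "bundle": bundle,
        }
    return {
        "sequences": io.read_fasta(cfg.fasta),
        "counts": io.read_counts(cfg.counts),
        "variants": io.read_vcf(cfg.vcf),
        "gene_map": io.read_gene_map(cfg.genemap),
        "sheet": io.read_sample_sheet(cfg.samples),
        "truth": None,
        "bundle": None,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle into ``cfg.outdir``.

    Returns the report dictionary; identical configurations produce
    byte-identical bundles. On any stage error the partial output directory
    is removed and a stage-tagged :class:`PipelineError` is raised.
    """
    outdir = Path(cfg.outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        report = _run(cfg, outdir)
    except Exception:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        raise
    return report


def _run(cfg: PipelineConfig, outdir: Path) -> dict:
    data = _load_inputs(cfg)
    sheet = data["sheet"]
    counts = data["counts"]
    sequences = data["sequences"]
    variants = data["variants"]
    gene_map = data["gene_map"]
    truth: simdata.SimTruth | None = data["truth"]
    if data["bundle"] is not None:
        simdata.write_dataset(outdir / "data", data["bundle"])

    # ---- depletion -------------------------------------------------------
    hb_ids = cfg.hemoglobin_ids
    if hb_ids is None and truth is not None:
        # pilot-assembly knowledge in synthetic mode: the generator's globins
        hb_ids = truth.hemoglobin_ids
    accounting, depleted_counts = _deplete_stage(cfg, counts, sheet, hb_ids)
    io.write_json(outdir / "accounting.json", accounting.to_json())

    # ---- ORF annotation --------------------------------------------------
    retained, effects = _orf_stage(cfg, sequences, variants)
    orf.orf_table(retained).to_csv(outdir / "orfs.tsv", sep="\t", index=False)

    # ---- SNP markers -----------------------------------------------------
    classifications, snp_summary = _snp_stage(cfg, variants, sheet, sequences, effects)
    classifications.to_csv(outdir / "snp_classification.tsv", sep="\t", index=False)
    snp_summary.to_csv(outdir / "snp_summary.tsv", sep="\t", index=False)

    # ---- differential expression ----------------------------------------
    norm, de_species, species_calls, de_sex, sex_calls = _de_stage(
        cfg, depleted_counts, sheet
    )
    de_species.join(species_calls).to_csv(outdir / "de_species.tsv", sep="\t")
    de_sex.join(sex_calls).to_csv(outdir / "de_sex.tsv", sep="\t")

    # ---- sex-chromosome scan --------------------------------------------
    scan = _scan_stage(cfg, norm, variants, gene_map, sheet, sequences)
    scan["stats"].to_csv(outdir / "scan_stats.tsv", sep="\t", index=False)
    sexscan.regions_to_bed(scan["regions"]).to_csv(
        outdir / "regions.bed", sep="\t", index=False, header=False
    )

    # ---- cross-stage summaries ------------------------------------------
    corr = _snp_read_corr(classifications, variants, counts, cfg)

    report = {
        "config": _config_echo(cfg),
        "accounting": accounting.to_json(),
        "snp_summary": snp_summary.to_dict(orient="records"),
        "n_coding_transcripts": len(retained),
        "de": {
            "species": {k: int(v) for k, v in species_calls.value_counts().items()},
            "sex": {k: int(v) for k, v in sex_calls["call"].value_counts().items()},
            "sex_ge_min_fold": int(sex_calls["ge_min_fold"].sum()),
        },
        "scan": {
            "boundary_index": scan["boundary"],
            "boundary_sse": scan["sse"],
            "bimodality": scan["bimodality"],
            "regions": [asdict(r) for r in scan["regions"]],
            "n_unmapped_genes": scan["n_unmapped"],
        },
        "snp_read_pearson_r": corr,
    }
    if truth is not None:
        report["truth_recovery"] = _truth_metrics(truth, classifications, scan)

    io.write_json(outdir / "report.json", report)
    (outdir / "report.md").write_text(_markdown_report(report))
    return report


@_stage("depletion")
def _deplete_stage(cfg, counts, sheet, hb_ids=None):
    assign = depletion.assignments_from_counts(counts)
    flagged = depletion.flag_high_share_transcripts(assign, cfg.hemoglobin_threshold)
    flagged |= set(hb_ids or []) & set(counts.index)
    remaining, _removed = depletion.deplete(assign, flagged)
    post_sub = None
    if cfg.target_pairs is not None:
        remaining = depletion.subsample(remaining, cfg.target_pairs, cfg.seed)
        post_sub = int(remaining["read_pairs"].sum())
    accounting = depletion.accounting_report(assign, flagged, sheet, post_sub)
    return accounting, depletion.counts_from_assignments(remaining)


@_stage("orf")
def _orf_stage(cfg, sequences, variants):
    orfs = {tid: orf.find_orfs(seq, tid) for tid, seq in sequences.items()}
    retained = orf.filter_orfs(orfs, min_aa=cfg.min_aa)
    effects = orf.annotate_variants(variants.sites, sequences, retained)
    return retained, effects


@_stage("snpmarkers")
def _snp_stage(cfg, variants, sheet, sequences, effects):
    lengths = {tid: len(seq) for tid, seq in sequences.items()}
    classifications = snpmarkers.classify_sites(
        variants, sheet, lengths, cfg.thresholds, effects
    )
    return classifications, snpmarkers.summarize(classifications)


@_stage("diffexpr")
def _de_stage(cfg, depleted_counts, sheet):
    norm = diffexpr.quantile_normalize(depleted_counts)
    species = list(dict.fromkeys(sheet["species"]))
    by_species = {
        sp: [s for s in norm.columns if sheet.set_index("sample")["species"][s] == sp]
        for sp in species
    }
    de_species = diffexpr.de_test(
        norm, by_species[species[0]], by_species[species[1]], level=cfg.de_level
    )
    species_calls = diffexpr.classify_species_de(de_species, cfg.min_fold)
    sex_of = sheet.set_index("sample")["sex"]
    males = [s for s in norm.columns if sex_of[s] == "M"]
    females = [s for s in norm.columns if sex_of[s] == "F"]
    de_sex = diffexpr.de_test(norm, males, females, level=cfg.de_level)
    sex_calls = diffexpr.classify_sex_de(de_sex, cfg.min_fold)
    return norm, de_species, species_calls, de_sex, sex_calls


@_stage("sexscan")
def _scan_stage(cfg, norm, variants, gene_map, sheet, sequences):
    ordered, n_unmapped = sexscan.order_by_synteny(
        list(norm.index), gene_map, chrom=cfg.chrom
    )
    log2_mf = sexscan.mf_ratio(norm, sheet)
    lengths = {g: len(sequences[g]) for g in ordered["gene_id"]}
    densities = sexscan.sex_snp_density(
        variants, lengths, sheet, cfg.het_band, cfg.het_min_depth
    )
    stats = sexscan.gene_sex_stats(ordered, log2_mf, densities, cfg.window)
    regions = sexscan.call_nonpar_regions(stats, cfg.tau_expr, cfg.tau_dens, cfg.min_run)
    boundary, sse = sexscan.fit_par_boundary(stats["log2_mf"])
    bimod = sexscan.bimodality_summary(stats["log2_mf"])
    flagged = np.full(len(stats), False)
    for r in regions:
        if r.label == "nonPAR-like":
            flagged[r.start_index : r.end_index] = True
    stats = stats.assign(nonpar_flag=flagged)
    return {
        "stats": stats,
        "regions": regions,
        "boundary": int(boundary),
        "sse": float(sse),
        "bimodality": bimod,
        "n_unmapped": int(n_unmapped),
    }


@_stage("report")
def _snp_read_corr(classifications, variants, counts, cfg):
    """Per-individual SNP count (alt carried at a coverage-passing site)
    against per-individual total reads."""
    freq = variants.frequencies()
    if len(classifications) == 0:
        return None
    cov = classifications["coverage_pass"].to_numpy()
    carries = (freq > cfg.thresholds.high_freq).loc[cov]
    snp_counts = carries.sum(axis=0).reindex(counts.columns)
    read_totals = counts.sum(axis=0)
    try:
        return snp_read_correlation(snp_counts.to_numpy(), read_totals.to_numpy())
    except ValueError:
        return None


def _truth_metrics(truth, classifications, scan) -> dict:
    pred = {
        (row.contig, row.pos)
        for row in classifications.itertuples(index=False)
        if pd.notna(row.diagnostic)
    }
    true = {
        (contig, pos)
        for sites in truth.diagnostic_sites.values()
        for contig, pos in sites
    }
    tp = len(pred & true)
    stats = scan["stats"]
    b = truth.par_boundary_index
    in_nonpar_region = stats["nonpar_flag"].to_numpy()
    true_nonpar = np.arange(len(stats)) >= b  # PAR genes come first in the sim
    return {
        "diagnostic_precision": tp / len(pred) if pred else None,
        "diagnostic_recall": tp / len(true) if true else None,
        "boundary_true": int(b),
        "boundary_abs_error": abs(scan["boundary"] - b),
        "nonpar_recall": float(in_nonpar_region[true_nonpar].mean())
        if true_nonpar.any()
        else None,
        "par_false_flag_rate": float(in_nonpar_region[~true_nonpar].mean())
        if (~true_nonpar).any()
        else None,
    }


def _config_echo(cfg: PipelineConfig) -> dict:
    echo = asdict(cfg)
    if cfg.sim is not None:
        echo["sim"] = asdict(cfg.sim)
    echo["thresholds"] = asdict(cfg.thresholds)
    return echo


def _markdown_report(report: dict) -> str:
    acc = report["accounting"]
    lines = [
        "# zwscan pipeline report",
        "",
        "## Read accounting",
        f"- total read pairs: {acc['total_pairs']:,}",
        f"- hemoglobin-mapped pairs: {acc['hemoglobin_pairs']:,} ({acc['hemoglobin_percent']}%)",
        f"- remaining after depletion: {acc['post_depletion_pairs']:,}",
        "",
        "## SNP markers",
    ]
    for row in report["snp_summary"]:
        lines.append(
            f"- {row['category']}: {row['n_sites']:,} sites"
            f" ({row['n_aa_changing']:,} amino-acid changing)"
        )
    de = report["de"]
    lines += [
        "",
        "## Differential expression",
        f"- species calls: {de['species']}",
        f"- sex calls: {de['sex']} (of which >= fold threshold: {de['sex_ge_min_fold']})",
        "",
        "## Sex-chromosome scan",
        f"- PAR boundary estimate (gene ordinal): {report['scan']['boundary_index']}",
        f"- dosage bimodality: {report['scan']['bimodality']}",
        f"- regions: {len(report['scan']['regions'])} calls",
        f"- SNP-count vs read-total Pearson r: {report['snp_read_pearson_r']}",
    ]
    if "truth_recovery" in report:
        lines += ["", "## Truth recovery (synthetic mode)"]
        for k, v in report["truth_recovery"].items():
            lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"
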