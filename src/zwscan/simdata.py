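"""Synthetic ZW blood-transcriptome generator with ground truth.

Emulates the statistical structure the downstream stages assume for a
two-species bird cohort (ZW sex determination, females heterogametic, no
dosage compensation):

- two species of unequal nucleotide diversity, ``n_per_species`` birds each
  with an equal sex ratio;
- blood libraries dominated by two hemoglobin transcripts that jointly
  absorb a fixed fraction of every library;
- negative-binomial read counts with per-gene gamma-distributed dispersion;
- a chromosome-Z gene set split into a pseudoautosomal region (PAR: equal
  expression and SNP density between sexes) and a non-PAR remainder
  (``sex_effect_nonpar``-fold male expression; females hemizygous, so never
  heterozygous);
- species-diagnostic SNPs (alternate allele fixed in one species, absent in
  the other) and within-species polymorphic SNPs, with per-sample read
  depths proportional to the gene's count and alt depths binomially sampled
  from the genotype dosage.

Simulation happens at the count/allele-depth level: read alignment and
variant calling are treated as upstream steps whose output we model
directly, which keeps a full dataset desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from zwscan import io

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort; ``seed`` fixes every draw."""

    n_autosomal_genes: int = 4000
    n_z_genes: int = 300
    par_fraction: float = 2 / 3
    n_per_species: int = 8
    mean_depth: float = 500.0
    dispersion_shape: float = 2.0
    mean_dispersion: float = 0.1
    sex_effect_nonpar: float = 2.0
    hemoglobin_fraction: float = 0.20
    diag_snp_rate: float = 1.0  # diagnostic SNPs per kb of transcript
    within_snp_rate: float = 0.5  # within-species SNPs per kb, first species
    diversity_ratio: float = 2.0  # second species carries this multiple
    species_lfc_sd: float = 1.0
    de_gene_fraction: float = 0.1
    median_tx_length: float = 2000.0
    tx_length_sigma: float = 0.45
    species: tuple[str, str] = ("speciesA", "speciesB")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("par_fraction", "hemoglobin_fraction", "de_gene_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_per_species <= 0 or self.n_per_species % 2:
            raise ValueError("n_per_species must be positive and even (equal sexes)")
        if self.sex_effect_nonpar <= 0:
            raise ValueError("sex_effect_nonpar must be positive")
        if self.n_z_genes == 0 and self.par_fraction > 0:
            raise ValueError("par_fraction > 0 requires Z genes")
        if self.n_autosomal_genes < 0 or self.n_z_genes < 0:
            raise ValueError("gene counts must be non-negative")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream for one generator stage."""
        return np.random.default_rng([stage, self.seed])


@dataclass
class SimTruth:
    """Ground truth the generator records for recovery tests."""

    par_boundary_index: int
    diagnostic_sites: dict[str, list[list]] = field(default_factory=dict)
    within_species_sites: dict[str, list[list]] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)
    hemoglobin_ids: list[str] = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "SimTruth":
        return cls(**obj)


@dataclass
class SimBundle:
    """Everything one simulated study produces."""

    config: SimConfig
    gene_map: pd.DataFrame
    sequences: dict[str, str]
    counts: pd.DataFrame
    variants: io.VariantTable
    sheet: pd.DataFrame
    truth: SimTruth


def build_sample_sheet(cfg: SimConfig) -> pd.DataFrame:
    """Cohort layout: ``n_per_species`` birds per species, half of each sex."""
    rows = []
    for si, sp in enumerate(cfg.species):
        for i in range(cfg.n_per_species):
            sex = "M" if i < cfg.n_per_species // 2 else "F"
            rows.append(
                {
                    "sample": f"{sp}_{sex}{i % (cfg.n_per_species // 2) + 1}",
                    "species": sp,
                    "sex": sex,
                    "age_class": "adult" if si == 0 else "juvenile",
                    "location": f"site{si + 1}",
                }
            )
    return pd.DataFrame(rows, columns=io.SAMPLE_COLUMNS)


def build_gene_map(cfg: SimConfig) -> pd.DataFrame:
    """Lay out genes on an autosome "A" and the sex chromosome "Z".

    Transcript lengths are log-normal (median ``median_tx_length``); genes
    are placed end-to-end with 1 kb gaps so positions strictly increase
    along each chromosome. The first ``floor(par_fraction * n_z_genes)``
    Z genes in position order are flagged PAR. The two hemoglobin
    transcripts sit at the start of the autosome.
    """
    rng = cfg.rng(1)
    n_a, n_z = cfg.n_autosomal_genes, cfg.n_z_genes
    ids = (
        ["hb_alpha", "hb_beta"]
        + [f"geneA{i:05d}" for i in range(n_a)]
        + [f"geneZ{i:05d}" for i in range(n_z)]
    )
    chroms = ["A"] * (2 + n_a) + ["Z"] * n_z
    lengths = np.round(
        rng.lognormal(np.log(cfg.median_tx_length), cfg.tx_length_sigma, size=len(ids))
    ).astype(int)
    lengths = np.maximum(lengths, 600)

    starts = np.empty(len(ids), dtype=int)
    cursor: dict[str, int] = {"A": 0, "Z": 0}
    for i, chrom in enumerate(chroms):
        starts[i] = cursor[chrom]
        cursor[chrom] += lengths[i] + 1000

    n_par = int(np.floor(cfg.par_fraction * n_z))
    par = np.zeros(len(ids), dtype=bool)
    par[2 + n_a : 2 + n_a + n_par] = True
    return pd.DataFrame(
        {
            "gene_id": ids,
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "strand": "+",
            "par": par,
        }
    )


def par_boundary_index(gene_map: pd.DataFrame) -> int:
    """Number of PAR genes on Z, i.e. the ordinal of the first non-PAR gene."""
    z = gene_map[gene_map["chrom"] == "Z"].sort_values("start")
    return int(z["par"].sum())


def simulate_sequences(cfg: SimConfig, gene_map: pd.DataFrame) -> dict[str, str]:
    """One transcript per gene with a planted ORF.

    Layout: ~20% 5' UTR, then ATG + non-stop codons + a stop codon covering
    a bit over half the transcript, then 3' UTR. Random UTR sequence cannot
    realistically harbour a longer ORF than the planted one, so downstream
    ORF discovery has an unambiguous answer.
    """
    rng = cfg.rng(2)
    sense = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS
    ]
    sense = np.array(sense)
    seqs: dict[str, str] = {}
    for gene in gene_map.itertuples(index=False):
        length = gene.end - gene.start
        utr5 = int(0.2 * length)
        n_codons = max(int(0.55 * length) // 3, 110)
        coding = "ATG" + "".join(rng.choice(sense, size=n_codons - 2)) + str(rng.choice(STOP_CODONS))
        tail = length - utr5 - len(coding)
        seq = (
            "".join(rng.choice(_BASES, size=utr5))
            + coding
            + "".join(rng.choice(_BASES, size=max(tail, 0)))
        )
        seqs[gene.gene_id] = seq[:length] if len(seq) >= length else seq + "A" * (length - len(seq))
    return seqs


def _expected_means(
    cfg: SimConfig, gene_map: pd.DataFrame, sheet: pd.DataFrame, de_lfc: pd.Series
) -> pd.DataFrame:
    """Expected NB mean per gene and sample, hemoglobin share included."""
    genes = gene_map["gene_id"].to_numpy()
    is_hb = np.isin(genes, ["hb_alpha", "hb_beta"])
    is_nonpar_z = ((gene_map["chrom"] == "Z") & (~gene_map["par"])).to_numpy()

    mu = np.full((len(genes), len(sheet)), cfg.mean_depth, dtype=float)
    lfc = de_lfc.reindex(genes).fillna(0.0).to_numpy()
    for j, sample in enumerate(sheet.itertuples(index=False)):
        col = mu[:, j]
        if sample.species == cfg.species[1]:
            col *= 2.0 ** lfc
        if sample.sex == "M":
            col[is_nonpar_z] *= cfg.sex_effect_nonpar
        # the two globins jointly take hemoglobin_fraction of this library
        hb_total = cfg.hemoglobin_fraction / (1 - cfg.hemoglobin_fraction) * col[~is_hb].sum()
        col[is_hb] = hb_total * np.array([0.45, 0.55])[: is_hb.sum()]
    return pd.DataFrame(mu, index=genes, columns=sheet["sample"].to_numpy())


def simulate_expression(
    cfg: SimConfig, gene_map: pd.DataFrame, sheet: pd.DataFrame
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw the count matrix and record expression ground truth.

    Counts are NB(mu, alpha_g) with Var = mu + alpha*mu^2; per-gene alpha is
    gamma with shape ``dispersion_shape`` and mean ``mean_dispersion``.
    Non-PAR Z genes get ``sex_effect_nonpar``-fold male means; a
    ``de_gene_fraction`` of genes carries a species log2 fold change drawn
    from Normal(0, ``species_lfc_sd``).
    """
    if sheet.empty:
        raise ValueError("sample sheet is empty")
    for sp in cfg.species:
        sexes = set(sheet.loc[sheet["species"] == sp, "sex"])
        if not {"M", "F"} <= sexes:
            raise ValueError(f"species {sp} must include both sexes, has {sexes}")

    rng = cfg.rng(3)
    genes = gene_map["gene_id"].to_numpy()
    candidates = genes[~np.isin(genes, ["hb_alpha", "hb_beta"])]
    n_de = int(round(cfg.de_gene_fraction * len(candidates)))
    de_ids = rng.choice(candidates, size=n_de, replace=False)
    de_lfc = pd.Series(rng.normal(0.0, cfg.species_lfc_sd, size=n_de), index=de_ids)

    mu = _expected_means(cfg, gene_map, sheet, de_lfc)
    alpha = rng.gamma(cfg.dispersion_shape, cfg.mean_dispersion / cfg.dispersion_shape, size=len(genes))

    m = mu.to_numpy()
    n_param = (1.0 / alpha)[:, None] * np.ones_like(m)
    p_param = n_param / (n_param + m)
    counts = rng.negative_binomial(n_param, p_param).astype(np.int64)

    truth = SimTruth(
        par_boundary_index=par_boundary_index(gene_map),
        de_genes={g: float(v) for g, v in de_lfc.items()},
        hemoglobin_ids=[g for g in ("hb_alpha", "hb_beta") if g in genes],
        seed=cfg.seed,
    )
    return pd.DataFrame(counts, index=genes, columns=mu.columns), truth


def simulate_variants(
    cfg: SimConfig,
    gene_map: pd.DataFrame,
    sheet: pd.DataFrame,
    counts: pd.DataFrame,
    sequences: dict[str, str],
    truth: SimTruth | None = None,
) -> tuple[io.VariantTable, SimTruth]:
    """Plant diagnostic and within-species SNPs and draw allele depths.

    Diagnostic sites are fixed for the alternate allele in one species and
    absent from the other. Within-species sites segregate at an allele
    frequency drawn from U(0.1, 0.5); diploid genotypes are Binomial(2, q),
    but females at non-PAR Z sites are hemizygous — a single Bernoulli(q)
    allele, never heterozygous. Per-sample site depth equals the gene's
    count for that sample; alt depth ~ Binomial(depth, dosage).
    """
    rng = cfg.rng(4)
    truth = truth or SimTruth(par_boundary_index=par_boundary_index(gene_map), seed=cfg.seed)
    truth.diagnostic_sites = {sp: [] for sp in cfg.species}
    truth.within_species_sites = {sp: [] for sp in cfg.species}

    samples = list(counts.columns)
    species_of = sheet.set_index("sample")["species"]
    sex_of = sheet.set_index("sample")["sex"]
    within_rates = {cfg.species[0]: cfg.within_snp_rate, cfg.species[1]: cfg.within_snp_rate * cfg.diversity_ratio}

    rows, dp_rows, ad_rows, gt_rows = [], [], [], []
    for gene in gene_map.itertuples(index=False):
        if gene.gene_id in truth.hemoglobin_ids:
            continue
        length = gene.end - gene.start
        kb = length / 1000.0
        hemizygous_f = gene.chrom == "Z" and not gene.par

        n_diag = rng.poisson(cfg.diag_snp_rate * kb)
        n_within = {sp: rng.poisson(within_rates[sp] * kb) for sp in cfg.species}
        n_total = n_diag + sum(n_within.values())
        if n_total == 0:
            continue
        if n_total > length:
            raise ValueError(f"{gene.gene_id}: more sites than positions")
        positions = np.sort(rng.choice(length, size=n_total, replace=False))
        rng.shuffle(positions)
        cursor = 0

        site_plan: list[tuple[int, str, str | None]] = []  # (pos, kind, species)
        for _ in range(n_diag):
            carrier = cfg.species[int(rng.integers(2))]
            site_plan.append((int(positions[cursor]), "diag", carrier))
            cursor += 1
        for sp in cfg.species:
            for _ in range(n_within[sp]):
                site_plan.append((int(positions[cursor]), "within", sp))
                cursor += 1
        site_plan.sort(key=lambda t: t[0])

        depth_by_sample = counts.loc[gene.gene_id, samples].to_numpy(dtype=np.int64)
        seq = sequences[gene.gene_id]
        for pos, kind, sp in site_plan:
            ref = seq[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            dosage = np.zeros(len(samples))
            ploidy1 = np.array([hemizygous_f and sex_of[s] == "F" for s in samples])
            q = float(rng.uniform(0.1, 0.5)) if kind == "within" else 1.0
            for j, s in enumerate(samples):
                if species_of[s] != sp:
                    continue
                if kind == "diag":
                    dosage[j] = 1.0
                elif ploidy1[j]:
                    # hemizygous: one Bernoulli(q) allele, heterozygosity impossible
                    dosage[j] = float(rng.random() < q)
                else:
                    dosage[j] = rng.binomial(2, q) / 2.0
            ad = rng.binomial(depth_by_sample, dosage)
            gt = []
            for j in range(len(samples)):
                if ploidy1[j]:
                    gt.append(str(int(dosage[j])))
                else:
                    gt.append({0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}[dosage[j]])
            rows.append((gene.gene_id, pos, ref, alt))
            dp_rows.append(depth_by_sample)
            ad_rows.append(ad)
            gt_rows.append(gt)
            if kind == "diag":
                truth.diagnostic_sites[sp].append([gene.gene_id, pos])
            else:
                truth.within_species_sites[sp].append([gene.gene_id, pos])

    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    order = sites.sort_values(["contig", "pos"]).index if len(sites) else sites.index
    table = io.VariantTable(
        sites=sites.loc[order].reset_index(drop=True),
        dp=pd.DataFrame(np.asarray(dp_rows, dtype=np.int64)[order] if len(sites) else [], columns=samples, dtype=np.int64),
        ad=pd.DataFrame(np.asarray(ad_rows, dtype=np.int64)[order] if len(sites) else [], columns=samples, dtype=np.int64),
        gt=pd.DataFrame(np.asarray(gt_rows, dtype=object)[order] if len(sites) else [], columns=samples),
    )
    return table, truth


def simulate_dataset(cfg: SimConfig) -> SimBundle:
    """Run every generator stage under one seed."""
    sheet = build_sample_sheet(cfg)
    gene_map = build_gene_map(cfg)
    sequences = simulate_sequences(cfg, gene_map)
    counts, truth = simulate_expression(cfg, gene_map, sheet)
    variants, truth = simulate_variants(cfg, gene_map, sheet, counts, sequences, truth)
    return SimBundle(cfg, gene_map, sequences, counts, variants, sheet, truth)


def write_dataset(outdir: str | Path, bundle: SimBundle) -> dict[str, Path]:
    """Write the file bundle; a read round-trip reproduces all tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "transcripts.fasta",
        "counts": outdir / "counts.tsv",
        "vcf": outdir / "variants.vcf",
        "genemap": outdir / "genemap.bed",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
    }
    io.write_fasta(paths["fasta"], bundle.sequences)
    io.write_counts(paths["counts"], bundle.counts)
    lengths = {g.gene_id: g.end - g.start for g in bundle.gene_map.itertuples(index=False)}
    io.write_vcf(paths["vcf"], bundle.variants, contig_lengths=lengths)
    io.write_gene_map(paths["genemap"], bundle.gene_map)
    io.write_sample_sheet(paths["samples"], bundle.sheet)
    io.write_json(paths["truth"], bundle.truth.to_json())
    return paths


def read_dataset(outdir: str | Path) -> dict:
    """Read a written bundle back into in-memory containers."""
    outdir = Path(outdir)
    return {
        "sequences": io.read_fasta(outdir / "transcripts.fasta"),
        "counts": io.read_counts(outdir / "counts.tsv"),
        "variants": io.read_vcf(outdir / "variants.vcf"),
        "gene_map": io.read_gene_map(outdir / "genemap.bed"),
        "sheet": io.read_sample_sheet(outdir / "samples.tsv"),
        "truth": SimTruth.from_json(io.read_json(outdir / "truth.json")),
    }
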