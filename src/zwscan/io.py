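"""Readers and writers for the plain-text formats the pipeline exchanges.

Internal conventions: positions are 0-based half-open everywhere in memory;
the VCF/BED dialects on disk are 1-based (VCF POS) and 0-based half-open
(BED) as their specs require.

Containers:

- count matrix: ``pandas.DataFrame`` of non-negative integers, genes in the
  index, sample ids in the columns;
- sample sheet: ``pandas.DataFrame`` with columns sample/species/sex
  (``M``/``F``) and optional age_class/location;
- gene map: ``pandas.DataFrame`` with columns gene_id/chrom/start/end/strand
  (plus a ``par`` flag in synthetic mode);
- variant table: :class:`VariantTable` below.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SAMPLE_COLUMNS = ["sample", "species", "sex", "age_class", "location"]


@dataclass
class VariantTable:
    """Per-site, per-sample sequencing evidence on transcript coordinates.

    ``sites`` has one row per variant (columns contig, pos, ref, alt; pos is
    0-based), and ``dp``/``ad`` are integer DataFrames aligned row-for-row
    with ``sites`` whose columns are sample ids: total read depth and
    alt-allele read depth. ``gt`` carries VCF-style genotype strings
    ("0/1", haploid "1", missing "./.") when genotypes are known.
    """

    sites: pd.DataFrame
    dp: pd.DataFrame
    ad: pd.DataFrame
    gt: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.sites)
        for name in ("dp", "ad"):
            mat = getattr(self, name)
            if len(mat) != n:
                raise ValueError(f"{name} has {len(mat)} rows for {n} sites")
        if (self.ad.to_numpy() > self.dp.to_numpy()).any():
            raise ValueError("alt depth exceeds total depth")

    @property
    def samples(self) -> list[str]:
        return list(self.dp.columns)

    def __len__(self) -> int:
        return len(self.sites)

    def frequencies(self) -> pd.DataFrame:
        """Per-sample alt-allele read frequency; NaN where depth is zero."""
        dp = self.dp.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(dp > 0, self.ad.to_numpy(dtype=float) / dp, np.nan)
        return pd.DataFrame(freq, index=self.dp.index, columns=self.dp.columns)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# TSV tables


def write_counts(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    counts.index.name = None
    return counts


def write_sample_sheet(path: str | Path, sheet: pd.DataFrame) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample", "species", "sex"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


# ---------------------------------------------------------------------------
# Gene map (BED6; the score column stores the PAR flag when known, else 0)


def write_gene_map(path: str | Path, gene_map: pd.DataFrame) -> None:
    bed = pd.DataFrame(
        {
            "chrom": gene_map["chrom"],
            "start": gene_map["start"],
            "end": gene_map["end"],
            "name": gene_map["gene_id"],
            "score": gene_map["par"].astype(int) if "par" in gene_map else 0,
            "strand": gene_map.get("strand", "+"),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_gene_map(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "strand": bed["strand"],
            "par": bed["score"].astype(int).astype(bool),
        }
    )


# ---------------------------------------------------------------------------
# VCF 4.2 with per-sample GT:DP:AD


def write_vcf(
    path: str | Path,
    variants: VariantTable,
    contig_lengths: dict[str, int] | None = None,
    info: pd.Series | None = None,
) -> None:
    """Write a plain-text VCF 4.2 file; POS is 1-based on disk.

    ``info`` optionally supplies a preformatted INFO string per site
    (aligned with ``variants.sites``), e.g. ``EFF=SYN``.
    """
    samples = variants.samples
    lines = [
        "##fileformat=VCFv4.2",
        "##source=zwscan",
        '##INFO=<ID=EFF,Number=1,Type=String,Description="Predicted coding effect: SYN, NSY, NCD or IND">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
    ]
    if contig_lengths:
        for contig, length in contig_lengths.items():
            lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))

    dp = variants.dp.to_numpy()
    ad = variants.ad.to_numpy()
    gt = variants.gt.to_numpy() if variants.gt is not None else None
    for i, site in enumerate(variants.sites.itertuples(index=False)):
        info_str = info.iloc[i] if info is not None else "."
        cells = []
        for j in range(len(samples)):
            g = gt[i, j] if gt is not None else "./."
            cells.append(f"{g}:{dp[i, j]}:{dp[i, j] - ad[i, j]},{ad[i, j]}")
        lines.append(
            f"{site.contig}\t{site.pos + 1}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t{info_str}\tGT:DP:AD\t"
            + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> VariantTable:
    """Read a VCF with FORMAT DP and AD back into a :class:`VariantTable`."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        rows, dp_rows, ad_rows, gt_rows = [], [], [], []
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else "."
            rows.append((rec.contig, rec.start, rec.ref, alt))
            dp_rows.append([rec.samples[s].get("DP", 0) or 0 for s in samples])
            ad_rows.append(
                [(rec.samples[s].get("AD") or (0, 0))[1] for s in samples]
            )
            gts = []
            for s in samples:
                alleles = rec.samples[s].get("GT", (None,))
                if alleles is None or all(a is None for a in alleles):
                    gts.append("./.")
                else:
                    sep = "|" if rec.samples[s].phased else "/"
                    gts.append(sep.join(str(a) for a in alleles))
            gt_rows.append(gts)
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    idx = sites.index
    return VariantTable(
        sites=sites,
        dp=pd.DataFrame(dp_rows, columns=samples, index=idx, dtype=np.int64)
        if rows
        else pd.DataFrame(columns=samples, dtype=np.int64),
        ad=pd.DataFrame(ad_rows, columns=samples, index=idx, dtype=np.int64)
        if rows
        else pd.DataFrame(columns=samples, dtype=np.int64),
        gt=pd.DataFrame(gt_rows, columns=samples, index=idx)
        if rows
        else pd.DataFrame(columns=samples),
    )


# ---------------------------------------------------------------------------
# JSON helpers


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
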