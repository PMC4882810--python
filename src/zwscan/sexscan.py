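"""Sex-chromosome scan: dosage, SNP density, smoothing and PAR inference.

Birds lack global dosage compensation, so a gene on Z outside the
pseudoautosomal region (PAR) is expected at twice the expression in ZZ
males as in ZW females (log2 M:F ~ 1), while PAR genes are diploid in both
sexes (log2 ~ 0). Likewise, females are hemizygous outside the PAR, so
heterozygous-site density there collapses to zero in females but not
males. This module orders genes along a synteny map of a reference
chromosome, computes per-gene log2 male:female expression and per-sex
heterozygous-SNP density, smooths both with a 10-gene moving average, flags
runs of jointly male-biased genes as non-PAR-like regions, and estimates
the PAR boundary with a single-changepoint step fit to the dosage profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PSEUDOCOUNT = 0.5
EPS = 1e-9


def order_by_synteny(
    genes: list[str], gene_map: pd.DataFrame, chrom: str = "Z"
) -> tuple[pd.DataFrame, int]:
    """Genes of ``chrom`` sorted by mapped position.

    Returns (ordered frame with gene_id/chrom/start, number of input genes
    without a map entry). Ties in position keep input order; a gene mapped
    twice with conflicting positions is an error.
    """
    dup = gene_map[gene_map.duplicated("gene_id", keep=False)]
    if len(dup) and dup.groupby("gene_id")["start"].nunique().gt(1).any():
        raise ValueError("duplicate gene with conflicting positions")
    mapped = gene_map.drop_duplicates("gene_id").set_index("gene_id")
    present = [g for g in genes if g in mapped.index]
    n_unmapped = len(genes) - len(present)
    sub = mapped.loc[present]
    sub = sub[sub["chrom"] == chrom]
    ordered = sub.sort_values("start", kind="stable").reset_index()
    return ordered[["gene_id", "chrom", "start"]], n_unmapped


def mf_ratio(norm_counts: pd.DataFrame, sheet: pd.DataFrame) -> pd.Series:
    """Per-gene log2 of male over female mean expression (pseudocount 0.5)."""
    sex_of = sheet.set_index("sample")["sex"]
    males = [s for s in norm_counts.columns if sex_of.get(s) == "M"]
    females = [s for s in norm_counts.columns if sex_of.get(s) == "F"]
    if not males or not females:
        raise ValueError("both sexes must be present")
    m = norm_counts[males].mean(axis=1)
    f = norm_counts[females].mean(axis=1)
    return np.log2((m + PSEUDOCOUNT) / (f + PSEUDOCOUNT)).rename("log2_mf")


def sex_snp_density(
    variants,
    gene_lengths: dict[str, int],
    sheet: pd.DataFrame,
    het_band: tuple[float, float] = (0.2, 0.8),
    min_depth: int = 20,
) -> pd.DataFrame:
    """Heterozygous sites per kb per individual, by sex and gene.

    A sample is called heterozygous at a site when its alt-read frequency
    falls inside ``het_band`` (inclusive) with at least ``min_depth`` reads;
    the density for a sex is (heterozygous sample-site events) divided by
    (number of individuals of that sex x transcript length in kb).
    """
    lo, hi = het_band
    sex_of = sheet.set_index("sample")["sex"]
    by_sex = {
        sex: [s for s in variants.samples if sex_of.get(s) == sex] for sex in ("M", "F")
    }
    n_by_sex = {sex: len(cols) for sex, cols in by_sex.items()}
    for length in gene_lengths.values():
        if length <= 0:
            raise ValueError("zero-length gene span")

    freq = variants.frequencies()
    dp = variants.dp
    rows = {g: {"snp_density_m": 0.0, "snp_density_f": 0.0} for g in gene_lengths}
    if len(variants):
        het = (freq >= lo) & (freq <= hi) & (dp >= min_depth)
        het_events = het.groupby(variants.sites["contig"].to_numpy()).sum()
        for contig, row in het_events.iterrows():
            if contig not in rows:
                continue
            kb = gene_lengths[contig] / 1000.0
            for sex, key in (("M", "snp_density_m"), ("F", "snp_density_f")):
                if n_by_sex[sex]:
                    rows[contig][key] = float(row[by_sex[sex]].sum()) / (n_by_sex[sex] * kb)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out


def moving_average(series, window: int = 10) -> np.ndarray:
    """Centered moving average truncated at the ends; length-preserving.

    For an even window the center is offset left (offsets -w/2 ... w/2-1,
    i.e. -5..+4 for the default 10); windows are truncated where they run
    off the series, so every output is the mean of at least one value.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if window < 1:
        raise ValueError("window must be >= 1")
    lo = window // 2
    hi = window - lo - 1
    out = np.empty_like(x)
    for i in range(x.size):
        out[i] = x[max(0, i - lo) : min(x.size, i + hi + 1)].mean()
    return out


@dataclass(frozen=True)
class RegionCall:
    """A contiguous stretch of genes labelled PAR-like or non-PAR-like."""

    chrom: str
    start_index: int  # gene-order ordinals, half-open
    end_index: int
    start_pos: int
    end_pos: int
    label: str  # "PAR-like" | "nonPAR-like"

    @property
    def n_genes(self) -> int:
        return self.end_index - self.start_index


def gene_sex_stats(
    ordered: pd.DataFrame,
    log2_mf: pd.Series,
    densities: pd.DataFrame,
    window: int = 10,
) -> pd.DataFrame:
    """Assemble the per-gene scan table with moving-average columns."""
    stats = ordered.copy()
    stats["log2_mf"] = log2_mf.reindex(stats["gene_id"]).to_numpy()
    for col in ("snp_density_m", "snp_density_f"):
        stats[col] = densities[col].reindex(stats["gene_id"]).fillna(0.0).to_numpy()
    stats["ma_log2_mf"] = moving_average(stats["log2_mf"], window)
    ma_m = moving_average(stats["snp_density_m"], window)
    ma_f = moving_average(stats["snp_density_f"], window)
    stats["ma_density_ratio"] = ma_m / (ma_f + EPS)
    return stats


def call_nonpar_regions(
    stats: pd.DataFrame,
    tau_expr: float = 0.5,
    tau_dens: float = 1.5,
    min_run: int = 5,
) -> list[RegionCall]:
    """Partition the ordered genes into PAR-like and non-PAR-like regions.

    A gene is non-PAR-flagged when its smoothed log2 M:F exceeds
    ``tau_expr`` and its smoothed male/female SNP-density ratio exceeds
    ``tau_dens``; runs of at least ``min_run`` flagged genes become
    non-PAR-like regions and everything else is PAR-like. The regions are
    ordered, non-overlapping and cover every mapped gene.
    """
    flags = (stats["ma_log2_mf"] > tau_expr) & (stats["ma_density_ratio"] > tau_dens)
    flags = flags.to_numpy()
    n = len(stats)
    labels = np.full(n, "PAR-like", dtype=object)
    i = 0
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            if j - i >= min_run:
                labels[i:j] = "nonPAR-like"
            i = j
        else:
            i += 1

    regions: list[RegionCall] = []
    i = 0
    chrom = stats["chrom"].iloc[0] if n else "Z"
    pos = stats["start"].to_numpy() if n else np.array([])
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        regions.append(
            RegionCall(chrom, i, j, int(pos[i]), int(pos[j - 1]), str(labels[i]))
        )
        i = j
    return regions


def fit_par_boundary(log2_mf) -> tuple[int, float]:
    """Least-squares single-changepoint step fit along the gene order.

    Finds the boundary k minimizing the summed squared error of one mean
    fitted to genes [0, k) and another to [k, n); exhaustive over k with
    ties broken toward the smallest k. Returns (k, SSE at k).
    """
    x = np.asarray(log2_mf, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two genes")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(lo: int, hi: int) -> float:
        m = hi - lo
        if m == 0:
            return 0.0
        s = csum[hi] - csum[lo]
        return (csq[hi] - csq[lo]) - s * s / m

    best_k, best = 0, np.inf
    for k in range(n + 1):
        total = sse(0, k) + sse(k, n)
        if total < best - 1e-12:
            best_k, best = k, total
    return best_k, float(best)


def bimodality_summary(log2_mf, cut: float = 0.5) -> dict:
    """Counts and mean of the genes below/above ``cut`` on the dosage axis."""
    x = np.asarray(log2_mf, dtype=float)
    low = x[x <= cut]
    high = x[x > cut]
    return {
        "n_low": int(low.size),
        "n_high": int(high.size),
        "mean_low": float(low.mean()) if low.size else None,
        "mean_high": float(high.mean()) if high.size else None,
    }


def regions_to_bed(regions: list[RegionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start_pos,
                "end": r.end_pos,
                "name": r.label,
                "score": r.n_genes,
                "strand": ".",
            }
            for r in regions
        ]
    )
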