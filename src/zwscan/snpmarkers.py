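"""SNP marker filtering and classification.

Applies a population-marker filtering cohort to per-sample allele-depth
observations:

- coverage: every bird in the evaluated cohort must carry at least
  ``min_depth`` reads across the site (default 50, inclusive);
- density: within-species markers are only accepted on contigs with fewer
  than 1 variant per 200 bp (strict);
- within-species marker: at least one individual with alt-read frequency
  below ``low_freq`` (expected reference genotype, default 5%) and at least
  one above ``high_freq`` (expected heterozygote/homozygote, default 35%),
  both strict;
- species-diagnostic marker: every individual of one species above
  ``diag_high`` (default 80%) and every individual of the other below
  ``diag_low`` (default 5%).

Frequencies are per individual (alt reads / total reads at the site), not
pooled; a pooled mode for the diagnostic rule is available via
``diag_mode="pooled"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from zwscan.io import VariantTable


@dataclass
class Thresholds:
    """Filtering thresholds; comparison directions are documented per rule."""

    min_depth: int = 50
    max_density: float = 1.0 / 200.0  # variants per bp, strict <
    low_freq: float = 0.05
    high_freq: float = 0.35
    diag_high: float = 0.80
    diag_low: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.diag_low < self.diag_high <= 1:
            raise ValueError("need 0 <= diag_low < diag_high <= 1")
        if not 0 <= self.low_freq < self.high_freq <= 1:
            raise ValueError("need 0 <= low_freq < high_freq <= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.max_density <= 0:
            raise ValueError("max_density must be positive")


def site_frequency(depth: int, alt_depth: int) -> float:
    """Alt-allele read frequency; NaN (missing) at zero depth."""
    if alt_depth < 0 or alt_depth > depth:
        raise ValueError(f"alt depth {alt_depth} outside [0, {depth}]")
    if depth == 0:
        return float("nan")
    return alt_depth / depth


def coverage_filter(depths, thr: Thresholds) -> bool:
    """True iff every individual has depth >= ``min_depth`` (inclusive)."""
    depths = np.asarray(depths)
    return bool((depths >= thr.min_depth).all())


def density_filter(contig_len: int, n_variants: int, thr: Thresholds) -> bool:
    """True iff the contig's variant density is strictly below the cap."""
    if contig_len <= 0:
        raise ValueError("contig length must be positive")
    return n_variants / contig_len < thr.max_density


def within_species_marker(freqs, thr: Thresholds) -> bool:
    """Segregation rule within one species.

    True iff at least one individual sits below ``low_freq`` and at least
    one above ``high_freq`` (both strict). Missing frequencies (NaN) do not
    satisfy either side.
    """
    freqs = np.asarray(freqs, dtype=float)
    defined = freqs[~np.isnan(freqs)]
    if defined.size < 2:
        return False
    return bool((defined < thr.low_freq).any() and (defined > thr.high_freq).any())


def species_diagnostic(freqs_a, freqs_b, thr: Thresholds, mode: str = "per_bird") -> str | None:
    """Which species, if either, is fixed for the alternate allele.

    ``per_bird`` (default): diagnostic for A iff every A individual has
    frequency > ``diag_high`` and every B individual < ``diag_low``;
    symmetric for B. ``pooled`` applies the same cutoffs to each species'
    mean frequency across individuals. Returns "A", "B" or None.
    """
    fa = np.asarray(freqs_a, dtype=float)
    fb = np.asarray(freqs_b, dtype=float)
    if fa.size == 0 or fb.size == 0:
        raise ValueError("both species must be represented")
    if mode == "pooled":
        fa = np.asarray([np.nanmean(fa)])
        fb = np.asarray([np.nanmean(fb)])
    elif mode != "per_bird":
        raise ValueError(f"unknown mode {mode!r}")
    if np.isnan(fa).any() or np.isnan(fb).any():
        return None
    if (fa > thr.diag_high).all() and (fb < thr.diag_low).all():
        return "A"
    if (fb > thr.diag_high).all() and (fa < thr.diag_low).all():
        return "B"
    return None


def classify_sites(
    variants: VariantTable,
    sheet: pd.DataFrame,
    contig_lengths: dict[str, int],
    thr: Thresholds | None = None,
    effects: pd.Series | None = None,
    diag_mode: str = "per_bird",
) -> pd.DataFrame:
    """Apply every rule to every site.

    Returns one row per site with columns: contig, pos, coverage_pass,
    density_pass, within_<species> per species, diagnostic (species name or
    None) and effect (if provided). The coverage cohort is all samples; the
    density rule counts all sites on the contig (pre-coverage-filter) and
    gates only the within-species calls; diagnostic calls require only the
    coverage rule, matching how each rule is stated.
    """
    thr = thr or Thresholds()
    species = list(dict.fromkeys(sheet["species"]))
    if len(species) != 2:
        raise ValueError(f"expected exactly two species, got {species}")
    sample_species = sheet.set_index("sample")["species"]
    cols = {sp: [s for s in variants.samples if sample_species[s] == sp] for sp in species}

    # vectorized application of the per-site rules above
    dp = variants.dp.to_numpy()
    freq = variants.frequencies()
    cov = (dp >= thr.min_depth).all(axis=1)
    lengths = variants.sites["contig"].map(contig_lengths).to_numpy(dtype=float)
    n_on_contig = variants.sites.groupby("contig")["pos"].transform("size").to_numpy()
    dens = n_on_contig / lengths < thr.max_density

    f = {sp: freq[cols[sp]].to_numpy() for sp in species}
    with np.errstate(invalid="ignore"):
        within = {}
        for sp in species:
            defined = (~np.isnan(f[sp])).sum(axis=1)
            within[sp] = (
                cov
                & dens
                & (defined >= 2)
                & np.nan_to_num(f[sp] < thr.low_freq).any(axis=1)
                & np.nan_to_num(f[sp] > thr.high_freq).any(axis=1)
            )
        fa, fb = f[species[0]], f[species[1]]
        if diag_mode == "pooled":
            fa = np.nanmean(fa, axis=1, keepdims=True)
            fb = np.nanmean(fb, axis=1, keepdims=True)
        elif diag_mode != "per_bird":
            raise ValueError(f"unknown mode {diag_mode!r}")
        no_missing = ~(np.isnan(fa).any(axis=1) | np.isnan(fb).any(axis=1))
        diag_a = cov & no_missing & (fa > thr.diag_high).all(axis=1) & (fb < thr.diag_low).all(axis=1)
        diag_b = cov & no_missing & (fb > thr.diag_high).all(axis=1) & (fa < thr.diag_low).all(axis=1)

    diag = np.where(diag_a, species[0], np.where(diag_b, species[1], None))
    out = variants.sites[["contig", "pos"]].copy()
    out["coverage_pass"] = cov
    out["density_pass"] = dens
    out["diagnostic"] = diag
    for sp in species:
        out[f"within_{sp}"] = within[sp]
    if effects is not None:
        out["effect"] = effects.to_numpy()
    return out


def summarize(classifications: pd.DataFrame) -> pd.DataFrame:
    """Marker counts by category with amino-acid-changing subtotals.

    One row per category (coverage-passing sites, species-diagnostic and
    within-species markers per species) with the total number of sites and
    how many are predicted nonsynonymous.
    """
    def count(mask) -> tuple[int, int]:
        sub = classifications[mask] if len(classifications) else classifications
        n = int(mask.sum()) if len(classifications) else 0
        if "effect" in classifications.columns and n:
            nsy = int((sub["effect"] == "nonsynonymous").sum())
        else:
            nsy = 0
        return n, nsy

    rows = []
    if len(classifications):
        n, nsy = count(classifications["coverage_pass"])
    else:
        n = nsy = 0
    rows.append({"category": "coverage_pass", "n_sites": n, "n_aa_changing": nsy})
    if len(classifications):
        species = sorted(
            c.removeprefix("within_") for c in classifications.columns if c.startswith("within_")
        )
        for sp in species:
            n, nsy = count(classifications["diagnostic"] == sp)
            rows.append({"category": f"diagnostic_{sp}", "n_sites": n, "n_aa_changing": nsy})
        for sp in species:
            n, nsy = count(classifications[f"within_{sp}"])
            rows.append({"category": f"within_{sp}", "n_sites": n, "n_aa_changing": nsy})
    return pd.DataFrame(rows, columns=["category", "n_sites", "n_aa_changing"])
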