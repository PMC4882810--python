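"""Hemoglobin read accounting, depletion and library subsampling.

Whole-blood RNA-seq libraries are dominated by a handful of globin
transcripts. This module flags transcripts holding a large share of the
pooled library, removes their reads, optionally subsamples the remainder to
a fixed read-pair budget, and produces the per-species accounting table a
study reports (total pairs, hemoglobin-mapped pairs, overall percentage).

The read-assignment table is a long-format DataFrame with columns
``transcript_id``, ``sample_id`` and ``read_pairs`` (one row per cell); a
genes-by-samples count matrix converts via :func:`assignments_from_counts`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ASSIGNMENT_COLUMNS = ["transcript_id", "sample_id", "read_pairs"]


def assignments_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Melt a genes-by-samples count matrix into a read-assignment table."""
    long = counts.rename_axis("transcript_id").reset_index().melt(
        id_vars="transcript_id", var_name="sample_id", value_name="read_pairs"
    )
    return long[ASSIGNMENT_COLUMNS]


def counts_from_assignments(assign: pd.DataFrame) -> pd.DataFrame:
    """Pivot a read-assignment table back to a genes-by-samples matrix."""
    return (
        assign.pivot_table(
            index="transcript_id", columns="sample_id", values="read_pairs", fill_value=0
        )
        .rename_axis(index=None, columns=None)
        .astype(np.int64)
    )


def _validate(assign: pd.DataFrame) -> None:
    missing = set(ASSIGNMENT_COLUMNS) - set(assign.columns)
    if missing:
        raise ValueError(f"assignment table missing columns: {sorted(missing)}")
    if (assign["read_pairs"] < 0).any():
        raise ValueError("negative read counts")
    if assign.duplicated(["transcript_id", "sample_id"]).any():
        raise ValueError("duplicate (transcript, sample) cell")


def flag_high_share_transcripts(assign: pd.DataFrame, threshold: float = 0.20) -> set[str]:
    """Transcripts whose pooled share of all read pairs is >= ``threshold``.

    The comparison is inclusive; the default 0.20 reflects the roughly
    one-fifth of blood-library reads a pair of hemoglobin subunit
    transcripts typically absorbs.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    _validate(assign)
    total = assign["read_pairs"].sum()
    if total <= 0:
        raise ValueError("total read count must be positive")
    shares = assign.groupby("transcript_id")["read_pairs"].sum() / total
    return set(shares.index[shares >= threshold])


def deplete(assign: pd.DataFrame, flagged: set[str]) -> tuple[pd.DataFrame, int]:
    """Drop every read assigned to a flagged transcript.

    Returns the remaining table and the number of pairs removed; reads are
    conserved (removed + remaining = input total).
    """
    _validate(assign)
    keep = ~assign["transcript_id"].isin(flagged)
    remaining = assign[keep].reset_index(drop=True)
    removed = int(assign.loc[~keep, "read_pairs"].sum())
    return remaining, removed


def subsample(assign: pd.DataFrame, target_pairs: int, seed: int) -> pd.DataFrame:
    """Randomly keep exactly ``target_pairs`` read pairs without replacement.

    A multivariate hypergeometric draw across all (transcript, sample)
    cells: each retained pair is an independent uniform pick from the pool,
    mirroring random read subsampling before assembly.
    """
    _validate(assign)
    total = int(assign["read_pairs"].sum())
    if target_pairs > total:
        raise ValueError(f"target {target_pairs} exceeds available {total}")
    if target_pairs < 0:
        raise ValueError("target must be non-negative")
    rng = np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(
        assign["read_pairs"].to_numpy(dtype=np.int64), target_pairs, method="marginals"
    )
    out = assign.copy()
    out["read_pairs"] = drawn
    return out


@dataclass
class AccountingReport:
    """Study-style read accounting, overall and per species."""

    per_species_total: dict[str, int]
    per_species_hemoglobin: dict[str, int]
    total_pairs: int
    hemoglobin_pairs: int
    hemoglobin_percent: int  # nearest integer, ties away from zero
    post_depletion_pairs: int
    post_subsample_pairs: int | None = None

    def to_json(self) -> dict:
        return {
            "per_species_total": self.per_species_total,
            "per_species_hemoglobin": self.per_species_hemoglobin,
            "total_pairs": self.total_pairs,
            "hemoglobin_pairs": self.hemoglobin_pairs,
            "hemoglobin_percent": self.hemoglobin_percent,
            "post_depletion_pairs": self.post_depletion_pairs,
            "post_subsample_pairs": self.post_subsample_pairs,
        }


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (presentation rule)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def accounting_report(
    assign: pd.DataFrame,
    flagged: set[str],
    sheet: pd.DataFrame,
    post_subsample_pairs: int | None = None,
) -> AccountingReport:
    """Tabulate totals and hemoglobin-mapped pairs per species.

    ``sheet`` must map every sample id in the table to a species.
    """
    _validate(assign)
    species_of = sheet.set_index("sample")["species"]
    unknown = set(assign["sample_id"]) - set(species_of.index)
    if unknown:
        raise ValueError(f"samples missing from sheet: {sorted(unknown)}")

    work = assign.assign(species=assign["sample_id"].map(species_of))
    totals = work.groupby("species")["read_pairs"].sum()
    hb = (
        work[work["transcript_id"].isin(flagged)]
        .groupby("species")["read_pairs"]
        .sum()
        .reindex(totals.index, fill_value=0)
    )
    total = int(totals.sum())
    hb_total = int(hb.sum())
    return AccountingReport(
        per_species_total={k: int(v) for k, v in totals.items()},
        per_species_hemoglobin={k: int(v) for k, v in hb.items()},
        total_pairs=total,
        hemoglobin_pairs=hb_total,
        hemoglobin_percent=round_half_away(100.0 * hb_total / total) if total else 0,
        post_depletion_pairs=total - hb_total,
        post_subsample_pairs=post_subsample_pairs,
    )
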