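"""Synteny ordering, dosage ratios, densities, smoothing, region calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zwscan import sexscan, simdata
from zwscan.io import VariantTable


def sheet_of(samples, sexes):
    return pd.DataFrame(
        {"sample": samples, "species": "x", "sex": sexes}
    )


class TestOrderBySynteny:
    def gm(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "par"])

    def test_sorted_by_position(self):
        gm = self.gm([("g1", "Z", 30, 31, "+", 0), ("g2", "Z", 10, 11, "+", 0), ("g3", "Z", 20, 21, "+", 0)])
        ordered, n_unmapped = sexscan.order_by_synteny(["g1", "g2", "g3"], gm)
        assert ordered["gene_id"].tolist() == ["g2", "g3", "g1"]
        assert n_unmapped == 0

    def test_unmapped_counted_and_excluded(self):
        gm = self.gm([("g1", "Z", 5, 6, "+", 0)])
        ordered, n_unmapped = sexscan.order_by_synteny(["g1", "mystery"], gm)
        assert ordered["gene_id"].tolist() == ["g1"]
        assert n_unmapped == 1

    def test_position_ties_keep_input_order(self):
        gm = self.gm([("a", "Z", 5, 6, "+", 0), ("b", "Z", 5, 6, "+", 0)])
        ordered, _ = sexscan.order_by_synteny(["b", "a"], gm)
        assert ordered["gene_id"].tolist() == ["b", "a"]

    def test_conflicting_duplicate_rejected(self):
        gm = self.gm([("a", "Z", 5, 6, "+", 0), ("a", "Z", 9, 10, "+", 0)])
        with pytest.raises(ValueError, match="conflicting"):
            sexscan.order_by_synteny(["a"], gm)


class TestMfRatio:
    def test_equal_means_zero(self):
        counts = pd.DataFrame({"m1": [100], "f1": [100]}, index=["g"])
        mf = sexscan.mf_ratio(counts, sheet_of(["m1", "f1"], ["M", "F"]))
        assert mf.iloc[0] == 0.0

    def test_two_fold_limit(self):
        counts = pd.DataFrame({"m1": [20000], "f1": [10000]}, index=["g"])
        mf = sexscan.mf_ratio(counts, sheet_of(["m1", "f1"], ["M", "F"]))
        assert mf.iloc[0] == pytest.approx(1.0, abs=1e-4)

    def test_zero_counts_symmetric(self):
        counts = pd.DataFrame({"m1": [0], "f1": [0]}, index=["g"])
        mf = sexscan.mf_ratio(counts, sheet_of(["m1", "f1"], ["M", "F"]))
        assert mf.iloc[0] == 0.0

    def test_absent_sex_rejected(self):
        counts = pd.DataFrame({"m1": [1]}, index=["g"])
        with pytest.raises(ValueError):
            sexscan.mf_ratio(counts, sheet_of(["m1"], ["M"]))


class TestSnpDensity:
    def table(self, contigs, dp, ad, samples):
        sites = pd.DataFrame(
            {"contig": contigs, "pos": range(len(contigs)), "ref": "A", "alt": "G"}
        )
        return VariantTable(
            sites=sites,
            dp=pd.DataFrame(dp, columns=samples),
            ad=pd.DataFrame(ad, columns=samples),
        )

    def test_no_variants_zero_density(self):
        v = self.table([], np.empty((0, 2), dtype=int), np.empty((0, 2), dtype=int), ["m1", "f1"])
        out = sexscan.sex_snp_density(v, {"g": 1000}, sheet_of(["m1", "f1"], ["M", "F"]))
        assert out.loc["g", "snp_density_m"] == 0.0
        assert out.loc["g", "snp_density_f"] == 0.0

    def test_length_doubling_halves_density(self):
        v = self.table(["g"], [[100, 100]], [[50, 0]], ["m1", "f1"])
        sheet = sheet_of(["m1", "f1"], ["M", "F"])
        short = sexscan.sex_snp_density(v, {"g": 1000}, sheet)
        long = sexscan.sex_snp_density(v, {"g": 2000}, sheet)
        assert short.loc["g", "snp_density_m"] == 2 * long.loc["g", "snp_density_m"]
        assert short.loc["g", "snp_density_f"] == 0.0

    def test_zero_length_rejected(self):
        v = self.table(["g"], [[10, 10]], [[5, 5]], ["m1", "f1"])
        with pytest.raises(ValueError):
            sexscan.sex_snp_density(v, {"g": 0}, sheet_of(["m1", "f1"], ["M", "F"]))

    def test_hemizygous_females_show_no_het_density(self, small_bundle):
        """Outside the PAR, female heterozygosity is structurally absent."""
        gm = small_bundle.gene_map
        nonpar = gm[(gm["chrom"] == "Z") & ~gm["par"]]
        lengths = {g: e - s for g, s, e in zip(nonpar["gene_id"], nonpar["start"], nonpar["end"])}
        out = sexscan.sex_snp_density(small_bundle.variants, lengths, small_bundle.sheet)
        assert out["snp_density_f"].sum() == pytest.approx(0.0, abs=1e-6)
        assert out["snp_density_m"].mean() > 0

    def test_sex_label_swap_swaps_densities(self, small_bundle):
        gm = small_bundle.gene_map
        z = gm[gm["chrom"] == "Z"]
        lengths = {g: e - s for g, s, e in zip(z["gene_id"], z["start"], z["end"])}
        swapped = small_bundle.sheet.copy()
        swapped["sex"] = swapped["sex"].map({"M": "F", "F": "M"})
        a = sexscan.sex_snp_density(small_bundle.variants, lengths, small_bundle.sheet)
        b = sexscan.sex_snp_density(small_bundle.variants, lengths, swapped)
        assert np.allclose(a["snp_density_m"], b["snp_density_f"])
        assert np.allclose(a["snp_density_f"], b["snp_density_m"])


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        assert np.allclose(sexscan.moving_average([3.0] * 20, 10), 3.0)

    def test_window_one_is_identity(self):
        x = [1.0, 5.0, 2.0]
        assert np.allclose(sexscan.moving_average(x, 1), x)

    @given(
        values=st.lists(st.floats(-100, 100), min_size=1, max_size=40),
        window=st.integers(min_value=1, max_value=12),
    )
    def test_matches_direct_loop_oracle(self, values, window):
        out = sexscan.moving_average(values, window)
        lo, hi = window // 2, window - window // 2 - 1
        for i in range(len(values)):
            chunk = values[max(0, i - lo) : min(len(values), i + hi + 1)]
            assert out[i] == pytest.approx(sum(chunk) / len(chunk), rel=1e-9, abs=1e-9)

    def test_window_values_bounded_by_inputs(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        out = sexscan.moving_average(x, 10)
        assert (out >= x.min() - 1e-12).all() and (out <= x.max() + 1e-12).all()

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            sexscan.moving_average([], 10)


class TestRegionsAndBoundary:
    def stats_frame(self, log2_mf, ratio):
        n = len(log2_mf)
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "chrom": "Z",
                "start": np.arange(n) * 10,
                "log2_mf": log2_mf,
                "ma_log2_mf": log2_mf,
                "ma_density_ratio": ratio,
            }
        )

    def test_flat_profile_is_single_par_region(self):
        stats = self.stats_frame([0.0] * 30, [1.0] * 30)
        regions = sexscan.call_nonpar_regions(stats)
        assert len(regions) == 1
        assert regions[0].label == "PAR-like"
        assert regions[0].n_genes == 30

    def test_infinite_threshold_never_flags(self):
        stats = self.stats_frame([5.0] * 30, [9.0] * 30)
        regions = sexscan.call_nonpar_regions(stats, tau_expr=np.inf)
        assert all(r.label == "PAR-like" for r in regions)

    def test_runs_below_min_run_not_called(self):
        flags = [0.0] * 10 + [1.0] * 3 + [0.0] * 10
        stats = self.stats_frame(flags, [2.0] * 23)
        regions = sexscan.call_nonpar_regions(stats, min_run=5)
        assert all(r.label == "PAR-like" for r in regions)

    def test_partition_covers_every_gene_once(self, small_bundle):
        from zwscan import diffexpr

        norm = diffexpr.quantile_normalize(
            small_bundle.counts.drop(index=small_bundle.truth.hemoglobin_ids)
        )
        ordered, _ = sexscan.order_by_synteny(list(norm.index), small_bundle.gene_map)
        lengths = {g: len(small_bundle.sequences[g]) for g in ordered["gene_id"]}
        dens = sexscan.sex_snp_density(small_bundle.variants, lengths, small_bundle.sheet)
        stats = sexscan.gene_sex_stats(
            ordered, sexscan.mf_ratio(norm, small_bundle.sheet), dens
        )
        regions = sexscan.call_nonpar_regions(stats)
        covered = []
        for r in regions:
            covered.extend(range(r.start_index, r.end_index))
        assert covered == list(range(len(stats)))

    def test_step_series_boundary_exact(self):
        k, _ = sexscan.fit_par_boundary([0.0] * 10 + [1.0] * 10)
        assert k == 10

    def test_constant_series_boundary_zero(self):
        k, _ = sexscan.fit_par_boundary([0.7] * 15)
        assert k == 0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            sexscan.fit_par_boundary([1.0])

    def test_noisy_step_recovered_within_tolerance(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 0.25, 60), rng.normal(1, 0.25, 30)])
        k, _ = sexscan.fit_par_boundary(x)
        assert abs(k - 60) <= 3

    def test_ma_window_inputs_bound_ma_columns(self, small_bundle):
        from zwscan import diffexpr

        norm = diffexpr.quantile_normalize(
            small_bundle.counts.drop(index=small_bundle.truth.hemoglobin_ids)
        )
        ordered, _ = sexscan.order_by_synteny(list(norm.index), small_bundle.gene_map)
        lengths = {g: len(small_bundle.sequences[g]) for g in ordered["gene_id"]}
        dens = sexscan.sex_snp_density(small_bundle.variants, lengths, small_bundle.sheet)
        stats = sexscan.gene_sex_stats(
            ordered, sexscan.mf_ratio(norm, small_bundle.sheet), dens
        )
        x = stats["log2_mf"].to_numpy()
        ma = stats["ma_log2_mf"].to_numpy()
        lo, hi = 5, 4
        for i in range(len(x)):
            w = x[max(0, i - lo) : min(len(x), i + hi + 1)]
            assert w.min() - 1e-9 <= ma[i] <= w.max() + 1e-9


class TestBimodality:
    def test_all_zero(self):
        out = sexscan.bimodality_summary([0.0] * 5)
        assert out == {"n_low": 5, "n_high": 0, "mean_low": 0.0, "mean_high": None}

    def test_split_at_cut(self):
        out = sexscan.bimodality_summary([0.0, 0.1, 0.9, 1.1], cut=0.5)
        assert (out["n_low"], out["n_high"]) == (2, 2)
        assert out["mean_high"] == pytest.approx(1.0)
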