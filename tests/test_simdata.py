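"""Generator structure: gene map, dosage, hemizygosity, round-trips."""

import numpy as np
import pandas as pd
import pytest

from zwscan import io, simdata
from zwscan.simdata import SimConfig


class TestGeneMap:
    @pytest.mark.parametrize(
        "par_fraction,n_z,expected_par",
        [(0.0, 90, 0), (1.0, 90, 90), (2 / 3, 300, 200)],
    )
    def test_par_gene_count(self, par_fraction, n_z, expected_par):
        cfg = SimConfig(n_autosomal_genes=10, n_z_genes=n_z, par_fraction=par_fraction)
        gm = simdata.build_gene_map(cfg)
        assert int(gm.loc[gm["chrom"] == "Z", "par"].sum()) == expected_par
        assert simdata.par_boundary_index(gm) == expected_par

    def test_par_genes_form_a_prefix_of_z(self):
        gm = simdata.build_gene_map(SimConfig(n_autosomal_genes=5, n_z_genes=40))
        z = gm[gm["chrom"] == "Z"].sort_values("start")
        par = z["par"].to_numpy()
        assert not par[par.argmin() :].any()  # no PAR gene after the first non-PAR

    def test_positions_strictly_increase_per_chromosome(self):
        gm = simdata.build_gene_map(SimConfig(n_autosomal_genes=30, n_z_genes=30))
        for _, sub in gm.groupby("chrom"):
            starts = sub.sort_values("start")["start"].to_numpy()
            assert (np.diff(starts) > 0).all()
            assert (sub["end"] > sub["start"]).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_z_genes": 0, "par_fraction": 0.5},
            {"par_fraction": 1.5},
            {"n_per_species": 7},
            {"sex_effect_nonpar": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestExpression:
    def test_same_seed_identical_counts(self, small_config, small_bundle):
        again = simdata.simulate_dataset(small_config)
        pd.testing.assert_frame_equal(again.counts, small_bundle.counts)
        pd.testing.assert_frame_equal(again.variants.dp, small_bundle.variants.dp)

    def test_no_sex_effect_means_unit_ratio(self):
        cfg = SimConfig(
            n_autosomal_genes=50, n_z_genes=60, mean_depth=500, sex_effect_nonpar=1.0, seed=3
        )
        gm = simdata.build_gene_map(cfg)
        sheet = simdata.build_sample_sheet(cfg)
        counts, _ = simdata.simulate_expression(cfg, gm, sheet)
        males = sheet.loc[sheet["sex"] == "M", "sample"]
        females = sheet.loc[sheet["sex"] == "F", "sample"]
        z = gm.loc[(gm["chrom"] == "Z") & ~gm["par"], "gene_id"]
        ratio = counts.loc[z, males].mean(axis=1) / counts.loc[z, females].mean(axis=1)
        assert ratio.mean() == pytest.approx(1.0, abs=0.1)

    def test_nonpar_dosage_two_fold_monte_carlo(self):
        """Mean M:F raw-count ratio over non-PAR Z genes is ~2 (20 seeds)."""
        ratios = []
        for seed in range(20):
            cfg = SimConfig(n_autosomal_genes=50, n_z_genes=300, mean_depth=500, seed=seed)
            gm = simdata.build_gene_map(cfg)
            sheet = simdata.build_sample_sheet(cfg)
            counts, _ = simdata.simulate_expression(cfg, gm, sheet)
            males = sheet.loc[sheet["sex"] == "M", "sample"]
            females = sheet.loc[sheet["sex"] == "F", "sample"]
            z = gm.loc[(gm["chrom"] == "Z") & ~gm["par"], "gene_id"]
            r = counts.loc[z, males].mean(axis=1) / counts.loc[z, females].mean(axis=1)
            ratios.append(r.mean())
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)

    def test_hemoglobin_share_matches_config(self):
        shares = []
        for seed in range(3):
            cfg = SimConfig(n_autosomal_genes=200, n_z_genes=60, mean_depth=500, seed=seed)
            gm = simdata.build_gene_map(cfg)
            sheet = simdata.build_sample_sheet(cfg)
            counts, truth = simdata.simulate_expression(cfg, gm, sheet)
            shares.append(
                counts.loc[truth.hemoglobin_ids].sum().sum() / counts.sum().sum()
            )
        assert np.mean(shares) == pytest.approx(0.20, abs=0.02)

    def test_missing_sex_rejected(self):
        cfg = SimConfig(n_autosomal_genes=10, n_z_genes=10)
        gm = simdata.build_gene_map(cfg)
        sheet = simdata.build_sample_sheet(cfg)
        males_only = sheet[sheet["sex"] == "M"]
        with pytest.raises(ValueError, match="both sexes"):
            simdata.simulate_expression(cfg, gm, males_only)
        with pytest.raises(ValueError, match="empty"):
            simdata.simulate_expression(cfg, gm, sheet.iloc[0:0])


class TestVariants:
    def test_females_never_heterozygous_at_nonpar_z(self, small_bundle):
        gm = small_bundle.gene_map
        nonpar_z = set(gm.loc[(gm["chrom"] == "Z") & ~gm["par"], "gene_id"])
        females = small_bundle.sheet.loc[small_bundle.sheet["sex"] == "F", "sample"]
        mask = small_bundle.variants.sites["contig"].isin(nonpar_z).to_numpy()
        gts = small_bundle.variants.gt.loc[mask, females].to_numpy().ravel()
        assert len(gts) > 0
        assert set(gts) <= {"0", "1"}  # haploid calls only, never 0/1

    def test_diagnostic_sites_fixed_between_species(self, small_bundle):
        species_of = small_bundle.sheet.set_index("sample")["species"]
        sites = small_bundle.variants.sites.set_index(["contig", "pos"])
        gt = small_bundle.variants.gt.set_index(sites.index)
        for carrier, planted in small_bundle.truth.diagnostic_sites.items():
            for contig, pos in planted[:50]:
                row = gt.loc[(contig, pos)]
                for sample, g in row.items():
                    if species_of[sample] == carrier:
                        assert g in {"1/1", "1"}
                    else:
                        assert g in {"0/0", "0"}

    def test_diagnostic_and_within_sets_disjoint(self, small_bundle):
        truth = small_bundle.truth
        diag = {tuple(s) for v in truth.diagnostic_sites.values() for s in v}
        within = {tuple(s) for v in truth.within_species_sites.values() for s in v}
        assert diag and within
        assert not diag & within

    def test_heterozygote_alt_depth_is_binomial_mean(self):
        """At dosage 0.5 the expected alt depth is half the site depth."""
        rng = np.random.default_rng(0)
        draws = rng.binomial(100, 0.5, size=2000)
        assert draws.mean() == pytest.approx(50, rel=0.02)


class TestBundleIO:
    def test_round_trip_exact(self, small_bundle, tmp_path):
        simdata.write_dataset(tmp_path, small_bundle)
        back = simdata.read_dataset(tmp_path)
        pd.testing.assert_frame_equal(back["counts"], small_bundle.counts)
        pd.testing.assert_frame_equal(back["variants"].sites, small_bundle.variants.sites)
        pd.testing.assert_frame_equal(back["variants"].dp, small_bundle.variants.dp)
        pd.testing.assert_frame_equal(back["variants"].ad, small_bundle.variants.ad)
        pd.testing.assert_frame_equal(back["variants"].gt, small_bundle.variants.gt)
        pd.testing.assert_frame_equal(back["gene_map"], small_bundle.gene_map[back["gene_map"].columns])
        pd.testing.assert_frame_equal(back["sheet"], small_bundle.sheet)
        assert back["truth"].to_json() == small_bundle.truth.to_json()
        assert back["sequences"] == small_bundle.sequences

    def test_vcf_pos_is_one_based(self, small_bundle, tmp_path):
        paths = simdata.write_dataset(tmp_path, small_bundle)
        first = small_bundle.variants.sites.iloc[0]
        for line in paths["vcf"].read_text().splitlines():
            if not line.startswith("#"):
                chrom, pos = line.split("\t")[:2]
                break
        assert chrom == first["contig"]
        assert int(pos) == first["pos"] + 1  # disk is 1-based, memory 0-based

    def test_empty_variant_set_is_valid_vcf(self, tmp_path):
        empty = io.VariantTable(
            sites=pd.DataFrame(columns=["contig", "pos", "ref", "alt"]),
            dp=pd.DataFrame(columns=["s1", "s2"], dtype=np.int64),
            ad=pd.DataFrame(columns=["s1", "s2"], dtype=np.int64),
        )
        path = tmp_path / "empty.vcf"
        io.write_vcf(path, empty, contig_lengths={"c1": 100})
        back = io.read_vcf(path)
        assert len(back) == 0
        assert back.samples == ["s1", "s2"]

    def test_same_config_byte_identical_bundle(self, tmp_path):
        cfg = SimConfig(n_autosomal_genes=30, n_z_genes=30, mean_depth=100, seed=9)
        p1 = simdata.write_dataset(tmp_path / "a", simdata.simulate_dataset(cfg))
        p2 = simdata.write_dataset(tmp_path / "b", simdata.simulate_dataset(cfg))
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key
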