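"""The synthetic-cohort generator: structure, planted effects, determinism."""

import numpy as np
import pandas as pd
import pytest

from eqtmkit import synthetic
from eqtmkit.synthetic import (
    CountBaseline,
    Coupling,
    GeneEffect,
    GroupDesign,
    MethylationNoise,
    RegionEffect,
    couple_eqtm,
    generate_cohort,
    generate_manifest,
    simulate_counts,
    simulate_methylation,
)


class TestManifest:
    def test_requested_size_and_sortedness(self):
        man = generate_manifest(100, {"chr1": 100_000}, seed=0)
        assert len(man) == 100
        assert np.all(np.diff(man["pos"]) > 0)

    def test_zero_flag_fraction(self):
        man = generate_manifest(200, flag_fractions={"snp": 0.0}, seed=1)
        assert not man["snp_flag"].any()

    def test_flag_fraction_is_respected(self):
        man = generate_manifest(5000, flag_fractions={"snp": 0.3}, seed=2)
        assert man["snp_flag"].mean() == pytest.approx(0.3, abs=0.03)

    def test_same_seed_identical(self):
        a = generate_manifest(150, seed=42)
        b = generate_manifest(150, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_layout_rejected(self):
        with pytest.raises(ValueError):
            generate_manifest(10, {}, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_manifest(10, flag_fractions={"snp": 1.5}, seed=0)


class TestCohort:
    def test_study_shaped_design(self, study_sheet):
        meth = study_sheet[study_sheet["assay"].isin(["methylation", "both"])]
        expr = study_sheet[study_sheet["assay"].isin(["expression", "both"])]
        both = study_sheet[study_sheet["assay"] == "both"]
        assert (len(meth), meth["patient_id"].nunique()) == (18, 10)
        assert (len(expr), expr["patient_id"].nunique()) == (21, 14)
        assert (len(both), both["patient_id"].nunique()) == (9, 6)
        # per-group sample counts of the study
        assert meth["group"].value_counts().to_dict() == {
            "NINF": 7, "nonCD": 5, "STEN": 4, "INF": 2,
        }
        assert expr["group"].value_counts().to_dict() == {
            "NINF": 6, "nonCD": 6, "STEN": 5, "INF": 4,
        }

    def test_anonymous_control_blanked(self, study_sheet):
        anon = study_sheet[study_sheet["patient_id"] == synthetic.ANONYMOUS_PATIENT]
        assert len(anon) >= 1
        assert (anon["sex"] == "unknown").all()
        assert anon["age"].isna().all()

    def test_single_sample_design(self):
        sheet = generate_cohort([GroupDesign("NINF", n_meth=1, n_patients=1)], seed=0)
        assert len(sheet) == 1
        assert sheet.iloc[0]["assay"] == "methylation"

    def test_zero_inf_design(self):
        sheet = generate_cohort(
            [
                GroupDesign("NINF", n_meth=3, n_patients=2),
                GroupDesign("INF", n_meth=0, n_patients=1),
            ],
            seed=0,
        )
        assert not (sheet["group"] == "INF").any()

    def test_impossible_sharing_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign("NINF", n_meth=2, n_expr=1, n_shared=2)

    def test_determinism(self):
        a = generate_cohort(seed=3)
        b = generate_cohort(seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestMethylation:
    def test_no_noise_no_effect_identical_samples(self, small_manifest, study_sheet):
        noise = MethylationNoise(probe_sd=0.5, patient_sd=0.0, sample_sd=0.0)
        beta = simulate_methylation(small_manifest, study_sheet, [], noise, seed=0)
        # all-male check is irrelevant here: restrict to autosomes
        auto = small_manifest.loc[small_manifest.chrom != "chrY", "probe_id"]
        vals = beta.loc[auto].to_numpy()
        assert np.all(vals == vals[:, [0]])

    def test_values_strictly_inside_unit_interval(self, small_manifest, study_sheet):
        beta = simulate_methylation(small_manifest, study_sheet, [], seed=1)
        assert beta.to_numpy().min() > 0
        assert beta.to_numpy().max() < 1

    def test_planted_shift_recovers_delta(self):
        # mid-range baseline so the +0.2 shift is not clipped
        man = generate_manifest(50, {"chr1": 50_000}, seed=2)
        design = [
            GroupDesign("STEN", n_meth=30, n_patients=30),
            GroupDesign("NINF", n_meth=30, n_patients=30),
        ]
        sheet = generate_cohort(design, seed=3)
        noise = MethylationNoise(
            mode_low=0.35, mode_high=0.55, probe_sd=0.1, patient_sd=0.0,
            sample_sd=0.3,
        )
        eff = [RegionEffect("chr1", 10, 8, 0.2, "STEN")]
        beta = simulate_methylation(man, sheet, eff, noise, seed=4)
        sten = sheet.loc[sheet.group == "STEN", "sample_id"]
        ninf = sheet.loc[sheet.group == "NINF", "sample_id"]
        probes = man["probe_id"].iloc[10:18]
        diff = (
            beta.loc[probes, sten].mean(axis=1)
            - beta.loc[probes, ninf].mean(axis=1)
        )
        assert diff.mean() == pytest.approx(0.2, abs=0.04)
        # off-target probes are untouched
        off = man["probe_id"].iloc[25:45]
        off_diff = (
            beta.loc[off, sten].mean(axis=1) - beta.loc[off, ninf].mean(axis=1)
        )
        assert np.abs(off_diff.mean()) < 0.03

    def test_effect_out_of_bounds_rejected(self, small_manifest, study_sheet):
        n_chr1 = (small_manifest.chrom == "chr1").sum()
        eff = [RegionEffect("chr1", n_chr1 - 2, 8, 0.1, "STEN")]
        with pytest.raises(ValueError, match="bounds"):
            simulate_methylation(small_manifest, study_sheet, eff, seed=0)

    def test_overlapping_effects_rejected(self, small_manifest, study_sheet):
        eff = [
            RegionEffect("chr1", 5, 4, 0.1, "STEN"),
            RegionEffect("chr1", 7, 3, 0.1, "INF"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            simulate_methylation(small_manifest, study_sheet, eff, seed=0)

    def test_chry_tracks_sex(self, small_manifest, study_sheet):
        beta = simulate_methylation(small_manifest, study_sheet, [], seed=5)
        chry = small_manifest.loc[small_manifest.chrom == "chrY", "probe_id"]
        meth = study_sheet[study_sheet["assay"].isin(["methylation", "both"])]
        for _, row in meth.iterrows():
            vals = beta.loc[chry, row["sample_id"]]
            if row["sex_true"] == "F":
                assert vals.max() < 0.1
            else:
                assert vals.max() > 0.3


class TestCounts:
    def test_poisson_limit(self, small_genes):
        design = [GroupDesign("NINF", n_expr=1000, n_patients=1000)]
        sheet = generate_cohort(design, seed=6)
        base = CountBaseline(gene_means=np.full(len(small_genes), 50.0),
                             dispersion=1e-9)
        counts = simulate_counts(
            small_genes, sheet, [], base, size_factor_spread=0.0, seed=7
        )
        auto = small_genes.loc[small_genes.chrom != "chrY", "gene_id"]
        vals = counts.loc[auto].to_numpy()
        ratio = vals.var(axis=1, ddof=1) / vals.mean(axis=1)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.15)

    def test_lfc_doubles_group_mean(self, small_genes):
        design = [
            GroupDesign("STEN", n_expr=60, n_patients=60),
            GroupDesign("NINF", n_expr=60, n_patients=60),
        ]
        sheet = generate_cohort(design, seed=8)
        gene = small_genes.loc[small_genes.chrom == "chr1", "gene_id"].iloc[0]
        base = CountBaseline(gene_means=np.full(len(small_genes), 500.0),
                             dispersion=0.05)
        counts = simulate_counts(
            small_genes, sheet, [GeneEffect(gene, 1.0, "STEN")], base,
            size_factor_spread=0.0, seed=9,
        )
        sten = sheet.loc[sheet.group == "STEN", "sample_id"]
        ninf = sheet.loc[sheet.group == "NINF", "sample_id"]
        ratio = counts.loc[gene, sten].mean() / counts.loc[gene, ninf].mean()
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_zero_mean_gives_zero_row(self, small_genes):
        sheet = generate_cohort([GroupDesign("NINF", n_expr=5, n_patients=5)], seed=0)
        means = np.full(len(small_genes), 100.0)
        means[0] = 0.0
        counts = simulate_counts(
            small_genes, sheet, [], CountBaseline(gene_means=means), seed=1
        )
        assert (counts.iloc[0] == 0).all()

    def test_nonnegative_integers(self, small_genes, study_sheet):
        counts = simulate_counts(small_genes, study_sheet, [], seed=2)
        assert counts.to_numpy().min() >= 0
        assert np.issubdtype(counts.to_numpy().dtype, np.integer)

    def test_unknown_effect_gene_rejected(self, small_genes, study_sheet):
        with pytest.raises(ValueError):
            simulate_counts(
                small_genes, study_sheet, [GeneEffect("NOPE", 1.0, "STEN")], seed=0
            )


class TestCoupling:
    def _setup(self, n_shared, seed):
        man = generate_manifest(100, {"chr1": 100_000}, seed=seed)
        genes = synthetic.generate_gene_model(10, {"chr1": 100_000}, seed=seed)
        design = [GroupDesign(
            "NINF", n_meth=n_shared, n_expr=n_shared, n_shared=n_shared,
            n_patients=n_shared,
        )]
        sheet = generate_cohort(design, seed=seed)
        beta = simulate_methylation(man, sheet, [], seed=seed + 1)
        counts = simulate_counts(genes, sheet, [], seed=seed + 2)
        return man, genes, sheet, beta, counts

    def test_empty_couplings_identity(self):
        man, genes, sheet, beta, counts = self._setup(5, 10)
        b2, c2 = couple_eqtm(beta, counts, [], man, seed=0)
        pd.testing.assert_frame_equal(b2, beta)
        pd.testing.assert_frame_equal(c2, counts)

    def test_perfect_negative_coupling(self):
        man, genes, sheet, beta, counts = self._setup(12, 20)
        # constant baseline on both sides: the injected latent is the only
        # source of variation, so r = -1 up to count rounding
        beta.loc[:, :] = 0.5
        counts.loc[:, :] = 100_000
        cp = Coupling("chr1", 3, 4, genes["gene_id"].iloc[0], -1.0)
        b2, c2 = couple_eqtm(beta, counts, [cp], man, seed=21)
        probes = man["probe_id"].iloc[3:7]
        x = b2.loc[probes].mean(axis=0)
        y = np.log2(c2.loc[genes["gene_id"].iloc[0]] + 1)
        r = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-5)

    def test_target_r_realised_at_large_n(self):
        man, genes, sheet, beta, counts = self._setup(200, 30)
        cp = Coupling("chr1", 5, 6, genes["gene_id"].iloc[1], -0.8)
        b2, c2 = couple_eqtm(beta, counts, [cp], man, seed=31)
        probes = man["probe_id"].iloc[5:11]
        x = b2.loc[probes].mean(axis=0)
        y = np.log2(c2.loc[genes["gene_id"].iloc[1]] + 1)
        r = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(-0.8, abs=0.1)

    def test_unknown_gene_rejected(self):
        man, genes, sheet, beta, counts = self._setup(5, 40)
        with pytest.raises(ValueError):
            couple_eqtm(beta, counts, [Coupling("chr1", 0, 3, "NOPE", 0.5)], man)

    def test_invalid_target_r_rejected(self):
        with pytest.raises(ValueError):
            Coupling("chr1", 0, 3, "G", 1.5)
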