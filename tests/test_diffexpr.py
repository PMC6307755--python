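"""CPM filtering, size factors, and the negative-binomial Wald test."""

import warnings

import numpy as np
import pandas as pd
import pytest

from eqtmkit import diffexpr, synthetic
from eqtmkit.diffexpr import (
    compute_cpm,
    estimate_size_factors,
    filter_low_expression,
    fit_degs,
    log_expression,
)
from eqtmkit.synthetic import CountBaseline, GeneEffect, GroupDesign


def cmat(vals, genes=None):
    vals = np.atleast_2d(np.asarray(vals))
    genes = genes or [f"g{i}" for i in range(vals.shape[0])]
    return pd.DataFrame(
        vals, index=genes, columns=[f"s{j}" for j in range(vals.shape[1])]
    )


class TestCpm:
    def test_known_value(self):
        counts = cmat(np.concatenate([[100], np.full(999, 1000)])[:, None] * [1, 1])
        counts.iloc[:, :] = counts.to_numpy()
        lib = counts.sum(axis=0)
        cpm = compute_cpm(counts)
        assert cpm.iloc[0, 0] == pytest.approx(100 / lib.iloc[0] * 1e6)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        counts = cmat(rng.integers(0, 500, size=(200, 6)))
        np.testing.assert_allclose(compute_cpm(counts).sum(axis=0), 1e6, rtol=1e-12)

    def test_zero_gene_row(self):
        counts = cmat([[0, 0], [10, 20]])
        assert (compute_cpm(counts).iloc[0] == 0).all()

    def test_zero_library_named(self):
        counts = cmat([[0, 5], [0, 5]])
        with pytest.raises(ValueError, match="s0"):
            compute_cpm(counts)


class TestFilter:
    def _counts_with_low_gene(self, n_low):
        """21 samples; gene 0 below 1 CPM in exactly n_low samples."""
        rng = np.random.default_rng(1)
        vals = rng.integers(500, 1500, size=(1000, 21))
        lib = vals.sum(axis=0)
        # CPM 1 needs count ~ lib/1e6 ~ 1; set low samples to 0, others high
        vals[0] = 50
        vals[0, :n_low] = 0
        return cmat(vals)

    def test_gene_below_in_twelve_of_21_removed(self):
        counts = self._counts_with_low_gene(12)
        out = filter_low_expression(counts, cpm_threshold=1.0, max_below=11)
        assert "g0" not in out.index

    def test_gene_below_in_exactly_max_below_retained(self):
        counts = self._counts_with_low_gene(11)
        out = filter_low_expression(counts, cpm_threshold=1.0, max_below=11)
        assert "g0" in out.index

    def test_zero_threshold_keeps_everything(self):
        counts = self._counts_with_low_gene(21)
        out = filter_low_expression(counts, cpm_threshold=0.0, max_below=0)
        assert len(out) == len(counts)

    def test_default_max_below_is_half(self):
        counts = self._counts_with_low_gene(10)  # 10 <= floor(21/2)
        assert "g0" in filter_low_expression(counts).index
        counts = self._counts_with_low_gene(11)  # 11 > floor(21/2) = 10
        assert "g0" not in filter_low_expression(counts).index


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(2)
        col = rng.integers(1, 1000, size=300)
        counts = cmat(np.column_stack([col] * 5))
        np.testing.assert_allclose(estimate_size_factors(counts), 1.0, rtol=1e-12)

    def test_scaling_equivariance_of_factor_ratios(self):
        rng = np.random.default_rng(3)
        counts = cmat(rng.integers(1, 2000, size=(400, 8)))
        base = estimate_size_factors(counts)
        c = 3.0
        scaled = counts.copy()
        scaled["s2"] = np.rint(scaled["s2"] * c)
        # exact property of median-of-ratios: factor ratios scale by c
        new = estimate_size_factors(cmat(scaled.to_numpy()))
        ratio_old = base["s2"] / base["s0"]
        ratio_new = new.iloc[2] / new.iloc[0]
        assert ratio_new / ratio_old == pytest.approx(c, rel=0.02)

    def test_reciprocal_ratio_example(self):
        # two samples with per-gene counts (2, 8) and (8, 2): by symmetry
        # both factors are equal, i.e. 1 after fixing the overall scale
        counts = cmat([[2, 8], [8, 2]])
        f = estimate_size_factors(counts, normalize=True)
        np.testing.assert_allclose(f, [1.0, 1.0], rtol=1e-12)

    def test_all_zero_gene_requires_prefilter(self):
        counts = cmat([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="filter"):
            estimate_size_factors(counts)


def _expr_study(seed, n_genes=300, dispersion=0.1, effects=()):
    genes = synthetic.generate_gene_model(n_genes, {"chr1": 10**6}, seed=seed)
    design = [
        GroupDesign("STEN", n_expr=10, n_patients=10),
        GroupDesign("NINF", n_expr=10, n_patients=10),
    ]
    sheet = synthetic.generate_cohort(design, seed=seed + 1)
    counts = synthetic.simulate_counts(
        genes, sheet, list(effects), CountBaseline(dispersion=dispersion),
        seed=seed + 2,
    )
    return genes, sheet, counts


class TestFitDegs:
    def test_wald_statistic_identity_and_floor(self):
        genes, sheet, counts = _expr_study(seed=50, n_genes=120)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = fit_degs(filter_low_expression(counts), sheet, ("STEN", "NINF"), ())
        ok = out[out["converged"]]
        np.testing.assert_allclose(
            ok["wald_stat"], ok["log2_fold_change"] / ok["lfc_se"], rtol=1e-10
        )
        assert (ok["alpha"] >= diffexpr.DISPERSION_FLOOR).all()
        assert (ok["p_adj"] >= ok["p"] - 1e-15).all()

    def test_planted_lfc_recovered(self):
        effects = [GeneEffect(f"GENE{i:05d}", 1.0, "STEN") for i in range(25)]
        genes, sheet, counts = _expr_study(seed=60, effects=effects)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = fit_degs(filter_low_expression(counts), sheet, ("STEN", "NINF"), ())
        planted = out[out["gene_id"].isin([e.gene_id for e in effects])]
        assert planted["log2_fold_change"].mean() == pytest.approx(1.0, abs=0.2)

    def test_constant_gene_is_null(self):
        rng = np.random.default_rng(70)
        vals = rng.integers(100, 1000, size=(80, 20))
        vals[0] = 500  # identical in every sample
        genes, sheet, _ = _expr_study(seed=71, n_genes=80)
        counts = pd.DataFrame(
            vals, index=genes["gene_id"], columns=sheet["sample_id"]
        )
        unit = pd.Series(1.0, index=counts.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = fit_degs(counts, sheet, ("STEN", "NINF"), (), size_factors=unit)
        rec = out.iloc[0]
        assert rec["log2_fold_change"] == pytest.approx(0.0, abs=1e-6)
        assert rec["p"] > 0.99

    def test_power_monotone_in_lfc(self):
        power = []
        for lfc in (0.5, 1.0, 2.0):
            effects = [GeneEffect(f"GENE{i:05d}", lfc, "STEN") for i in range(40)]
            genes, sheet, counts = _expr_study(seed=80, n_genes=200, effects=effects)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = fit_degs(
                    filter_low_expression(counts), sheet, ("STEN", "NINF"), ()
                )
            planted = out[out["gene_id"].isin([e.gene_id for e in effects])]
            power.append((planted["p"] < 0.05).mean())
        assert power[0] < power[1] < power[2] or (
            power[0] <= power[1] and power[2] == 1.0
        )

    def test_agrees_with_pydeseq2_on_small_dataset(self):
        """Independent cross-check of the NB Wald machinery."""
        import anndata
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        genes, sheet, counts = _expr_study(seed=90, n_genes=80)
        filtered = filter_low_expression(counts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ours = fit_degs(filtered, sheet, ("STEN", "NINF"), ())
            meta = sheet.set_index("sample_id").loc[filtered.columns, ["group"]]
            adata = anndata.AnnData(
                X=filtered.T.to_numpy().astype(np.float32), obs=meta
            )
            adata.obs_names = filtered.columns
            adata.var_names = filtered.index
            dds = DeseqDataSet(adata=adata, design="~group", quiet=True)
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["group", "STEN", "NINF"], quiet=True)
            ds.summary()
        ref = ds.results_df["log2FoldChange"]
        merged = ours.set_index("gene_id").join(ref.rename("ref_lfc"))
        ok = merged.dropna(subset=["log2_fold_change", "ref_lfc"])
        r = np.corrcoef(ok["log2_fold_change"], ok["ref_lfc"])[0, 1]
        assert r > 0.95
        assert np.mean(np.abs(ok["log2_fold_change"] - ok["ref_lfc"])) < 0.25


class TestLogExpression:
    def test_default_log2_with_pseudocount(self):
        counts = cmat([[3, 3], [3, 3]])
        out = log_expression(counts, size_factors=pd.Series([1.0, 1.0], index=["s0", "s1"]))
        np.testing.assert_allclose(out.to_numpy(), 2.0)

    def test_base_configurable(self):
        counts = cmat([[np.e - 1]])
        out = log_expression(
            counts, size_factors=pd.Series([1.0], index=["s0"]), base=np.e
        )
        assert out.iloc[0, 0] == pytest.approx(1.0)
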