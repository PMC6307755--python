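"""Stage-wise pipeline: simulate -> screen -> dmp -> dmr -> de -> dmeg ->
eqtm -> impute.

Each stage writes its outputs (with provenance headers) before the next
one runs, so a failure halts with the stage name while earlier results
persist. All randomness derives from the single configured seed via a
seed sequence, making the whole bundle byte-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, diffmeth, impute, integrate, io, preprocess, synthetic
from .config import RunConfig

_DEFAULT_LAYOUT = {
    "chr1": 2_400_000,
    "chr2": 2_000_000,
    "chr3": 1_600_000,
    "chr4": 1_200_000,
    "chr5": 1_000_000,
    "chrX": 600_000,
    "chrY": 150_000,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class StudyData:
    """A simulated (or loaded) study bundle with optional ground truth."""

    manifest: pd.DataFrame
    genes: pd.DataFrame
    sheet: pd.DataFrame
    beta: pd.DataFrame
    counts: pd.DataFrame
    region_effects: list = field(default_factory=list)
    gene_effects: list = field(default_factory=list)
    couplings: list = field(default_factory=list)


def _derived_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def choose_planted_regions(
    manifest: pd.DataFrame,
    n_regions: int,
    n_cpgs: int,
    rng: np.random.Generator,
    min_separation_bp: int = 20_000,
    target_group: str = "STEN",
    delta_beta: float = 0.15,
) -> list[synthetic.RegionEffect]:
    """Pick non-overlapping unflagged autosomal probe runs to plant DMRs in.

    Runs are chosen among stretches of probes that survive standard
    filtering (no SNP/cross-reactive flag, autosomal), separated by at
    least ``min_separation_bp`` so adjacent planted regions cannot merge
    during region calling. Alternate regions flip the sign of
    ``delta_beta`` so both hyper- and hypomethylation are exercised.
    """
    effects: list[synthetic.RegionEffect] = []
    occupied: list[tuple[str, int, int]] = []
    autosomes = [
        c for c in manifest["chrom"].unique()
        if c not in preprocess.SEX_CHROMOSOMES
    ]
    candidates = []
    for chrom in autosomes:
        sub = manifest[manifest["chrom"] == chrom].reset_index(drop=True)
        ok = ~(sub["snp_flag"] | sub["crossreactive_flag"]).to_numpy()
        pos = sub["pos"].to_numpy()
        for start in range(len(sub) - n_cpgs + 1):
            if ok[start : start + n_cpgs].all():
                candidates.append((chrom, start, pos[start], pos[start + n_cpgs - 1]))
    rng.shuffle(candidates)
    for chrom, start, lo, hi in candidates:
        if len(effects) == n_regions:
            break
        clash = any(
            c == chrom and lo - min_separation_bp <= h and hi + min_separation_bp >= l
            for c, l, h in occupied
        )
        if clash:
            continue
        sign = 1.0 if len(effects) % 2 == 0 else -1.0
        effects.append(
            synthetic.RegionEffect(
                chrom=chrom,
                start_probe_index=start,
                n_cpgs=n_cpgs,
                delta_beta=sign * delta_beta,
                target_group=target_group,
            )
        )
        occupied.append((chrom, lo, hi))
    if len(effects) < n_regions:
        raise ValueError(
            f"could only place {len(effects)} of {n_regions} regions; "
            "increase the manifest size"
        )
    return effects


def simulate_study(config: RunConfig) -> StudyData:
    """Generate the study-shaped synthetic cohort described by the config.

    Plants DMRs (STEN vs NINF), fold changes on the genes nearest the
    planted regions (so DMEG pairs exist) plus extra DEGs, and couples
    the first ``n_couplings`` region-gene pairs at the configured target
    correlation.
    """
    seeds = _derived_seeds(config.seed, 6)
    manifest = synthetic.generate_manifest(
        config.n_probes, _DEFAULT_LAYOUT, seed=seeds[0]
    )
    genes = synthetic.generate_gene_model(
        config.n_genes, _DEFAULT_LAYOUT, seed=seeds[1]
    )
    sheet = synthetic.generate_cohort(seed=seeds[2])
    rng = np.random.default_rng(seeds[3])

    region_effects = choose_planted_regions(
        manifest,
        config.n_planted_dmrs,
        config.planted_n_cpgs,
        rng,
        target_group=config.contrast[0],
        delta_beta=config.planted_delta_beta,
    )
    # annotate planted regions to their nearest gene so that planting a
    # matching expression effect yields true DMEGs
    truth = synthetic.planted_region_table(region_effects, manifest)
    annotated = diffmeth.annotate_nearest_tss(truth, genes)
    nearest = list(annotated["gene_id"])
    gene_effects = [
        synthetic.GeneEffect(g, -config.planted_lfc, config.contrast[0])
        for g in dict.fromkeys(nearest)
        if g is not None
    ]
    other = [g for g in genes["gene_id"] if g not in set(nearest)]
    extra = rng.choice(
        other, size=max(config.n_planted_degs - len(gene_effects), 0), replace=False
    )
    for i, g in enumerate(extra):
        sign = 1.0 if i % 2 == 0 else -1.0
        gene_effects.append(
            synthetic.GeneEffect(g, sign * config.planted_lfc, config.contrast[0])
        )
    couplings = [
        synthetic.Coupling(
            chrom=eff.chrom,
            start_probe_index=eff.start_probe_index,
            n_cpgs=eff.n_cpgs,
            gene_id=gene,
            target_r=config.coupling_target_r,
        )
        for eff, gene in list(zip(region_effects, nearest))[: config.n_couplings]
        if gene is not None
    ]

    beta = synthetic.simulate_methylation(
        manifest, sheet, region_effects, seed=seeds[4]
    )
    counts = synthetic.simulate_counts(genes, sheet, gene_effects, seed=seeds[5])
    beta, counts = synthetic.couple_eqtm(
        beta, counts, couplings, manifest, seed=seeds[3]
    )
    return StudyData(
        manifest, genes, sheet, beta, counts,
        region_effects, gene_effects, couplings,
    )


def load_study(config: RunConfig) -> StudyData:
    sheet = io.read_sample_sheet(config.sample_sheet_path)
    return StudyData(
        manifest=io.read_manifest(config.manifest_path),
        genes=io.read_gene_model(config.gene_model_path),
        sheet=sheet,
        beta=io.read_beta_matrix(config.beta_path, sheet=sheet),
        counts=io.read_count_matrix(config.counts_path, sheet=sheet),
    )


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute all stages; returns the result bundle as a dict of tables."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    results: dict = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # halt with the stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    # --- simulate / load -------------------------------------------------
    @stage("simulate")
    def _():
        data = simulate_study(config) if config.simulate else load_study(config)
        results["data"] = data
        if config.simulate:
            io.write_manifest(data.manifest, outdir / "manifest.tsv", meta)
            io.write_gene_model(data.genes, outdir / "gene_model.tsv", meta)
            io.write_sample_sheet(data.sheet, outdir / "sample_sheet.csv", meta)
            io.write_matrix(data.beta, outdir / "beta.tsv", meta)
            io.write_matrix(data.counts, outdir / "counts.tsv", meta)
            truth = synthetic.planted_region_table(data.region_effects, data.manifest)
            io.write_table(truth, outdir / "truth_regions.tsv", meta)
            io.write_table(
                pd.DataFrame(
                    [
                        {"gene_id": e.gene_id, "log2_fold_change": e.log2_fold_change,
                         "target_group": e.target_group}
                        for e in data.gene_effects
                    ]
                ),
                outdir / "truth_genes.tsv",
                meta,
            )

    data: StudyData = results["data"]

    # --- preprocess + covariate screen ----------------------------------
    @stage("screen")
    def _():
        filtered, report = preprocess.filter_probes(data.manifest)
        results["manifest_filtered"] = filtered
        results["filter_report"] = report
        beta_f = data.beta.loc[[p for p in filtered["probe_id"] if p in data.beta.index]]
        results["beta_filtered"] = beta_f
        results["m_filtered"] = preprocess.beta_to_m(beta_f, config.epsilon)
        meth_sheet = data.sheet[data.sheet["assay"].isin(["methylation", "both"])]
        screen_m = preprocess.pc_covariate_screen(
            results["m_filtered"], meth_sheet, config.n_components
        )
        io.write_table(screen_m, outdir / "screen_methylation.tsv", meta)
        expr_sheet = data.sheet[data.sheet["assay"].isin(["expression", "both"])]
        loge = diffexpr.log_expression(
            data.counts, base=config.log_base
        )
        screen_e = preprocess.pc_covariate_screen(
            loge, expr_sheet, config.n_components
        )
        io.write_table(screen_e, outdir / "screen_expression.tsv", meta)
        results["screen_methylation"] = screen_m
        results["screen_expression"] = screen_e

    # --- differential methylation ---------------------------------------
    @stage("dmp")
    def _():
        dmps = diffmeth.fit_dmps(
            results["m_filtered"],
            data.sheet,
            config.contrast,
            config.covariates,
            blocking=config.blocking,
        )
        results["dmps"] = dmps
        io.write_table(dmps, outdir / "dmps.tsv", meta)

    @stage("dmr")
    def _():
        dmrs = diffmeth.call_dmrs(
            results["dmps"],
            results["manifest_filtered"],
            max_gap_bp=config.max_gap_bp,
            seed_alpha=config.seed_alpha,
            min_cpgs=config.min_cpgs,
        )
        dmrs = diffmeth.annotate_nearest_tss(dmrs, data.genes)
        results["dmrs"] = dmrs
        io.write_dmrs(dmrs, outdir / "dmrs.tsv", meta)
        io.write_region_bed(dmrs, outdir / "dmrs.bed")

    # --- differential expression ----------------------------------------
    @stage("de")
    def _():
        filtered = diffexpr.filter_low_expression(
            data.counts, config.cpm_threshold, config.max_below
        )
        sf = diffexpr.estimate_size_factors(filtered)
        degs = diffexpr.fit_degs(
            filtered, data.sheet, config.contrast, config.covariates,
            size_factors=sf,
        )
        results["counts_filtered"] = filtered
        results["size_factors"] = sf
        results["degs"] = degs
        results["log_expr"] = diffexpr.log_expression(
            filtered, sf, base=config.log_base
        )
        io.write_table(degs, outdir / "degs.tsv", meta)

    # --- integration -----------------------------------------------------
    @stage("dmeg")
    def _():
        dmrs_sig = results["dmrs"][results["dmrs"]["p_adj"] < config.alpha]
        degs = results["degs"]
        degs_sig = degs[degs["p_adj"] < config.alpha]
        results["dmegs"] = integrate.find_dmegs(dmrs_sig, degs_sig)
        io.write_table(results["dmegs"], outdir / "dmegs.tsv", meta)

    @stage("eqtm")
    def _():
        table = integrate.eqtm_table(
            results["dmegs"],
            results["beta_filtered"],
            results["log_expr"],
            results["manifest_filtered"],
            gene_model=data.genes,
            B_bootstrap=config.B_bootstrap,
            B_null=config.B_null,
            seed=_derived_seeds(config.seed, 8)[6],
        )
        results["eqtm"] = table
        io.write_eqtm_report(table, outdir / "eqtm.tsv", meta)

    # --- metadata imputation ---------------------------------------------
    @stage("impute")
    def _():
        rows = None
        try:
            sex_meth = impute.infer_sex_from_methylation(data.beta, data.manifest)
            rows = sex_meth.rename(columns={"sex": "sex_meth"})
        except ValueError as exc:
            warnings.warn(f"methylation sex call skipped: {exc}", stacklevel=2)
        chry_genes = list(
            data.genes.loc[data.genes["chrom"].isin(["chrY", "Y"]), "gene_id"]
        )
        if chry_genes:
            sex_expr = impute.infer_sex_from_expression(data.counts, chry_genes)
            sex_expr = sex_expr.rename(columns={"sex": "sex_expr"})
            rows = (
                sex_expr
                if rows is None
                else rows.merge(sex_expr, on="sample_id", how="outer")
            )
        if config.clock_path:
            clock = impute.read_clock(config.clock_path)
            ages, _ = impute.predict_age(data.beta, clock)
            age_tab = ages.rename("age_estimate").reset_index(names="sample_id")
            rows = (
                age_tab if rows is None
                else rows.merge(age_tab, on="sample_id", how="outer")
            )
        results["imputation"] = rows if rows is not None else pd.DataFrame()
        io.write_table(results["imputation"], outdir / "imputation.tsv", meta)

    return results
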