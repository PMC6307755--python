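"""The eQTM core: DMEG intersection, correlations, bootstrap, matched nulls.

A DMEG is a gene that is both differentially expressed and annotated to
a differentially methylated region. For each DMR-gene pair the region's
mean Beta per sample is Pearson-correlated with the gene's log
expression over the samples assayed on both platforms; a percentile
bootstrap gives the 95% confidence interval, and significance comes
from a permutation null built from random probe runs with the same
number of CpGs as the observed region ("null-DMRs"), with the add-one
rule p = (1 + #{|r_null| >= |r_obs|}) / (B + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NullDistribution:
    """Null correlations from CpG-count-matched random regions."""

    r_null: np.ndarray
    n_cpgs: int
    seed: int | None

    def __post_init__(self):
        self.r_null = np.asarray(self.r_null, dtype=float)
        if np.any(np.abs(self.r_null) > 1 + 1e-12):
            raise ValueError("null correlations must lie in [-1, 1]")


def find_dmegs(dmrs: pd.DataFrame, degs: pd.DataFrame) -> pd.DataFrame:
    """Pair annotated DMRs with significant DEGs on the shared gene.

    ``dmrs`` must carry a ``gene_id`` annotation; ``degs`` is the table
    of significant genes. One row per DMR-gene pair (a gene with several
    DMRs appears once per region). The DE p-value is carried along.
    """
    if "gene_id" not in dmrs.columns:
        raise ValueError("DMRs must be annotated with gene_id first")
    sig = degs.set_index("gene_id")
    hits = dmrs[dmrs["gene_id"].isin(sig.index)].copy()
    if hits.empty:
        return hits.assign(p_de=pd.Series(dtype=float))
    hits["p_de"] = hits["gene_id"].map(sig["p"]).to_numpy()
    return hits.reset_index(drop=True)


def dmr_mean_beta(
    beta: pd.DataFrame,
    region: pd.Series | dict,
    manifest: pd.DataFrame | None = None,
) -> pd.Series:
    """Unweighted mean Beta over the region's member probes, per sample.

    Member probes come from the region's ``probe_ids`` field when
    present, otherwise from the manifest probes falling inside
    [start, end] on the region's chromosome.
    """
    if "probe_ids" in region and isinstance(region["probe_ids"], str) and region["probe_ids"]:
        probes = region["probe_ids"].split(",")
    elif manifest is not None:
        sel = (
            (manifest["chrom"] == region["chrom"])
            & (manifest["pos"] >= region["start"])
            & (manifest["pos"] <= region["end"])
        )
        probes = list(manifest.loc[sel, "probe_id"])
    else:
        raise ValueError("region lacks probe_ids and no manifest was given")
    present = [p for p in probes if p in beta.index]
    if not present:
        raise ValueError("none of the region's probes are in the Beta matrix")
    return beta.loc[present].mean(axis=0)


def eqtm_correlate(
    mean_beta: pd.Series, log_expr: pd.Series, shared_samples: list[str]
) -> float:
    """Pearson correlation over exactly the shared samples."""
    if len(shared_samples) < 3:
        raise ValueError("need >= 3 shared samples for a correlation")
    x = mean_beta.loc[shared_samples].to_numpy(dtype=float)
    y = log_expr.loc[shared_samples].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance on one side")
    return float(stats.pearsonr(x, y)[0])


def _pearson_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r for paired 2-d arrays; 0-variance rows give NaN."""
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def bootstrap_ci(
    mean_beta: pd.Series,
    log_expr: pd.Series,
    shared_samples: list[str] | None = None,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float, int]:
    """Percentile bootstrap CI for the methylation-expression correlation.

    Samples are resampled in pairs with replacement; degenerate
    resamples (zero variance on either side) are redrawn, and more than
    10*B redraws raises (the data are then nearly constant). Returns
    (ci_low, ci_high, n_redrawn).
    """
    if shared_samples is None:
        shared_samples = [s for s in mean_beta.index if s in log_expr.index]
    if len(shared_samples) < 3:
        raise ValueError("need >= 3 shared samples for a bootstrap CI")
    x = mean_beta.loc[shared_samples].to_numpy(dtype=float)
    y = log_expr.loc[shared_samples].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance on one side")
    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(B, n))
    r = _pearson_rows(x[idx], y[idx])
    n_redrawn = 0
    bad = np.flatnonzero(np.isnan(r))
    while bad.size:
        n_redrawn += bad.size
        if n_redrawn > 10 * B:
            raise ValueError(
                "bootstrap exhausted redraws; data are nearly constant"
            )
        idx = rng.integers(0, n, size=(bad.size, n))
        r[bad] = _pearson_rows(x[idx], y[idx])
        bad = bad[np.isnan(r[bad])]
    lo = (1.0 - level) / 2.0
    ci_low, ci_high = np.quantile(r, [lo, 1.0 - lo])
    return float(ci_low), float(ci_high), n_redrawn


def _candidate_runs(
    manifest: pd.DataFrame, beta_index: pd.Index, n_cpgs: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """All runs of exactly n_cpgs consecutive manifest probes present in beta.

    Returns (run table of (chrom index, start offset), per-chromosome
    probe-row arrays into the Beta matrix).
    """
    runs = []
    chrom_rows: list[np.ndarray] = []
    row_of = {p: i for i, p in enumerate(beta_index)}
    for ci, (_, sub) in enumerate(manifest.groupby("chrom", sort=False)):
        probes = [p for p in sub["probe_id"] if p in row_of]
        rows = np.array([row_of[p] for p in probes], dtype=int)
        chrom_rows.append(rows)
        for start in range(len(rows) - n_cpgs + 1):
            runs.append((ci, start))
    return np.array(runs, dtype=int), chrom_rows


def null_dmr_pvalue(
    r_obs: float,
    n_cpgs: int,
    beta: pd.DataFrame,
    log_expr: pd.Series,
    manifest: pd.DataFrame,
    B: int = 10_000,
    seed: int | None = None,
    exclude_probe_ids: set[str] | None = None,
) -> tuple[float, NullDistribution]:
    """Permutation p-value against CpG-count-matched null regions.

    Null-DMRs are runs of exactly ``n_cpgs`` consecutive probes in the
    (filtered) manifest, drawn uniformly — without replacement when the
    candidate pool is at least B, with replacement otherwise. A run
    identical to the observed region (given via ``exclude_probe_ids``)
    is excluded from the pool. Each null region's mean Beta is
    correlated with the same expression vector; the two-sided p-value is
    (1 + #{|r_null| >= |r_obs|}) / (B + 1).
    """
    shared = [s for s in beta.columns if s in log_expr.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    y = log_expr.loc[shared].to_numpy(dtype=float)
    bvals = beta[shared].to_numpy(dtype=float)
    runs, chrom_rows = _candidate_runs(manifest, beta.index, n_cpgs)
    if runs.size == 0:
        raise ValueError(
            f"no chromosome holds {n_cpgs} consecutive probes"
        )
    if exclude_probe_ids:
        keep = []
        for k, (ci, start) in enumerate(runs):
            pids = {beta.index[r] for r in chrom_rows[ci][start : start + n_cpgs]}
            keep.append(pids != set(exclude_probe_ids))
        runs = runs[np.array(keep, dtype=bool)]
        if runs.size == 0:
            raise ValueError("excluding the observed region emptied the pool")
    rng = np.random.default_rng(seed)
    n_pool = len(runs)
    chosen = (
        rng.choice(n_pool, size=B, replace=False)
        if n_pool >= B
        else rng.integers(0, n_pool, size=B)
    )
    # sliding-window means per chromosome, then gather the chosen runs
    r_null = np.empty(B)
    window_means: dict[int, np.ndarray] = {}
    for ci in np.unique(runs[chosen, 0]):
        rows = chrom_rows[ci]
        c = np.cumsum(
            np.vstack([np.zeros((1, len(shared))), bvals[rows]]), axis=0
        )
        window_means[ci] = (c[n_cpgs:] - c[:-n_cpgs]) / n_cpgs
    for j, k in enumerate(chosen):
        ci, start = runs[k]
        x = window_means[ci][start]
        r_null[j] = _pearson_rows(x[None, :], y[None, :])[0]
    r_null = np.nan_to_num(r_null, nan=0.0)
    p = (1.0 + np.sum(np.abs(r_null) >= abs(r_obs) - 1e-12)) / (B + 1.0)
    return float(p), NullDistribution(r_null, n_cpgs, seed)


def coexpression_matrix(
    log_expr: pd.DataFrame,
    gene_set: list[str],
    threshold: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations among a gene set, with |r| flags.

    Constant genes are dropped with a warning. Returns (correlation
    matrix with unit diagonal, table of flagged pairs with |r| >
    threshold).
    """
    if log_expr.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    present = [g for g in gene_set if g in log_expr.index]
    absent = sorted(set(gene_set) - set(present))
    if absent:
        warnings.warn(f"genes absent from the matrix: {absent}", stacklevel=2)
    sub = log_expr.loc[present]
    sd = sub.std(axis=1)
    constant = list(sd.index[sd == 0])
    if constant:
        warnings.warn(
            f"constant genes dropped from co-expression: {constant}",
            stacklevel=2,
        )
        sub = sub.drop(index=constant)
    corr = sub.T.corr(method="pearson")
    np.fill_diagonal(corr.to_numpy(), 1.0)
    pairs = []
    genes = list(corr.index)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = corr.iloc[i, j]
            if abs(r) > threshold:
                pairs.append({"gene_a": genes[i], "gene_b": genes[j], "r": float(r)})
    return corr, pd.DataFrame(pairs, columns=["gene_a", "gene_b", "r"])


def eqtm_table(
    dmegs: pd.DataFrame,
    beta: pd.DataFrame,
    log_expr: pd.DataFrame,
    manifest: pd.DataFrame,
    gene_model: pd.DataFrame | None = None,
    B_bootstrap: int = 10_000,
    B_null: int = 10_000,
    seed: int = 0,
    exclude_observed: bool = True,
) -> pd.DataFrame:
    """Full eQTM analysis of DMEG pairs; one record per DMR-gene pair.

    Columns mirror the headline report: coordinates, n_cpgs, gene_id
    (plus Ensembl/Entrez ids when the gene model carries them), r,
    ci_low, ci_high, p_corr, p_de, p_dm. Derived seeds below 2^31 keep
    every pair's bootstrap and null reproducible.
    """
    shared = [s for s in beta.columns if s in log_expr.columns]
    rows = []
    ss = np.random.SeedSequence(seed)
    ens = ent = None
    if gene_model is not None and "ensembl" in gene_model.columns:
        ens = gene_model.set_index("gene_id")["ensembl"]
    if gene_model is not None and "entrez" in gene_model.columns:
        ent = gene_model.set_index("gene_id")["entrez"]
    for _, pair in dmegs.iterrows():
        child = ss.spawn(1)[0]
        s_boot, s_null = (int(x) % (2**31) for x in child.generate_state(2))
        mb = dmr_mean_beta(beta, pair, manifest)
        ge = log_expr.loc[pair["gene_id"]]
        r = eqtm_correlate(mb, ge, shared)
        ci_low, ci_high, _ = bootstrap_ci(mb, ge, shared, B=B_bootstrap, seed=s_boot)
        if not ci_low <= r <= ci_high:
            warnings.warn(
                f"percentile CI excludes the point estimate for "
                f"{pair['gene_id']} (pathological resampling)",
                stacklevel=2,
            )
        excl = (
            set(str(pair.get("probe_ids", "")).split(","))
            if exclude_observed
            else None
        )
        p_corr, _ = null_dmr_pvalue(
            r,
            int(pair["n_cpgs"]),
            beta,
            ge,
            manifest,
            B=B_null,
            seed=s_null,
            exclude_probe_ids=excl,
        )
        rows.append(
            {
                "coordinates": f"{pair['chrom']}:{pair['start']}-{pair['end']}",
                "n_cpgs": int(pair["n_cpgs"]),
                "gene_id": pair["gene_id"],
                "ensembl": ens.get(pair["gene_id"], "") if ens is not None else "",
                "entrez": ent.get(pair["gene_id"], "") if ent is not None else "",
                "r": r,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "p_corr": p_corr,
                "p_de": float(pair.get("p_de", np.nan)),
                "p_dm": float(pair.get("p_adj", np.nan)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "coordinates", "n_cpgs", "gene_id", "ensembl", "entrez",
            "r", "ci_low", "ci_high", "p_corr", "p_de", "p_dm",
        ],
    )
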