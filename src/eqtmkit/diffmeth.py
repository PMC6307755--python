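"""Differential methylation: per-CpG models, region calling, TSS annotation.

Per-CpG differential methylation positions (DMPs) come from linear
models of M-values on group plus covariates, with optional patient
blocking through a pooled intra-patient residual correlation (GLS) and
empirical-Bayes moderation of residual variances. Regions (DMRs) are
maximal runs of nominally significant CpGs within a base-pair gap limit,
require at least 3 CpGs, and are scored by Stouffer combination of the
member CpGs' signed z-scores with Benjamini-Hochberg adjustment across
regions. Regions are annotated to the gene with the nearest
transcription start site.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, signed_z, squeeze_variances, stouffer_combine
from .design import DesignError, build_design
from .preprocess import m_to_beta

RHO_BOUNDS = (-0.3, 0.99)
MODERATION_MIN_PROBES = 50


def _pooled_patient_correlation(
    resid: np.ndarray, patients: np.ndarray, x: np.ndarray
) -> float | None:
    """Pooled intra-patient residual correlation, projection-corrected.

    OLS residuals are e = (I - H) y, so even independent errors show
    spurious cross-sample correlation of order -H_ij. Writing the error
    covariance as sigma^2 (I + rho * (B - I)) with B the same-patient
    indicator, the residual cross-product matrix has expectation
    sigma^2 (A + rho * A (B - I) A) with A = I - H; (sigma^2,
    sigma^2 * rho) are recovered by least squares on the probe-averaged
    cross-products, and the ratio gives a single pooled rho. Returns
    None when no patient contributes more than one sample.
    """
    n = resid.shape[1]
    b_off = np.zeros((n, n))
    for patient in pd.unique(patients):
        idx = np.flatnonzero(patients == patient)
        for a in idx:
            for b in idx:
                if a != b:
                    b_off[a, b] = 1.0
    if not b_off.any():
        return None
    h = x @ np.linalg.inv(x.T @ x) @ x.T
    a_mat = np.eye(n) - h
    c_obs = resid.T @ resid / resid.shape[0]
    m1 = a_mat
    m2 = a_mat @ b_off @ a_mat
    iu = np.triu_indices(n)
    design = np.column_stack([m1[iu], m2[iu]])
    coef, *_ = np.linalg.lstsq(design, c_obs[iu], rcond=None)
    if coef[0] <= 0:
        return None
    rho = float(coef[1] / coef[0])
    if not RHO_BOUNDS[0] < rho < RHO_BOUNDS[1]:
        clipped = float(np.clip(rho, RHO_BOUNDS[0] + 1e-6, RHO_BOUNDS[1]))
        warnings.warn(
            f"pooled intra-patient correlation {rho:.3f} outside "
            f"({RHO_BOUNDS[0]}, {RHO_BOUNDS[1]}); clipped to {clipped:.3f}",
            stacklevel=3,
        )
        rho = clipped
    return rho


def _block_whitener(patients: np.ndarray, rho: float) -> np.ndarray:
    """Inverse Cholesky factor of the block-equicorrelation matrix."""
    n = len(patients)
    v = np.eye(n)
    for patient in pd.unique(patients):
        idx = np.flatnonzero(patients == patient)
        for a in idx:
            for b in idx:
                if a != b:
                    v[a, b] = rho
    chol = np.linalg.cholesky(v)
    return np.linalg.inv(chol)


def fit_dmps(
    m: pd.DataFrame,
    sheet: pd.DataFrame,
    contrast: tuple[str, str],
    covariates: list[str] | tuple[str, ...] = (),
    blocking: str | None = "patient_id",
    moderate: bool = True,
) -> pd.DataFrame:
    """Fit per-CpG linear models of M on group + covariates.

    With ``blocking`` set to a sample-sheet column (normally
    ``patient_id``), a single pooled intra-patient residual correlation
    is estimated from an initial OLS pass and all probes are refit by
    GLS under the implied block-equicorrelation structure. Residual
    variances are shrunk by empirical-Bayes moderation (method of
    moments on log variances) when at least 50 probes are available;
    otherwise the ordinary t is used.

    Returns a DataFrame with columns probe_id, effect (adjusted M
    difference, contrast[0] minus contrast[1]), t, p, p_adj (BH), and
    delta_beta (unadjusted group mean Beta difference).
    """
    present = sheet[sheet["sample_id"].isin(m.columns)]
    x, names, sub = build_design(present, contrast, covariates)
    samples = list(sub["sample_id"])
    y = m[samples].to_numpy(dtype=float)  # probes x samples
    n, p = x.shape
    if n - p < 1:
        raise DesignError("no residual degrees of freedom")

    def _ols(xw: np.ndarray, yw: np.ndarray):
        xtx_inv = np.linalg.inv(xw.T @ xw)
        coef = yw @ xw @ xtx_inv  # probes x p
        resid = yw - coef @ xw.T
        s2 = (resid**2).sum(axis=1) / (n - p)
        return coef, resid, s2, xtx_inv

    coef, resid, s2, xtx_inv = _ols(x, y)
    rho = None
    if blocking is not None:
        patients = sub[blocking].to_numpy()
        rho = _pooled_patient_correlation(resid, patients, x)
        if rho is not None and abs(rho) > 1e-12:
            w = _block_whitener(patients, rho)
            coef, resid, s2, xtx_inv = _ols(w @ x, y @ w.T)

    gi = names.index("group")
    df = float(n - p)
    if moderate and y.shape[0] >= MODERATION_MIN_PROBES:
        s2_post, df0, _ = squeeze_variances(s2, df)
        df_total = df + df0
    else:
        s2_post, df_total = np.maximum(s2, 1e-300), df
    se = np.sqrt(s2_post * xtx_inv[gi, gi])
    tstat = coef[:, gi] / se
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    pvals = np.clip(pvals, 5e-324, 1.0)

    beta = m_to_beta(m[samples])
    in_a = (sub["group"] == contrast[0]).to_numpy()
    delta_beta = (
        beta.to_numpy()[:, in_a].mean(axis=1)
        - beta.to_numpy()[:, ~in_a].mean(axis=1)
    )
    out = pd.DataFrame(
        {
            "probe_id": m.index.to_numpy(),
            "effect": coef[:, gi],
            "t": tstat,
            "p": pvals,
            "p_adj": bh_adjust(pvals),
            "delta_beta": delta_beta,
        }
    )
    out.attrs["rho"] = rho
    return out


def call_dmrs(
    dmps: pd.DataFrame,
    manifest: pd.DataFrame,
    max_gap_bp: int = 1000,
    seed_alpha: float = 0.05,
    min_cpgs: int = 3,
) -> pd.DataFrame:
    """Call differentially methylated regions from per-CpG statistics.

    Seed CpGs are probes with raw p <= seed_alpha. Seeds on the same
    chromosome are clustered while consecutive seeds lie within
    ``max_gap_bp``; each cluster is extended to include the non-seed
    probes falling inside its span. Clusters with fewer than
    ``min_cpgs`` seed probes (or member probes) are discarded: requiring
    the minimum on seeds keeps two nominal CpGs bridged by an
    uninformative interior probe from qualifying as a region. The region
    p-value is Stouffer's combination of the members' signed z-scores
    (two-sided), BH-adjusted across regions.
    """
    if dmps.empty:
        return _empty_dmr_frame()
    merged = manifest.merge(dmps, on="probe_id", how="inner")
    rows = []
    for chrom, sub in merged.groupby("chrom", sort=False):
        sub = sub.sort_values("pos").reset_index(drop=True)
        pos = sub["pos"].to_numpy()
        seeds = np.flatnonzero(sub["p"].to_numpy() <= seed_alpha)
        if seeds.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos[seeds]) > max_gap_bp)
        clusters = np.split(seeds, breaks + 1)
        for cl in clusters:
            if len(cl) < min_cpgs:
                continue
            lo, hi = cl[0], cl[-1]
            members = sub.iloc[lo : hi + 1]
            if len(members) < min_cpgs:
                continue
            z = signed_z(members["p"].to_numpy(), members["effect"].to_numpy())
            zc, p_region = stouffer_combine(z)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(members["pos"].iloc[0]),
                    "end": int(members["pos"].iloc[-1]),
                    "n_cpgs": len(members),
                    "stouffer_z": zc,
                    "p_region": p_region,
                    "mean_delta_beta": float(members["delta_beta"].mean()),
                    "probe_ids": ",".join(members["probe_id"]),
                }
            )
    if not rows:
        return _empty_dmr_frame()
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_region"].to_numpy())
    return out[
        [
            "chrom", "start", "end", "n_cpgs", "stouffer_z",
            "p_region", "p_adj", "mean_delta_beta", "probe_ids",
        ]
    ]


def _empty_dmr_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "chrom", "start", "end", "n_cpgs", "stouffer_z",
            "p_region", "p_adj", "mean_delta_beta", "probe_ids",
        ]
    )


def annotate_nearest_tss(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Annotate each region with the gene whose TSS is nearest its midpoint.

    Distance is 0 when the TSS lies inside the region; ties are broken
    by the lexicographically smallest gene_id. Regions on chromosomes
    without genes get a missing annotation.
    """
    if genes.empty:
        raise ValueError("gene model is empty")
    out = regions.copy()
    gene_ids, distances = [], []
    by_chrom = dict(tuple(genes.groupby("chrom", sort=False)))
    for _, region in regions.iterrows():
        sub = by_chrom.get(region["chrom"])
        if sub is None or sub.empty:
            gene_ids.append(None)
            distances.append(np.nan)
            continue
        mid = (region["start"] + region["end"]) / 2.0
        d = np.abs(sub["tss"].to_numpy(dtype=float) - mid)
        order = sorted(
            range(len(sub)), key=lambda i: (d[i], sub["gene_id"].iloc[i])
        )
        best = order[0]
        tss = int(sub["tss"].iloc[best])
        inside = region["start"] <= tss <= region["end"]
        gene_ids.append(sub["gene_id"].iloc[best])
        distances.append(0.0 if inside else float(d[best]))
    out["gene_id"] = gene_ids
    out["tss_distance"] = distances
    return out
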