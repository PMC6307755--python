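"""Probe filtering, Beta/M conversion, and the PCA covariate screen.

Methylation modelling is done on M-values, M = log2(Beta / (1 - Beta)),
which are unbounded and closer to homoscedastic; Beta-values stay the
reporting/visualisation scale. Before any modelling, probes flagged as
SNP-overlapping (MAF > 0.05) or cross-reactive and probes on the sex
chromosomes are removed, and a PCA screen quantifies how strongly each
recorded covariate (passage, age, sex, disease degree, medication,
smoking) tracks the leading principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .validate import MEDICATION_COLUMNS

SEX_CHROMOSOMES = ("chrX", "chrY", "X", "Y")


def beta_to_m(beta: pd.DataFrame, epsilon: float = 1e-6) -> pd.DataFrame:
    """Convert Beta-values to M-values, M = log2(beta / (1 - beta)).

    Values are clipped to [epsilon, 1 - epsilon] first so that boundary
    Betas map to finite M-values.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    vals = beta.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("Beta matrix contains non-finite values")
    clipped = np.clip(vals, epsilon, 1.0 - epsilon)
    m = np.log2(clipped / (1.0 - clipped))
    return pd.DataFrame(m, index=beta.index, columns=beta.columns)


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse transform: Beta = 2^M / (1 + 2^M)."""
    vals = m.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("M matrix contains non-finite values")
    # expit in base 2, written to avoid overflow for large |M|
    beta = np.where(vals >= 0, 1.0 / (1.0 + 2.0 ** (-vals)),
                    2.0 ** vals / (1.0 + 2.0 ** vals))
    return pd.DataFrame(beta, index=m.index, columns=m.columns)


@dataclass
class FilterReport:
    """Probes dropped per criterion by :func:`filter_probes`."""

    n_input: int
    n_snp: int = 0
    n_crossreactive: int = 0
    n_sex_chromosome: int = 0
    n_kept: int = 0


def filter_probes(
    manifest: pd.DataFrame,
    drop_snp: bool = True,
    drop_crossreactive: bool = True,
    drop_sex_chromosomes: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove flagged probes from the manifest, preserving order.

    Drops probes whose CpG overlaps a common SNP, cross-reactive
    (promiscuous) probes, and probes mapping to chrX/chrY. Idempotent.
    """
    report = FilterReport(n_input=len(manifest))
    keep = pd.Series(True, index=manifest.index)
    if drop_snp:
        snp = manifest["snp_flag"].astype(bool)
        report.n_snp = int((keep & snp).sum())
        keep &= ~snp
    if drop_crossreactive:
        xr = manifest["crossreactive_flag"].astype(bool)
        report.n_crossreactive = int((keep & xr).sum())
        keep &= ~xr
    if drop_sex_chromosomes:
        sex = manifest["chrom"].isin(SEX_CHROMOSOMES)
        report.n_sex_chromosome = int((keep & sex).sum())
        keep &= ~sex
    out = manifest.loc[keep].copy()
    report.n_kept = len(out)
    return out, report


# ordinal coding of disease degree used in the screen; non-CD samples are
# left out of the degree covariate rather than forced onto the scale
_DEGREE_CODE = {"NINF": 0.0, "INF": 1.0, "STEN": 2.0}


def _covariate_codings(sheet: pd.DataFrame) -> dict[str, pd.Series]:
    """Numeric codings of the screened covariates, indexed by sample_id."""
    idx = pd.Index(sheet["sample_id"])
    med = sheet[list(MEDICATION_COLUMNS)].astype(bool)
    cov: dict[str, pd.Series] = {
        "passage": pd.Series(sheet["passage"].to_numpy(dtype=float), index=idx),
        "age": pd.Series(sheet["age"].to_numpy(dtype=float), index=idx),
        "sex": pd.Series(
            sheet["sex"].map({"F": 0.0, "M": 1.0}).to_numpy(), index=idx
        ),
        "degree_cd": pd.Series(
            sheet["group"].map(_DEGREE_CODE).to_numpy(), index=idx
        ),
        "cd_status": pd.Series(
            (sheet["group"] != "nonCD").to_numpy(dtype=float), index=idx
        ),
        "smoker": pd.Series(sheet["smoker"].to_numpy(dtype=float), index=idx),
        "medication": pd.Series(med.any(axis=1).to_numpy(dtype=float), index=idx),
    }
    for drug in MEDICATION_COLUMNS:
        cov[drug] = pd.Series(med[drug].to_numpy(dtype=float), index=idx)
    return cov


def pc_covariate_screen(
    data: pd.DataFrame,
    sheet: pd.DataFrame,
    n_components: int = 3,
) -> pd.DataFrame:
    """Correlate sample-level principal components with recorded covariates.

    PCA is run on samples (features centered, unscaled). For every
    covariate the Pearson r, r^2, and p against each component score are
    reported; categorical covariates are coded as ordered integers
    (disease degree NINF < INF < STEN; non-CD excluded from that scale),
    medication as per-drug indicators plus an any-medication indicator.

    Returns a tidy table (component, covariate, r, r2, p, n).
    """
    samples = list(data.columns)
    n = len(samples)
    if n_components > n - 1:
        raise ValueError("n_components must be <= n_samples - 1")
    x = data.to_numpy(dtype=float).T  # samples x features
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(
        x - x.mean(axis=0)
    )
    cov = _covariate_codings(sheet.set_index("sample_id").loc[samples].reset_index())
    rows = []
    for name, series in cov.items():
        v = series.loc[samples].to_numpy(dtype=float)
        ok = np.isfinite(v)
        for k in range(n_components):
            s = scores[ok, k]
            if ok.sum() < 3 or np.std(v[ok]) == 0 or np.std(s) == 0:
                if np.std(v[ok]) == 0:
                    warnings.warn(
                        f"covariate {name!r} is constant; r^2 reported as 0",
                        stacklevel=2,
                    )
                r, p = 0.0, 1.0
            else:
                r, p = stats.pearsonr(v[ok], s)
            rows.append(
                {
                    "component": f"PC{k + 1}",
                    "covariate": name,
                    "r": float(r),
                    "r2": float(r) ** 2,
                    "p": float(p),
                    "n": int(ok.sum()),
                }
            )
    return pd.DataFrame(rows)
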