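"""Differential expression: CPM filtering, normalization, NB Wald tests.

Genes expressed below 1 count-per-million in most samples are removed,
per-sample size factors come from the median-of-ratios estimator, and
each remaining gene is fit with a negative-binomial log-linear model
(size factors as fixed offsets, the study's covariate set in the
design). Gene-wise dispersions are estimated by Cox-Reid-adjusted
maximum likelihood with a floor and shrinkage toward a fitted
mean-dispersion trend; the contrast coefficient is tested with a Wald
test and BH adjustment across genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from ._stats import bh_adjust
from .design import build_design

DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 20.0


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: cpm[g, s] = counts[g, s] / library_size[s] * 1e6."""
    libsize = counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero library size")
    return counts / libsize * 1e6


def filter_low_expression(
    counts: pd.DataFrame,
    cpm_threshold: float = 1.0,
    max_below: int | None = None,
) -> pd.DataFrame:
    """Drop genes with CPM < threshold in more than ``max_below`` samples.

    ``max_below`` defaults to floor(n_samples / 2); a gene below
    threshold in exactly ``max_below`` samples is retained (the rule is
    strictly "more than").
    """
    n = counts.shape[1]
    if max_below is None:
        max_below = n // 2
    if max_below > n:
        raise ValueError("max_below cannot exceed the sample count")
    below = (compute_cpm(counts) < cpm_threshold).sum(axis=1)
    return counts.loc[below <= max_below]


def estimate_size_factors(counts: pd.DataFrame, normalize: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    factor[s] = median over all-positive genes of counts[g, s] /
    geometric-mean_g. With ``normalize=True`` factors are rescaled to
    geometric mean 1 (only relative factors are identified).
    """
    vals = counts.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; filter low-count "
            "genes first"
        )
    logs = np.log(vals[allpos])
    log_geomean = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    if normalize:
        factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log_expression(
    counts: pd.DataFrame,
    size_factors: pd.Series | None = None,
    base: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Normalized log expression, log_base(count / size_factor + pseudocount)."""
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    norm = counts / size_factors
    return np.log(norm + pseudocount) / np.log(base)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    inv = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + inv)
            - special.gammaln(inv)
            - special.gammaln(y + 1.0)
            + y * np.log(alpha * mu / (1.0 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _cox_reid_penalty(x: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    w = mu / (1.0 + alpha * mu)
    xtwx = x.T @ (x * w[:, None])
    sign, logdet = np.linalg.slogdet(xtwx)
    return 0.5 * logdet if sign > 0 else np.inf


def _estimate_alpha(y: np.ndarray, mu: np.ndarray, x: np.ndarray) -> float:
    """Cox-Reid-adjusted profile ML dispersion for one gene, mu held fixed."""

    def neg(log_alpha: float) -> float:
        a = np.exp(log_alpha)
        return -(_nb_loglik(y, mu, a) - _cox_reid_penalty(x, mu, a))

    res = optimize.minimize_scalar(
        neg,
        bounds=(np.log(DISPERSION_FLOOR), np.log(DISPERSION_CEIL)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def _fit_dispersion_trend(means: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Parametric trend alpha(mu) = a0 + a1 / mu, fit by non-negative LS."""
    ok = (alphas > 10 * DISPERSION_FLOOR) & (means > 0)
    if ok.sum() < 10:
        return np.maximum(alphas, DISPERSION_FLOOR)
    a = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, _ = optimize.nnls(a, alphas[ok])
    trend = coef[0] + coef[1] / np.maximum(means, 1e-8)
    return np.maximum(trend, DISPERSION_FLOOR)


def fit_degs(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    contrast: tuple[str, str],
    covariates: list[str] | tuple[str, ...] = (),
    size_factors: pd.Series | None = None,
    dispersion_shrinkage: float = 0.5,
) -> pd.DataFrame:
    """Negative-binomial Wald test for each gene.

    Per gene: a Poisson GLM provides fitted means, the NB dispersion is
    estimated by Cox-Reid-adjusted profile likelihood, gene-wise
    log-dispersions are shrunk toward the fitted mean-dispersion trend
    with weight ``dispersion_shrinkage``, and a final NB GLM yields the
    Wald statistic for the contrast coefficient. Non-converging genes
    are flagged (``converged`` False, p missing) and excluded from BH.

    Returns a DataFrame with gene_id, base_mean, log2_fold_change,
    lfc_se, wald_stat, p, p_adj, alpha, converged.
    """
    present = sheet[sheet["sample_id"].isin(counts.columns)]
    x, names, sub = build_design(present, contrast, covariates)
    samples = list(sub["sample_id"])
    y_all = counts[samples].to_numpy(dtype=float)
    if size_factors is None:
        size_factors = estimate_size_factors(counts[samples])
    offset = np.log(size_factors.loc[samples].to_numpy(dtype=float))
    gi = names.index("group")
    log2e = np.log2(np.e)

    n_genes = y_all.shape[0]
    alphas = np.full(n_genes, np.nan)
    mus = [None] * n_genes
    base_means = (y_all / np.exp(offset)[None, :]).mean(axis=1)
    for g in range(n_genes):
        y = y_all[g]
        if y.sum() == 0:
            continue
        try:
            pois = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset).fit()
            mu = np.maximum(pois.fittedvalues, 1e-8)
            alphas[g] = _estimate_alpha(y, mu, x)
            mus[g] = mu
        except Exception:
            pass

    fitted = np.isfinite(alphas)
    trend = _fit_dispersion_trend(base_means[fitted], alphas[fitted])
    alpha_final = np.full(n_genes, np.nan)
    w = float(np.clip(dispersion_shrinkage, 0.0, 1.0))
    alpha_final[fitted] = np.exp(
        (1 - w) * np.log(alphas[fitted]) + w * np.log(trend)
    )
    alpha_final = np.clip(alpha_final, DISPERSION_FLOOR, DISPERSION_CEIL)

    records = []
    n_failed = 0
    for g in range(n_genes):
        rec = {
            "gene_id": counts.index[g],
            "base_mean": base_means[g],
            "log2_fold_change": np.nan,
            "lfc_se": np.nan,
            "wald_stat": np.nan,
            "p": np.nan,
            "alpha": alpha_final[g],
            "converged": False,
        }
        if mus[g] is not None:
            try:
                fam = sm.families.NegativeBinomial(alpha=float(alpha_final[g]))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.GLM(y_all[g], x, family=fam, offset=offset).fit(
                        maxiter=100
                    )
                if fit.converged and np.isfinite(fit.bse[gi]) and fit.bse[gi] > 0:
                    rec["log2_fold_change"] = float(fit.params[gi]) * log2e
                    rec["lfc_se"] = float(fit.bse[gi]) * log2e
                    rec["wald_stat"] = rec["log2_fold_change"] / rec["lfc_se"]
                    rec["p"] = float(
                        np.clip(2.0 * stats.norm.sf(abs(rec["wald_stat"])), 5e-324, 1.0)
                    )
                    rec["converged"] = True
            except Exception:
                pass
        if not rec["converged"] and y_all[g].sum() > 0:
            n_failed += 1
        records.append(rec)
    if n_failed:
        warnings.warn(
            f"{n_failed} gene(s) failed to converge and were excluded from "
            "multiple-testing adjustment",
            stacklevel=2,
        )
    out = pd.DataFrame(records)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
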