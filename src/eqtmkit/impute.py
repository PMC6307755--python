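"""Molecular imputation of missing sample metadata (age and sex).

Age is predicted from CpG Beta-values with a linear epigenetic clock:
the linear score s = intercept + sum(w_i * Beta_i) is mapped to years by
the inverse of the piecewise log/linear age transform (logarithmic in
childhood, linear in adulthood, hinged at ``adult_age``). Sex is called
from the presence of chromosome-Y signal, in methylation (fraction of
chrY probes with detectable Beta) and independently in expression
(number of chrY genes above a CPM cutoff). Clock coefficients are
user-supplied; the clock CpGs are removed from the manifest afterwards
to keep age from confounding the differential analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import compute_cpm


@dataclass
class ClockModel:
    """Linear age clock: intercept, per-probe weights, adult-age hinge."""

    intercept: float
    coefficients: dict[str, float]
    adult_age: float = 20.0

    def __post_init__(self):
        if not self.coefficients:
            raise ValueError("clock must have at least one coefficient")


def age_transform(age: np.ndarray, adult_age: float = 20.0) -> np.ndarray:
    """Forward transform of calendar age to the clock's linear scale.

    log((age + 1) / (adult_age + 1)) below the hinge, linear above.
    """
    age = np.asarray(age, dtype=float)
    return np.where(
        age <= adult_age,
        np.log((age + 1.0) / (adult_age + 1.0)),
        (age - adult_age) / (adult_age + 1.0),
    )


def inverse_age_transform(s: np.ndarray, adult_age: float = 20.0) -> np.ndarray:
    """Inverse of :func:`age_transform`: s <= 0 maps through the anti-log."""
    s = np.asarray(s, dtype=float)
    return np.where(
        s <= 0,
        (1.0 + adult_age) * np.exp(s) - 1.0,
        (1.0 + adult_age) * s + adult_age,
    )


def predict_age(
    beta: pd.DataFrame,
    clock: ClockModel,
    min_probe_fraction: float = 0.5,
) -> tuple[pd.Series, int]:
    """Predict per-sample age from the clock's CpGs.

    Clock probes absent from the matrix are imputed with the cohort mean
    Beta of the present clock probes; if fewer than
    ``min_probe_fraction`` of them are present, an error lists the
    missing ids. Returns (ages in years, number of missing probes).
    """
    probes = list(clock.coefficients)
    present = [p for p in probes if p in beta.index]
    missing = [p for p in probes if p not in beta.index]
    if len(present) < min_probe_fraction * len(probes):
        raise ValueError(
            f"only {len(present)}/{len(probes)} clock probes present; "
            f"missing: {missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    w_present = np.array([clock.coefficients[p] for p in present])
    s = clock.intercept + w_present @ beta.loc[present].to_numpy(dtype=float)
    if missing:
        cohort_mean = float(beta.loc[present].to_numpy().mean())
        s = s + cohort_mean * sum(clock.coefficients[p] for p in missing)
    ages = inverse_age_transform(s, clock.adult_age)
    return pd.Series(ages, index=beta.columns, name="age_estimate"), len(missing)


def exclude_clock_probes(
    manifest: pd.DataFrame, clock: ClockModel
) -> tuple[pd.DataFrame, int]:
    """Drop the clock's CpGs from the manifest (anti-confounding step)."""
    drop = manifest["probe_id"].isin(clock.coefficients)
    return manifest.loc[~drop].copy(), int(drop.sum())


def infer_sex_from_methylation(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    threshold_fraction: float = 0.5,
    detection_beta: float = 0.1,
) -> pd.DataFrame:
    """Call sample sex from chromosome-Y methylation signal.

    A chrY probe is "detected" in a sample when its Beta is at least
    ``detection_beta``; female samples show only cross-hybridisation
    background (Beta below ~0.1) on chrY, while male chrY probes span
    the usual bimodal range.
    A sample is called M when the detected fraction exceeds
    ``threshold_fraction``. Returns a table (sample, sex, detected
    fraction, margin from the threshold).
    """
    chry = manifest.loc[manifest["chrom"].isin(["chrY", "Y"]), "probe_id"]
    probes = [p for p in chry if p in beta.index]
    if not probes:
        raise ValueError("no chromosome-Y probes in the Beta matrix")
    if len(probes) < 5:
        raise ValueError(
            f"only {len(probes)} chrY probes available; need >= 5 for a call"
        )
    frac = (beta.loc[probes] >= detection_beta).mean(axis=0)
    return pd.DataFrame(
        {
            "sample_id": beta.columns,
            "sex": np.where(frac > threshold_fraction, "M", "F"),
            "chry_detected_fraction": frac.to_numpy(dtype=float),
            "margin": frac.to_numpy(dtype=float) - threshold_fraction,
        }
    )


def infer_sex_from_expression(
    counts: pd.DataFrame,
    chry_genes: list[str],
    cpm_cutoff: float = 1.0,
    min_genes: int = 2,
) -> pd.DataFrame:
    """Call sample sex from chromosome-Y gene expression.

    A sample is M when at least ``min_genes`` chrY genes exceed
    ``cpm_cutoff`` CPM. Returns (sample, sex, number of expressed chrY
    genes).
    """
    present = [g for g in chry_genes if g in counts.index]
    if not present:
        raise ValueError("no chromosome-Y genes in the count matrix")
    if len(present) < min_genes:
        raise ValueError(
            f"only {len(present)} chrY genes available; need >= {min_genes}"
        )
    cpm = compute_cpm(counts).loc[present]
    n_expressed = (cpm > cpm_cutoff).sum(axis=0)
    return pd.DataFrame(
        {
            "sample_id": counts.columns,
            "sex": np.where(n_expressed >= min_genes, "M", "F"),
            "n_chry_expressed": n_expressed.to_numpy(dtype=int),
        }
    )


def read_clock(path) -> ClockModel:
    """Read a clock coefficient TSV (probe_id, weight; one intercept row)."""
    tab = pd.read_csv(path, sep="\t")
    if not {"probe_id", "weight"} <= set(tab.columns):
        raise ValueError("clock file needs columns probe_id, weight")
    inter = tab[tab["probe_id"].str.lower().isin(["intercept", "(intercept)"])]
    if len(inter) != 1:
        raise ValueError("clock file must contain exactly one intercept row")
    coefs = tab.drop(index=inter.index)
    return ClockModel(
        intercept=float(inter["weight"].iloc[0]),
        coefficients=dict(zip(coefs["probe_id"], coefs["weight"].astype(float))),
    )


def write_clock(clock: ClockModel, path) -> None:
    rows = [{"probe_id": "intercept", "weight": clock.intercept}]
    rows += [{"probe_id": p, "weight": w} for p, w in clock.coefficients.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
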