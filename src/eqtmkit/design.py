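"""Design-matrix construction shared by the methylation and expression models.

Covariates mirror the study's adjustment set: culture passage, age, sex,
and medication usage (azathioprine, purinethol, adalimumab, infliximab).
Medication enters as per-drug indicators but collapses to a single
any-medication indicator when a drug column is confounded with the
contrast — non-CD samples receive no medication, so per-drug columns are
collinear with any CD/non-CD contrast.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .validate import MEDICATION_COLUMNS

DEFAULT_COVARIATES = ("passage", "age", "sex", "medication")


class DesignError(ValueError):
    """Raised when a full-rank design cannot be constructed."""


def _numeric_covariate(sheet: pd.DataFrame, name: str) -> np.ndarray:
    if name == "passage":
        return sheet["passage"].to_numpy(dtype=float)
    if name == "age":
        v = sheet["age"].to_numpy(dtype=float)
        if np.isnan(v).any():
            if np.isnan(v).all():
                raise DesignError("age covariate requested but all ages missing")
            warnings.warn(
                f"{int(np.isnan(v).sum())} missing age(s) imputed with the "
                "cohort mean",
                stacklevel=3,
            )
            v = np.where(np.isnan(v), np.nanmean(v), v)
        return v
    if name == "sex":
        v = sheet["sex"].map({"F": 0.0, "M": 1.0}).to_numpy(dtype=float)
        if np.isnan(v).any():
            warnings.warn(
                "unknown sex imputed with the cohort mean", stacklevel=3
            )
            v = np.where(np.isnan(v), np.nanmean(v), v)
        return v
    if name == "smoker":
        return sheet["smoker"].to_numpy(dtype=float)
    if name in MEDICATION_COLUMNS:
        return sheet[name].to_numpy(dtype=float)
    raise DesignError(f"unknown covariate {name!r}")


def _rank(x: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(x)) if x.size else 0


def build_design(
    sheet: pd.DataFrame,
    contrast: tuple[str, str],
    covariates: list[str] | tuple[str, ...] = DEFAULT_COVARIATES,
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Build intercept + contrast-indicator + covariate design.

    The returned coefficient of interest is the column ``group``, coded 1
    for ``contrast[0]`` and 0 for ``contrast[1]``; its estimate is the
    adjusted A-minus-B difference. Samples outside the two groups are
    excluded. Constant covariate columns are dropped with a warning;
    per-drug medication columns collinear with the rest of the design are
    collapsed to an any-medication indicator; any remaining rank
    deficiency raises :class:`DesignError` naming the offending columns.

    Returns (X, column_names, subset_sheet).
    """
    group_a, group_b = contrast
    sub = sheet[sheet["group"].isin([group_a, group_b])].reset_index(drop=True)
    n_a = int((sub["group"] == group_a).sum())
    n_b = int((sub["group"] == group_b).sum())
    if n_a < 2 or n_b < 2:
        raise DesignError(
            f"contrast {group_a} vs {group_b} needs >= 2 samples per group "
            f"(got {n_a} and {n_b})"
        )
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(sub)),
        "group": (sub["group"] == group_a).to_numpy(dtype=float),
    }
    requested: list[str] = []
    for cov in covariates:
        if cov == "medication":
            requested.extend(MEDICATION_COLUMNS)
        else:
            requested.append(cov)
    for cov in requested:
        v = _numeric_covariate(sub, cov)
        if np.std(v) == 0:
            warnings.warn(
                f"covariate {cov!r} is constant in this contrast; dropped",
                stacklevel=2,
            )
            continue
        cols[cov] = v

    names = list(cols)
    x = np.column_stack([cols[c] for c in names])
    drug_cols = [c for c in names if c in MEDICATION_COLUMNS]
    if drug_cols and _rank(x) < x.shape[1]:
        # collapse per-drug indicators into a single usage flag
        any_med = sub[list(MEDICATION_COLUMNS)].astype(float).max(axis=1).to_numpy()
        names = [c for c in names if c not in MEDICATION_COLUMNS]
        cols = {c: cols[c] for c in names}
        if np.std(any_med) > 0:
            cols["medication"] = any_med
            names.append("medication")
        warnings.warn(
            "per-drug medication columns confounded with the design; "
            "collapsed to a single any-medication indicator",
            stacklevel=2,
        )
        x = np.column_stack([cols[c] for c in names])
        if _rank(x) < x.shape[1] and "medication" in names:
            names.remove("medication")
            warnings.warn(
                "any-medication indicator still confounded; dropped",
                stacklevel=2,
            )
            x = np.column_stack([cols[c] for c in names])
    if _rank(x) < x.shape[1]:
        bad = []
        for j, name in enumerate(names):
            others = np.delete(x, j, axis=1)
            if _rank(others) == _rank(x):
                bad.append(name)
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")
    return x, names, sub
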