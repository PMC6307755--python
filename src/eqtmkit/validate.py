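"""Validation of the tabular containers used throughout the pipeline.

All study data are plain pandas objects with fixed column conventions:

* probe manifest — columns ``probe_id, chrom, pos, snp_flag,
  crossreactive_flag``; sorted by (chrom, pos), positions strictly
  increasing within a chromosome, probe ids unique.
* gene model — columns ``gene_id, chrom, tss, strand`` (optional
  ``ensembl``/``entrez`` id columns carried through to reports).
* sample sheet — one row per sample with assay membership, group,
  patient, passage, age, sex, medication flags and smoker status.
* Beta matrix — probes x samples DataFrame, entries strictly in (0, 1).
* count matrix — genes x samples DataFrame of non-negative integers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GROUPS = ("NINF", "INF", "STEN", "nonCD")
ASSAYS = ("methylation", "expression", "both")
MEDICATION_COLUMNS = ("azathioprine", "purinethol", "adalimumab", "infliximab")

MANIFEST_COLUMNS = ("probe_id", "chrom", "pos", "snp_flag", "crossreactive_flag")
GENE_MODEL_COLUMNS = ("gene_id", "chrom", "tss", "strand")
SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "assay",
    "group",
    "patient_id",
    "passage",
    "age",
    "sex",
    *MEDICATION_COLUMNS,
    "smoker",
)


class ValidationError(ValueError):
    """Raised when a study table violates its contract."""


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing columns: {missing}")


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    _require_columns(manifest, MANIFEST_COLUMNS, "probe manifest")
    if manifest["probe_id"].duplicated().any():
        dup = manifest.loc[manifest["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"duplicate probe_id {dup!r} in manifest")
    for chrom, sub in manifest.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValidationError(
                f"positions not strictly increasing on {chrom}"
            )
    if (manifest["pos"] < 1).any():
        raise ValidationError("manifest positions must be >= 1 (1-based)")
    return manifest


def validate_gene_model(genes: pd.DataFrame) -> pd.DataFrame:
    _require_columns(genes, GENE_MODEL_COLUMNS, "gene model")
    if genes["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in gene model")
    if (genes["tss"] < 1).any():
        raise ValidationError("gene TSS positions must be >= 1")
    bad = set(genes["strand"].unique()) - {"+", "-"}
    if bad:
        raise ValidationError(f"invalid strand values: {sorted(bad)}")
    return genes


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    _require_columns(sheet, SAMPLE_SHEET_COLUMNS, "sample sheet")
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    bad = set(sheet["group"].unique()) - set(GROUPS)
    if bad:
        raise ValidationError(f"unknown group labels: {sorted(bad)}")
    bad = set(sheet["assay"].unique()) - set(ASSAYS)
    if bad:
        raise ValidationError(f"unknown assay labels: {sorted(bad)}")
    passage = sheet["passage"]
    if ((passage < 1) | (passage > 5)).any():
        raise ValidationError("passage must lie in [1, 5]")
    bad = set(sheet["sex"].dropna().unique()) - {"M", "F", "unknown"}
    if bad:
        raise ValidationError(f"invalid sex labels: {sorted(bad)}")
    return sheet


def validate_beta_matrix(beta: pd.DataFrame) -> pd.DataFrame:
    vals = beta.to_numpy(dtype=float)
    if np.isnan(vals).any():
        r, c = np.argwhere(np.isnan(vals))[0]
        raise ValidationError(
            f"missing Beta at probe {beta.index[r]!r}, sample {beta.columns[c]!r}"
        )
    bad = (vals < 0) | (vals > 1)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"Beta outside [0, 1] at probe {beta.index[r]!r}, "
            f"sample {beta.columns[c]!r} (value {vals[r, c]!r})"
        )
    if beta.index.duplicated().any():
        raise ValidationError("duplicate probe ids in Beta matrix")
    if beta.columns.duplicated().any():
        raise ValidationError("duplicate sample ids in Beta matrix")
    return beta


def validate_count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValidationError("count matrix must be numeric")
    if np.isnan(vals.astype(float)).any():
        raise ValidationError("count matrix contains missing values")
    if (vals < 0).any():
        r, c = np.argwhere(vals < 0)[0]
        raise ValidationError(
            f"negative count at gene {counts.index[r]!r}, "
            f"sample {counts.columns[c]!r}"
        )
    if np.any(vals != np.rint(vals)):
        r, c = np.argwhere(vals != np.rint(vals))[0]
        raise ValidationError(
            f"non-integer count at gene {counts.index[r]!r}, "
            f"sample {counts.columns[c]!r}"
        )
    if counts.index.duplicated().any():
        raise ValidationError("duplicate gene ids in count matrix")
    if counts.columns.duplicated().any():
        raise ValidationError("duplicate sample ids in count matrix")
    return counts


def check_sample_consistency(
    sheet: pd.DataFrame,
    beta: pd.DataFrame | None = None,
    counts: pd.DataFrame | None = None,
) -> None:
    """Cross-check that matrix columns are described by the sample sheet."""
    ids = set(sheet["sample_id"])
    if beta is not None:
        extra = [s for s in beta.columns if s not in ids]
        if extra:
            raise ValidationError(
                f"Beta matrix sample {extra[0]!r} absent from the sample sheet"
            )
    if counts is not None:
        extra = [s for s in counts.columns if s not in ids]
        if extra:
            raise ValidationError(
                f"count matrix sample {extra[0]!r} absent from the sample sheet"
            )
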