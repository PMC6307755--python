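"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV with a single header line of sample ids; sample
sheets as CSV or TSV; regions additionally as BED. Coordinate strings
are 1-based inclusive ``chrom:start-end`` (an en-dash is accepted on
input, a hyphen is written); BED exports are 0-based half-open. Every
written table can carry provenance comment lines (version, config hash,
seeds) which readers skip.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .validate import (
    check_sample_consistency,
    validate_beta_matrix,
    validate_count_matrix,
    validate_gene_model,
    validate_manifest,
    validate_sample_sheet,
)

_COORD_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)[-–](?P<end>\d+)$")


def format_coordinates(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def parse_coordinates(text: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (hyphen or en-dash), 1-based inclusive."""
    m = _COORD_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse coordinates {text!r}")
    return m["chrom"], int(m["start"]), int(m["end"])


def _provenance_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    fields = " | ".join(f"{k}={v}" for k, v in meta.items())
    return f"# eqtmkit v{__version__} | {fields}\n"


def write_table(df: pd.DataFrame, path, meta: dict | None = None, sep="\t") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(meta))
        df.to_csv(fh, sep=sep, index=False)


def _read_table(path, sep="\t", **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", **kw)


def write_matrix(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(meta))
        df.to_csv(fh, sep="\t", index=True, index_label="id")


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = None
    return df


def read_beta_matrix(path, sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    beta = validate_beta_matrix(_read_matrix(path).astype(float))
    if sheet is not None:
        check_sample_consistency(sheet, beta=beta)
    return beta


def read_count_matrix(path, sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    counts = validate_count_matrix(_read_matrix(path))
    counts = counts.astype(np.int64)
    if sheet is not None:
        check_sample_consistency(sheet, counts=counts)
    return counts


def read_sample_sheet(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return validate_sample_sheet(_read_table(path, sep=sep))


def read_manifest(path) -> pd.DataFrame:
    return validate_manifest(_read_table(path))


def read_gene_model(path) -> pd.DataFrame:
    return validate_gene_model(_read_table(path))


def write_sample_sheet(sheet: pd.DataFrame, path, meta=None) -> None:
    write_table(sheet, path, meta=meta, sep=",")


def write_manifest(manifest: pd.DataFrame, path, meta=None) -> None:
    write_table(manifest, path, meta=meta)


def write_gene_model(genes: pd.DataFrame, path, meta=None) -> None:
    write_table(genes, path, meta=meta)


def write_dmrs(regions: pd.DataFrame, path, meta=None) -> None:
    """DMR TSV with the report-style 1-based coordinate string."""
    out = regions.copy()
    if not out.empty:
        out.insert(
            0,
            "coordinates",
            [
                format_coordinates(r["chrom"], int(r["start"]), int(r["end"]))
                for _, r in regions.iterrows()
            ],
        )
    write_table(out, path, meta=meta)


def write_region_bed(regions: pd.DataFrame, path) -> None:
    """BED export: 0-based half-open, name = annotated gene, score =
    -log10(adjusted p) capped at 1000."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            name = r.get("gene_id") or "."
            p_adj = float(r.get("p_adj", np.nan))
            score = min(-np.log10(max(p_adj, 1e-300)), 1000.0) if np.isfinite(p_adj) else 0.0
            fh.write(
                f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}"
                f"\t{name}\t{score:.4g}\n"
            )


def read_region_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, *rest = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start) + 1,
                    "end": int(end),
                    "gene_id": rest[0] if rest else None,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


#: exact column layout of the headline eQTM report
EQTM_REPORT_COLUMNS = (
    "Coordinates", "nCpGs", "Gene", "Ensembl", "Entrez",
    "Correlation", "p_correlation", "p_DE", "p_DM",
)


def format_eqtm_report(table: pd.DataFrame) -> pd.DataFrame:
    """Render internal eQTM records in the published column layout.

    The correlation column is formatted ``r [ci_low, ci_high]``.
    """
    rows = []
    for _, r in table.iterrows():
        rows.append(
            {
                "Coordinates": r["coordinates"],
                "nCpGs": int(r["n_cpgs"]),
                "Gene": r["gene_id"],
                "Ensembl": r.get("ensembl", ""),
                "Entrez": r.get("entrez", ""),
                "Correlation": f"{r['r']:.2f} [{r['ci_low']:.2f}, {r['ci_high']:.2f}]",
                "p_correlation": r["p_corr"],
                "p_DE": r["p_de"],
                "p_DM": r["p_dm"],
            }
        )
    return pd.DataFrame(rows, columns=list(EQTM_REPORT_COLUMNS))


def write_eqtm_report(table: pd.DataFrame, path, meta=None) -> None:
    write_table(format_eqtm_report(table), path, meta=meta)
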