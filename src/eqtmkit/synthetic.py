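"""Synthetic cohorts with planted methylation, expression, and eQTM signal.

The generator emulates the structure of a two-assay ileal-fibroblast
study: a CpG probe manifest with realistic spacing and filter flags, a
sample sheet with repeated samples per patient across culture passages,
a bimodal Beta-value matrix, a negative-binomial count matrix, and
optional planted effects — differentially methylated regions, fold
changes on genes, and shared latent factors that couple a region's
methylation to a gene's expression at a prescribed Pearson correlation.
Every downstream stage of the pipeline can therefore be checked against
known ground truth.

The default cohort reproduces the study design: 18 methylation samples
from 10 patients, 21 expression samples from 14 patients, with 9 samples
from 6 patients assayed on both platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .validate import (
    GROUPS,
    MEDICATION_COLUMNS,
    validate_manifest,
    validate_sample_sheet,
)

_BETA_CLIP = 1e-3


# ---------------------------------------------------------------------------
# planted-effect descriptions (ground truth for recovery tests)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionEffect:
    """A planted differentially methylated region.

    ``start_probe_index`` indexes probes of ``chrom`` in manifest order;
    the effect spans ``n_cpgs`` consecutive probes and shifts Beta by
    ``delta_beta`` (clipped into (0, 1)) in ``target_group`` samples.
    """

    chrom: str
    start_probe_index: int
    n_cpgs: int
    delta_beta: float
    target_group: str

    def __post_init__(self):
        if self.n_cpgs < 3:
            raise ValueError("planted regions must span >= 3 CpGs")
        if not -0.5 <= self.delta_beta <= 0.5:
            raise ValueError("delta_beta must lie in [-0.5, 0.5]")
        if self.target_group not in GROUPS:
            raise ValueError(f"unknown group {self.target_group!r}")


@dataclass(frozen=True)
class GeneEffect:
    """A planted log2 fold change on one gene in one group."""

    gene_id: str
    log2_fold_change: float
    target_group: str

    def __post_init__(self):
        if not np.isfinite(self.log2_fold_change):
            raise ValueError("log2_fold_change must be finite")
        if self.target_group not in GROUPS:
            raise ValueError(f"unknown group {self.target_group!r}")


@dataclass(frozen=True)
class Coupling:
    """A methylation-expression coupling with a target Pearson r.

    A shared per-sample latent factor is injected into the region's
    probes and the gene's counts so the realised correlation between
    region mean Beta and log2 counts approaches ``target_r``.
    """

    chrom: str
    start_probe_index: int
    n_cpgs: int
    gene_id: str
    target_r: float

    def __post_init__(self):
        if not -1.0 <= self.target_r <= 1.0:
            raise ValueError("|target_r| must be <= 1")


# ---------------------------------------------------------------------------
# manifest and gene model
# ---------------------------------------------------------------------------


def generate_manifest(
    n_probes: int,
    chrom_layout: dict[str, int] | None = None,
    flag_fractions: dict[str, float] | None = None,
    seed: int = 0,
    mean_gap_bp: float = 500.0,
) -> pd.DataFrame:
    """Generate a CpG probe manifest with exponential inter-probe gaps.

    Probes are allotted to chromosomes proportionally to their nominal
    lengths and spaced by 1 + Exponential(mean_gap_bp) base pairs, which
    makes gap-based region clustering behave as on a real array. Flags
    (``snp``, ``crossreactive``) are independent Bernoulli draws.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if chrom_layout is None:
        chrom_layout = {"chr1": 2_000_000, "chr2": 1_500_000, "chr3": 1_000_000}
    if not chrom_layout:
        raise ValueError("chrom_layout must name at least one chromosome")
    fractions = {"snp": 0.03, "crossreactive": 0.02}
    if flag_fractions:
        fractions.update(flag_fractions)
    for name, frac in fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"flag fraction {name!r}={frac} outside [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_layout)
    lengths = np.array([chrom_layout[c] for c in chroms], dtype=float)
    # proportional allotment, remainders to the largest chromosomes
    raw = n_probes * lengths / lengths.sum()
    alloc = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - alloc))[: n_probes - alloc.sum()]:
        alloc[i] += 1
    rows = []
    for chrom, k in zip(chroms, alloc):
        if k == 0:
            continue
        gaps = 1 + np.floor(rng.exponential(mean_gap_bp, size=k)).astype(int)
        pos = np.cumsum(gaps)
        for p in pos:
            rows.append((chrom, int(p)))
    manifest = pd.DataFrame(rows, columns=["chrom", "pos"])
    manifest["probe_id"] = [f"cg{i:08d}" for i in range(len(manifest))]
    manifest["snp_flag"] = rng.random(len(manifest)) < fractions["snp"]
    manifest["crossreactive_flag"] = (
        rng.random(len(manifest)) < fractions["crossreactive"]
    )
    manifest = manifest[
        ["probe_id", "chrom", "pos", "snp_flag", "crossreactive_flag"]
    ]
    return validate_manifest(manifest)


def generate_gene_model(
    n_genes: int,
    chrom_layout: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniformly placed TSSs with random strand, plus Ensembl/Entrez-style ids."""
    if chrom_layout is None:
        chrom_layout = {"chr1": 2_000_000, "chr2": 1_500_000, "chr3": 1_000_000}
    rng = np.random.default_rng(seed)
    chroms = list(chrom_layout)
    lengths = np.array([chrom_layout[c] for c in chroms], dtype=float)
    which = rng.choice(len(chroms), size=n_genes, p=lengths / lengths.sum())
    rows = []
    for i in range(n_genes):
        chrom = chroms[which[i]]
        tss = int(rng.integers(1, chrom_layout[chrom] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(
            {
                "gene_id": f"GENE{i:05d}",
                "chrom": chrom,
                "tss": tss,
                "strand": strand,
                "ensembl": f"ENSG9{i:07d}",
                "entrez": str(100000 + i),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupDesign:
    """Per-group sample counts for a generic cohort."""

    group: str
    n_meth: int = 0
    n_expr: int = 0
    n_shared: int = 0
    n_patients: int = 1

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if min(self.n_meth, self.n_expr, self.n_shared) < 0:
            raise ValueError("sample counts must be >= 0")
        if self.n_shared > min(self.n_meth, self.n_expr):
            raise ValueError(
                f"group {self.group}: cannot share {self.n_shared} samples "
                f"with only {self.n_meth} methylation / {self.n_expr} "
                "expression samples"
            )
        if self.n_patients < 1:
            raise ValueError("each group needs >= 1 patient")


# Explicit study-design layout: (group, patient, in_meth, in_expr).
# Totals: 18 methylation samples / 10 unique patients, 21 expression
# samples / 14 unique patients, 9 samples from 6 patients in both assays.
_PAPER_LAYOUT: list[tuple[str, str, bool, bool]] = [
    # shared samples (both assays): 9 samples, 6 patients
    ("NINF", "P01", True, True),
    ("NINF", "P02", True, True),
    ("NINF", "P03", True, True),
    ("INF", "P01", True, True),
    ("INF", "P05", True, True),
    ("STEN", "P02", True, True),
    ("STEN", "P06", True, True),
    ("STEN", "P06", True, True),
    ("STEN", "P07", True, True),
    # methylation-only: 9 samples
    ("NINF", "P01", True, False),
    ("NINF", "P02", True, False),
    ("NINF", "P03", True, False),
    ("NINF", "P04", True, False),
    ("nonCD", "P08", True, False),
    ("nonCD", "P08", True, False),
    ("nonCD", "P09", True, False),
    ("nonCD", "P09", True, False),
    ("nonCD", "P10", True, False),
    # expression-only: 12 samples
    ("NINF", "P04", False, True),
    ("NINF", "P11", False, True),
    ("NINF", "P12", False, True),
    ("INF", "P12", False, True),
    ("INF", "P13", False, True),
    ("STEN", "P11", False, True),
    ("nonCD", "P08", False, True),
    ("nonCD", "P08", False, True),
    ("nonCD", "P09", False, True),
    ("nonCD", "P09", False, True),
    ("nonCD", "P10", False, True),
    ("nonCD", "P16", False, True),
]

#: control patient whose metadata is withheld (age missing, sex unknown),
#: mimicking the study's anonymous control sample
ANONYMOUS_PATIENT = "P16"


def _patient_metadata(patients: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-patient age, sex, medication and smoking status.

    Crohn's patients: age ~ N(35.7, 14.4), 60% male, 60% on one biologic
    or thiopurine, 20% smokers. Controls: age ~ N(54.5, 18.3), 75% male,
    no medication, no smokers — typical demographics for such cohorts.
    """
    rows = []
    for p in patients:
        is_control = p in {"P08", "P09", "P10", "P16"} or p.startswith("C")
        if is_control:
            age = float(np.clip(rng.normal(54.5, 18.3), 20, 85))
            sex = "M" if rng.random() < 0.75 else "F"
            meds = {d: False for d in MEDICATION_COLUMNS}
            smoker = False
        else:
            age = float(np.clip(rng.normal(35.7, 14.4), 18, 80))
            sex = "M" if rng.random() < 0.6 else "F"
            meds = {d: False for d in MEDICATION_COLUMNS}
            if rng.random() < 0.6:
                meds[MEDICATION_COLUMNS[rng.integers(len(MEDICATION_COLUMNS))]] = True
            smoker = bool(rng.random() < 0.2)
        rows.append({"patient_id": p, "age": round(age, 1), "sex": sex,
                     "smoker": smoker, **meds})
    return pd.DataFrame(rows).set_index("patient_id")


def _assemble_sheet(
    layout: list[tuple[str, str, bool, bool]],
    rng: np.random.Generator,
    anonymous: str | None,
) -> pd.DataFrame:
    patients = sorted({p for _, p, _, _ in layout})
    meta = _patient_metadata(patients, rng)
    # distinct passages for repeated samples of the same patient+group
    passage_pool: dict[tuple[str, str], list[int]] = {}
    rows = []
    counter: dict[str, int] = {}
    for group, patient, in_meth, in_expr in layout:
        key = (patient, group)
        if key not in passage_pool:
            passage_pool[key] = list(rng.permutation(np.arange(1, 6)))
        passage = int(passage_pool[key].pop())
        counter[patient] = counter.get(patient, 0) + 1
        sid = f"{patient}_{group}_s{counter[patient]}"
        assay = "both" if (in_meth and in_expr) else (
            "methylation" if in_meth else "expression"
        )
        m = meta.loc[patient]
        rows.append(
            {
                "sample_id": sid,
                "assay": assay,
                "group": group,
                "patient_id": patient,
                "passage": passage,
                "age": m["age"],
                "sex": m["sex"],
                **{d: bool(m[d]) for d in MEDICATION_COLUMNS},
                "smoker": bool(m["smoker"]),
            }
        )
    sheet = pd.DataFrame(rows)
    # ground-truth columns kept for simulation; the public fields are
    # blanked for the anonymous patient, as for the study's control
    sheet["sex_true"] = sheet["sex"]
    sheet["age_true"] = sheet["age"]
    if anonymous is not None and (sheet["patient_id"] == anonymous).any():
        mask = sheet["patient_id"] == anonymous
        sheet.loc[mask, "sex"] = "unknown"
        sheet.loc[mask, "age"] = np.nan
    return validate_sample_sheet(sheet)


def generate_cohort(
    design: list[GroupDesign] | None = None,
    seed: int = 0,
    anonymize_control: bool = True,
) -> pd.DataFrame:
    """Generate a sample sheet; the default reproduces the study design.

    With ``design=None`` the study-shaped default cohort is produced: 18
    methylation samples from 10 patients, 21 expression samples from 14
    patients, 9 samples (6 patients) shared between assays, and one
    anonymous control patient with withheld age/sex. A custom design is
    a list of :class:`GroupDesign`; samples are assigned to patients
    round-robin, shared samples first.
    """
    rng = np.random.default_rng(seed)
    if design is None:
        return _assemble_sheet(
            _PAPER_LAYOUT, rng, ANONYMOUS_PATIENT if anonymize_control else None
        )
    layout: list[tuple[str, str, bool, bool]] = []
    pidx = 0
    for spec in design:
        prefix = "C" if spec.group == "nonCD" else "P"
        patients = [f"{prefix}{pidx + i:02d}" for i in range(spec.n_patients)]
        pidx += spec.n_patients
        k = 0
        for _ in range(spec.n_shared):
            layout.append((spec.group, patients[k % len(patients)], True, True))
            k += 1
        for _ in range(spec.n_meth - spec.n_shared):
            layout.append((spec.group, patients[k % len(patients)], True, False))
            k += 1
        for _ in range(spec.n_expr - spec.n_shared):
            layout.append((spec.group, patients[k % len(patients)], False, True))
            k += 1
    return _assemble_sheet(layout, rng, None)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MethylationNoise:
    """Noise/baseline parameters for the Beta simulator (log2-logit scale).

    The baseline per-probe mean is a two-component mixture of
    logit-normals with modes near ``mode_low``/``mode_high``, matching
    the bimodal marginal of array Betas.
    """

    mode_low: float = 0.1
    mode_high: float = 0.9
    p_high: float = 0.5
    probe_sd: float = 0.6  # spread of probe means around their mode
    patient_sd: float = 0.15  # shared per-patient effect
    sample_sd: float = 0.35  # per-sample, per-probe residual

    def __post_init__(self):
        if not (0 < self.mode_low < 1 and 0 < self.mode_high < 1):
            raise ValueError("modes must lie in (0, 1)")
        if min(self.probe_sd, self.patient_sd, self.sample_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


def _logit2(b):
    return np.log2(b / (1.0 - b))


def _expit2(m):
    return np.where(m >= 0, 1.0 / (1.0 + 2.0 ** (-m)), 2.0 ** m / (1.0 + 2.0 ** m))


def simulate_methylation(
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    effects: list[RegionEffect] | None = None,
    noise: MethylationNoise | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a Beta matrix for the sheet's methylation samples.

    Per-probe baselines are bimodal; patient and residual noise act on
    the M (log2-logit) scale; planted region effects shift Beta
    additively in the target group, clipped into (0, 1). Probes on chrY
    carry signal only in male samples (background Beta < 0.1 in
    females), which is what the sex caller exploits.
    """
    effects = list(effects or [])
    noise = noise or MethylationNoise()
    rng = np.random.default_rng(seed)
    meth = sheet[sheet["assay"].isin(["methylation", "both"])]
    samples = list(meth["sample_id"])
    n_probes, n_samples = len(manifest), len(samples)

    is_high = rng.random(n_probes) < noise.p_high
    mode_m = np.where(is_high, _logit2(noise.mode_high), _logit2(noise.mode_low))
    probe_mu = mode_m + rng.normal(0.0, noise.probe_sd, size=n_probes)

    patients = meth["patient_id"].to_numpy()
    uniq = pd.unique(patients)
    pat_eff = {
        p: rng.normal(0.0, noise.patient_sd, size=n_probes) for p in uniq
    }
    m = (
        probe_mu[:, None]
        + np.column_stack([pat_eff[p] for p in patients])
        + rng.normal(0.0, noise.sample_sd, size=(n_probes, n_samples))
    )
    beta = _expit2(m)

    # chrY background in female samples
    chry = manifest["chrom"].isin(["chrY", "Y"]).to_numpy()
    if chry.any():
        sex = meth["sex_true"] if "sex_true" in meth.columns else meth["sex"]
        female = (sex == "F").to_numpy()
        if female.any():
            bg = rng.uniform(0.01, 0.08, size=(int(chry.sum()), int(female.sum())))
            beta[np.ix_(chry, female)] = bg

    # planted region effects
    chrom_index = {
        c: manifest.index[manifest["chrom"] == c].to_numpy()
        for c in manifest["chrom"].unique()
    }
    claimed: set[int] = set()
    groups = meth["group"].to_numpy()
    for eff in effects:
        if eff.chrom not in chrom_index:
            raise ValueError(f"effect chromosome {eff.chrom!r} not in manifest")
        rows = chrom_index[eff.chrom]
        if eff.start_probe_index < 0 or eff.start_probe_index + eff.n_cpgs > len(rows):
            raise ValueError(
                f"effect at {eff.chrom}:{eff.start_probe_index} "
                f"(+{eff.n_cpgs} CpGs) exceeds manifest bounds"
            )
        idx = rows[eff.start_probe_index : eff.start_probe_index + eff.n_cpgs]
        if claimed & set(idx):
            raise ValueError("planted regions overlap")
        claimed.update(idx)
        target = groups == eff.target_group
        beta[np.ix_(idx, target)] += eff.delta_beta

    beta = np.clip(beta, _BETA_CLIP, 1.0 - _BETA_CLIP)
    return pd.DataFrame(beta, index=manifest["probe_id"].to_numpy(), columns=samples)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountBaseline:
    """Baseline for the negative-binomial count simulator.

    Gene means are log-normal (median ``exp(mean_log)``); the NB
    dispersion alpha enters as Var = mu + alpha * mu^2 and may itself be
    log-normally spread across genes. An explicit ``gene_means`` vector
    overrides the log-normal draw.
    """

    mean_log: float = float(np.log(200.0))
    mean_sigma: float = 1.2
    dispersion: float = 0.1
    dispersion_sigma: float = 0.0
    gene_means: np.ndarray | None = None

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def simulate_counts(
    genes: pd.DataFrame,
    sheet: pd.DataFrame,
    effects: list[GeneEffect] | None = None,
    baseline: CountBaseline | None = None,
    size_factor_spread: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a count matrix for the sheet's expression samples.

    counts[g, s] ~ NB(mean = mu_g * sf_s * 2^lfc_g(group_s), Var = mu +
    alpha_g mu^2) with log-normal size factors sf_s. chrY genes are
    silenced (mean 0) in female samples.
    """
    effects = list(effects or [])
    baseline = baseline or CountBaseline()
    if size_factor_spread < 0:
        raise ValueError("size_factor_spread must be >= 0")
    rng = np.random.default_rng(seed)
    expr = sheet[sheet["assay"].isin(["expression", "both"])]
    samples = list(expr["sample_id"])
    n_genes, n_samples = len(genes), len(samples)

    if baseline.gene_means is not None:
        mu_g = np.asarray(baseline.gene_means, dtype=float)
        if mu_g.shape != (n_genes,):
            raise ValueError("gene_means must have one entry per gene")
    else:
        mu_g = rng.lognormal(baseline.mean_log, baseline.mean_sigma, size=n_genes)
    if baseline.dispersion_sigma > 0:
        alpha_g = rng.lognormal(
            np.log(baseline.dispersion), baseline.dispersion_sigma, size=n_genes
        )
    else:
        alpha_g = np.full(n_genes, baseline.dispersion)
    sf = rng.lognormal(0.0, size_factor_spread, size=n_samples)

    lfc = np.zeros((n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes["gene_id"])}
    groups = expr["group"].to_numpy()
    for eff in effects:
        if eff.gene_id not in gene_pos:
            raise ValueError(f"effect gene {eff.gene_id!r} not in gene model")
        lfc[gene_pos[eff.gene_id], groups == eff.target_group] = eff.log2_fold_change

    mu = mu_g[:, None] * sf[None, :] * 2.0 ** lfc

    chry = genes["chrom"].isin(["chrY", "Y"]).to_numpy()
    if chry.any():
        sex = expr["sex_true"] if "sex_true" in expr.columns else expr["sex"]
        female = (sex == "F").to_numpy()
        mu[np.ix_(chry, female)] = 0.0

    counts = np.zeros((n_genes, n_samples), dtype=np.int64)
    pos = mu > 0
    if pos.any():
        a = np.broadcast_to(alpha_g[:, None], mu.shape)[pos]
        m = mu[pos]
        if np.all(a < 1e-8):
            counts[pos] = rng.poisson(m)
        else:
            counts[pos] = rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * m))
    return pd.DataFrame(counts, index=genes["gene_id"].to_numpy(), columns=samples)


# ---------------------------------------------------------------------------
# eQTM coupling
# ---------------------------------------------------------------------------


def couple_eqtm(
    beta: pd.DataFrame,
    counts: pd.DataFrame,
    couplings: list[Coupling],
    manifest: pd.DataFrame,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject shared latent factors so region methylation tracks gene counts.

    For each coupling a standard-normal latent u_s is drawn over the
    samples present in both matrices. Writing c = |r| / (1 - |r|), the
    latent is added to the region's Betas with scale sqrt(c * var(x0))
    and to log2 counts with scale sqrt(c * var(y0)) (sign-flipped for
    negative targets), which drives the realised correlation between
    region mean Beta and log2 counts to c / (1 + c) = |target_r| as the
    sample count grows. Counts stay integers, so correlations of exactly
    +/-1 hold only up to rounding.
    """
    if not couplings:
        return beta, counts
    shared = [s for s in beta.columns if s in set(counts.columns)]
    if len(shared) < 2:
        raise ValueError("need >= 2 samples shared between the matrices")
    rng = np.random.default_rng(seed)
    beta = beta.copy()
    counts = counts.copy()
    b = beta.to_numpy(dtype=float)
    y = counts.to_numpy(dtype=float)
    bcol = {s: i for i, s in enumerate(beta.columns)}
    ycol = {s: i for i, s in enumerate(counts.columns)}
    bs = np.array([bcol[s] for s in shared])
    ys = np.array([ycol[s] for s in shared])
    probe_row = {p: i for i, p in enumerate(beta.index)}
    chrom_probes = {
        c: manifest.loc[manifest["chrom"] == c, "probe_id"].to_numpy()
        for c in manifest["chrom"].unique()
    }
    for cp in couplings:
        if cp.gene_id not in counts.index:
            raise ValueError(f"coupling gene {cp.gene_id!r} not in count matrix")
        if cp.chrom not in chrom_probes:
            raise ValueError(f"coupling chromosome {cp.chrom!r} not in manifest")
        probes = chrom_probes[cp.chrom]
        if cp.start_probe_index < 0 or cp.start_probe_index + cp.n_cpgs > len(probes):
            raise ValueError("coupling region exceeds manifest bounds")
        pids = probes[cp.start_probe_index : cp.start_probe_index + cp.n_cpgs]
        try:
            rows = np.array([probe_row[p] for p in pids])
        except KeyError as exc:
            raise ValueError(f"coupling probe {exc} absent from Beta matrix")
        grow = counts.index.get_loc(cp.gene_id)

        u = rng.standard_normal(len(shared))
        x0 = b[np.ix_(rows, bs)].mean(axis=0)
        y0 = np.log2(y[grow, ys] + 1.0)
        vx = float(np.var(x0))
        vy = float(np.var(y0))
        absr = min(abs(cp.target_r), 1.0 - 1e-9)
        # variance ratio giving corr -> c/(1+c) = |target_r|; capped so
        # |target_r| = 1 stays numerically finite (then exactness comes
        # from a constant baseline, not an infinite ratio)
        c = min(absr / (1.0 - absr), 1e4)
        # constant baselines carry no variance to overwhelm: inject at a
        # fixed small scale and the link is exactly linear
        ax = np.sqrt(c * vx) if vx > 0 else 0.05
        ay = min(np.sqrt(c * vy) if vy > 0 else 1.0, 12.0)
        sign = 1.0 if cp.target_r >= 0 else -1.0
        b[np.ix_(rows, bs)] = np.clip(
            b[np.ix_(rows, bs)] + ax * u[None, :], _BETA_CLIP, 1.0 - _BETA_CLIP
        )
        y[grow, ys] = np.clip(
            np.rint(y[grow, ys] * 2.0 ** (sign * ay * u)), 0.0, 2.0**62
        )
    beta.loc[:, :] = b
    counts.loc[:, :] = y.astype(np.int64)
    return beta, counts


def planted_region_table(effects: list[RegionEffect], manifest: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth table (chrom, start, end, probes) for planted regions."""
    rows = []
    for eff in effects:
        sub = manifest[manifest["chrom"] == eff.chrom]
        probes = sub.iloc[eff.start_probe_index : eff.start_probe_index + eff.n_cpgs]
        rows.append(
            {
                "chrom": eff.chrom,
                "start": int(probes["pos"].iloc[0]),
                "end": int(probes["pos"].iloc[-1]),
                "n_cpgs": eff.n_cpgs,
                "delta_beta": eff.delta_beta,
                "target_group": eff.target_group,
                "probe_ids": ",".join(probes["probe_id"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_cpgs", "delta_beta",
            "target_group", "probe_ids",
        ],
    )
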