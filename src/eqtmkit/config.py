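"""Run configuration for the stage-wise pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Parameters for every pipeline stage plus input/output paths.

    When ``simulate`` is true the pipeline generates its own cohort
    (study-shaped design with planted effects) and ignores the input
    paths; otherwise manifest/sheet/matrix paths must be given.
    """

    outdir: str = "results"
    seed: int = 0
    simulate: bool = True

    # input paths (used when simulate is false)
    manifest_path: str | None = None
    gene_model_path: str | None = None
    sample_sheet_path: str | None = None
    beta_path: str | None = None
    counts_path: str | None = None
    clock_path: str | None = None

    # simulation sizes and planted effects
    n_probes: int = 4000
    n_genes: int = 1500
    n_planted_dmrs: int = 3
    planted_n_cpgs: int = 8
    planted_delta_beta: float = 0.15
    n_planted_degs: int = 5
    planted_lfc: float = 1.0
    n_couplings: int = 2
    coupling_target_r: float = -0.8

    # stage parameters
    epsilon: float = 1e-6
    n_components: int = 3
    contrast: tuple[str, str] = ("STEN", "NINF")
    covariates: tuple[str, ...] = ("passage", "age", "sex", "medication")
    blocking: str | None = "patient_id"
    max_gap_bp: int = 1000
    seed_alpha: float = 0.05
    min_cpgs: int = 3
    cpm_threshold: float = 1.0
    max_below: int | None = None
    B_bootstrap: int = 10_000
    B_null: int = 10_000
    alpha: float = 0.05
    log_base: float = 2.0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        self.contrast = tuple(self.contrast)
        self.covariates = tuple(self.covariates)
        if not self.simulate:
            required = {
                "manifest_path": self.manifest_path,
                "gene_model_path": self.gene_model_path,
                "sample_sheet_path": self.sample_sheet_path,
                "beta_path": self.beta_path,
                "counts_path": self.counts_path,
            }
            missing = [k for k, v in required.items() if not v]
            if missing:
                raise ValueError(
                    f"simulate=false requires input paths: {missing}"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["contrast"] = list(self.contrast)
        d["covariates"] = list(self.covariates)
        return d

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.as_dict(), sort_keys=True)
        return hashlib.sha1(text.encode()).hexdigest()[:12]
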