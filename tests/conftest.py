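import numpy as np
import pandas as pd
import pytest

from eqtmkit import synthetic
from eqtmkit.synthetic import GroupDesign


@pytest.fixture(scope="session")
def small_manifest():
    return synthetic.generate_manifest(
        300,
        {"chr1": 200_000, "chr2": 150_000, "chrY": 30_000},
        seed=11,
    )


@pytest.fixture(scope="session")
def study_sheet():
    return synthetic.generate_cohort(seed=7)


@pytest.fixture(scope="session")
def balanced_sheet():
    """10 vs 10 single-sample patients, both assays, for calibration tests."""
    design = [
        GroupDesign("STEN", n_meth=10, n_expr=10, n_shared=10, n_patients=10),
        GroupDesign("NINF", n_meth=10, n_expr=10, n_shared=10, n_patients=10),
    ]
    return synthetic.generate_cohort(design, seed=13)


@pytest.fixture(scope="session")
def small_genes():
    return synthetic.generate_gene_model(
        80, {"chr1": 200_000, "chr2": 150_000, "chrY": 30_000}, seed=5
    )


def make_manifest_one_chrom(positions, chrom="chr1"):
    """Hand-built manifest at explicit positions (no flags)."""
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:05d}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": list(positions),
            "snp_flag": False,
            "crossreactive_flag": False,
        }
    )
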