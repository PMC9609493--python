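import numpy as np
import pandas as pd
import pytest

from mrmediate.instruments import InstrumentSet


def make_iv(bx, sx, by, sy, snps=None) -> InstrumentSet:
    """Build a harmonized InstrumentSet directly from effect arrays."""
    bx = np.asarray(bx, float)
    n = len(bx)
    if snps is None:
        snps = [f"rs{i + 1:04d}" for i in range(n)]
    data = pd.DataFrame({
        "snp": snps,
        "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3,
        "beta_exposure": bx, "se_exposure": np.asarray(sx, float),
        "pval_exposure": 1e-10,
        "beta_outcome": np.asarray(by, float),
        "se_outcome": np.asarray(sy, float),
        "palindromic": False, "flipped": False, "eaf_missing": False,
    })
    return InstrumentSet(data=data, counts={"candidates": n})


@pytest.fixture
def iv_builder():
    return make_iv


@pytest.fixture
def simple_sumstats() -> pd.DataFrame:
    """Three well-formed SNP records in canonical form."""
    return pd.DataFrame({
        "snp": ["rs1", "rs2", "rs3"],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
        "eaf": [0.25, 0.4, np.nan],
        "beta": [0.11, -0.07, 0.032],
        "se": [0.01, 0.012, 0.008],
        "pval": [1e-28, 4e-9, 6.3e-5],
        "n": [10000.0, 10000.0, np.nan],
    })
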