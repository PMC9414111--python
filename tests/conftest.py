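import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_weights() -> pd.DataFrame:
    """Five-variant weights table with known MAF / imputation quality."""
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(1, 6)],
        "chrom": ["1", "2", "3", "4", "5"],
        "pos": [100, 200, 300, 400, 500],
        "effect_allele": ["A", "C", "G", "T", "A"],
        "other_allele": ["G", "T", "A", "C", "C"],
        "effect_allele_freq": [0.0005, 0.002, 0.3, 0.4, 0.0009],
        "imputation_r2": [0.9, 0.3, 0.9, 0.5, 0.9],
        "weight_maternal_adj": [0.02, -0.01, 0.03, 0.05, -0.02],
        "weight_fetal_adj": [0.01, 0.02, -0.03, 0.04, 0.00],
        "weight_fetal_unadj": [0.015, 0.025, -0.02, 0.05, 0.01],
    })


@pytest.fixture(scope="session")
def genotype_cohort():
    """Small genotype-mode cohort shared by pipeline-level tests."""
    from bwvar.config import preset_config
    from bwvar.simulate import simulate_cohort

    cfg = preset_config("m7", seed=42, n_trios=150).replace(n_snps=30)
    return simulate_cohort(cfg, mode="genotype")
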