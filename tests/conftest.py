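import numpy as np
import pytest

from dnamclocks.synthetic_data import SimulationConfig, inject_defects, simulate_cohort

ALL_DEFECTS = {
    "sex_swap": 1,
    "genotype_mismatch": 1,
    "pca_outlier": 1,
    "bad_sample_detp": 1,
    "low_conversion": 1,
}


@pytest.fixture(scope="session")
def qc_cohort():
    """Clean multi-region cohort with SNP and sex-chromosome probes."""
    cfg = SimulationConfig(n_donors=30, regions_per_donor=2, n_sites=400,
                           n_age_sites=20, n_snp_sites=30, sex_effect=True,
                           noise_sd=0.02, seed=5)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def defect_cohort(qc_cohort):
    """Same cohort with one of each QC defect planted."""
    return inject_defects(qc_cohort, ALL_DEFECTS, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
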