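import numpy as np
import pandas as pd
import pytest

from sexlink import GenotypeMatrix, SampleSheet, SimConfig, simulate_dataset
from sexlink.matrix import MISSING


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    """4 males + 4 females in two populations."""
    return SampleSheet(pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(8)],
        "sex": ["male"] * 4 + ["female"] * 4,
        "population_id": ["P1", "P1", "P2", "P2"] * 2,
    }))


@pytest.fixture
def tiny_pa(tiny_sheet) -> GenotypeMatrix:
    """3 PA loci: male-specific, female-specific, uniform-present."""
    calls = np.array([
        [1, 1, 1, 1, 0, 0, 0, 0],
        [0, 0, 0, 0, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1, 1],
    ], dtype=np.int8)
    return GenotypeMatrix(calls, ["L1", "L2", "L3"], tiny_sheet.sample_ids, "PA")


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free simulated cohort (40M/35F) with planted structure."""
    config = SimConfig(seed=101, n_snp=120, n_pa=120, n_specific=10,
                       linked_spec=((10, 0.1),), missing_rate=0.0,
                       genotype_error_rate=0.0)
    snp, pa, sheet, truth = simulate_dataset(config)
    return config, snp, pa, sheet, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Cohort with the default error/missingness and 200 planted loci."""
    config = SimConfig(seed=202, n_snp=1000, n_pa=1000, n_specific=50,
                       linked_spec=((50, 0.05), (50, 0.15), (50, 0.25)),
                       missing_rate=0.05, genotype_error_rate=0.01)
    snp, pa, sheet, truth = simulate_dataset(config)
    return config, snp, pa, sheet, truth
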