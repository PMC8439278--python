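import numpy as np
import pandas as pd
import pytest

from mrscore import SimulationConfig, simulate_cohort
from mrscore.containers import GenotypeMatrix


@pytest.fixture(scope="session")
def small_null_cohort():
    """Two-dataset null cohort (no causal effect, no pleiotropy)."""
    cfg = SimulationConfig(
        n_variants=20, n_datasets=2,
        n_cases_per_dataset=300, n_controls_per_dataset=300, seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_genotypes():
    """Deterministic 6-sample x 3-variant matrix with one missing entry."""
    dos = np.array([
        [0.0, 1.0, 2.0],
        [1.0, 1.0, 0.0],
        [2.0, 0.0, 1.0],
        [0.0, np.nan, 2.0],
        [1.0, 2.0, 0.0],
        [2.0, 1.0, 1.0],
    ])
    variants = pd.DataFrame(dict(
        rsid=["rs1", "rs2", "rs3"],
        chrom=["1", "2", "3"],
        pos=[100, 200, 300],
        ref=["A", "A", "A"],
        alt=["G", "G", "G"],
    ))
    return GenotypeMatrix(dosages=dos, sample_ids=[f"s{i}" for i in range(6)],
                         variants=variants)
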