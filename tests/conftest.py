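import numpy as np
import pandas as pd
import pytest

from pediclocks.simulate import (
    SimulationConfig,
    make_consistent_clock,
    simulate_cell_reference,
    simulate_cohort,
)
from pediclocks.types import BetaMatrix, SampleSheet


@pytest.fixture
def toy_beta() -> BetaMatrix:
    """3 probes x 2 samples, one missing value."""
    df = pd.DataFrame(
        {"s1": [0.1, 0.5, 0.9], "s2": [0.2, np.nan, 0.8]},
        index=["cg01", "cg02", "cg03"],
    )
    return BetaMatrix(df)


@pytest.fixture
def toy_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {"age_years": [4.0, 10.5], "tissue": ["blood", "blood"]},
            index=pd.Index(["s1", "s2"], name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def linear_cohort():
    """Noiseless linear-link cohort with its exactly consistent clock."""
    cfg = SimulationConfig(n_samples=200, beta_noise_sd=0.0, link="linear", seed=11)
    beta, sheet, truth = simulate_cohort(cfg)
    clock = make_consistent_clock(truth)
    return beta, sheet, truth, clock


@pytest.fixture(scope="session")
def blood_reference():
    return simulate_cell_reference(n_probes=200, seed=42)
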