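import numpy as np
import pytest

from regionchart.fitting import fit_reference_model
from regionchart.synthetic import SimulationConfig, generate_reference_population

#: a small region subset spanning both metrics and several lobes,
#: used by unit tests that need a fitted model but not all 72 regions
UNIT_REGIONS = [
    "lh_superiorfrontal", "lh_middletemporal", "rh_precuneus",
    "Left-Hippocampus", "Right-Amygdala",
]


@pytest.fixture(scope="session")
def small_ref():
    """3-batch reference cohort (n=1,800) with retained truth."""
    cfg = SimulationConfig(n_batches=3, subjects_per_batch=600, seed=314)
    return generate_reference_population(cfg)


@pytest.fixture(scope="session")
def small_model(small_ref):
    cohort, _truth = small_ref
    return fit_reference_model(cohort, regions=UNIT_REGIONS, min_n=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
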