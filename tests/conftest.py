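import numpy as np
import pandas as pd
import pytest

from mcisurv.io import region_columns
from mcisurv.simulate import SimulationConfig, simulate_cohort
from mcisurv.volumetrics import load_catalog, zscore_to_reference


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """A small, fully reproducible cohort with its truth table."""
    cfg = SimulationConfig(n_subjects=120, seed=77, group_fractions=(0.25, 0.25, 0.25, 0.25))
    cohort, truth = simulate_cohort(cfg, catalog)
    return cohort, truth


@pytest.fixture(scope="session")
def small_z(small_cohort, catalog):
    cohort, _ = small_cohort
    vols = cohort.set_index("subject_id")[region_columns(cohort)]
    return zscore_to_reference(vols, catalog.reference())
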