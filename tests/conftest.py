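import numpy as np
import pandas as pd
import pytest

from rametab import SimulationConfig, simulate_cohort
from rametab.preprocess import preprocess


def small_config(**overrides):
    """A reduced cohort that keeps the full statistical structure."""
    base = dict(n_patients=16, n_validation_patients=6, n_metabolites=40,
                n_causal=3, n_visit_shift=2, n_treatment_effect=1,
                acylcarnitine_size=8, seed=11)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_processed(small_bundle):
    abundance, meta, annotation, truth = small_bundle
    processed, removed = preprocess(abundance)
    return processed, meta, annotation, truth


@pytest.fixture(scope="session")
def discovery(small_processed):
    processed, meta, annotation, truth = small_processed
    mask = meta["cohort"] == "discovery"
    return processed.loc[mask], meta.loc[mask], annotation, truth


@pytest.fixture()
def toy_matrix():
    return pd.DataFrame(
        {"m1": [2.0, 4.0, 6.0], "m2": [2.0, np.nan, 6.0],
         "m3": [1.0, 1.0, 1.0]},
        index=["s1", "s2", "s3"])
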