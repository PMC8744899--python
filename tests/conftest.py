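import numpy as np
import pytest

from arealsurv import (
    McmcConfig,
    SimulationConfig,
    build_design,
    generate,
    sample_posterior,
    validate_records,
)


@pytest.fixture(scope="session")
def small_dataset():
    """8-area synthetic dataset, large enough to fit but quick."""
    ds = generate(SimulationConfig(n_areas=8, children_per_area_mean=80, seed=42))
    records = validate_records(ds.records, ds.graph)
    design = build_design(records)
    return ds, records, design


@pytest.fixture(scope="session")
def small_chains_spatial(small_dataset):
    ds, records, design = small_dataset
    cfg = McmcConfig(n_iterations=1600, burn_in=600, thinning=2, seed=7)
    return sample_posterior(records, design, ds.graph, None, cfg)


@pytest.fixture(scope="session")
def small_chains_nonspatial(small_dataset):
    _, records, design = small_dataset
    cfg = McmcConfig(n_iterations=1600, burn_in=600, thinning=2, seed=7)
    return sample_posterior(records, design, None, None, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
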