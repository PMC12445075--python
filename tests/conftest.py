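import dataclasses

import numpy as np
import pytest

import stressig as sg

SMALL = dict(
    # reduced gene universe for fast generator runs; planted structure intact
    # (kept large enough that planted genes stay a minority, so
    # median-of-ratios normalization remains well-anchored)
    n_genes=600, n_enhancers=30, n_condition_private=5,
    n_background_peaks=50, n_cells=400,
)


@pytest.fixture(scope="session")
def default_config() -> sg.SimConfig:
    return sg.SimConfig(seed=1)


@pytest.fixture(scope="session")
def small_config() -> sg.SimConfig:
    return sg.SimConfig(seed=1, **SMALL)


@pytest.fixture(scope="session")
def reference(default_config) -> sg.Reference:
    return sg.synthdata.simulate_reference(default_config)


@pytest.fixture(scope="session")
def small_reference(small_config) -> sg.Reference:
    return sg.synthdata.simulate_reference(small_config)


@pytest.fixture(scope="session")
def cohort(default_config, reference):
    return sg.synthdata.simulate_bulk_cohort(default_config, reference)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def replace(cfg: sg.SimConfig, **kwargs) -> sg.SimConfig:
    return dataclasses.replace(cfg, **kwargs)
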