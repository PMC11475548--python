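from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from equitrb.simulate import SimConfig, TrimP, build_default_germline, simulate_repertoire


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    """The default study conditions with a fixed session seed."""
    return SimConfig(seed=101)


@pytest.fixture(scope="session")
def germline(sim_config):
    """One verified germline build shared by the whole session."""
    return build_default_germline(sim_config)


@pytest.fixture(scope="session")
def default_sim(sim_config, germline):
    """A medium default-condition simulation reused across tests."""
    return simulate_repertoire(sim_config, 800, germline=germline)


@pytest.fixture(scope="session")
def degenerate_sim(sim_config, germline):
    """Trimming, N-addition and errors disabled: junctions are exact
    germline concatenations."""
    cfg = dataclasses.replace(
        sim_config, trim_geometric_p=TrimP(1.0, 1.0, 1.0, 1.0),
        n_insert_length_dist={0: 1.0}, substitution_error_rate=0.0)
    return simulate_repertoire(cfg, 500, germline=germline)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
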