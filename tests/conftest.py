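"""Shared fixtures: one small synthetic world reused across test modules."""

import warnings

import pytest

from gonadpi.config import SimConfig
from gonadpi.simulate import build_world, simulate_libraries


SMALL = dict(
    n_genes=120, n_pirna=600, depth_per_library=6000,
    n_mirna=30, n_ncrna=24, n_repeat=16, n_other=40,
    transcript_length_range=(200, 2000),
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_world(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_world(small_config)


@pytest.fixture(scope="session")
def small_libraries(small_config, small_world, tmp_path_factory):
    out = tmp_path_factory.mktemp("libs")
    paths, counts = simulate_libraries(small_config, small_world.truth, out)
    return paths, counts
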