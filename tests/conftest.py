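import numpy as np
import pytest

from polca import ParameterSet, build_molecule, build_topology


@pytest.fixture(scope="session")
def params():
    return ParameterSet.default()


@pytest.fixture(scope="session")
def topologies(params):
    """Cache of built topologies for the registry compounds used in tests."""
    cache = {}

    def _get(name):
        if name not in cache:
            cache[name] = build_topology(build_molecule(name), params)
        return cache[name]

    return _get


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
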