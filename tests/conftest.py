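import numpy as np
import pytest

from invertasome.synthetic import (FixtureSpec, make_toy_components,
                                   make_enhancer_model,
                                   make_substrate_geometry)
from invertasome.docking import AssemblyConfig, assemble_invertasome


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def enhancer(spec):
    return make_enhancer_model(spec)


@pytest.fixture(scope="session")
def substrate(spec):
    return make_substrate_geometry(spec)


def _assembly(spec, enhancer, state):
    cfg = AssemblyConfig(enhancer=enhancer, layout=spec.layout,
                         components=make_toy_components(spec, state))
    return assemble_invertasome(cfg, state)


@pytest.fixture(scope="session")
def cleaved(spec, enhancer):
    return _assembly(spec, enhancer, "cleaved")


@pytest.fixture(scope="session")
def pre_cleaved(spec, enhancer):
    return _assembly(spec, enhancer, "pre_cleaved")


@pytest.fixture(scope="session")
def dimer_docked(spec, enhancer):
    return _assembly(spec, enhancer, "dimer_docked")
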