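import numpy as np
import pytest

import cellgrammar as cg
from cellgrammar import grammar
from cellgrammar.agents import CellDefinition, Population
from cellgrammar.microenv import Microenvironment, Substrate


@pytest.fixture(scope="session")
def example_rules():
    """The five bundled detailed-statement listings, parsed."""
    out = {}
    for i in range(1, 6):
        path = cg.example_path(f"example{i}.txt")
        with open(path) as fh:
            out[i] = grammar.parse_statements_text(fh.read(), source=path)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_oxygen_env():
    """Small mesh with a uniform 38 mmHg oxygen field."""
    env = Microenvironment((-100, 100, -100, 100), voxel_size=20.0)
    env.add_substrate(Substrate("oxygen", diffusion=1e5, decay=0.0, initial=38.0))
    return env


@pytest.fixture
def small_population():
    defs = [
        CellDefinition("tumor", behaviors={"cycle entry": 1.7e-5,
                                           "necrosis": 0.0028}),
        CellDefinition("CD8 T cell", behaviors={"migration speed": 1.0,
                                                "attack tumor": 0.1,
                                                "damage rate": 1.8}),
    ]
    return Population(defs)
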