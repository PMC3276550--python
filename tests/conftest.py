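import numpy as np
import pytest

from spinesim import configuration as cfgmod
from spinesim import geometry
from spinesim.network import (ReactionNetwork, SpeciesSpec, load_default_network,
                              parse_row)


@pytest.fixture(scope="session")
def network():
    return load_default_network()


@pytest.fixture(scope="session")
def short_mesh():
    return geometry.build_short_dendrite(0.3)


@pytest.fixture(scope="session")
def desk_mesh():
    return geometry.build_short_dendrite(0.3, preset="desk")


@pytest.fixture(scope="session")
def long_mesh():
    return geometry.build_long_dendrite()


def make_network(rows_text: str, species: dict[str, float] | None = None):
    """Small helper: build a network from reaction rows (D per species)."""
    rows = [parse_row(line) for line in rows_text.strip().splitlines()
            if line.strip() and not line.strip().startswith("#")]
    if species is None:
        names: list[str] = []
        for row in rows:
            for group in (row.reactants, row.products, row.complex_products):
                for name, _ in group:
                    if name not in names:
                        names.append(name)
            if row.complex_species and row.complex_species not in names:
                names.append(row.complex_species)
        specs = [SpeciesSpec(n) for n in names]
    else:
        specs = [SpeciesSpec(n, D=d) for n, d in species.items()]
    return ReactionNetwork(specs, rows)


@pytest.fixture(scope="session")
def default_config():
    return cfgmod.SpatialConfig()
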