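"""Shared fixtures: tiny registries, known-answer cases, and a small
synthetic network cheap enough for every test that needs a full pipeline."""

from __future__ import annotations

import pytest
from hypothesis import settings

from shippath import PathwayModel
from shippath.io import PortRecord, VoyageRoute
from shippath.synthetic import SyntheticNetworkConfig, generate_known_answer_case, generate_network

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_registry():
    return [
        PortRecord("A", "Alpha", "AA"),
        PortRecord("B", "Bravo", "BB"),
        PortRecord("C", "Charlie", "AA"),
        PortRecord("D", "Delta", "AUS", is_domestic=True),
    ]


def voyage(calls, ship="S1", vid="V1", date="2004-06-01"):
    return VoyageRoute(ship_id=ship, voyage_id=vid, arrival_date=date, calls=list(calls))


@pytest.fixture(scope="session")
def chain3_case():
    return generate_known_answer_case("chain3")


@pytest.fixture(scope="session")
def corridor6_case():
    return generate_known_answer_case("corridor6")


@pytest.fixture(scope="session")
def small_network():
    """A ~30-port generated network with all pipeline structure present."""
    config = SyntheticNetworkConfig(
        n_foreign_ports=25,
        n_domestic_ports=5,
        n_countries=8,
        n_ships=10,
        n_voyages=150,
        hub_fraction=0.08,
        pest_country_fraction=0.5,
        pest_extra_countries=2,
        seed=7,
    )
    registry, routes, pest_range = generate_network(config)
    return config, registry, routes, pest_range


@pytest.fixture(scope="session")
def small_model(small_network):
    _, registry, routes, pest_range = small_network
    return PathwayModel(routes, registry, pest_range)
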