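"""Shared fixtures and world-builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from denialsim.network import TieStore
from denialsim.params import ParameterSet, default_parameter_set
from denialsim.population import World, initialize_population

NEG = -(10**6)


def zeroed_params(n: int = 200, seed: int = 0, **overrides) -> ParameterSet:
    """A parameter set whose behavior/outcome probabilities are all ~0.

    Useful for hand-built scenarios: individual tables are then re-enabled
    with forced intercepts (+/-30 gives probabilities of 1 or 0 to within
    1e-13).
    """
    ps = default_parameter_set(seed=seed, scale=1.0)
    ps.population_size = n
    ps.scale = min(1.0, n / 800_000)
    side = max(10, int(round(np.sqrt(n / 5.0))))
    ps.grid_width = ps.grid_height = side
    ps.n_neighborhoods = min(ps.n_neighborhoods, max(1, n // 10))
    for t in ps.tables.values():
        t.intercept = -30.0
        t.terms = []
    ps.mortality_table = [[float(a), 0.0, 0.0] for a in range(18, 111)]
    ps.police_per_neighborhood = 0
    for k, v in overrides.items():
        setattr(ps, k, v)
    ps.validate()
    return ps


def make_world(ps: ParameterSet, seed: int = 0, ties: bool = True) -> World:
    from denialsim.network import build_social_network

    w = initialize_population(ps, seed)
    if ties:
        build_social_network(w, ps)
    else:
        w.ties = TieStore.from_edges(np.empty((0, 2)), np.zeros(ps.population_size), ps.population_size)
    return w


def place_agents(world: World, coords: list[tuple[int, int]]) -> None:
    """Pin the first len(coords) agents to explicit grid cells."""
    for i, (x, y) in enumerate(coords):
        world.x[i] = x
        world.y[i] = y


def force_table(ps: ParameterSet, name: str, prob: float) -> None:
    """Make one outcome fire with (approximately) the given probability."""
    from denialsim.params import logit

    ps.tables[name].terms = []
    if prob <= 0:
        ps.tables[name].intercept = -30.0
    elif prob >= 1:
        ps.tables[name].intercept = 30.0
    else:
        ps.tables[name].intercept = logit(prob)


@pytest.fixture(scope="session")
def default_params_small():
    """Default parameterization at desk scale (shared, read-only)."""
    return default_parameter_set(seed=0, scale=1 / 32)


@pytest.fixture(scope="session")
def tiny_world_factory():
    def factory(n=200, seed=0, **overrides):
        ps = zeroed_params(n=n, seed=seed, **overrides)
        return ps, make_world(ps, seed=seed)

    return factory
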