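"""Shared fixtures: small models used across the suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from hrdme.model import ReactionChannel, ReactionModel, SolverConfig, Species


@pytest.fixture(autouse=True)
def _quiet_subcritical_mesh_warnings():
    # the benchmark fixtures deliberately run at (slightly below) h*
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*below the critical mesh size.*")
        yield


@pytest.fixture(scope="session")
def rebind_model():
    from hrdme.fixtures import fixture

    return fixture("rebind")


@pytest.fixture(scope="session")
def single_layer_model():
    from hrdme.fixtures import fixture

    return fixture("single_layer")


def make_pair_model(
    n_levels: int = 3,
    radius: float = 0.03,
    k: float = 10.0,
    D: tuple[float, float] = (1.0, 1.0),
    reversible: float = 0.0,
    initial=None,
) -> ReactionModel:
    """A + B -> C (optionally reversible) on a small hierarchy."""
    reactions = [ReactionChannel(("A", "B"), ("C",), k)]
    if reversible > 0:
        reactions.append(ReactionChannel(("C",), ("A", "B"), reversible))
    m = ReactionModel(
        [Species("A", D[0], radius), Species("B", D[1], radius),
         Species("C", 0.0, radius)],
        reactions,
        volume=1.0, n_levels=n_levels,
        initial=dict(initial or {"A": 1, "B": 1}),
        solver=SolverConfig(),
    )
    m.resolve(assign_levels=False)
    return m


def pure_diffusion_model(n_levels: int, level: int, n: int = 1,
                         D: float = 1.0) -> ReactionModel:
    """A single inert species, pinned to ``level``."""
    m = ReactionModel([Species("A", D, 0.0)], [], volume=1.0,
                      n_levels=n_levels, initial={"A": n},
                      solver=SolverConfig())
    m.resolve(assign_levels=False)
    m.species[0].finest_level = level
    return m


@pytest.fixture
def pair_model():
    return make_pair_model()
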