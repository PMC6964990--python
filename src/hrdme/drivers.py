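"""High-level drivers: trajectory ensembles and the rebinding benchmark.

Child seeds for the trajectories of an ensemble are derived from the
master seed with :class:`numpy.random.SeedSequence`, so ensembles with
different master seeds are statistically independent and a fixed master
seed reproduces the whole ensemble exactly.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

from .coupling import TransferPolicy
from .engine import SimulationState, Trajectory, initialize
from .model import ReactionModel
from .observables import RebindSample, collect_rebinds
from .reference import npm_single_mesh_state

__all__ = ["child_seeds", "run_ensemble", "rebind_sample"]


def child_seeds(seed: int, n: int) -> np.ndarray:
    """``n`` independent 31-bit seeds derived from ``seed``."""
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def run_ensemble(
    model: ReactionModel,
    n_trajectories: int,
    t_final: float,
    sample_times: Sequence[float] | None = None,
    seed: int = 0,
    single_mesh_level: int | None = None,
    make_state: Callable[[int], SimulationState] | None = None,
    **init_kwargs,
) -> list[Trajectory]:
    """Independent trajectories of ``model`` (hierarchical by default).

    ``single_mesh_level`` switches to the pinned single-mesh reference
    mode; ``make_state`` overrides state construction entirely.
    """
    if make_state is None:
        if single_mesh_level is None:
            def make_state(s: int) -> SimulationState:
                return initialize(model, seed=s, **init_kwargs)
        else:
            def make_state(s: int) -> SimulationState:
                return npm_single_mesh_state(model, single_mesh_level,
                                             seed=s, **init_kwargs)
    out = []
    for s in child_seeds(seed, n_trajectories):
        out.append(make_state(int(s)).run(t_final, sample_times=sample_times))
    return out


def rebind_sample(
    model: ReactionModel,
    n_events: int,
    seed: int = 0,
    C: float | None = None,
    single_mesh_level: int | None = None,
    chunk_events: int = 2_000_000,
) -> RebindSample:
    """Rebinding times of the model's reversible pair.

    Runs one long trajectory until at least ``n_events`` completed
    dissociation -> re-association cycles are on the event log.  ``C``
    overrides the transfer constant; ``single_mesh_level`` runs the pinned
    single-mesh reference instead of the hierarchy.
    """
    if single_mesh_level is not None:
        state = npm_single_mesh_state(model, single_mesh_level, seed=seed,
                                      log_reactions=True)
    else:
        policy = TransferPolicy(C=C if C is not None else model.solver.C)
        state = initialize(model, seed=seed, transfer_policy=policy,
                           log_reactions=True)
    while True:
        state.advance_events(chunk_events, math.inf)
        # each completed cycle logs one dissociation and one association
        if state._k.rl_n[0] >= 2 * n_events:
            sample = collect_rebinds(state.reaction_log(), state.model)
            if len(sample) >= n_events:
                return RebindSample(sample.durations[:n_events])
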