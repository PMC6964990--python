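"""Reference solvers: a well-mixed direct-method SSA and single-mesh runs.

These are the oracles the hierarchical solver is validated against.  The
well-mixed SSA samples the chemical master equation directly (Gillespie's
direct method) and is an entirely independent code path from the event
kernel.  ``npm_single_mesh`` pins every species to one mesh level and
disables transfers, turning the hierarchical engine into a plain
single-mesh next-particle solver — same code path, flags only — which
serves as the fine-grained reference for resolution sweeps and the
rebinding benchmark.

By default the well-mixed bimolecular propensity uses the mesoscopic rate
at ``h = V**(1/3)``, i.e. exactly the rate the coarsest hierarchy level
reacts with, so a one-level hierarchical run and the SSA sample the same
master equation.  Pure mass-action ``k/V`` is available behind a flag.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .engine import SimulationState, Trajectory, initialize
from .model import ReactionModel

__all__ = ["ssa_run", "npm_single_mesh", "npm_single_mesh_state"]


def _propensities(model: ReactionModel, x: np.ndarray,
                  rates: np.ndarray) -> np.ndarray:
    a = np.empty(len(model.reactions))
    for c, r in enumerate(model.reactions):
        if r.order == 0:
            a[c] = rates[c]
        elif r.order == 1:
            a[c] = rates[c] * x[model.species_index(r.reactants[0])]
        else:
            i, j = (model.species_index(n) for n in r.reactants)
            if i == j:
                a[c] = rates[c] * x[i] * (x[i] - 1) / 2.0
            else:
                a[c] = rates[c] * x[i] * x[j]
    return a


def ssa_run(model: ReactionModel, t_final: float,
            sample_times: Sequence[float] | None = None, seed: int = 0,
            mass_action: bool = False, check_propensities: bool = False) -> Trajectory:
    """Gillespie direct-method trajectory of the well-mixed model.

    The next event fires after an Exp(sum a_r) waiting time and the channel
    is chosen proportionally to its propensity.  With
    ``check_propensities`` the incrementally updated propensities are
    compared against a from-scratch recomputation after every firing.
    """
    if not model.resolved:
        model.resolve()
    ns = len(model.species)
    if sample_times is None:
        sample_times = np.linspace(0.0, t_final, model.solver.n_samples + 1)
    sample_times = np.asarray(sample_times, dtype=float)
    rates = np.empty(len(model.reactions))
    for c, r in enumerate(model.reactions):
        if r.order == 2:
            rates[c] = r.k_micro / model.volume if mass_action \
                else r.k_meso_by_level[0]
        else:
            rates[c] = r.k_micro
    stoich = np.zeros((len(model.reactions), ns), dtype=np.int64)
    touches = []
    for c, r in enumerate(model.reactions):
        for n in r.reactants:
            stoich[c, model.species_index(n)] -= 1
        for n in r.products:
            stoich[c, model.species_index(n)] += 1
        touches.append(sorted({model.species_index(n)
                               for n in (*r.reactants, *r.products)}))
    dependent = [
        [c2 for c2, r2 in enumerate(model.reactions)
         if r2.order > 0 and any(model.species_index(n) in touches[c]
                                 for n in r2.reactants)]
        for c in range(len(model.reactions))
    ]

    rng = np.random.default_rng(seed)
    x = np.zeros(ns, dtype=np.int64)
    for name, count in model.initial.items():
        x[model.species_index(name)] = count
    a = _propensities(model, x, rates)
    t = 0.0
    counts = np.empty((sample_times.size, ns), dtype=np.int64)
    si = 0
    while True:
        a_tot = a.sum()
        t_next = t + rng.exponential(1.0 / a_tot) if a_tot > 0 else np.inf
        while si < sample_times.size and sample_times[si] < t_next:
            counts[si] = x
            si += 1
        if si >= sample_times.size or t_next > t_final:
            break
        t = t_next
        c = int(np.searchsorted(np.cumsum(a), rng.random() * a_tot))
        x += stoich[c]
        for c2 in dependent[c]:
            r2 = model.reactions[c2]
            if r2.order == 1:
                a[c2] = rates[c2] * x[model.species_index(r2.reactants[0])]
            else:
                i, j = (model.species_index(n) for n in r2.reactants)
                a[c2] = rates[c2] * (x[i] * (x[i] - 1) / 2.0 if i == j
                                     else x[i] * x[j])
        if check_propensities:
            fresh = _propensities(model, x, rates)
            if not np.allclose(a, fresh):
                raise AssertionError("incremental propensities diverged "
                                     f"at t={t}: {a} vs {fresh}")
    return Trajectory(sample_times.copy(), counts,
                      [s.name for s in model.species], int(seed))


def npm_single_mesh_state(model: ReactionModel, level: int, seed: int = 0,
                          **kwargs) -> SimulationState:
    """Initialized state with every species pinned to ``level`` and
    fine-to-coarse transfers disabled."""
    from .coupling import TransferPolicy

    pinned = model.pinned(level)
    return initialize(pinned, seed=seed,
                      transfer_policy=TransferPolicy(C=pinned.solver.C,
                                                     enabled=False),
                      **kwargs)


def npm_single_mesh(model: ReactionModel, level: int, t_final: float,
                    sample_times: Sequence[float] | None = None,
                    seed: int = 0, **kwargs) -> Trajectory:
    """Single-mesh next-particle trajectory at the given level."""
    state = npm_single_mesh_state(model, level, seed=seed, **kwargs)
    return state.run(t_final, sample_times=sample_times)
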