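"""Transfers of molecules between mesh levels and product placement.

Fine-to-coarse: a molecule born on (or transferred to) a level must first
become well-mixed on the length scale of its current voxels before it may
be coarsened.  It is promoted to the parent voxel one level up once it has
diffused for

    t_transfer = (C * h)**2 / (6 * D)

i.e. once its RMS displacement is a multiple ``C`` of the current voxel
width ``h``.  ``C = 20`` is a conservative default that preserves
fine-scale rebinding statistics; ``C = 1`` already suffices for many
systems.  Promotion only happens immediately after a diffusion event has
fired (before new tentative events are sampled), which avoids biasing the
event queue and costs nothing extra: a transfer is itself "like a diffusion
event" and forces the same resampling.

Coarse-to-fine: demotion never happens spontaneously.  Reaction products
whose species require a finer mesh than the reacting molecule's level are
placed in a uniformly sampled descendant of the reactant voxel; products of
one dissociation that target the *same* level share a single sampled voxel
(this co-placement is what preserves fast rebinding after a dissociation).
Products targeting a coarser level go to the unique ancestor voxel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mesh import MeshHierarchy, VoxelRef
from .model import ReactionModel, Species

__all__ = ["TransferPolicy", "transfer_time", "maybe_promote", "place_products"]


@dataclass(frozen=True)
class TransferPolicy:
    """Fine-to-coarse transfer settings.

    C
        Dimensionless transfer constant: the multiple of the voxel width a
        molecule must diffuse (RMS) before promotion one level up.
    enabled
        When False no promotion ever fires (single-mesh mode).
    """

    C: float = 20.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"transfer constant C must be positive, got {self.C}")

    def table(self, model: ReactionModel, hierarchy: MeshHierarchy) -> np.ndarray:
        """(n_species, n_levels) array of transfer times for the kernel."""
        out = np.empty((len(model.species), hierarchy.n_levels))
        for i, s in enumerate(model.species):
            for l in range(hierarchy.n_levels):
                if not self.enabled:
                    out[i, l] = math.inf
                else:
                    out[i, l] = transfer_time(s.D, float(hierarchy.widths[l]), self.C)
        return out


def transfer_time(D: float, h: float, C: float) -> float:
    """Time to diffuse an RMS distance ``C*h``: ``(C*h)**2 / (6*D)``.

    Infinite for an immobile species (D = 0): it is never promoted.
    """
    if D < 0 or h <= 0 or C <= 0:
        raise ValueError(f"bad arguments D={D}, h={h}, C={C}")
    if D == 0.0:
        return math.inf
    return (C * h) ** 2 / (6.0 * D)


def maybe_promote(
    voxel: VoxelRef,
    t_since_transfer: float,
    D: float,
    hierarchy: MeshHierarchy,
    policy: TransferPolicy,
) -> tuple[VoxelRef, float, int]:
    """Promotion rule applied after a diffusion event.

    While the molecule has diffused at least ``t_transfer`` of its current
    level and is not yet on level 0, move it to the parent voxel and reset
    its diffusion clock.  Returns ``(voxel, t_since_transfer, n_promoted)``.
    In practice at most one promotion fires per call because the clock
    resets, but the loop keeps the rule self-contained.

    This mirrors the arithmetic used inside the simulation kernel; the
    caller (the event loop) must resample the molecule's diffusion and
    bimolecular events after any promotion.
    """
    n = 0
    while (
        policy.enabled
        and voxel.level > 0
        and t_since_transfer
        >= transfer_time(D, float(hierarchy.widths[voxel.level]), policy.C)
    ):
        voxel = hierarchy.parent(voxel)
        t_since_transfer = 0.0
        n += 1
    return voxel, t_since_transfer, n


def place_products(
    products: list[Species],
    reactant_voxel: VoxelRef,
    hierarchy: MeshHierarchy,
    rng: np.random.Generator,
) -> list[tuple[Species, VoxelRef]]:
    """Voxels for reaction products born at their species' finest levels.

    Relative to the reacting molecule's voxel: an equal target level is an
    identity placement; a coarser target is the unique ancestor; a finer
    target is a uniformly sampled descendant (iterated uniform child
    choice).  Products of the same reaction that target the same level are
    co-placed in one sampled voxel.  Every placed product starts with a
    fresh diffusion clock.
    """
    placed: dict[int, VoxelRef] = {}
    out = []
    for s in products:
        if s.finest_level is None:
            raise ValueError(f"species {s.name} has no assigned level; resolve first")
        target = s.finest_level
        if target not in placed:
            if target == reactant_voxel.level:
                v = reactant_voxel
            elif target < reactant_voxel.level:
                v = hierarchy.ancestor_at(reactant_voxel, target)
            else:
                v = reactant_voxel
                for _ in range(target - reactant_voxel.level):
                    v = hierarchy.children(v)[rng.integers(8)]
            placed[target] = v
        out.append((s, placed[target]))
    return out
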