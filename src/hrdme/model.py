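"""Reaction models: species, channels, rate tables and level assignment.

A :class:`ReactionModel` collects species (diffusion constant, reaction
radius), reaction channels of order 0/1/2 with microscopic rates, the cubic
domain, and solver settings.  :meth:`ReactionModel.resolve` turns it into a
simulation-ready object: per-channel summed radii and diffusion constants,
per-level mesoscopic rates (for every bimolecular channel and every mesh
level), and each species' *finest level* — the finest mesh it is ever
simulated on.

Level assignment follows the admissible-mesh criterion: a voxel width ``h``
is admissible for a bimolecular channel when

    k_micro / (1 + eps) < k_meso(h) * h**3

(equivalently ``W(h) < eps``), and a species is assigned the *coarsest*
level admissible for every bimolecular channel it participates in.  Species
with no bimolecular involvement live on the coarsest level (level 0) —
their products may still be born on finer levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .mesh import MeshHierarchy
from .rates import RateConfig, critical_mesh_size, meso_rate

__all__ = [
    "Species",
    "ReactionChannel",
    "SolverConfig",
    "ReactionModel",
    "assign_species_levels",
    "load_model",
    "save_model",
]

log = logging.getLogger(__name__)


@dataclass
class Species:
    """A chemical species.

    D
        Diffusion constant (length^2/time), >= 0.
    radius
        Reaction radius (length); must be positive for any species that
        appears as a reactant of a bimolecular channel.  The per-channel
        ``sigma`` is the *sum* of the two reactants' radii.
    finest_level
        Mesh level this species is born on (filled by ``resolve``).
    """

    name: str
    D: float
    radius: float = 0.0
    finest_level: int | None = None

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"species {self.name}: D must be >= 0, got {self.D}")
        if self.radius < 0:
            raise ValueError(f"species {self.name}: radius must be >= 0")


@dataclass
class ReactionChannel:
    """A reaction channel of order 0, 1 or 2.

    ``k_micro`` is the microscopic rate: molecules/time for order 0, 1/time
    for order 1, volume/time for order 2 (3D).  For bimolecular channels
    ``resolve`` fills ``sigma`` (summed radii), ``D_pair`` (summed diffusion
    constants) and ``k_meso_by_level``.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k_micro: float
    sigma: float | None = None
    D_pair: float | None = None
    k_meso_by_level: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reactants = tuple(self.reactants)
        self.products = tuple(self.products)
        if self.k_micro < 0:
            raise ValueError(f"reaction {self}: rate must be >= 0")
        if len(self.reactants) > 2:
            raise ValueError(f"reaction {self}: at most two reactants")

    @property
    def order(self) -> int:
        return len(self.reactants)

    def __str__(self) -> str:
        lhs = " + ".join(self.reactants) if self.reactants else "0"
        rhs = " + ".join(self.products) if self.products else "0"
        return f"{lhs} -> {rhs} (k={self.k_micro:g})"


@dataclass
class SolverConfig:
    """Solver settings: transfer constant, tolerance, seed and horizon."""

    C: float = 20.0
    epsilon: float = 0.025
    seed: int = 0
    t_final: float = 1.0
    n_samples: int = 100
    n_trajectories: int = 1

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"transfer constant C must be positive, got {self.C}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")


class ReactionModel:
    """A reaction-diffusion model on a cubic domain with a mesh hierarchy."""

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[ReactionChannel],
        volume: float = 1.0,
        n_levels: int = 1,
        initial: Mapping[str, int] | None = None,
        solver: SolverConfig | None = None,
        name: str = "model",
    ) -> None:
        self.name = name
        self.species = list(species)
        self.reactions = list(reactions)
        self.volume = float(volume)
        self.n_levels = int(n_levels)
        self.initial = dict(initial or {})
        self.solver = solver or SolverConfig()
        self._index = {s.name: i for i, s in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise ValueError("duplicate species names")
        for r in self.reactions:
            for n in (*r.reactants, *r.products):
                if n not in self._index:
                    raise ValueError(f"reaction {r}: unknown species {n!r}")
        for n in self.initial:
            if n not in self._index:
                raise ValueError(f"initial counts: unknown species {n!r}")
        self.resolved = False

    # -- lookups ---------------------------------------------------------

    def species_index(self, name: str) -> int:
        return self._index[name]

    def get_species(self, name: str) -> Species:
        return self.species[self._index[name]]

    def hierarchy(self) -> MeshHierarchy:
        return MeshHierarchy(self.n_levels, self.volume)

    def bimolecular_channels(self) -> list[ReactionChannel]:
        return [r for r in self.reactions if r.order == 2]

    # -- resolution ------------------------------------------------------

    def resolve(self, assign_levels: bool = True) -> "ReactionModel":
        """Fill per-channel sigma/D sums, mesoscopic rate tables and (by
        default) per-species finest levels.  Idempotent; returns self."""
        hierarchy = self.hierarchy()
        for r in self.bimolecular_channels():
            a, b = (self.get_species(n) for n in r.reactants)
            if a.radius <= 0 or b.radius <= 0:
                raise ValueError(
                    f"reaction {r}: bimolecular reactants need positive radii")
            r.sigma = a.radius + b.radius
            r.D_pair = a.D + b.D
            r.k_meso_by_level = {
                l: meso_rate(r.k_micro, r.sigma, r.D_pair, float(hierarchy.widths[l]))
                for l in range(self.n_levels)
            }
        if assign_levels:
            levels = assign_species_levels(self, hierarchy, self.solver.epsilon)
            for s in self.species:
                s.finest_level = levels[s.name]
        else:
            for s in self.species:
                if s.finest_level is None:
                    s.finest_level = 0
        self.resolved = True
        log.info("resolved model %s:\n%s", self.name, self.describe())
        return self

    def pinned(self, level: int) -> "ReactionModel":
        """A copy with every species pinned to ``level`` (single-mesh mode)."""
        m = self.copy()
        m.hierarchy()._check_level(level)
        m.resolve(assign_levels=False)
        for s in m.species:
            s.finest_level = level
        return m

    def copy(self) -> "ReactionModel":
        return ReactionModel(
            [Species(s.name, s.D, s.radius) for s in self.species],
            [ReactionChannel(r.reactants, r.products, r.k_micro) for r in self.reactions],
            volume=self.volume,
            n_levels=self.n_levels,
            initial=dict(self.initial),
            solver=SolverConfig(**vars(self.solver)),
            name=self.name,
        )

    # -- reporting -------------------------------------------------------

    def describe(self) -> str:
        """The fully resolved model as plain text (species, levels, rates)."""
        h = self.hierarchy()
        lines = [f"model {self.name!r}: volume {self.volume:g}, "
                 f"{self.n_levels} mesh levels (finest {h.grid_size(self.n_levels-1)}^3)"]
        for s in self.species:
            lines.append(
                f"  species {s.name:>8}: D={s.D:g} radius={s.radius:g} "
                f"finest_level={s.finest_level}")
        for r in self.reactions:
            lines.append(f"  reaction {r}")
            if r.order == 2 and r.k_meso_by_level:
                lines.append(f"    sigma={r.sigma:g} D_pair={r.D_pair:g} "
                             f"h*={critical_mesh_size(r.sigma):g}")
                for l, k in r.k_meso_by_level.items():
                    lines.append(f"    level {l}: h={h.widths[l]:g} k_meso={k:.6g}")
        lines.append(f"  initial: {self.initial}")
        lines.append(f"  solver: {vars(self.solver)}")
        return "\n".join(lines)


def assign_species_levels(
    model: ReactionModel, hierarchy: MeshHierarchy, epsilon: float
) -> dict[str, int]:
    """Coarsest admissible mesh level per species.

    For each species the finest level is the *coarsest* level whose width
    satisfies ``k_micro/(1+eps) < k_meso * h**3`` for every bimolecular
    channel the species takes part in (strict inequality; equality fails).
    Species in no bimolecular channel are assigned level 0.  If even the
    finest level violates the criterion for some channel, the finest level
    is assigned and a warning is logged.
    """
    involving: dict[str, list[ReactionChannel]] = {s.name: [] for s in model.species}
    for r in model.bimolecular_channels():
        for n in set(r.reactants):
            involving[n].append(r)

    def admissible(r: ReactionChannel, level: int) -> bool:
        h = float(hierarchy.widths[level])
        km = meso_rate(r.k_micro, r.sigma or 0.0, r.D_pair or 0.0, h)
        return r.k_micro / (1.0 + epsilon) < km * h**3

    out: dict[str, int] = {}
    for s in model.species:
        chans = involving[s.name]
        if not chans:
            out[s.name] = 0
            continue
        for level in range(hierarchy.n_levels):
            if all(admissible(r, level) for r in chans):
                out[s.name] = level
                break
        else:
            out[s.name] = hierarchy.n_levels - 1
            log.warning(
                "species %s: even the finest level (h=%g) violates the "
                "admissible-mesh criterion at eps=%g; assigning the finest level",
                s.name, float(hierarchy.widths[-1]), epsilon)
    return out


# -- model files ---------------------------------------------------------


def save_model(model: ReactionModel, path: str) -> None:
    """Write the model as a flat YAML document (round-trips via load_model)."""
    doc = {
        "name": model.name,
        "species": [
            {"name": s.name, "D": s.D, "radius": s.radius} for s in model.species
        ],
        "reactions": [
            {"reactants": list(r.reactants), "products": list(r.products),
             "rate": r.k_micro}
            for r in model.reactions
        ],
        "domain": {"volume": model.volume, "levels": model.n_levels},
        "initial": dict(model.initial),
        "solver": {k: v for k, v in vars(model.solver).items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path: str) -> ReactionModel:
    """Read a model file written by :func:`save_model` (validating it)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        species = [Species(d["name"], float(d["D"]), float(d.get("radius", 0.0)))
                   for d in doc["species"]]
        reactions = [
            ReactionChannel(tuple(d.get("reactants") or ()),
                            tuple(d.get("products") or ()),
                            float(d["rate"]))
            for d in doc["reactions"]
        ]
        domain = doc.get("domain", {})
        model = ReactionModel(
            species,
            reactions,
            volume=float(domain.get("volume", 1.0)),
            n_levels=int(domain.get("levels", 1)),
            initial={k: int(v) for k, v in (doc.get("initial") or {}).items()},
            solver=SolverConfig(**(doc.get("solver") or {})),
            name=doc.get("name", "model"),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed model file {path}: {exc}") from exc
    return model
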