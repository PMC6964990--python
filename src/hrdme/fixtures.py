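"""Built-in benchmark models.

Four fully parameterized systems on the unit cube with a 7-level hierarchy
(1 to 64^3 voxels).  All are tuned so that the admissible-mesh criterion
is satisfied only at the finest level for the diffusion-limited channels —
the regime where a plain coarse mesh fails and the hierarchy pays off.

rebind
    ``S1 + S2 <-> S3``: a single reversible pair, radius 0.00246 per
    species so that the critical width ``h* ~ 3.2 * 2*sigma ~ 1/64``;
    association rate 1.0.  Used to measure rebinding-time distributions.
single_layer
    ``S1 -> S11 + S12 -> S2``: 100 S1 molecules dissociate (k1 = 1) into
    product pairs (radius 0.0025 each) that re-associate fast (k2 = 1).
    S1 and S2 live on the coarsest mesh; S11/S12 are born co-located on
    the finest.
double_layer
    The same with a second dissociation/association layer appended
    (``S2 -> S21 + S22 -> S3``); all rates 1.0.
mapk
    A two-stage phosphorylation cascade: a kinase KK double-phosphorylates
    the substrate K (K -> Kp -> Kpp) through transient enzyme-substrate
    complexes, and a phosphatase P reverses both steps; the enzymes leave
    each catalytic step in a transiently inactive form (KK*, P*) that
    relaxes at k7 = 693147.18.  120 K + 30 KK + 30 P, every species on the
    finest mesh (no coarse-graining assumption is made for this system;
    criterion-based assignment stays available via ``resolve``).
"""

from __future__ import annotations

from .model import ReactionChannel, ReactionModel, SolverConfig, Species

__all__ = ["fixture", "FIXTURES"]

FIXTURES = ("rebind", "single_layer", "double_layer", "mapk")


def fixture(name: str) -> ReactionModel:
    """A fully parameterized, resolved benchmark model by name."""
    if name == "rebind":
        model = ReactionModel(
            [Species("S1", 1.0, 0.00246), Species("S2", 1.0, 0.00246),
             Species("S3", 1.0, 0.00246)],
            [ReactionChannel(("S1", "S2"), ("S3",), 1.0),
             ReactionChannel(("S3",), ("S1", "S2"), 1.0)],
            volume=1.0, n_levels=7, initial={"S3": 1},
            solver=SolverConfig(C=20.0, epsilon=0.025, t_final=1000.0,
                                n_samples=100, n_trajectories=1),
            name="rebind",
        )
    elif name == "single_layer":
        model = ReactionModel(
            _layer_species(1) + [Species("S2", 1.0, 0.0025)],
            _layer_reactions(1, "S2", 1.0, 1.0),
            volume=1.0, n_levels=7, initial={"S1": 100},
            solver=SolverConfig(C=20.0, epsilon=0.025, t_final=5.0,
                                n_samples=100, n_trajectories=200),
            name="single_layer",
        )
    elif name == "double_layer":
        model = ReactionModel(
            _layer_species(1) + _layer_species(2) + [Species("S3", 1.0, 0.0025)],
            _layer_reactions(1, "S2", 1.0, 1.0) + _layer_reactions(2, "S3", 1.0, 1.0),
            volume=1.0, n_levels=7, initial={"S1": 100},
            solver=SolverConfig(C=20.0, epsilon=0.025, t_final=5.0,
                                n_samples=100, n_trajectories=200),
            name="double_layer",
        )
    elif name == "mapk":
        return _mapk()  # resolved with all species pinned to the finest mesh
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    model.resolve()
    return model


def _layer_species(i: int) -> list[Species]:
    return [Species(f"S{i}", 1.0, 0.0025), Species(f"S{i}1", 1.0, 0.0025),
            Species(f"S{i}2", 1.0, 0.0025)]


def _layer_reactions(i: int, product: str, k1: float, k2: float):
    return [ReactionChannel((f"S{i}",), (f"S{i}1", f"S{i}2"), k1),
            ReactionChannel((f"S{i}1", f"S{i}2"), (product,), k2)]


def _mapk() -> ReactionModel:
    sigma = 0.0024599
    k1, k2, k3 = 0.0448346, 1.35, 1.5
    k4, k5, k6 = 0.0929902, 1.73, 15.0
    k7 = 693147.18
    names = ["K", "Kp", "Kpp", "KK", "KKs", "P", "Ps",
             "KK_K", "KK_Kp", "P_Kpp", "P_Kp"]
    species = [Species(n, 1.0, sigma) for n in names]
    reactions = [
        # kinase arm: K -> Kp -> Kpp
        ReactionChannel(("KK", "K"), ("KK_K",), k1),
        ReactionChannel(("KK_K",), ("KK", "K"), k2),
        ReactionChannel(("KK_K",), ("KKs", "Kp"), k3),
        ReactionChannel(("KK", "Kp"), ("KK_Kp",), k4),
        ReactionChannel(("KK_Kp",), ("KK", "Kp"), k5),
        ReactionChannel(("KK_Kp",), ("KKs", "Kpp"), k6),
        # phosphatase arm: Kpp -> Kp -> K (shares the kinase-arm rates)
        ReactionChannel(("P", "Kpp"), ("P_Kpp",), k1),
        ReactionChannel(("P_Kpp",), ("P", "Kpp"), k2),
        ReactionChannel(("P_Kpp",), ("Ps", "Kp"), k3),
        ReactionChannel(("P", "Kp"), ("P_Kp",), k4),
        ReactionChannel(("P_Kp",), ("P", "Kp"), k5),
        ReactionChannel(("P_Kp",), ("Ps", "K"), k6),
        # enzyme recovery
        ReactionChannel(("KKs",), ("KK",), k7),
        ReactionChannel(("Ps",), ("P",), k7),
    ]
    model = ReactionModel(
        species, reactions, volume=1.0, n_levels=7,
        initial={"K": 120, "KK": 30, "P": 30},
        solver=SolverConfig(C=20.0, epsilon=0.025, t_final=50.0,
                            n_samples=100, n_trajectories=200),
        name="mapk",
    )
    # every species starts on the finest mesh: no coarse-graining assumption
    model.resolve(assign_levels=False)
    for s in model.species:
        s.finest_level = model.n_levels - 1
    return model
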