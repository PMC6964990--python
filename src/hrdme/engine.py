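"""Next-particle-method event loop over a mesh hierarchy.

The solver tracks every molecule individually.  A global queue holds
*tentative* events — diffusion jumps, unimolecular firings, one event per
co-located reactive pair per bimolecular channel, and one pending event per
zeroth-order channel — and executes them in time order:

* a diffusion event moves the molecule to a uniformly chosen face
  neighbor, may promote it to coarser levels (see
  :mod:`hrdme.coupling`), drops its pending bimolecular events and
  resamples them together with a fresh diffusion event;
* a unimolecular event replaces the reactant by its products (placed by
  the product-placement rule) and samples the products' events;
* a bimolecular event may fire between molecules on *different* levels
  whenever the finer voxel is contained in the coarser one, at the
  mesoscopic rate of the coarser level;
* unimolecular clocks are sampled once at a molecule's birth and are
  unaffected by diffusion.

All waiting times are exponential; ties in the queue are broken by
insertion order, and a single seeded random stream drives everything, so a
fixed seed reproduces a trajectory bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernel as K
from .coupling import TransferPolicy
from .mesh import MeshHierarchy, VoxelRef
from .model import ReactionChannel, ReactionModel

__all__ = [
    "Molecule",
    "TentativeEvent",
    "EventQueue",
    "SimulationState",
    "Trajectory",
    "initialize",
    "step",
    "run",
    "sample_bimolecular",
]


@dataclass(frozen=True)
class Molecule:
    """Read-only view of one live molecule."""

    uid: int
    species: str
    voxel: VoxelRef
    t_since_transfer: float
    t_birth: float


@dataclass(frozen=True)
class TentativeEvent:
    """Read-only view of one live queue entry."""

    time: float
    kind: str
    actors: tuple[int, ...]
    channel: int | None
    seq: int


class EventQueue:
    """View of the live content of the kernel's event heap.

    Stale entries (whose actors died or were resampled) are filtered out;
    :meth:`remove_by_actor` invalidates every event of a molecule by
    bumping its version stamps.
    """

    def __init__(self, sim: "SimulationState") -> None:
        self._sim = sim

    def _live(self, i: int) -> bool:
        S = self._sim._k
        kind = S.hp_kind[i]
        a1 = S.hp_a1[i]
        if kind == K.BIRTH:
            return True
        if not S.mol_alive[a1]:
            return False
        if kind == K.UNIMOLECULAR:
            return S.mol_uver[a1] == S.hp_v1[i]
        if kind == K.DIFFUSION:
            return S.mol_ver[a1] == S.hp_v1[i]
        a2 = S.hp_a2[i]
        return (S.mol_ver[a1] == S.hp_v1[i] and S.mol_alive[a2]
                and S.mol_ver[a2] == S.hp_v2[i])

    def events(self) -> list[TentativeEvent]:
        """Live events sorted by (time, insertion order)."""
        S = self._sim._k
        out = []
        for i in range(int(S.hp_n[0])):
            if not self._live(i):
                continue
            kind = int(S.hp_kind[i])
            if kind == K.BIRTH:
                actors: tuple[int, ...] = ()
            elif kind == K.BIMOLECULAR:
                actors = (int(S.hp_a1[i]), int(S.hp_a2[i]))
            else:
                actors = (int(S.hp_a1[i]),)
            ch = int(S.hp_ch[i])
            out.append(TentativeEvent(float(S.hp_t[i]), K.KIND_NAMES[kind],
                                      actors, ch if ch >= 0 else None,
                                      int(S.hp_seq[i])))
        out.sort(key=lambda e: (e.time, e.seq))
        return out

    def __len__(self) -> int:
        return sum(self._live(i) for i in range(int(self._sim._k.hp_n[0])))

    def remove_by_actor(self, uid: int) -> None:
        S = self._sim._k
        S.mol_ver[uid] += 1
        S.mol_uver[uid] += 1


@dataclass
class Trajectory:
    """Copy-number time series of one realization plus its event logs."""

    times: np.ndarray
    counts: np.ndarray           # (n_times, n_species) integers
    species: list[str]
    seed: int
    reactions: pd.DataFrame | None = None
    transfers: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.species)
        df.insert(0, "time", self.times)
        return df

    def write_tsv(self, path: str, header_comment: str | None = None) -> None:
        """Wide delimited table: a time column plus one column per species."""
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


class SimulationState:
    """Live state of one stochastic realization."""

    def __init__(self, model: ReactionModel, hierarchy: MeshHierarchy,
                 policy: TransferPolicy, kstate: K.KernelState, seed: int) -> None:
        self.model = model
        self.hierarchy = hierarchy
        self.policy = policy
        self.seed = seed
        self._k = kstate
        self.queue = EventQueue(self)

    # -- inspection ------------------------------------------------------

    @property
    def time(self) -> float:
        return float(self._k.time[0])

    def counts(self) -> dict[str, int]:
        return {s.name: int(self._k.mem_n[i])
                for i, s in enumerate(self.model.species)}

    def counts_vector(self) -> np.ndarray:
        return self._k.mem_n.copy()

    def molecules(self) -> list[Molecule]:
        S = self._k
        out = []
        for s in range(len(self.model.species)):
            for slot in range(int(S.mem_n[s])):
                out.append(self.molecule(int(S.mem[s, slot])))
        out.sort(key=lambda m: m.uid)
        return out

    def molecule(self, uid: int) -> Molecule:
        S = self._k
        if not S.mol_alive[uid]:
            raise KeyError(f"molecule {uid} is not alive")
        return Molecule(
            uid=uid,
            species=self.model.species[int(S.mol_spe[uid])].name,
            voxel=VoxelRef(int(S.mol_lvl[uid]),
                           (int(S.mol_x[uid]), int(S.mol_y[uid]), int(S.mol_z[uid]))),
            t_since_transfer=float(S.time[0] - S.mol_tlast[uid]),
            t_birth=float(S.mol_tbirth[uid]),
        )

    # -- propagation -----------------------------------------------------

    def step(self) -> "SimulationState":
        """Execute the single next event (if any)."""
        self._advance(math.inf, 1)
        return self

    def advance_to(self, t: float) -> "SimulationState":
        """Execute every event with firing time <= t, then set the clock to t."""
        self._advance(t, -1)
        return self

    def advance_events(self, n: int, t_stop: float = math.inf) -> "SimulationState":
        self._advance(t_stop, n)
        return self

    def run(self, t_final: float, sample_times: Sequence[float] | None = None,
            n_samples: int | None = None) -> Trajectory:
        """Propagate to ``t_final`` recording counts at the sample times."""
        if sample_times is None:
            n = n_samples if n_samples is not None else self.model.solver.n_samples
            sample_times = np.linspace(0.0, t_final, n + 1)
        sample_times = np.asarray(sample_times, dtype=float)
        if np.any(np.diff(sample_times) < 0):
            raise ValueError("sample_times must be sorted")
        if sample_times.size and sample_times[-1] > t_final:
            raise ValueError("sample_times must lie within [0, t_final]")
        counts = np.empty((sample_times.size, len(self.model.species)), dtype=np.int64)
        for i, ts in enumerate(sample_times):
            if ts > self.time:
                self.advance_to(float(ts))
            counts[i] = self._k.mem_n
        if t_final > self.time:
            self.advance_to(float(t_final))
        return Trajectory(sample_times.copy(), counts,
                          [s.name for s in self.model.species], self.seed,
                          reactions=self.reaction_log(),
                          transfers=self.transfer_log())

    def _advance(self, t_stop: float, max_events: int) -> None:
        while True:
            status = K.advance(self._k, t_stop, max_events)
            if status in (K.DONE, K.MAXEVENTS):
                return
            self._grow(status)

    # -- event logs ------------------------------------------------------

    def reaction_log(self) -> pd.DataFrame | None:
        S = self._k
        if not S.rl_on:
            return None
        n = int(S.rl_n[0])
        return pd.DataFrame({
            "time": S.rl_t[:n].copy(),
            "channel": S.rl_ch[:n].copy(),
            "kind": [K.KIND_NAMES[int(k)] for k in S.rl_kind[:n]],
            "reactant1": S.rl_r[:n, 0].copy(),
            "reactant2": S.rl_r[:n, 1].copy(),
            "product1": S.rl_pu[:n, 0].copy(),
            "product2": S.rl_pu[:n, 1].copy(),
            "p1_level": S.rl_pv[:n, 0, 0].copy(),
            "p1_i": S.rl_pv[:n, 0, 1].copy(),
            "p1_j": S.rl_pv[:n, 0, 2].copy(),
            "p1_k": S.rl_pv[:n, 0, 3].copy(),
            "p2_level": S.rl_pv[:n, 1, 0].copy(),
            "p2_i": S.rl_pv[:n, 1, 1].copy(),
            "p2_j": S.rl_pv[:n, 1, 2].copy(),
            "p2_k": S.rl_pv[:n, 1, 3].copy(),
        })

    def transfer_log(self) -> pd.DataFrame | None:
        S = self._k
        if not S.tl_on:
            return None
        n = int(S.tl_n[0])
        return pd.DataFrame({
            "time": S.tl_t[:n].copy(),
            "uid": S.tl_u[:n].copy(),
            "from_level": S.tl_from[:n].copy(),
            "to_level": S.tl_from[:n].copy() - 1,
        })

    # -- growth ----------------------------------------------------------

    def _grow(self, status: int) -> None:
        S = self._k
        rep: dict[str, np.ndarray] = {}

        def double(names: list[str], axis: int = 0) -> None:
            for nm in names:
                a = getattr(S, nm)
                shape = list(a.shape)
                shape[axis] *= 2
                b = np.zeros(shape, dtype=a.dtype)
                b[tuple(slice(0, n) for n in a.shape)] = a
                rep[nm] = b

        if status == K.NEED_MOL:
            double(["mol_spe", "mol_lvl", "mol_x", "mol_y", "mol_z", "mol_tlast",
                    "mol_tbirth", "mol_alive", "mol_ver", "mol_uver", "free",
                    "mol_slot"])
        elif status == K.NEED_MEM:
            double(["mem"], axis=1)
        elif status == K.NEED_HEAP:
            double(["hp_t", "hp_kind", "hp_a1", "hp_v1", "hp_a2", "hp_v2",
                    "hp_ch", "hp_seq"])
        elif status == K.NEED_RLOG:
            double(["rl_t", "rl_ch", "rl_kind", "rl_r", "rl_pu", "rl_pv"])
        elif status == K.NEED_TLOG:
            double(["tl_t", "tl_u", "tl_from"])
        else:  # pragma: no cover
            raise RuntimeError(f"unknown kernel status {status}")
        self._k = S._replace(**rep)
        self.queue._sim = self


def _build_kernel_state(model: ReactionModel, hierarchy: MeshHierarchy,
                        policy: TransferPolicy, n_initial: int,
                        log_reactions: bool, log_transfers: bool) -> K.KernelState:
    ns = len(model.species)
    nl = hierarchy.n_levels
    nc = len(model.reactions)
    finest = np.array([s.finest_level for s in model.species], dtype=np.int64)
    face_rate = np.zeros((ns, nl))
    for i, s in enumerate(model.species):
        for l in range(1, nl):
            face_rate[i, l] = hierarchy.face_rate(s.D, l)
    ttrans = policy.table(model, hierarchy)

    uni_lists: list[list[int]] = [[] for _ in range(ns)]
    bi_lists: list[list[tuple[int, int]]] = [[] for _ in range(ns)]
    birth = []
    kmeso = np.zeros((nc, nl))
    ch_k = np.zeros(nc)
    prods: list[list[int]] = []
    for c, r in enumerate(model.reactions):
        ch_k[c] = r.k_micro
        prods.append([model.species_index(p) for p in r.products])
        if r.order == 0:
            birth.append(c)
        elif r.order == 1:
            uni_lists[model.species_index(r.reactants[0])].append(c)
        else:
            ia, ib = (model.species_index(n) for n in r.reactants)
            for l, k in r.k_meso_by_level.items():
                kmeso[c, l] = k
            bi_lists[ia].append((c, ib))
            if ib != ia:
                bi_lists[ib].append((c, ia))

    def csr(lists: list[list]) -> tuple[np.ndarray, list]:
        off = np.zeros(ns + 1, dtype=np.int64)
        flat: list = []
        for i, row in enumerate(lists):
            flat.extend(row)
            off[i + 1] = len(flat)
        return off, flat

    uni_off, uni_flat = csr(uni_lists)
    bi_off, bi_flat = csr(bi_lists)
    uni_ch = np.array(uni_flat, dtype=np.int64)
    uni_k = np.array([ch_k[c] for c in uni_flat], dtype=float)
    uni_tot = np.zeros(ns)
    for i in range(ns):
        uni_tot[i] = uni_k[uni_off[i]:uni_off[i + 1]].sum()
    bi_ch = np.array([c for c, _ in bi_flat], dtype=np.int64)
    bi_other = np.array([o for _, o in bi_flat], dtype=np.int64)
    prod_off = np.zeros(nc + 1, dtype=np.int64)
    prod_flat: list[int] = []
    for c in range(nc):
        if len(prods[c]) > 8:
            raise ValueError("at most 8 products per channel are supported")
        prod_flat.extend(prods[c])
        prod_off[c + 1] = len(prod_flat)
    prod_spe = np.array(prod_flat, dtype=np.int64)
    prod_lvl = np.array([finest[p] for p in prod_flat], dtype=np.int64)

    cap = max(64, 2 * n_initial + 64)
    mcap = max(64, n_initial + 64)
    hcap = max(512, 8 * n_initial + 256)
    rcap = 4096 if log_reactions else 1
    tcap = 4096 if log_transfers else 1
    i8 = np.int64
    return K.KernelState(
        n_levels=nl,
        finest=finest,
        face_rate=face_rate,
        ttrans=ttrans,
        uni_off=uni_off, uni_ch=uni_ch, uni_k=uni_k, uni_tot=uni_tot,
        bi_off=bi_off, bi_ch=bi_ch, bi_other=bi_other,
        kmeso=kmeso, ch_k=ch_k,
        birth_ch=np.array(birth, dtype=i8),
        prod_off=prod_off, prod_spe=prod_spe, prod_lvl=prod_lvl,
        rl_on=1 if log_reactions else 0,
        tl_on=1 if log_transfers else 0,
        time=np.zeros(1),
        n_slots=np.zeros(1, i8), n_alive=np.zeros(1, i8),
        mol_spe=np.zeros(cap, i8), mol_lvl=np.zeros(cap, i8),
        mol_x=np.zeros(cap, i8), mol_y=np.zeros(cap, i8), mol_z=np.zeros(cap, i8),
        mol_tlast=np.zeros(cap), mol_tbirth=np.zeros(cap),
        mol_alive=np.zeros(cap, np.uint8),
        mol_ver=np.zeros(cap, i8), mol_uver=np.zeros(cap, i8),
        free=np.zeros(cap, i8), n_free=np.zeros(1, i8),
        mem=np.zeros((ns, mcap), i8), mem_n=np.zeros(ns, i8),
        mol_slot=np.zeros(cap, i8),
        hp_t=np.zeros(hcap), hp_kind=np.zeros(hcap, np.uint8),
        hp_a1=np.zeros(hcap, i8), hp_v1=np.zeros(hcap, i8),
        hp_a2=np.zeros(hcap, i8), hp_v2=np.zeros(hcap, i8),
        hp_ch=np.zeros(hcap, i8), hp_seq=np.zeros(hcap, i8),
        hp_n=np.zeros(1, i8), seq=np.zeros(1, i8),
        rl_t=np.zeros(rcap), rl_ch=np.zeros(rcap, i8),
        rl_kind=np.zeros(rcap, np.uint8), rl_r=np.zeros((rcap, 2), i8),
        rl_pu=np.zeros((rcap, 2), i8), rl_pv=np.zeros((rcap, 2, 4), i8),
        rl_n=np.zeros(1, i8),
        tl_t=np.zeros(tcap), tl_u=np.zeros(tcap, i8), tl_from=np.zeros(tcap, i8),
        tl_n=np.zeros(1, i8),
    )


def initialize(
    model: ReactionModel,
    seed: int = 0,
    initial_placement: Mapping[str, Sequence[VoxelRef]] | None = None,
    transfer_policy: TransferPolicy | None = None,
    log_reactions: bool = False,
    log_transfers: bool = False,
) -> SimulationState:
    """Build a ready-to-run simulation state.

    Molecules from ``model.initial`` are placed uniformly on their species'
    finest level unless ``initial_placement`` pins them to explicit voxels.
    The queue is primed with one diffusion event per molecule, one
    unimolecular event per molecule of a species with first-order channels,
    one event per co-located reactive pair, and one event per zeroth-order
    channel.
    """
    if not model.resolved:
        model.resolve()
    hierarchy = model.hierarchy()
    policy = transfer_policy or TransferPolicy(C=model.solver.C)
    placement = dict(initial_placement or {})
    for name, voxels in placement.items():
        want = model.initial.get(name, 0)
        if len(voxels) != want:
            raise ValueError(
                f"placement for {name} has {len(voxels)} voxels, expected {want}")
        for v in voxels:
            hierarchy._check_level(v.level)
    n0 = sum(model.initial.values())
    kstate = _build_kernel_state(model, hierarchy, policy, n0,
                                 log_reactions, log_transfers)
    K.seed_rng(int(seed) & 0x7FFFFFFF)
    for name in (s.name for s in model.species):
        count = model.initial.get(name, 0)
        si = model.species_index(name)
        if name in placement:
            for v in placement[name]:
                K.spawn(kstate, si, v.level, *(np.int64(c) for c in v.ijk))
        else:
            for _ in range(count):
                K.spawn_uniform(kstate, si)
    K.init_births(kstate)
    return SimulationState(model, hierarchy, policy, kstate, int(seed))


def step(state: SimulationState) -> SimulationState:
    """Execute the single next event in ``state`` (functional spelling)."""
    return state.step()


def run(state: SimulationState, t_final: float,
        sample_times: Sequence[float] | None = None) -> Trajectory:
    """Propagate ``state`` to ``t_final`` (functional spelling of
    :meth:`SimulationState.run`)."""
    return state.run(t_final, sample_times=sample_times)


def sample_bimolecular(
    state: SimulationState,
    m1: Molecule,
    m2: Molecule,
    channel: ReactionChannel,
    rng: np.random.Generator | None = None,
) -> TentativeEvent | None:
    """Tentative reaction event for a molecule pair, or None.

    The pair can react when the two voxels overlap: same voxel on the same
    level, or the finer voxel contained in the coarser one.  The waiting
    time is exponential with the mesoscopic rate of the *coarser* of the
    two levels.  This is the contract the kernel implements internally;
    the function is exposed for inspection and testing.
    """
    pair = {m1.species, m2.species}
    if set(channel.reactants) != pair and tuple(channel.reactants) != (m1.species,) * 2:
        raise ValueError(f"channel {channel} does not match pair {pair}")
    lam = min(m1.voxel.level, m2.voxel.level)
    h = state.hierarchy
    if h.ancestor_at(m1.voxel, lam) != h.ancestor_at(m2.voxel, lam):
        return None
    rate = channel.k_meso_by_level[lam]
    if rate <= 0:
        return None
    rng = rng or np.random.default_rng()
    t = state.time + rng.exponential(1.0 / rate)
    ch = state.model.reactions.index(channel)
    return TentativeEvent(t, "bimolecular", (m1.uid, m2.uid), ch, -1)
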