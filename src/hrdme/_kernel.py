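"""Compiled event loop of the next-particle method on a mesh hierarchy.

Internal module.  The simulation state lives in a flat ``KernelState``
namedtuple of numpy arrays so the whole event loop can run inside numba.
Molecules are rows of parallel arrays; the event queue is an array-backed
binary min-heap ordered by (time, insertion sequence).  Removal-by-molecule
is lazy: every molecule carries two version counters (one for diffusion and
bimolecular events, one for unimolecular events) and every queued event
stores the versions of its actors at sampling time; stale entries are
discarded when they surface at the top of the heap.  Molecule slots are
recycled through a free list, so memory is bounded by the maximum number of
concurrently alive molecules, not by the total number ever created.

``advance`` returns to Python whenever an array is about to overflow; the
wrapper in :mod:`hrdme.engine` grows the arrays and re-enters the loop.
"""

from __future__ import annotations

from collections import namedtuple

import numpy as np
from numba import njit

# Event kinds.
DIFFUSION = 0
UNIMOLECULAR = 1
BIMOLECULAR = 2
BIRTH = 3

KIND_NAMES = {DIFFUSION: "diffusion", UNIMOLECULAR: "unimolecular",
              BIMOLECULAR: "bimolecular", BIRTH: "birth"}

# advance() statuses.
DONE = 0          # reached t_stop
MAXEVENTS = 1     # executed the requested number of events
NEED_MOL = 2      # molecule arrays full
NEED_MEM = 3      # per-species member rows full
NEED_HEAP = 4     # heap full
NEED_RLOG = 5     # reaction log full
NEED_TLOG = 6     # transfer log full

KernelState = namedtuple(
    "KernelState",
    [
        # static model tables
        "n_levels",      # int
        "finest",        # i8[S] birth level per species
        "face_rate",     # f8[S, L] per-face jump rate D/h^2
        "ttrans",        # f8[S, L] fine-to-coarse transfer time (inf = never)
        "uni_off",       # i8[S+1] CSR offsets into uni_ch/uni_k
        "uni_ch",        # i8[U] unimolecular channel ids per species
        "uni_k",         # f8[U]
        "uni_tot",       # f8[S] summed unimolecular rate per species
        "bi_off",        # i8[S+1] CSR offsets into bi_ch/bi_other
        "bi_ch",         # i8[B] bimolecular channel ids per species
        "bi_other",      # i8[B] partner species per entry
        "kmeso",         # f8[C, L] per-pair mesoscopic rate by level
        "ch_k",          # f8[C] microscopic rate per channel
        "birth_ch",      # i8[Z] zeroth-order channel ids
        "prod_off",      # i8[C+1] CSR offsets into prod_spe/prod_lvl
        "prod_spe",      # i8[P] product species per channel
        "prod_lvl",      # i8[P] product birth level per channel
        "rl_on",         # int flag: log reaction events
        "tl_on",         # int flag: log transfers
        # dynamic state
        "time",          # f8[1]
        "n_slots",       # i8[1] high-water mark of molecule slots
        "n_alive",       # i8[1]
        "mol_spe", "mol_lvl", "mol_x", "mol_y", "mol_z",   # i8[cap]
        "mol_tlast",     # f8[cap] time of birth or last transfer
        "mol_tbirth",    # f8[cap]
        "mol_alive",     # u1[cap]
        "mol_ver",       # i8[cap] diffusion/bimolecular event version
        "mol_uver",      # i8[cap] unimolecular event version
        "free",          # i8[cap] free slot stack
        "n_free",        # i8[1]
        "mem",           # i8[S, mcap] alive molecules per species
        "mem_n",         # i8[S]
        "mol_slot",      # i8[cap] position of a molecule in its mem row
        # event heap
        "hp_t",          # f8[hcap]
        "hp_kind",       # u1[hcap]
        "hp_a1", "hp_v1", "hp_a2", "hp_v2", "hp_ch", "hp_seq",  # i8[hcap]
        "hp_n",          # i8[1]
        "seq",           # i8[1] insertion counter
        # reaction log (times, channel, kind, reactants, products + birth voxels)
        "rl_t",          # f8[rcap]
        "rl_ch",         # i8[rcap]
        "rl_kind",       # u1[rcap]
        "rl_r",          # i8[rcap, 2]
        "rl_pu",         # i8[rcap, 2]
        "rl_pv",         # i8[rcap, 2, 4]  (level, i, j, k) at birth
        "rl_n",          # i8[1]
        # transfer log
        "tl_t",          # f8[tcap]
        "tl_u",          # i8[tcap]
        "tl_from",       # i8[tcap]
        "tl_n",          # i8[1]
    ],
)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


# -- heap ----------------------------------------------------------------


@njit(cache=True, inline="always")
def _hless(S, i, j):
    ti = S.hp_t[i]
    tj = S.hp_t[j]
    if ti < tj:
        return True
    if ti > tj:
        return False
    return S.hp_seq[i] < S.hp_seq[j]


@njit(cache=True, inline="always")
def _hswap(S, i, j):
    S.hp_t[i], S.hp_t[j] = S.hp_t[j], S.hp_t[i]
    S.hp_kind[i], S.hp_kind[j] = S.hp_kind[j], S.hp_kind[i]
    S.hp_a1[i], S.hp_a1[j] = S.hp_a1[j], S.hp_a1[i]
    S.hp_v1[i], S.hp_v1[j] = S.hp_v1[j], S.hp_v1[i]
    S.hp_a2[i], S.hp_a2[j] = S.hp_a2[j], S.hp_a2[i]
    S.hp_v2[i], S.hp_v2[j] = S.hp_v2[j], S.hp_v2[i]
    S.hp_ch[i], S.hp_ch[j] = S.hp_ch[j], S.hp_ch[i]
    S.hp_seq[i], S.hp_seq[j] = S.hp_seq[j], S.hp_seq[i]


@njit(cache=True, inline="always")
def _heap_push(S, t, kind, a1, v1, a2, v2, ch):
    i = S.hp_n[0]
    S.hp_n[0] = i + 1
    S.hp_t[i] = t
    S.hp_kind[i] = kind
    S.hp_a1[i] = a1
    S.hp_v1[i] = v1
    S.hp_a2[i] = a2
    S.hp_v2[i] = v2
    S.hp_ch[i] = ch
    S.hp_seq[i] = S.seq[0]
    S.seq[0] += 1
    while i > 0:
        p = (i - 1) >> 1
        if _hless(S, i, p):
            _hswap(S, i, p)
            i = p
        else:
            break


@njit(cache=True, inline="always")
def _heap_remove_root(S):
    n = S.hp_n[0] - 1
    S.hp_n[0] = n
    if n == 0:
        return
    _hswap(S, 0, n)
    i = 0
    while True:
        l = 2 * i + 1
        if l >= n:
            break
        c = l
        r = l + 1
        if r < n and _hless(S, r, l):
            c = r
        if _hless(S, c, i):
            _hswap(S, i, c)
            i = c
        else:
            break


# -- geometry ------------------------------------------------------------


@njit(cache=True, inline="always")
def _coloc_level(l1, x1, y1, z1, l2, x2, y2, z2):
    """Coarser shared level if the two voxels overlap, else -1."""
    if l1 <= l2:
        s = l2 - l1
        if (x2 >> s) == x1 and (y2 >> s) == y1 and (z2 >> s) == z1:
            return l1
        return -1
    s = l1 - l2
    if (x1 >> s) == x2 and (y1 >> s) == y2 and (z1 >> s) == z2:
        return l2
    return -1


@njit(cache=True, inline="always")
def _count_faces(l, x, y, z):
    g = 1 << l
    nf = 0
    if x > 0:
        nf += 1
    if x + 1 < g:
        nf += 1
    if y > 0:
        nf += 1
    if y + 1 < g:
        nf += 1
    if z > 0:
        nf += 1
    if z + 1 < g:
        nf += 1
    return nf


# -- event sampling ------------------------------------------------------


@njit(cache=True, inline="always")
def _texp(t, scale):
    """t plus an exponential waiting time, strictly after t.

    At large simulation times a tiny increment can round to t itself;
    event times must strictly advance, so bump by one ulp in that case."""
    tn = t + np.random.exponential(scale)
    if tn == t:
        tn = np.nextafter(t, np.inf)
    return tn

@njit(cache=True, inline="always")
def _schedule_diffusion(S, m):
    l = S.mol_lvl[m]
    if l == 0:
        return
    s = S.mol_spe[m]
    nf = _count_faces(l, S.mol_x[m], S.mol_y[m], S.mol_z[m])
    rate = nf * S.face_rate[s, l]
    if rate <= 0.0:
        return
    _heap_push(S, _texp(S.time[0], 1.0 / rate),
               DIFFUSION, m, S.mol_ver[m], -1, 0, -1)


@njit(cache=True, inline="always")
def _schedule_unimolecular(S, m):
    s = S.mol_spe[m]
    tot = S.uni_tot[s]
    if tot <= 0.0:
        return
    _heap_push(S, _texp(S.time[0], 1.0 / tot),
               UNIMOLECULAR, m, S.mol_uver[m], -1, 0, -1)


@njit(cache=True, inline="always")
def _schedule_bimolecular(S, m):
    """One tentative event per co-located reactive partner of ``m``."""
    s = S.mol_spe[m]
    l = S.mol_lvl[m]
    x = S.mol_x[m]
    y = S.mol_y[m]
    z = S.mol_z[m]
    for e in range(S.bi_off[s], S.bi_off[s + 1]):
        c = S.bi_ch[e]
        o = S.bi_other[e]
        for slot in range(S.mem_n[o]):
            j = S.mem[o, slot]
            if j == m:
                continue
            lam = _coloc_level(l, x, y, z,
                               S.mol_lvl[j], S.mol_x[j], S.mol_y[j], S.mol_z[j])
            if lam < 0:
                continue
            rate = S.kmeso[c, lam]
            if rate <= 0.0:
                continue
            _heap_push(S, _texp(S.time[0], 1.0 / rate),
                       BIMOLECULAR, m, S.mol_ver[m], j, S.mol_ver[j], c)


# -- molecule bookkeeping ------------------------------------------------


@njit(cache=True, inline="always")
def spawn(S, s, l, x, y, z):
    """Create a molecule and sample its tentative events.  Returns its id."""
    if S.n_free[0] > 0:
        S.n_free[0] -= 1
        m = S.free[S.n_free[0]]
    else:
        m = S.n_slots[0]
        S.n_slots[0] += 1
    S.mol_spe[m] = s
    S.mol_lvl[m] = l
    S.mol_x[m] = x
    S.mol_y[m] = y
    S.mol_z[m] = z
    S.mol_tlast[m] = S.time[0]
    S.mol_tbirth[m] = S.time[0]
    S.mol_alive[m] = 1
    slot = S.mem_n[s]
    S.mem[s, slot] = m
    S.mol_slot[m] = slot
    S.mem_n[s] = slot + 1
    S.n_alive[0] += 1
    _schedule_diffusion(S, m)
    _schedule_unimolecular(S, m)
    _schedule_bimolecular(S, m)
    return m


@njit(cache=True)
def spawn_uniform(S, s):
    """Create a molecule uniformly placed on its species' birth level."""
    l = S.finest[s]
    g = 1 << l
    x = np.int64(np.random.random() * g)
    y = np.int64(np.random.random() * g)
    z = np.int64(np.random.random() * g)
    return spawn(S, s, l, x, y, z)


@njit(cache=True, inline="always")
def _kill(S, m):
    S.mol_alive[m] = 0
    S.mol_ver[m] += 1
    S.mol_uver[m] += 1
    s = S.mol_spe[m]
    slot = S.mol_slot[m]
    last = S.mem_n[s] - 1
    moved = S.mem[s, last]
    S.mem[s, slot] = moved
    S.mol_slot[moved] = slot
    S.mem_n[s] = last
    S.n_alive[0] -= 1
    S.free[S.n_free[0]] = m
    S.n_free[0] += 1


@njit(cache=True)
def init_births(S):
    """Queue one tentative event per zeroth-order channel."""
    for e in range(S.birth_ch.shape[0]):
        c = S.birth_ch[e]
        k = S.ch_k[c]
        if k > 0.0:
            _heap_push(S, _texp(S.time[0], 1.0 / k),
                       BIRTH, -1, 0, -1, 0, c)


# -- reactions -----------------------------------------------------------


@njit(cache=True, inline="always")
def _log_reaction(S, t, c, kind, a1, a2):
    if S.rl_on == 0:
        return -1
    i = S.rl_n[0]
    S.rl_n[0] = i + 1
    S.rl_t[i] = t
    S.rl_ch[i] = c
    S.rl_kind[i] = kind
    S.rl_r[i, 0] = a1
    S.rl_r[i, 1] = a2
    S.rl_pu[i, 0] = -1
    S.rl_pu[i, 1] = -1
    return i


@njit(cache=True, inline="always")
def _spawn_products(S, c, rl, rx, ry, rz, log_idx):
    """Place and create the products of channel ``c`` fired in the voxel
    ``(rl, rx, ry, rz)``.  Products targeting the same level share one
    sampled voxel; a finer target is a uniform descendant, a coarser one
    the unique ancestor."""
    seen_lvl = np.empty(8, np.int64)
    seen_x = np.empty(8, np.int64)
    seen_y = np.empty(8, np.int64)
    seen_z = np.empty(8, np.int64)
    n_seen = 0
    pi = 0
    for e in range(S.prod_off[c], S.prod_off[c + 1]):
        tl = S.prod_lvl[e]
        x = np.int64(-1)
        y = np.int64(-1)
        z = np.int64(-1)
        for q in range(n_seen):
            if seen_lvl[q] == tl:
                x = seen_x[q]
                y = seen_y[q]
                z = seen_z[q]
                break
        if x < 0:
            if tl <= rl:
                s2 = rl - tl
                x = rx >> s2
                y = ry >> s2
                z = rz >> s2
            else:
                x = rx
                y = ry
                z = rz
                for _ in range(tl - rl):
                    r = np.int64(np.random.random() * 8)
                    x = 2 * x + (r & 1)
                    y = 2 * y + ((r >> 1) & 1)
                    z = 2 * z + ((r >> 2) & 1)
            seen_lvl[n_seen] = tl
            seen_x[n_seen] = x
            seen_y[n_seen] = y
            seen_z[n_seen] = z
            n_seen += 1
        m = spawn(S, S.prod_spe[e], tl, x, y, z)
        if log_idx >= 0 and pi < 2:
            S.rl_pu[log_idx, pi] = m
            S.rl_pv[log_idx, pi, 0] = tl
            S.rl_pv[log_idx, pi, 1] = x
            S.rl_pv[log_idx, pi, 2] = y
            S.rl_pv[log_idx, pi, 3] = z
        pi += 1


# -- main loop -----------------------------------------------------------


@njit(cache=True)
def _exec_reaction(S, kind, a1, a2, c, t):
    """Execute a unimolecular, bimolecular or birth event.

    Outlined from ``advance`` on purpose: reaction events are rare next to
    diffusion events, and keeping their (large, fully inlined) product
    machinery out of the hot loop keeps the diffusion path fast."""
    if kind == UNIMOLECULAR:
        m = a1
        s = S.mol_spe[m]
        # competing first-order channels: draw proportional to rate
        u = np.random.random() * S.uni_tot[s]
        c = S.uni_ch[S.uni_off[s]]
        acc = 0.0
        for e in range(S.uni_off[s], S.uni_off[s + 1]):
            acc += S.uni_k[e]
            if u < acc:
                c = S.uni_ch[e]
                break
        log_idx = _log_reaction(S, t, c, UNIMOLECULAR, m, -1)
        rl = S.mol_lvl[m]
        rx = S.mol_x[m]
        ry = S.mol_y[m]
        rz = S.mol_z[m]
        _kill(S, m)
        _spawn_products(S, c, rl, rx, ry, rz, log_idx)
    elif kind == BIMOLECULAR:
        log_idx = _log_reaction(S, t, c, BIMOLECULAR, a1, a2)
        # the reaction fires as if in the coarser molecule's voxel
        if S.mol_lvl[a1] <= S.mol_lvl[a2]:
            mref = a1
        else:
            mref = a2
        rl = S.mol_lvl[mref]
        rx = S.mol_x[mref]
        ry = S.mol_y[mref]
        rz = S.mol_z[mref]
        _kill(S, a1)
        _kill(S, a2)
        _spawn_products(S, c, rl, rx, ry, rz, log_idx)
    else:  # BIRTH
        log_idx = _log_reaction(S, t, c, BIRTH, -1, -1)
        _spawn_products(S, c, 0, 0, 0, 0, log_idx)
        _heap_push(S, _texp(t, 1.0 / S.ch_k[c]),
                   BIRTH, -1, 0, -1, 0, c)


@njit(cache=True)
def advance(S, t_stop, max_events):
    """Execute events in time order up to ``t_stop``.

    ``max_events < 0`` means unlimited.  Returns a status code; capacity
    statuses mean "grow the arrays and call again".
    """
    executed = 0
    while True:
        if max_events >= 0 and executed >= max_events:
            return MAXEVENTS
        # conservative headroom checks before touching anything
        if S.n_slots[0] - S.n_free[0] + 8 > S.mol_spe.shape[0]:
            return NEED_MOL
        mx = 0
        for s in range(S.mem_n.shape[0]):
            if S.mem_n[s] > mx:
                mx = S.mem_n[s]
        if mx + 8 > S.mem.shape[1]:
            return NEED_MEM
        if S.hp_n[0] + 5 * S.n_alive[0] + 40 > S.hp_t.shape[0]:
            return NEED_HEAP
        if S.rl_on != 0 and S.rl_n[0] + 1 > S.rl_t.shape[0]:
            return NEED_RLOG
        if S.tl_on != 0 and S.tl_n[0] + S.n_levels > S.tl_t.shape[0]:
            return NEED_TLOG
        # surface the next live event
        while S.hp_n[0] > 0:
            kind = S.hp_kind[0]
            a1 = S.hp_a1[0]
            a2 = S.hp_a2[0]
            if kind == BIRTH:
                break
            if kind == UNIMOLECULAR:
                if S.mol_alive[a1] == 1 and S.mol_uver[a1] == S.hp_v1[0]:
                    break
            elif kind == DIFFUSION:
                if S.mol_alive[a1] == 1 and S.mol_ver[a1] == S.hp_v1[0]:
                    break
            else:  # BIMOLECULAR
                if (S.mol_alive[a1] == 1 and S.mol_ver[a1] == S.hp_v1[0]
                        and S.mol_alive[a2] == 1 and S.mol_ver[a2] == S.hp_v2[0]):
                    break
            _heap_remove_root(S)
        if S.hp_n[0] == 0 or S.hp_t[0] > t_stop:
            S.time[0] = t_stop
            return DONE
        t = S.hp_t[0]
        kind = S.hp_kind[0]
        a1 = S.hp_a1[0]
        a2 = S.hp_a2[0]
        c = S.hp_ch[0]
        _heap_remove_root(S)
        S.time[0] = t
        executed += 1

        if kind == DIFFUSION:
            m = a1
            S.mol_ver[m] += 1  # drop pending bimolecular events of the mover
            l = S.mol_lvl[m]
            g = 1 << l
            x = S.mol_x[m]
            y = S.mol_y[m]
            z = S.mol_z[m]
            nf = _count_faces(l, x, y, z)
            r = np.int64(np.random.random() * nf)
            if x > 0:
                if r == 0:
                    x -= 1
                r -= 1
            if x + 1 < g:
                if r == 0:
                    x += 1
                r -= 1
            if y > 0:
                if r == 0:
                    y -= 1
                r -= 1
            if y + 1 < g:
                if r == 0:
                    y += 1
                r -= 1
            if z > 0:
                if r == 0:
                    z -= 1
                r -= 1
            if z + 1 < g:
                if r == 0:
                    z += 1
                r -= 1
            S.mol_x[m] = x
            S.mol_y[m] = y
            S.mol_z[m] = z
            # fine-to-coarse transfer, only ever right after a diffusion event
            s = S.mol_spe[m]
            while S.mol_lvl[m] > 0 and t - S.mol_tlast[m] >= S.ttrans[s, S.mol_lvl[m]]:
                if S.tl_on != 0:
                    i = S.tl_n[0]
                    S.tl_n[0] = i + 1
                    S.tl_t[i] = t
                    S.tl_u[i] = m
                    S.tl_from[i] = S.mol_lvl[m]
                S.mol_lvl[m] -= 1
                S.mol_x[m] >>= 1
                S.mol_y[m] >>= 1
                S.mol_z[m] >>= 1
                S.mol_tlast[m] = t
            # resample events; scheduling is inlined by hand here because
            # this is the hot path and a helper call would dominate the cost
            l = S.mol_lvl[m]
            if l > 0:
                s = S.mol_spe[m]
                nf = _count_faces(l, S.mol_x[m], S.mol_y[m], S.mol_z[m])
                rate = nf * S.face_rate[s, l]
                if rate > 0.0:
                    _heap_push(S, _texp(t, 1.0 / rate),
                               DIFFUSION, m, S.mol_ver[m], -1, 0, -1)
            s = S.mol_spe[m]
            l = S.mol_lvl[m]
            x = S.mol_x[m]
            y = S.mol_y[m]
            z = S.mol_z[m]
            for e in range(S.bi_off[s], S.bi_off[s + 1]):
                cb = S.bi_ch[e]
                o = S.bi_other[e]
                for slot in range(S.mem_n[o]):
                    j = S.mem[o, slot]
                    if j == m:
                        continue
                    lam = _coloc_level(l, x, y, z, S.mol_lvl[j],
                                       S.mol_x[j], S.mol_y[j], S.mol_z[j])
                    if lam < 0:
                        continue
                    rb = S.kmeso[cb, lam]
                    if rb <= 0.0:
                        continue
                    _heap_push(S, _texp(t, 1.0 / rb),
                               BIMOLECULAR, m, S.mol_ver[m], j, S.mol_ver[j], cb)
        else:
            _exec_reaction(S, kind, a1, a2, c, t)
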