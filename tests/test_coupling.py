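"""Level transfers and product placement."""

import math

import numpy as np
import pytest
from scipy import stats

from hrdme.coupling import TransferPolicy, maybe_promote, place_products, transfer_time
from hrdme.engine import initialize
from hrdme.mesh import MeshHierarchy, VoxelRef
from hrdme.model import ReactionChannel, ReactionModel, SolverConfig, Species

from conftest import pure_diffusion_model


class TestTransferTime:
    def test_direct_evaluation(self):
        assert transfer_time(1.0, 1 / 64, 20.0) == pytest.approx((20 / 64) ** 2 / 6)
        assert transfer_time(1.0, 1 / 64, 20.0) == pytest.approx(0.016276, rel=1e-4)

    def test_quadruples_per_coarser_level(self):
        assert transfer_time(1.0, 2 * 0.1, 20.0) == pytest.approx(
            4 * transfer_time(1.0, 0.1, 20.0))

    def test_quadratic_in_C(self):
        assert transfer_time(1.0, 0.1, 20.0) == pytest.approx(
            400 * transfer_time(1.0, 0.1, 1.0))

    def test_immobile_species_never_transfers(self):
        assert transfer_time(0.0, 0.1, 20.0) == math.inf


class TestMaybePromote:
    def setup_method(self):
        self.hier = MeshHierarchy(7, 1.0)
        self.policy = TransferPolicy(C=20.0)

    def test_fresh_molecule_unchanged(self):
        v = VoxelRef(6, (10, 11, 12))
        assert maybe_promote(v, 0.0, 1.0, self.hier, self.policy) == (v, 0.0, 0)

    def test_root_unchanged_regardless_of_clock(self):
        v = VoxelRef(0, (0, 0, 0))
        assert maybe_promote(v, 1e9, 1.0, self.hier, self.policy)[2] == 0

    def test_promotion_moves_to_parent_and_resets_clock(self):
        v = VoxelRef(6, (10, 11, 12))
        tt = transfer_time(1.0, float(self.hier.widths[6]), 20.0)
        out, clock, n = maybe_promote(v, tt * 1.01, 1.0, self.hier, self.policy)
        assert n == 1
        assert clock == 0.0
        assert out == self.hier.parent(v)

    def test_disabled_policy_never_promotes(self):
        v = VoxelRef(6, (1, 2, 3))
        policy = TransferPolicy(C=20.0, enabled=False)
        assert maybe_promote(v, 1e12, 1.0, self.hier, policy)[2] == 0


class TestPlaceProducts:
    def setup_method(self):
        self.hier = MeshHierarchy(4, 1.0)
        self.rng = np.random.default_rng(5)

    def _species(self, level):
        s = Species("X", 1.0, 0.01)
        s.finest_level = level
        return s

    def test_identity_placement_same_level(self):
        v = VoxelRef(2, (1, 2, 3))
        [(_, out)] = place_products([self._species(2)], v, self.hier, self.rng)
        assert out == v

    def test_coarser_target_is_ancestor(self):
        v = VoxelRef(3, (5, 6, 7))
        [(_, out)] = place_products([self._species(1)], v, self.hier, self.rng)
        assert out == self.hier.ancestor_at(v, 1)

    def test_finer_target_is_descendant(self):
        v = VoxelRef(1, (1, 0, 1))
        [(_, out)] = place_products([self._species(3)], v, self.hier, self.rng)
        assert self.hier.ancestor_at(out, 1) == v

    def test_same_level_products_share_a_voxel(self):
        v = VoxelRef(0, (0, 0, 0))
        prods = [self._species(3), self._species(3)]
        placed = place_products(prods, v, self.hier, self.rng)
        assert placed[0][1] == placed[1][1]

    def test_descendant_placement_uniform(self):
        # from the root to level 2: 64 equally likely voxels
        v = VoxelRef(0, (0, 0, 0))
        counts = np.zeros(64, dtype=int)
        for _ in range(6400):
            [(_, out)] = place_products([self._species(2)], v, self.hier, self.rng)
            i, j, k = out.ijk
            counts[(i * 4 + j) * 4 + k] += 1
        chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
        assert stats.chi2.sf(chi2, df=63) > 0.05

    def test_unresolved_species_rejected(self):
        s = Species("X", 1.0, 0.01)
        with pytest.raises(ValueError, match="no assigned level"):
            place_products([s], VoxelRef(0, (0, 0, 0)), self.hier, self.rng)


class TestEngineCoupling:
    """The kernel's transfer/placement behaviour, via event and transfer logs."""

    def test_promotion_ladder_timing_and_order(self):
        # a single molecule born on the finest of 7 levels climbs to the
        # root; each rung takes at least (C h_l)^2 / 6D of diffusing time
        model = pure_diffusion_model(n_levels=7, level=6)
        policy = TransferPolicy(C=20.0)
        state = initialize(model, seed=3, transfer_policy=policy,
                           log_transfers=True)
        state.advance_to(2000.0)
        log = state.transfer_log()
        assert list(log["from_level"]) == [6, 5, 4, 3, 2, 1]
        hier = model.hierarchy()
        t_prev = 0.0
        for lvl, t in zip(log["from_level"], log["time"]):
            assert t - t_prev >= transfer_time(1.0, float(hier.widths[lvl]), 20.0)
            t_prev = t
        (m,) = state.molecules()
        assert m.voxel.level == 0

    def test_transfers_disabled_matches_huge_C_exactly(self):
        # with C so large that no transfer can fire before t_final, the
        # hierarchical run and the transfer-free run are bit-identical
        model = pure_diffusion_model(n_levels=5, level=4, n=20)
        a = initialize(model, seed=8,
                       transfer_policy=TransferPolicy(C=1e9)).run(2.0, n_samples=10)
        b = initialize(model, seed=8,
                       transfer_policy=TransferPolicy(C=20.0, enabled=False)
                       ).run(2.0, n_samples=10)
        assert np.array_equal(a.counts, b.counts)

    def test_dissociation_products_coplaced_on_finest_mesh(self):
        # X -> A + B with A, B requiring level 2: both products of every
        # dissociation appear in the same voxel, uniformly distributed
        m = ReactionModel(
            [Species("X", 1.0, 0.0), Species("A", 1.0, 0.03),
             Species("B", 1.0, 0.03)],
            [ReactionChannel(("X",), ("A", "B"), 1.0)],
            volume=1.0, n_levels=3, initial={"X": 6400},
            solver=SolverConfig())
        m.resolve(assign_levels=False)
        for s in m.species:
            s.finest_level = 2 if s.name in ("A", "B") else 0
        state = initialize(m, seed=77, log_reactions=True)
        state.advance_to(15.0)
        log = state.reaction_log()
        dis = log[log["channel"] == 0]
        assert len(dis) > 6000
        assert (dis["p1_level"] == 2).all() and (dis["p2_level"] == 2).all()
        same = ((dis["p1_i"] == dis["p2_i"]) & (dis["p1_j"] == dis["p2_j"])
                & (dis["p1_k"] == dis["p2_k"]))
        assert same.all()
        flat = (dis["p1_i"] * 4 + dis["p1_j"]) * 4 + dis["p1_k"]
        counts = np.bincount(flat, minlength=64)
        exp = len(dis) / 64.0
        chi2 = ((counts - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, df=63) > 0.05
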