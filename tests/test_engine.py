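"""Event loop: queue discipline, co-location rules, exactness, determinism."""

import math

import numpy as np
import pytest
from scipy import stats

from hrdme.coupling import TransferPolicy
from hrdme.engine import initialize, sample_bimolecular, step
from hrdme.mesh import VoxelRef
from hrdme.model import ReactionChannel, ReactionModel, SolverConfig, Species

from conftest import make_pair_model, pure_diffusion_model


class TestInitialize:
    def test_inert_molecule_on_root_has_no_events(self):
        model = pure_diffusion_model(n_levels=3, level=0)
        state = initialize(model, seed=0)
        assert len(state.queue) == 0

    def test_colocated_pair_gets_one_reaction_and_two_diffusion_events(self):
        model = make_pair_model(n_levels=3)
        v = VoxelRef(2, (1, 1, 1))
        state = initialize(model, seed=0,
                           initial_placement={"A": [v], "B": [v]})
        kinds = sorted(e.kind for e in state.queue.events())
        assert kinds == ["bimolecular", "diffusion", "diffusion"]

    def test_separated_pair_gets_no_reaction_event(self):
        model = make_pair_model(n_levels=3)
        state = initialize(model, seed=0, initial_placement={
            "A": [VoxelRef(2, (0, 0, 0))], "B": [VoxelRef(2, (3, 3, 3))]})
        assert sorted(e.kind for e in state.queue.events()) == \
            ["diffusion", "diffusion"]

    def test_benchmark_initial_queue(self, single_layer_model):
        # 100 molecules on the single-voxel level: no diffusion is possible
        # there, so the queue holds exactly one unimolecular event each
        state = initialize(single_layer_model, seed=1)
        events = state.queue.events()
        assert len(events) == 100
        assert {e.kind for e in events} == {"unimolecular"}

    def test_birth_channel_gets_one_pending_event(self):
        m = ReactionModel([Species("A", 1.0)],
                          [ReactionChannel((), ("A",), 3.0)],
                          n_levels=2, initial={}, solver=SolverConfig())
        m.resolve()
        state = initialize(m, seed=0)
        (e,) = state.queue.events()
        assert e.kind == "birth"

    def test_bad_placement_rejected(self):
        model = make_pair_model(n_levels=3)
        with pytest.raises(ValueError, match="expected 1"):
            initialize(model, initial_placement={"A": []})


class TestStep:
    def test_diffusion_conserves_molecules(self):
        model = pure_diffusion_model(n_levels=4, level=3, n=5)
        state = initialize(model, seed=2)
        for _ in range(200):
            step(state)
            assert state.counts() == {"A": 5}

    def test_event_times_nondecreasing(self):
        model = make_pair_model(n_levels=3, reversible=2.0,
                                initial={"A": 3, "B": 3})
        state = initialize(model, seed=5)
        prev = 0.0
        for _ in range(500):
            state.step()
            assert state.time >= prev
            prev = state.time

    def test_reaction_decrements_counts_and_places_product(self):
        model = make_pair_model(n_levels=3)
        v = VoxelRef(2, (1, 1, 1))
        state = initialize(model, seed=3,
                           initial_placement={"A": [v], "B": [v]})
        while state.counts()["C"] == 0:
            state.step()
        assert state.counts() == {"A": 0, "B": 0, "C": 1}
        (c,) = state.molecules()
        # C is a coarse species: it sits in the ancestor of the reaction voxel
        assert c.voxel == VoxelRef(0, (0, 0, 0))

    def test_queue_hygiene_along_a_run(self, single_layer_model):
        state = initialize(single_layer_model, seed=9)
        for _ in range(60):
            for _ in range(25):
                state.step()
            alive = {m.uid for m in state.molecules()}
            by_level = {m.uid: m.voxel.level for m in state.molecules()}
            diff_count: dict[int, int] = {}
            for e in state.queue.events():
                assert set(e.actors) <= alive
                if e.kind == "diffusion":
                    diff_count[e.actors[0]] = diff_count.get(e.actors[0], 0) + 1
            for uid, lvl in by_level.items():
                assert diff_count.get(uid, 0) == (1 if lvl > 0 else 0)

    def test_remove_by_actor_clears_all_events(self):
        model = make_pair_model(n_levels=3)
        v = VoxelRef(2, (0, 1, 0))
        state = initialize(model, seed=4,
                           initial_placement={"A": [v], "B": [v]})
        uid = state.molecules()[0].uid
        state.queue.remove_by_actor(uid)
        for e in state.queue.events():
            assert uid not in e.actors


class TestSampleBimolecular:
    def _state(self):
        model = make_pair_model(n_levels=3)
        return model, initialize(model, seed=0, initial_placement={
            "A": [VoxelRef(2, (1, 1, 1))], "B": [VoxelRef(2, (1, 1, 1))]})

    def test_same_voxel_same_level_uses_that_levels_rate(self):
        model, state = self._state()
        a, b = state.molecules()
        rng = np.random.default_rng(1)
        chan = model.reactions[0]
        ev = sample_bimolecular(state, a, b, chan, rng)
        assert ev is not None and ev.kind == "bimolecular"
        # the waiting time scale is 1/k_meso(level 2): check in distribution
        times = np.array([sample_bimolecular(state, a, b, chan, rng).time
                          for _ in range(4000)])
        assert times.mean() == pytest.approx(1.0 / chan.k_meso_by_level[2], rel=0.05)

    def test_fine_molecule_inside_coarse_uses_coarse_rate(self):
        model = make_pair_model(n_levels=3)
        state = initialize(model, seed=0, initial_placement={
            "A": [VoxelRef(0, (0, 0, 0))], "B": [VoxelRef(2, (3, 2, 1))]})
        a, b = state.molecules()
        chan = model.reactions[0]
        rng = np.random.default_rng(2)
        times = np.array([sample_bimolecular(state, a, b, chan, rng).time
                          for _ in range(4000)])
        assert times.mean() == pytest.approx(1.0 / chan.k_meso_by_level[0], rel=0.05)

    def test_disjoint_voxels_yield_no_event(self):
        model = make_pair_model(n_levels=3)
        state = initialize(model, seed=0, initial_placement={
            "A": [VoxelRef(1, (0, 0, 0))], "B": [VoxelRef(2, (3, 3, 3))]})
        a, b = state.molecules()
        assert sample_bimolecular(state, a, b, model.reactions[0]) is None

    def test_wrong_channel_rejected(self):
        model, state = self._state()
        a, b = state.molecules()
        bad = ReactionChannel(("A", "A"), (), 1.0)
        with pytest.raises(ValueError, match="does not match"):
            sample_bimolecular(state, a, a, model.reactions[0])
            sample_bimolecular(state, a, b, bad)


class TestExactness:
    def test_pure_decay_is_exponential(self):
        # A -> 0 with k = 2: first-reaction times across replicates follow
        # Exp(2) exactly (KS test)
        m = ReactionModel([Species("A", 1.0)],
                          [ReactionChannel(("A",), (), 2.0)],
                          n_levels=1, initial={"A": 1}, solver=SolverConfig())
        m.resolve()
        times = []
        for s in range(2000):
            st = initialize(m, seed=s, log_reactions=True)
            st.advance_to(1e9)
            times.append(st.reaction_log()["time"].iloc[0])
        res = stats.kstest(times, "expon", args=(0, 0.5))
        assert res.pvalue > 0.05

    def test_one_pair_mean_reaction_time(self):
        # A + B -> C both on the root voxel: waiting time mean 1/k_meso(0)
        model = make_pair_model(n_levels=2)
        v = VoxelRef(0, (0, 0, 0))
        chan = model.reactions[0]
        times = []
        for s in range(4000):
            st = initialize(model, seed=s, log_reactions=True,
                            initial_placement={"A": [v], "B": [v]})
            st.advance_to(1e9)
            times.append(st.reaction_log()["time"].iloc[0])
        times = np.array(times)
        expected = 1.0 / chan.k_meso_by_level[0]
        se = times.std(ddof=1) / math.sqrt(len(times))
        assert abs(times.mean() - expected) < 3 * se


class TestStoichiometricInvariants:
    def test_single_layer_conservation(self, single_layer_model):
        tr = initialize(single_layer_model, seed=13).run(3.0, n_samples=60)
        df = tr.to_frame()
        assert (df["S1"] + df["S11"] + df["S2"] == 100).all()
        assert (df["S1"] + df["S12"] + df["S2"] == 100).all()

    def test_rebind_conservation(self, rebind_model):
        tr = initialize(rebind_model, seed=14).run(50.0, n_samples=50)
        df = tr.to_frame()
        assert (df["S1"] + df["S3"] == 1).all()
        assert (df["S1"] == df["S2"]).all()


class TestDeterminism:
    def test_identical_seed_reproduces_trajectory_bitwise(self, single_layer_model):
        a = initialize(single_layer_model, seed=21, log_reactions=True,
                       log_transfers=True).run(1.0, n_samples=50)
        b = initialize(single_layer_model, seed=21, log_reactions=True,
                       log_transfers=True).run(1.0, n_samples=50)
        assert np.array_equal(a.counts, b.counts)
        assert a.reactions.equals(b.reactions)
        assert a.transfers.equals(b.transfers)

    def test_different_seeds_differ(self, single_layer_model):
        a = initialize(single_layer_model, seed=21).run(1.0, n_samples=50)
        b = initialize(single_layer_model, seed=22).run(1.0, n_samples=50)
        assert not np.array_equal(a.counts, b.counts)


class TestRunContract:
    def test_zero_horizon_echoes_initial_counts(self, single_layer_model):
        tr = initialize(single_layer_model, seed=0).run(0.0, sample_times=[0.0])
        assert tr.counts[0].tolist() == [100, 0, 0, 0]

    def test_sample_grid_shape(self, single_layer_model):
        tr = initialize(single_layer_model, seed=0).run(0.5, n_samples=100)
        assert tr.times.shape == (101,)
        assert tr.counts.shape == (101, 4)

    def test_unsorted_grid_rejected(self, single_layer_model):
        with pytest.raises(ValueError, match="sorted"):
            initialize(single_layer_model, seed=0).run(1.0, sample_times=[0.5, 0.1])

    def test_trajectory_tsv_round_trip(self, tmp_path, single_layer_model):
        import pandas as pd

        tr = initialize(single_layer_model, seed=0).run(0.2, n_samples=4)
        path = tmp_path / "traj.tsv"
        tr.write_tsv(str(path), header_comment="seed=0")
        back = pd.read_csv(path, sep="\t", comment="#")
        assert np.array_equal(back[tr.species].to_numpy(), tr.counts)


def test_growth_from_tiny_buffers():
    # birth chain 0 -> A -> 0 forces molecule/heap/log growth mid-run
    m = ReactionModel([Species("A", 1.0)],
                      [ReactionChannel((), ("A",), 500.0),
                       ReactionChannel(("A",), (), 1.0)],
                      n_levels=3, initial={}, solver=SolverConfig())
    m.resolve()
    state = initialize(m, seed=6, log_reactions=True)
    state.advance_to(2.0)
    x = state.counts()["A"]
    assert x > 300  # near the stationary mean of 500
    assert len(state.reaction_log()) > 500
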