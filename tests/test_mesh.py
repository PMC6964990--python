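"""Mesh hierarchy: index arithmetic, topology, jump rates, diffusion laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hrdme.engine import initialize
from hrdme.mesh import MeshHierarchy, VoxelRef

from conftest import pure_diffusion_model


@pytest.fixture(scope="module")
def hier():
    return MeshHierarchy(7, 1.0)


def voxels(max_level=6):
    return st.integers(0, max_level).flatmap(
        lambda l: st.tuples(*(st.integers(0, 2**l - 1),) * 3).map(
            lambda ijk: VoxelRef(l, ijk)))


class TestIndexArithmetic:
    def test_parent_examples(self, hier):
        assert hier.parent(VoxelRef(3, (5, 2, 7))) == VoxelRef(2, (2, 1, 3))
        assert hier.parent(VoxelRef(1, (0, 0, 0))) == VoxelRef(0, (0, 0, 0))
        with pytest.raises(ValueError):
            hier.parent(VoxelRef(0, (0, 0, 0)))

    @given(voxels(5))
    @settings(max_examples=100, deadline=None)
    def test_children_partition_their_parent(self, v):
        hier = MeshHierarchy(7, 1.0)
        kids = hier.children(v)
        assert len(kids) == 8
        assert len(set(kids)) == 8
        for c in kids:
            assert hier.parent(c) == v

    def test_no_children_on_finest_level(self, hier):
        with pytest.raises(ValueError):
            hier.children(VoxelRef(6, (0, 0, 0)))

    @given(voxels(6), st.integers(0, 6))
    @settings(max_examples=100, deadline=None)
    def test_ancestor_agrees_with_iterated_parent(self, v, level):
        hier = MeshHierarchy(7, 1.0)
        if level > v.level:
            with pytest.raises(ValueError):
                hier.ancestor_at(v, level)
            return
        expected = v
        while expected.level > level:
            expected = hier.parent(expected)
        assert hier.ancestor_at(v, level) == expected
        assert hier.ancestor_at(v, v.level) == v

    def test_root_ancestor(self, hier):
        assert hier.ancestor_at(VoxelRef(5, (31, 0, 12)), 0) == VoxelRef(0, (0, 0, 0))

    def test_descendants_tile(self, hier):
        v = VoxelRef(1, (1, 0, 1))
        d = list(hier.descendants(v, 3))
        assert len(d) == 64
        assert all(hier.ancestor_at(x, 1) == v for x in d)


class TestTopology:
    def test_neighbor_counts(self, hier):
        assert hier.neighbors(VoxelRef(0, (0, 0, 0))) == []
        assert len(hier.neighbors(VoxelRef(2, (0, 0, 0)))) == 3
        assert len(hier.neighbors(VoxelRef(6, (10, 20, 30)))) == 6
        assert len(hier.neighbors(VoxelRef(2, (0, 1, 0)))) == 4

    @given(voxels(4))
    @settings(max_examples=100, deadline=None)
    def test_neighbors_are_symmetric_same_level(self, v):
        hier = MeshHierarchy(7, 1.0)
        for n in hier.neighbors(v):
            assert n.level == v.level
            assert v in hier.neighbors(n)
            assert sum(abs(a - b) for a, b in zip(n.ijk, v.ijk)) == 1

    def test_voxel_counts_and_tiling(self, hier):
        for l in range(7):
            assert hier.n_voxels(l) == 8**l
            # per-level voxel volumes sum to the domain volume
            assert hier.n_voxels(l) * float(hier.widths[l]) ** 3 == pytest.approx(1.0)


class TestJumpRates:
    def test_interior_rate(self, hier):
        v = VoxelRef(6, (10, 20, 30))
        assert hier.jump_rate(1.0, v) == pytest.approx(6 * 64**2)
        assert hier.jump_rate(1.0, v) == pytest.approx(24576)

    def test_corner_is_half_interior(self, hier):
        corner = hier.jump_rate(1.0, VoxelRef(6, (0, 0, 0)))
        interior = hier.jump_rate(1.0, VoxelRef(6, (5, 5, 5)))
        assert corner == pytest.approx(interior / 2)

    def test_root_rate_zero(self, hier):
        assert hier.jump_rate(5.0, VoxelRef(0, (0, 0, 0))) == 0.0

    def test_summary_report(self, hier):
        text = hier.summary({"A": 1.0})
        assert "262144" in text and "7 levels" in text


class TestDiffusionLaws:
    def test_uniform_stationary_occupancy(self):
        # one molecule on the 4^3 mesh, positions sampled at intervals long
        # compared with the domain mixing time, chi^2 against uniform
        model = pure_diffusion_model(n_levels=3, level=2)
        from hrdme.coupling import TransferPolicy
        state = initialize(model, seed=12345,
                           transfer_policy=TransferPolicy(enabled=False))
        counts = np.zeros(64, dtype=int)
        for i in range(6400):
            state.advance_to((i + 1) * 1.0)
            (m,) = state.molecules()
            i0, j0, k0 = m.voxel.ijk
            counts[(i0 * 4 + j0) * 4 + k0] += 1
        chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
        p = stats.chi2.sf(chi2, df=63)
        assert p > 0.05

    def test_mean_squared_displacement(self):
        # 1e4 independent walkers on a 256^3 mesh (fine enough that the
        # reflecting walls bias MSD by ~1.5% at this horizon): voxel-center
        # MSD ~ 6 D t within 5% at t = 100 h^2 / D
        model = pure_diffusion_model(n_levels=9, level=8, n=10_000)
        hier = model.hierarchy()
        h = float(hier.widths[8])
        t = 100 * h * h
        state = initialize(model, seed=999)
        start = {m.uid: hier.voxel_center(m.voxel) for m in state.molecules()}
        state.advance_to(t)
        disp2 = [np.sum((hier.voxel_center(m.voxel) - start[m.uid]) ** 2)
                 for m in state.molecules()]
        assert np.mean(disp2) == pytest.approx(6.0 * t, rel=0.05)


def test_bounds_validation():
    with pytest.raises(ValueError):
        VoxelRef(2, (4, 0, 0))
    with pytest.raises(ValueError):
        VoxelRef(-1, (0, 0, 0))
    with pytest.raises(ValueError):
        MeshHierarchy(0)
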