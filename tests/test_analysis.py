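"""Lesion observables: profiles, front depths, drop depth, etch patterns."""

import numpy as np
import pytest

import rodemin as rm
from rodemin.analysis import (
    MineralProfile,
    classify_etch_pattern,
    drop_depth,
    extract_front,
    front_depth,
    mineral_profile,
    transverse_regions,
)
from rodemin.geometry import REGION_CODES
from rodemin.solver import SimState


@pytest.fixture(scope="module")
def grid():
    return rm.build_rve(rm.GeometryConfig(nx=48, ny=48, nz=32, L=64.0))


class TestMineralProfile:
    def test_pristine_profile_is_one(self, grid):
        state = SimState(H=np.zeros(grid.shape), Phi=np.ones(grid.shape))
        p = mineral_profile(state, grid)
        np.testing.assert_array_equal(p.M, 1.0)
        assert len(p.z) == grid.shape[2]

    def test_half_dissolved_section_gives_half(self, grid):
        Phi = np.ones(grid.shape)
        Phi[:24, :, 5] = 0.0  # exactly half the cells of one section
        p = mineral_profile(SimState(H=np.zeros(grid.shape), Phi=Phi), grid)
        assert p.M[5] == pytest.approx(0.5)
        assert p.M[6] == 1.0

    def test_matches_double_sum_oracle(self, grid):
        rng = np.random.default_rng(11)
        Phi = rng.random(grid.shape)
        p = mineral_profile(SimState(H=np.zeros(grid.shape), Phi=Phi), grid)
        nx, ny, _ = grid.shape
        oracle = np.array([
            sum(Phi[i, j, k] for i in range(nx) for j in range(ny)) / (nx * ny)
            for k in range(grid.shape[2])
        ])
        np.testing.assert_allclose(p.M, oracle, atol=1e-14)

    def test_validation(self):
        with pytest.raises(ValueError):
            MineralProfile(z=np.array([1.0, 1.0]), M=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            MineralProfile(z=np.array([1.0, 2.0]), M=np.array([0.5, 1.5]))


class TestFrontDepth:
    def test_step_profile(self):
        z = np.arange(0.5, 100.0)
        M = np.where(z < 40.0, 0.0, 1.0)
        p = MineralProfile(z=z, M=M)
        assert front_depth(p, 0.8) == pytest.approx(40.0, abs=0.5)

    def test_linear_profile_interpolates(self):
        z = np.arange(0.5, 250.0)
        p = MineralProfile(z=z, M=z / 250.0)
        assert front_depth(p, 0.8) == pytest.approx(200.0, abs=1e-9)

    def test_pristine_profile_gives_zero(self):
        z = np.arange(0.5, 10.0)
        p = MineralProfile(z=z, M=np.ones_like(z))
        assert front_depth(p, 0.8) == 0.0
        assert front_depth(p, 0.2) == 0.0

    def test_never_reached_gives_axis_length(self):
        z = np.arange(0.5, 10.0)
        p = MineralProfile(z=z, M=np.full_like(z, 0.1))
        assert front_depth(p, 0.8) == z[-1]


class TestDropDepth:
    def test_step_at_forty(self):
        z = np.arange(0.5, 100.0)
        p = MineralProfile(z=z, M=np.where(z < 40.0, 0.0, 1.0))
        assert drop_depth(p) == pytest.approx(40.0, abs=0.5)

    def test_constant_ramp_takes_shallowest(self):
        z = np.arange(0.5, 100.0)
        M = np.arange(z.size) / 256.0  # exactly representable: all steps tie
        p = MineralProfile(z=z, M=M)
        # every interface below M=0.5 ties; documented tie-break: shallowest
        assert drop_depth(p) == pytest.approx(0.5 * (z[0] + z[1]))

    def test_no_lesion_returns_nan(self):
        z = np.arange(0.5, 10.0)
        p = MineralProfile(z=z, M=np.full_like(z, 0.9))
        assert np.isnan(drop_depth(p))


class TestExtractFront:
    def test_pristine_gives_zero_depth(self, grid):
        state = SimState(H=np.zeros(grid.shape), Phi=np.ones(grid.shape))
        f = extract_front(state, grid)
        np.testing.assert_array_equal(f.depth, 0.0)

    def test_uniform_crossing_depth(self, grid):
        Phi = np.ones(grid.shape)
        Phi[:, :, :5] = 0.0  # dissolved to z = 10 µm (hz = 2)
        f = extract_front(SimState(H=np.zeros(grid.shape), Phi=Phi), grid)
        np.testing.assert_allclose(f.depth, 10.0, atol=grid.geometry.hz)

    def test_recovers_synthetic_front_surface(self, grid):
        g = grid.geometry
        X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
        target = 20.0 + 6.0 * np.sin(2 * np.pi * X / g.l) * np.cos(2 * np.pi * Y / g.l)
        eps = 1.5
        Z = grid.z[None, None, :]
        Phi = 1.0 / (1.0 + np.exp(-(Z - target[:, :, None]) / eps))
        f = extract_front(SimState(H=np.zeros(grid.shape), Phi=Phi), grid)
        assert np.abs(f.depth - target).max() < eps

    def test_consistency_with_profile_median(self, grid):
        """front_depth(0.5) of M and the median of the front surface agree
        within two cells for a smooth front."""
        Z = grid.z[None, None, :]
        Phi = np.broadcast_to(1.0 / (1.0 + np.exp(-(Z - 22.0) / 2.0)), grid.shape)
        state = SimState(H=np.zeros(grid.shape), Phi=Phi.copy())
        d1 = front_depth(mineral_profile(state, grid), 0.5)
        d2 = float(np.median(extract_front(state, grid).depth))
        assert abs(d1 - d2) <= 2 * grid.geometry.hz


class TestEtchPattern:
    def _front(self, grid, head_depth, inter_depth):
        labels = transverse_regions(grid, 2)
        depth = np.full(labels.shape, inter_depth, dtype=float)
        depth[labels == REGION_CODES["rod_head"]] = head_depth
        from rodemin.analysis import FrontSurface
        return FrontSurface(depth=depth, axis=2)

    def test_head_preferential_is_type1(self, grid):
        assert classify_etch_pattern(self._front(grid, 30.0, 10.0), grid) == "Type1"

    def test_periphery_preferential_is_type2(self, grid):
        assert classify_etch_pattern(self._front(grid, 10.0, 30.0), grid) == "Type2"

    def test_flat_front_indeterminate(self, grid):
        assert classify_etch_pattern(self._front(grid, 20.0, 20.0), grid) == "Indeterminate"

    def test_lateral_attack_transverse_labels(self, grid):
        labels = transverse_regions(grid, 1)
        assert labels.shape == (grid.geometry.nx, grid.geometry.nz)
        # lines through the head centre x carry the rod_head label
        g = grid.geometry
        ix = int(g.head_center[0] / g.hx)
        assert labels[ix, 0] == REGION_CODES["rod_head"]
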