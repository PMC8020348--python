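"""Transport and level-set solver: unit examples, conservation, oracles."""

import math

import numpy as np
import pytest

import rodemin as rm
from rodemin.analysis import front_depth, mineral_profile
from rodemin.fixtures import brute_force_step, erfc_solution
from rodemin.solver import (
    ADITransport,
    AxisBC,
    KineticsParams,
    SimState,
    SolverOptions,
    TransportOperator,
    axis_boundaries,
    arrhenius_diffusivity,
    concentration_to_ph,
    effective_diffusivity,
    limit_cross_terms,
    make_transport_stepper,
    ph_to_concentration,
    porosity_corrected_diffusivity,
    reaction_rate,
    run_simulation,
    step_level_set,
    R_GAS,
)

from conftest import column_config, tensor_dict


# ---------------------------------------------------------------------------
# pointwise helpers
# ---------------------------------------------------------------------------

class TestPointwise:
    def test_ph_conversion(self):
        assert ph_to_concentration(14.0) == 1e-14  # neutral-ish initial pore fluid
        assert ph_to_concentration(0.0) == 1.0
        assert ph_to_concentration(4.4) == pytest.approx(10 ** -4.4, rel=1e-15)
        assert concentration_to_ph(1e-7) == pytest.approx(7.0)

    def test_reaction_rate_sign_and_equilibrium(self):
        p = KineticsParams(k=2.0e-7, Hc=0.0)
        default = KineticsParams()
        assert reaction_rate(default.Hc, default) == 0.0
        assert reaction_rate(1.0, KineticsParams(k=0.0)) == 0.0
        # undersaturated solution consumes H at k*(Hc - H)
        assert reaction_rate(1e-5, p) == pytest.approx(-2.0e-12)

    def test_porosity_correction(self):
        assert porosity_corrected_diffusivity(5.0, KineticsParams()) == 5.0
        p = KineticsParams(porosity_eps_t=0.5, constrictivity_delta=0.8,
                           tortuosity_tau=2.0)
        assert porosity_corrected_diffusivity(1.0, p) == pytest.approx(0.2)

    def test_arrhenius(self):
        assert arrhenius_diffusivity(2.0, 0.0, 300.0) == 2.0
        assert arrhenius_diffusivity(1.0, R_GAS * 300, 300.0) == pytest.approx(math.exp(-1))
        with pytest.raises(ValueError):
            arrhenius_diffusivity(1.0, 1.0, -5.0)

    def test_effective_diffusivity_blend(self, default_grid):
        local = rm.LocalDiffusivity(d_fast=1.0, d_trans=1.0, d_sheath=1.0, d_demin=3.0)
        model = rm.OrientationModel(theta_coeffs=(0, 0, 0, 0), psi_coeffs=(0, 0, 0, 0))
        f = rm.assemble_diffusivity_field(default_grid, model, local)
        shape = default_grid.shape
        for phi, expected in ((1.0, 1.0), (0.0, 3.0), (0.5, 2.0)):
            D = effective_diffusivity(f, np.full(shape, phi), local)
            assert np.allclose(D["dzz"], expected)
            assert np.allclose(D["dxy"], 0.0)


# ---------------------------------------------------------------------------
# transport: conservation, maximum principle, oracles
# ---------------------------------------------------------------------------

def _iso_D(shape, value):
    D = {k: np.zeros(shape) for k in ("dxy", "dxz", "dyz")}
    D.update({k: np.full(shape, value) for k in ("dxx", "dyy", "dzz")})
    return D


NOFLUX = (AxisBC("periodic", "periodic"), AxisBC("periodic", "periodic"),
          AxisBC("noflux", "noflux"))


class TestTransport:
    def test_uniform_state_is_stationary(self, small_grid):
        op = TransportOperator(small_grid, NOFLUX)
        H = np.full(small_grid.shape, 0.37)
        out = op.step(H, _iso_D(small_grid.shape, 1e-2), KineticsParams(k=0.0), 5.0)
        np.testing.assert_allclose(out, H, rtol=1e-14)

    def test_mass_conserved_without_reaction(self, small_grid):
        """No-flux faces and k = 0: total amount is invariant (1000 steps)."""
        op = TransportOperator(small_grid, NOFLUX)
        rng = np.random.default_rng(3)
        H = rng.random(small_grid.shape)
        D = _iso_D(small_grid.shape, 5e-3)
        total0 = H.sum()
        kin = KineticsParams(k=0.0)
        for _ in range(1000):
            H = op.step(H, D, kin, 2.0)
        assert abs(H.sum() - total0) / total0 < 1e-10

    def test_discrete_maximum_principle(self, small_grid):
        """Pure diffusion: H stays within initial + boundary bounds."""
        bcs = (AxisBC("periodic", "periodic"), AxisBC("periodic", "periodic"),
               AxisBC("dirichlet", "dirichlet", 0.8, 0.1))
        op = TransportOperator(small_grid, bcs)
        rng = np.random.default_rng(4)
        H = 0.2 + 0.3 * rng.random(small_grid.shape)
        lo = min(H.min(), 0.1)
        hi = max(H.max(), 0.8)
        kin = KineticsParams(k=0.0)
        D = _iso_D(small_grid.shape, 1e-2)
        for _ in range(50):
            H = op.step(H, D, kin, 10.0)
            assert H.min() >= lo - 1e-12
            assert H.max() <= hi + 1e-12

    def test_steady_linear_profile_on_column(self):
        """Dirichlet H0 / 0 at the column ends relaxes to a linear profile."""
        cfg = column_config(D=1e-2, L=20.0, nz=40)
        grid = rm.build_rve(cfg.geometry)
        bcs = (AxisBC("periodic", "periodic"), AxisBC("periodic", "periodic"),
               AxisBC("dirichlet", "dirichlet", 1.0, 0.0))
        op = TransportOperator(grid, bcs)
        H = np.zeros(grid.shape)
        kin = KineticsParams(k=0.0)
        D = _iso_D(grid.shape, 1e-2)
        for _ in range(60):
            H = op.step(H, D, kin, 5e3)  # ~steady after a few diffusion times
        expected = 1.0 - grid.z / 20.0
        np.testing.assert_allclose(H[0, 0], expected, rtol=1e-6)

    def test_transient_matches_erfc_solution(self):
        """1-D semi-infinite transient agrees with the erfc oracle within 1%."""
        D0, t_end, dt = 1e-2, 5e4, 100.0
        cfg = column_config(D=D0, L=150.0, nz=300)
        grid = rm.build_rve(cfg.geometry)
        bcs = (AxisBC("periodic", "periodic"), AxisBC("periodic", "periodic"),
               AxisBC("dirichlet", "dirichlet", 1.0, 0.0))
        op = TransportOperator(grid, bcs)
        H = np.zeros(grid.shape)
        kin = KineticsParams(k=0.0)
        D = _iso_D(grid.shape, D0)
        for _ in range(int(t_end / dt)):
            H = op.step(H, D, kin, dt)
        ref = erfc_solution(grid.z, t_end, D0, 1.0)
        sel = (ref > 1e-2) & (grid.z > 1.0)  # interior, unaffected by far sink
        err = np.abs(H[0, 0][sel] - ref[sel]) / ref[sel]
        assert err.max() < 0.01

    def test_implicit_solver_matches_brute_force_oracle(self, small_grid, small_field,
                                                        small_local):
        """50 implicit steps vs tiny-dt explicit stepping within 0.5% per cell."""
        g = small_grid.geometry
        shape = small_grid.shape
        D = tensor_dict(small_field, shape)
        bcs = (AxisBC("periodic", "periodic"), AxisBC("periodic", "periodic"),
               AxisBC("dirichlet", "dirichlet", 1.0, 0.0))
        # the flux limiter must be inactive on this smooth sheath-free field,
        # so both solvers integrate the identical operator
        lim = limit_cross_terms(D, bcs)
        for name in D:
            np.testing.assert_array_equal(lim[name], D[name])
        kin = KineticsParams(k=1e-5, Hc=0.5)
        X, Y, Z = np.meshgrid(small_grid.x, small_grid.y, small_grid.z, indexing="ij")
        H0 = (1.0 - Z / g.L) + 0.2 * np.sin(2 * np.pi * X / g.l) * \
            np.cos(2 * np.pi * Y / g.l) * np.sin(np.pi * Z / g.L)
        op = TransportOperator(small_grid, bcs)
        dt, sub = 1.0, 100
        H = H0.copy()
        for _ in range(50):
            H = op.step(H, D, kin, dt)
        He = H0.copy()
        h = (g.hx, g.hy, g.hz)
        for _ in range(50 * sub):
            He = brute_force_step(He, D, bcs, h, dt / sub, k=kin.k, Hc=kin.Hc)
        err = np.abs(H - He) / np.maximum(np.abs(He), 1e-12)
        assert err.max() < 0.005

    def test_adi_path_consistent_with_direct_path(self):
        """The large-grid split integrator reproduces backward Euler closely."""
        g = rm.GeometryConfig(nx=36, ny=36, nz=16, L=32.0)
        grid = rm.build_rve(g)
        cfg = rm.SimulationConfig(geometry=g)
        field = rm.assemble_diffusivity_field(grid, cfg.orientation, cfg.diffusivity)
        D = effective_diffusivity(field, np.ones(grid.shape), cfg.diffusivity)
        bcs = axis_boundaries(cfg)
        kin = cfg.kinetics
        be = TransportOperator(grid, bcs)
        adi = ADITransport(grid, bcs, SolverOptions())
        Hb = np.full(grid.shape, 1e-14)
        Ha = Hb.copy()
        for _ in range(8):
            Hb = be.step(Hb, D, kin, 21600.0)
            Ha = adi.step(Ha, D, kin, 21600.0)
        assert np.linalg.norm(Hb - Ha) / np.linalg.norm(Hb) < 0.05
        thr = kin.trigger_concentration
        def crossing(Harr):
            below = Harr < thr
            out = np.argmax(below, axis=2).astype(float)
            out[~below.any(axis=2)] = Harr.shape[2]
            return out
        assert np.abs(crossing(Hb) - crossing(Ha)).max() <= 1.0

    def test_stepper_dispatch(self, small_grid):
        assert isinstance(make_transport_stepper(small_grid, NOFLUX), TransportOperator)
        opts = SolverOptions(method="adi")
        assert isinstance(make_transport_stepper(small_grid, NOFLUX, opts), ADITransport)
        opts = SolverOptions(direct_limit=10)
        assert isinstance(make_transport_stepper(small_grid, NOFLUX, opts), ADITransport)


# ---------------------------------------------------------------------------
# level set
# ---------------------------------------------------------------------------

class TestLevelSet:
    def test_no_trigger_leaves_phi_untouched(self):
        cfg = column_config(L=10.0, nz=20, dt_s=1e3)
        grid = rm.build_rve(cfg.geometry)
        state = SimState(H=np.full(grid.shape, 1e-9), Phi=np.ones(grid.shape))
        out = step_level_set(state, cfg, grid=grid)
        np.testing.assert_array_equal(out.Phi, 1.0)

    def test_uniform_half_phi_is_finite_and_bounded(self):
        cfg = column_config(L=10.0, nz=20, dt_s=1e3)
        grid = rm.build_rve(cfg.geometry)
        state = SimState(H=np.full(grid.shape, 1e-9), Phi=np.full(grid.shape, 0.5))
        out = step_level_set(state, cfg, grid=grid)
        assert np.all(np.isfinite(out.Phi))
        assert out.Phi.min() >= 0.0 and out.Phi.max() <= 0.5 + 1e-12

    def test_phi_never_increases(self):
        cfg = column_config(L=10.0, nz=20, dt_s=1e3, pH_acid=4.0)
        grid = rm.build_rve(cfg.geometry)
        rng = np.random.default_rng(7)
        Phi = rng.uniform(0.2, 1.0, grid.shape)
        H = rng.uniform(0, 1e-5, grid.shape)
        out = step_level_set(SimState(H=H, Phi=Phi.copy()), cfg, grid=grid)
        assert np.all(out.Phi <= Phi + 1e-15)
        assert out.Phi.min() >= 0.0

    def test_sheath_is_acid_resistant(self):
        g = rm.GeometryConfig(nx=48, ny=48, nz=4)
        cfg = rm.SimulationConfig(geometry=g, dt_s=1e5)
        grid = rm.build_rve(g)
        H = np.full(grid.shape, 1e-3)  # strongly acidic everywhere
        out = step_level_set(SimState(H=H, Phi=np.ones(grid.shape)), cfg, grid=grid)
        sheath3d = grid.region_3d() == rm.geometry.REGION_CODES["sheath"]
        assert np.all(out.Phi[sheath3d] == 1.0)
        assert out.Phi[~sheath3d].max() < 1.0

    def test_front_tracks_threshold_crossing_of_transport(self):
        """In a quasi-static column the Phi=0.5 surface sits at the depth
        where H crosses the critical concentration, within ~2 interface
        thicknesses."""
        cfg = column_config(
            D=1e-2, L=60.0, nz=240, pH_acid=4.4, duration_s=4e4, dt_s=200.0,
            snapshot_every_s=None,
            levelset=rm.LevelSetParams(demin_rate=5e-3),
        )
        res = run_simulation(cfg)
        H = res.final_state.H[0, 0]
        thr = cfg.kinetics.trigger_concentration
        z = res.grid.z
        z_thr = np.interp(thr, H[::-1], z[::-1])
        profile = res.profiles[-1]
        z_front = front_depth(profile, 0.5)
        eps = min(cfg.geometry.hx, cfg.geometry.hy, cfg.geometry.hz)
        assert abs(z_front - z_thr) < max(2 * eps, 2 * cfg.geometry.hz)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

class TestRunSimulation:
    def test_zero_duration_returns_pristine_state(self):
        cfg = column_config(L=10.0, nz=10, duration_s=0.0)
        res = run_simulation(cfg)
        assert res.final_state.t == 0.0
        np.testing.assert_array_equal(res.profiles[-1].M, 1.0)

    def test_neutral_control_produces_no_lesion(self):
        """pH 7 control stays above the pH 5.5 trigger: zero lesion."""
        cfg = column_config(D=1e-2, L=20.0, nz=40, pH_acid=7.0,
                            duration_s=2e5, dt_s=1e4)
        res = run_simulation(cfg)
        np.testing.assert_array_equal(res.final_state.Phi, 1.0)
        assert front_depth(res.profiles[-1], 0.8) == 0.0

    def test_front_grows_as_sqrt_time(self):
        """Diffusion-limited lesion: depth ~ t^0.5 over a decade of time."""
        cfg = column_config(
            D=1e-2, L=60.0, nz=240, pH_acid=4.4, duration_s=1.0e4, dt_s=50.0,
            snapshot_every_s=1e3,
            levelset=rm.LevelSetParams(demin_rate=5e-2),
        )
        res = run_simulation(cfg)
        t = np.array(res.times[1:])
        d = np.array([front_depth(p, 0.5) for p in res.profiles[1:]])
        sel = t >= 1e3
        slope = np.polyfit(np.log(t[sel]), np.log(d[sel]), 1)[0]
        assert abs(slope - 0.5) < 0.05

    def test_faster_axial_diffusivity_never_shallower(self):
        """Raising d_fast must not decrease the lesion depth at fixed time."""
        depths = []
        for dfast in (0.9e-2, 1.8e-2):
            cfg = column_config(D=dfast, L=60.0, nz=120, pH_acid=4.4,
                                duration_s=2e4, dt_s=500.0,
                                levelset=rm.LevelSetParams(demin_rate=1e-3))
            res = run_simulation(cfg)
            depths.append(front_depth(res.profiles[-1], 0.5))
        assert depths[1] >= depths[0]

    def test_mesh_convergence_of_mineral_profile(self):
        """M(z, t_final) changes by < 2% in sup-norm when the grid is doubled."""
        profiles = {}
        for factor in (1, 2):
            cfg = column_config(
                D=1e-2, L=80.0, nz=80 * factor, pH_acid=4.4,
                duration_s=3e4, dt_s=375.0,
                levelset=rm.LevelSetParams(demin_rate=1e-4),
            )
            cfg = rm.SimulationConfig(**{**cfg.__dict__})
            res = run_simulation(cfg)
            profiles[factor] = res.profiles[-1]
        coarse, fine = profiles[1], profiles[2]
        M_interp = np.interp(coarse.z, fine.z, fine.M)
        assert np.abs(M_interp - coarse.M).max() < 0.02

    def test_demin_diffusivity_insensitivity(self):
        """Once the dissolved zone conducts much faster than the mineral,
        doubling its diffusivity moves the front by < 5% (transport is
        limited by the pristine material ahead of the front)."""
        depths = []
        for dd in (1.82, 3.64):
            local = rm.LocalDiffusivity(d_fast=1.82e-2, d_trans=1.82e-2,
                                        d_sheath=1.82e-2, d_demin=dd)
            cfg = column_config(D=1.82e-2, L=60.0, nz=120, pH_acid=4.4,
                                duration_s=2e4, dt_s=500.0)
            cfg = rm.SimulationConfig(**{**cfg.__dict__, "diffusivity": local})
            res = run_simulation(cfg)
            depths.append(front_depth(res.profiles[-1], 0.5))
        assert abs(depths[1] - depths[0]) <= 0.05 * max(depths[0], 1e-9)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            rm.SimulationConfig(scenario="diagonal")
        with pytest.raises(ValueError):
            rm.SimulationConfig(pH_acid=15.0)
        with pytest.raises(ValueError):
            rm.SimulationConfig(dt_s=0.0)
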