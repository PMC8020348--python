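"""Shared fixtures: small grids, fields and configs used across the suite.

Everything is generated programmatically; no data files are read.
"""

from __future__ import annotations

import numpy as np
import pytest

import rodemin as rm
from rodemin.solver import AxisBC, SolverOptions, TransportOperator


@pytest.fixture(scope="session")
def default_grid():
    """Moderate-resolution enamel grid with a resolved sheath."""
    return rm.build_rve(rm.GeometryConfig(nx=48, ny=48, nz=8))


@pytest.fixture(scope="session")
def small_geometry():
    """Tiny sheath-free unit cell for solver oracle tests (6 x 6 x 12)."""
    return rm.GeometryConfig(l=2.0, L=6.0, rho_head=0.6, sheath_thickness=0.0,
                             nx=6, ny=6, nz=12)


@pytest.fixture(scope="session")
def small_grid(small_geometry):
    return rm.build_rve(small_geometry)


@pytest.fixture(scope="session")
def small_local():
    """Mildly anisotropic diffusivities that keep explicit oracles affordable."""
    return rm.LocalDiffusivity(d_fast=1e-2, d_trans=1e-3, d_sheath=1e-3, d_demin=1e-2)


@pytest.fixture(scope="session")
def small_field(small_grid, small_local):
    """Smoothly rotated tensor field on which the cross-term flux limiter is
    provably inactive, so exact-operator oracles apply."""
    return rm.assemble_diffusivity_field(
        small_grid, rm.OrientationModel(max_angle_rad=0.5, transition_um=1.2),
        small_local,
    )


def tensor_dict(field, shape):
    """Expand a 2-D DiffusivityField into per-cell 3-D component arrays."""
    return {
        name: np.broadcast_to(field.component(name)[:, :, None], shape).copy()
        for name in ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")
    }


def column_geometry(L=60.0, nz=120):
    """Pseudo-1-D column: 2 x 2 periodic in-plane, attack along z."""
    return rm.GeometryConfig(l=1.0, L=L, rho_head=0.3, sheath_thickness=0.0,
                             nx=2, ny=2, nz=nz)


def column_config(D=1e-2, L=60.0, nz=120, **kwargs):
    """Isotropic single-column simulation config (orientation flat, no sheath)."""
    geo = column_geometry(L=L, nz=nz)
    local = rm.LocalDiffusivity(d_fast=D, d_trans=D, d_sheath=D, d_demin=D)
    ori = rm.OrientationModel(theta_coeffs=(0, 0, 0, 0), psi_coeffs=(0, 0, 0, 0))
    return rm.SimulationConfig(geometry=geo, diffusivity=local, orientation=ori, **kwargs)


def make_operator(grid, bcs=None, options=None):
    if bcs is None:
        bcs = (AxisBC("periodic", "periodic"), AxisBC("periodic", "periodic"),
               AxisBC("noflux", "noflux"))
    return TransportOperator(grid, bcs, options or SolverOptions())
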