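"""Crystallite orientation field and global diffusivity tensors.

Proton transport in hydroxyapatite is strongly anisotropic: diffusion is fast
along the crystal c-axis and slow across it.  In the rod head the c-axis runs
along the rod (global z); toward the interrod the crystallites tilt away until
they lie approximately normal to the rod axis.  Each cell therefore carries a
pair of tilt angles -- ``theta`` about global x and ``psi`` about global y --
and the local diagonal diffusivity ``diag(d_fast, d_trans, d_trans)`` (c-axis
first) is rotated into the global frame:

    D_G = R . diag . R^T,   R = R_y(psi) . R_x(theta),

which preserves the eigenvalues {d_fast, d_trans, d_trans} exactly.  Sheath
cells are isotropic with ``d_sheath``.

The angle model is a cubic polynomial evaluated on a normalised abscissa
``u = clip(sd / w, -1, 1)`` where ``sd`` is the periodic signed distance to
the rod boundary and ``w`` a transition half-width.  The default cubic is the
smoothstep ``(2 + 3u - u^3)/4`` scaled to pi/2: crystals are axial well inside
the rod (u = -1 at the head core) and normal to the rod axis in the interrod
plateau (u = +1), with a smooth C^1 transition across the boundary.  Because
``sd`` is periodic, the tensor field is continuous across the periodic seams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .geometry import REGION_CODES, RVEGrid

__all__ = [
    "OrientationModel",
    "LocalDiffusivity",
    "DiffusivityField",
    "eval_cubic",
    "evaluate_angles",
    "rotate_diffusivity",
    "assemble_diffusivity_field",
]

_HALF_PI = 0.5 * np.pi
# smoothstep cubic: 0 at u=-1, 1 at u=+1, zero slope at both ends
_SMOOTHSTEP = (0.5, 0.75, 0.0, -0.25)
_DEFAULT_THETA = tuple(_HALF_PI * c for c in _SMOOTHSTEP)


def eval_cubic(coeffs, s):
    """Evaluate ``c0 + c1 s + c2 s^2 + c3 s^3`` (coefficients low order first)."""
    c0, c1, c2, c3 = coeffs
    s = np.asarray(s, dtype=float)
    return c0 + s * (c1 + s * (c2 + s * c3))


@dataclass(frozen=True)
class OrientationModel:
    """Cubic-polynomial tilt-angle model over the cross-section.

    ``theta_coeffs`` / ``psi_coeffs`` are low-order-first cubic coefficients in
    the normalised boundary-distance abscissa; the evaluated polynomials are
    multiplied by ``max_angle_rad`` (a convenience scale, default 1).  By
    default only ``theta`` is active: the interrod tilt is a rotation about x,
    i.e. the c-axis leans from z toward the head-to-tail (y) direction, the
    common tilt direction of interrod crystallites.
    """

    theta_coeffs: Tuple[float, float, float, float] = _DEFAULT_THETA
    psi_coeffs: Tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    max_angle_rad: float = 1.0
    transition_um: float = 0.8

    def __post_init__(self) -> None:
        if len(self.theta_coeffs) != 4 or len(self.psi_coeffs) != 4:
            raise ValueError("theta_coeffs and psi_coeffs must each have 4 entries")
        if self.transition_um <= 0:
            raise ValueError("transition_um must be positive")


@dataclass(frozen=True)
class LocalDiffusivity:
    """Crystal-frame diffusivities (µm²/s).

    ``d_fast`` acts along the c-axis, ``d_trans`` along the two transverse
    crystal axes; ``d_sheath`` is the isotropic sheath value and ``d_demin``
    the isotropic diffusivity of fully demineralised material.  Defaults are
    the calibrated rod-scale values.
    """

    d_fast: float = 1.82e-2
    d_trans: float = 3.25e-5
    d_sheath: float = 6.5e-7
    # dissolved material conducts at least as fast as the fastest mineral axis;
    # capped at d_fast (far below the free-solution value) for conditioning
    d_demin: float = 1.82e-2

    def __post_init__(self) -> None:
        for name in ("d_fast", "d_trans", "d_sheath", "d_demin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.d_fast < self.d_trans:
            raise ValueError("d_fast must be >= d_trans (c-axis is the fast direction)")


@dataclass(frozen=True)
class DiffusivityField:
    """Per-cell symmetric global tensor, six unique entries, shape (nx, ny).

    The field is constant along z (extruded geometry); symmetry is exact by
    construction since only six entries are stored.
    """

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    dxy: np.ndarray
    dxz: np.ndarray
    dyz: np.ndarray

    def as_tensors(self) -> np.ndarray:
        """Dense (nx, ny, 3, 3) tensor array (for tests and export)."""
        t = np.empty(self.dxx.shape + (3, 3))
        t[..., 0, 0] = self.dxx
        t[..., 1, 1] = self.dyy
        t[..., 2, 2] = self.dzz
        t[..., 0, 1] = t[..., 1, 0] = self.dxy
        t[..., 0, 2] = t[..., 2, 0] = self.dxz
        t[..., 1, 2] = t[..., 2, 1] = self.dyz
        return t

    def component(self, name: str) -> np.ndarray:
        return getattr(self, name)


def evaluate_angles(model: OrientationModel, grid: RVEGrid) -> Tuple[np.ndarray, np.ndarray]:
    """Per-cell tilt angles (theta, psi), each shape (nx, ny), radians.

    Angles are constant along z.  Sheath cells receive angles like any other
    cell but they are ignored downstream (the sheath is isotropic).

    Raises
    ------
    ValueError
        If the coefficient set produces an angle outside [-pi/2, pi/2]
        anywhere on the grid.
    """
    u = np.clip(grid.signed_distance / model.transition_um, -1.0, 1.0)
    theta = model.max_angle_rad * eval_cubic(model.theta_coeffs, u)
    psi = model.max_angle_rad * eval_cubic(model.psi_coeffs, u)
    limit = _HALF_PI + 1e-12
    if np.abs(theta).max() > limit or np.abs(psi).max() > limit:
        raise ValueError(
            "orientation model produces tilt angles outside [-pi/2, pi/2]; "
            "rescale the polynomial coefficients or max_angle_rad"
        )
    return theta, psi


def _c_axis(theta, psi):
    """Global unit vector of the crystal c-axis, R_y(psi) R_x(theta) applied to z."""
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(psi), np.cos(psi)
    return sp * ct, -st, cp * ct


def rotate_diffusivity(local: LocalDiffusivity, theta: float, psi: float) -> np.ndarray:
    """Rotate the crystal-frame diagonal into the global frame.

    Returns the symmetric positive-definite 3x3 array
    ``R diag(d_trans, d_trans, d_fast) R^T`` with ``R = R_y(psi) R_x(theta)``
    (the c-axis coincides with global z at zero angles).  Implemented through
    the rank-one form ``d_trans I + (d_fast - d_trans) c c^T`` with ``c`` the
    rotated c-axis, which is algebraically identical and keeps symmetry exact.
    """
    cx, cy, cz = _c_axis(float(theta), float(psi))
    c = np.array([cx, cy, cz])
    return local.d_trans * np.eye(3) + (local.d_fast - local.d_trans) * np.outer(c, c)


def assemble_diffusivity_field(
    grid: RVEGrid, model: OrientationModel, local: LocalDiffusivity
) -> DiffusivityField:
    """Build the per-cell global tensor field for the whole cross-section.

    Rod-head and interrod cells get the rotated anisotropic tensor from the
    orientation model; sheath cells get ``d_sheath`` times the identity.
    """
    theta, psi = evaluate_angles(model, grid)
    cx, cy, cz = _c_axis(theta, psi)
    dd = local.d_fast - local.d_trans
    dt = local.d_trans
    dxx = dt + dd * cx * cx
    dyy = dt + dd * cy * cy
    dzz = dt + dd * cz * cz
    dxy = dd * cx * cy
    dxz = dd * cx * cz
    dyz = dd * cy * cz
    sheath = grid.region == REGION_CODES["sheath"]
    for arr, iso in ((dxx, local.d_sheath), (dyy, local.d_sheath), (dzz, local.d_sheath)):
        arr[sheath] = iso
    for arr in (dxy, dxz, dyz):
        arr[sheath] = 0.0
    return DiffusivityField(dxx=dxx, dyy=dyy, dzz=dzz, dxy=dxy, dxz=dxz, dyz=dyz)
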