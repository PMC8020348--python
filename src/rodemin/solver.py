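"""Coupled hydrogen-ion transport and level-set demineralisation solver.

The model advances two fields on the structured RVE grid:

* ``H`` (mol/L): hydrogen-ion concentration obeying an anisotropic
  reaction-diffusion equation  dH/dt = div(D_G grad H) + k (Hc - H),
  where ``D_G`` is the per-cell global diffusivity tensor (full 3x3 with
  cross terms) blended between pristine mineral and demineralised material
  by the phase parameter, and the reaction term is the first-order
  dissolution source with apparent solubility ``Hc``.
* ``Phi`` (dimensionless, 1 = pristine, 0 = dissolved): a level-set style
  phase parameter.  Where the local pH falls below the critical value
  (H > 10^-pH_threshold) the phase decays at ``demin_rate``; everywhere a
  stabilisation term  gamma * div(eps grad Phi - Phi (1 - Phi) n_hat)
  keeps the 0-1 interface at thickness ~eps.  Dissolution is one-way:
  ``Phi`` never increases.  Sheath cells are acid-resistant and do not
  demineralise.

Discretisation: cell-centred finite volume on the uniform grid.  Normal
fluxes use harmonic-mean face diffusivities (exact for the sheath
discontinuity); tensor cross terms are discretised with symmetrised central
differences.  Dirichlet values live on faces (half-cell fluxes), so every
cell remains an unknown.  Units are µm, s and mol/L throughout.

Two transport integrators share that discretisation:

* small grids -- backward Euler with a cached sparse LU factorisation
  (exact up to solver precision; used by every validation oracle);
* large grids -- an alternating-direction (Lie-split) integrator: the three
  axis operators are solved implicitly in sequence by batched (cyclic)
  Thomas sweeps, with the flux-limited cross terms and the weak reaction
  source applied explicitly at the start of each sub-step.  Every implicit
  factor is an unconditional contraction, and the first-order splitting
  bias is controlled by sub-stepping against a per-axis stiffness cap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import REGION_CODES, GeometryConfig, RVEGrid, build_rve
from .orientation import (
    DiffusivityField,
    LocalDiffusivity,
    OrientationModel,
    assemble_diffusivity_field,
)

logger = logging.getLogger(__name__)

R_GAS = 8.314462618  # J/(mol K)

__all__ = [
    "KineticsParams",
    "LevelSetParams",
    "SolverOptions",
    "SimulationConfig",
    "SimState",
    "SimulationResult",
    "ph_to_concentration",
    "concentration_to_ph",
    "reaction_rate",
    "porosity_corrected_diffusivity",
    "arrhenius_diffusivity",
    "effective_diffusivity",
    "step_transport",
    "step_level_set",
    "run_simulation",
    "TransportOperator",
    "ADITransport",
    "make_transport_stepper",
    "axis_boundaries",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsParams:
    """Dissolution kinetics and optional diffusivity corrections.

    ``k`` is the first-order surface reaction rate of  R_diss = k (Hc - H);
    ``Hc`` the apparent solubility of hydroxyapatite in solution (default
    10^-5.5 mol/L, consistent with the critical-pH picture); ``pH_threshold``
    the critical pH below which mineral dissolves.  The porosity factors
    (transport porosity ``eps_t``, constrictivity ``delta``, tortuosity
    ``tau``) rescale every local diffusivity by eps_t * delta / tau and
    default to 1 (no correction).
    """

    k: float = 2.00e-7
    Hc: float = 10.0 ** -5.5
    pH_threshold: float = 5.5
    porosity_eps_t: float = 1.0
    constrictivity_delta: float = 1.0
    tortuosity_tau: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 0 or self.Hc < 0:
            raise ValueError("k and Hc must be non-negative")
        if not (0 < self.pH_threshold < 14):
            raise ValueError("pH_threshold must lie in (0, 14)")
        if not (0 < self.porosity_eps_t <= 1) or not (0 < self.constrictivity_delta <= 1):
            raise ValueError("porosity_eps_t and constrictivity_delta must lie in (0, 1]")
        if self.tortuosity_tau < 1:
            raise ValueError("tortuosity_tau must be >= 1")

    @property
    def trigger_concentration(self) -> float:
        return 10.0 ** (-self.pH_threshold)


@dataclass(frozen=True)
class LevelSetParams:
    """Stabilisation and kinetics of the phase equation.

    ``gamma`` (µm/s) scales the whole stabilisation flux; if ``None`` it
    defaults to 1% of the characteristic transport speed d_fast / L: the
    monotone-dissolution constraint turns any stronger clipped stabilisation
    flux into spurious interface erosion (several µm over three weeks),
    while the acid trigger already produces monotone fronts that need
    little smoothing.  ``eps``
    (µm) is the interface half-thickness; if ``None`` it defaults to the
    smallest grid spacing.  ``demin_rate`` (1/s) is the decay rate of Phi
    where the acid trigger is active; the default 1e-4/s empties a cell in
    ~1 day, fast against three weeks of transport, so the front is
    transport-limited.
    """

    gamma: Optional[float] = None
    eps: Optional[float] = None
    demin_rate: float = 1.0e-4
    grad_floor: float = 1.0e-12
    cfl_safety: float = 0.5

    def __post_init__(self) -> None:
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.eps is not None and self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.demin_rate <= 0:
            raise ValueError("demin_rate must be positive")
        if not (0 < self.cfl_safety <= 1):
            raise ValueError("cfl_safety must lie in (0, 1]")


@dataclass(frozen=True)
class SolverOptions:
    """Transport integrator strategy.

    ``method``: "auto" picks the exact backward-Euler/LU path up to
    ``direct_limit`` cells and the Douglas ADI path beyond; "direct" or
    "adi" force one path.  ``adi_rate_cap`` bounds the per-axis implicit
    stiffness dt*(w_lo+w_hi) of one ADI sub-step; larger caps take longer
    sub-steps but weaken the damping of modes that are stiff along two axes
    simultaneously.  ``phi_drift_refresh`` controls how far the phase field
    may drift before the cached LU factorisation is rebuilt.
    """

    method: str = "auto"
    direct_limit: int = 30000
    adi_rate_cap: float = 100.0
    phi_drift_refresh: float = 0.02

    def __post_init__(self) -> None:
        if self.method not in ("auto", "direct", "adi"):
            raise ValueError("method must be 'auto', 'direct' or 'adi'")
        if self.adi_rate_cap <= 0:
            raise ValueError("adi_rate_cap must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one demineralisation run."""

    scenario: str = "axial"
    pH_acid: float = 4.4
    duration_s: float = 21 * 86400.0
    dt_s: float = 21600.0
    snapshot_every_s: Optional[float] = 86400.0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    orientation: OrientationModel = field(default_factory=OrientationModel)
    diffusivity: LocalDiffusivity = field(default_factory=LocalDiffusivity)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    levelset: LevelSetParams = field(default_factory=LevelSetParams)
    solver: SolverOptions = field(default_factory=SolverOptions)
    store_states: bool = False
    H_initial: float = 1.0e-14
    H_far: float = 1.0e-14             # Dirichlet sink on the far face (axial scenario)

    def __post_init__(self) -> None:
        if self.scenario not in ("axial", "lateral"):
            raise ValueError(f"unknown scenario {self.scenario!r}; expected 'axial' or 'lateral'")
        if self.duration_s < 0:
            raise ValueError("duration_s must be non-negative")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if not (0 < self.pH_acid < 14):
            raise ValueError("pH_acid must lie in (0, 14)")

    @property
    def attack_axis(self) -> int:
        return 2 if self.scenario == "axial" else 1


@dataclass
class SimState:
    """Per-cell hydrogen concentration, phase parameter and elapsed time."""

    H: np.ndarray
    Phi: np.ndarray
    t: float = 0.0

    def validate(self) -> None:
        if self.H.min() < -1e-15:
            raise ValueError(f"negative concentration {self.H.min():.3e}")
        if self.Phi.min() < -1e-9 or self.Phi.max() > 1 + 1e-9:
            raise ValueError("Phi outside [0, 1]")

    def copy(self) -> "SimState":
        return SimState(H=self.H.copy(), Phi=self.Phi.copy(), t=self.t)


# ---------------------------------------------------------------------------
# pointwise helpers
# ---------------------------------------------------------------------------

def ph_to_concentration(pH):
    """Hydrogen-ion concentration 10^-pH (mol/L)."""
    return 10.0 ** (-np.asarray(pH, dtype=float)) if np.ndim(pH) else 10.0 ** (-float(pH))


def concentration_to_ph(H):
    """Inverse of :func:`ph_to_concentration`."""
    return -np.log10(H)


def reaction_rate(H, params: KineticsParams):
    """Dissolution source k (Hc - H) in mol/(L s); positive adds H."""
    return params.k * (params.Hc - np.asarray(H, dtype=float))


def porosity_corrected_diffusivity(D_star, params: KineticsParams):
    """Effective diffusivity D* eps_t delta / tau of a porous solid."""
    return (
        D_star
        * params.porosity_eps_t
        * params.constrictivity_delta
        / params.tortuosity_tau
    )


def arrhenius_diffusivity(D0, EA, T):
    """Temperature-dependent diffusivity D0 exp(-EA / (R T))."""
    if T <= 0:
        raise ValueError("absolute temperature must be positive")
    return D0 * math.exp(-EA / (R_GAS * T))


def effective_diffusivity(field2d: DiffusivityField, Phi: np.ndarray,
                          local: LocalDiffusivity) -> Dict[str, np.ndarray]:
    """Blend pristine and demineralised diffusivity by the phase parameter.

    Returns the six 3-D tensor-component arrays
    ``Phi * D_mineral + (1 - Phi) * d_demin * I``; symmetric positive
    definite for Phi in [0, 1] since both endpoint tensors are.
    """
    out: Dict[str, np.ndarray] = {}
    for name in ("dxx", "dyy", "dzz"):
        out[name] = Phi * field2d.component(name)[:, :, None] + (1.0 - Phi) * local.d_demin
    for name in ("dxy", "dxz", "dyz"):
        out[name] = Phi * field2d.component(name)[:, :, None]
    return out


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxisBC:
    """Boundary condition pair for one axis.

    ``kind_lo``/``kind_hi`` in {"periodic", "dirichlet", "noflux"}; periodic
    must be set on both ends (a periodic face cannot also be Dirichlet).
    """

    kind_lo: str
    kind_hi: str
    value_lo: float = 0.0
    value_hi: float = 0.0

    def __post_init__(self) -> None:
        kinds = {"periodic", "dirichlet", "noflux"}
        if self.kind_lo not in kinds or self.kind_hi not in kinds:
            raise ValueError("unknown boundary kind")
        if ("periodic" in (self.kind_lo, self.kind_hi)) and self.kind_lo != self.kind_hi:
            raise ValueError("periodic faces conflict with a Dirichlet/no-flux face on the same axis")

    @property
    def periodic(self) -> bool:
        return self.kind_lo == "periodic"


def axis_boundaries(config: SimulationConfig) -> Tuple[AxisBC, AxisBC, AxisBC]:
    """Boundary conditions for (x, y, z) implied by the scenario.

    axial:   acid Dirichlet at z=0, near-neutral Dirichlet sink at z=L,
             periodic in x and y.
    lateral: acid Dirichlet at y=0, no-flux at y=Ly, periodic in x and z
             (the attack rotated 90 degrees onto the rod flank).
    """
    H_acid = ph_to_concentration(config.pH_acid)
    per = AxisBC("periodic", "periodic")
    if config.scenario == "axial":
        return per, per, AxisBC("dirichlet", "dirichlet", H_acid, config.H_far)
    return per, AxisBC("dirichlet", "noflux", H_acid, 0.0), per


# ---------------------------------------------------------------------------
# shared discretisation pieces
# ---------------------------------------------------------------------------

def _cdiff(arr: np.ndarray, axis: int, h: float, periodic: bool) -> np.ndarray:
    """Cell-centred derivative, periodic wrap or one-sided at bounded ends."""
    if periodic:
        return (np.roll(arr, -1, axis=axis) - np.roll(arr, 1, axis=axis)) / (2.0 * h)
    out = np.empty_like(arr)
    sl = [slice(None)] * arr.ndim

    def _s(s):
        t = sl.copy()
        t[axis] = s
        return tuple(t)

    out[_s(slice(1, -1))] = (arr[_s(slice(2, None))] - arr[_s(slice(0, -2))]) / (2.0 * h)
    out[_s(0)] = (arr[_s(1)] - arr[_s(0)]) / h
    out[_s(-1)] = (arr[_s(-1)] - arr[_s(-2)]) / h
    return out


def _face_weights(D: np.ndarray, h: float, bc: AxisBC):
    """Per-cell lower/upper face weights along the LAST axis of ``D``.

    Returns (wl, wu, extra, bval): harmonic-mean interior weights, the extra
    diagonal weight of Dirichlet half-cell faces, and the constant Dirichlet
    inflow term, all divided by h^2 (units 1/s).
    """
    wl = np.zeros_like(D)
    wu = np.zeros_like(D)
    extra = np.zeros_like(D)
    bval = np.zeros_like(D)
    harm = 2.0 * D[..., :-1] * D[..., 1:] / (D[..., :-1] + D[..., 1:]) / h ** 2
    wu[..., :-1] = harm
    wl[..., 1:] = harm
    if bc.periodic:
        wrap = 2.0 * D[..., -1] * D[..., 0] / (D[..., -1] + D[..., 0]) / h ** 2
        wu[..., -1] = wrap
        wl[..., 0] = wrap
    else:
        if bc.kind_lo == "dirichlet":
            w0 = 2.0 * D[..., 0] / h ** 2
            extra[..., 0] += w0
            bval[..., 0] += w0 * bc.value_lo
        if bc.kind_hi == "dirichlet":
            w1 = 2.0 * D[..., -1] / h ** 2
            extra[..., -1] += w1
            bval[..., -1] += w1 * bc.value_hi
    return wl, wu, extra, bval


def _thomas_numpy(dl, dm, du, b):
    """Batched tridiagonal solve along the last axis (non-cyclic)."""
    n = b.shape[-1]
    c = np.empty_like(b)
    d = np.empty_like(b)
    c[..., 0] = du[..., 0] / dm[..., 0]
    d[..., 0] = b[..., 0] / dm[..., 0]
    for i in range(1, n):
        m = dm[..., i] - dl[..., i] * c[..., i - 1]
        c[..., i] = du[..., i] / m
        d[..., i] = (b[..., i] - dl[..., i] * d[..., i - 1]) / m
    x = np.empty_like(b)
    x[..., -1] = d[..., -1]
    for i in range(n - 2, -1, -1):
        x[..., i] = d[..., i] - c[..., i] * x[..., i + 1]
    return x


try:  # optional acceleration; the numpy kernels are the reference
    from numba import njit as _njit

    @_njit(cache=True)
    def _thomas_2d(dl, dm, du, b):  # pragma: no cover - compiled
        B, n = b.shape
        x = np.empty_like(b)
        c = np.empty(n)
        d = np.empty(n)
        for j in range(B):
            c[0] = du[j, 0] / dm[j, 0]
            d[0] = b[j, 0] / dm[j, 0]
            for i in range(1, n):
                m = dm[j, i] - dl[j, i] * c[i - 1]
                c[i] = du[j, i] / m
                d[i] = (b[j, i] - dl[j, i] * d[i - 1]) / m
            x[j, n - 1] = d[n - 1]
            for i in range(n - 2, -1, -1):
                x[j, i] = d[i] - c[i] * x[j, i + 1]
        return x

    def _thomas(dl, dm, du, b):
        shape = b.shape
        n = shape[-1]
        out = _thomas_2d(
            np.ascontiguousarray(dl).reshape(-1, n),
            np.ascontiguousarray(dm).reshape(-1, n),
            np.ascontiguousarray(du).reshape(-1, n),
            np.ascontiguousarray(b).reshape(-1, n),
        )
        return out.reshape(shape)
except ImportError:  # pragma: no cover
    _thomas = _thomas_numpy


def _cyclic_thomas(dl, dm, du, b):
    """Batched cyclic tridiagonal solve (Sherman-Morrison correction)."""
    alpha = dl[..., 0]
    beta = du[..., -1]
    gamma = -dm[..., 0]
    dmod = dm.copy()
    dmod[..., 0] = dm[..., 0] - gamma
    dmod[..., -1] = dm[..., -1] - alpha * beta / gamma
    x1 = _thomas(dl, dmod, du, b)
    u = np.zeros_like(b)
    u[..., 0] = gamma
    u[..., -1] = beta
    x2 = _thomas(dl, dmod, du, u)
    fact = (x1[..., 0] + alpha * x1[..., -1] / gamma) / (
        1.0 + x2[..., 0] + alpha * x2[..., -1] / gamma)
    return x1 - fact[..., None] * x2


def _clip_negative(x: np.ndarray) -> None:
    """Clip undershoots of the non-monotone cross-term stencil to zero.

    Small negative excursions (a few percent of the peak, next to strong
    material contrasts) are expected and clipped silently; anything larger
    indicates a discretisation failure and is logged.
    """
    lo = float(x.min())
    if lo < 0.0:
        hi = max(float(x.max()), 1e-300)
        if lo < -0.05 * hi:
            logger.warning(
                "transport step produced negative concentrations (min %.3e, %.1f%% of max); clipping",
                lo, -100.0 * lo / hi)
        np.clip(x, 0.0, None, out=x)


_NORMAL_NAMES = ("dxx", "dyy", "dzz")
_ROW_NAMES = (("dxx", "dxy", "dxz"), ("dxy", "dyy", "dyz"), ("dxz", "dyz", "dzz"))


def _neighbour_min(D: np.ndarray, axis: int, periodic: bool) -> np.ndarray:
    """Minimum of a cell value and its two neighbours along one axis."""
    if periodic:
        return np.minimum(D, np.minimum(np.roll(D, 1, axis), np.roll(D, -1, axis)))
    lo = np.roll(D, 1, axis)
    hi = np.roll(D, -1, axis)
    sl = [slice(None)] * D.ndim
    sl[axis] = 0
    lo[tuple(sl)] = D[tuple(sl)]
    sl[axis] = -1
    hi[tuple(sl)] = D[tuple(sl)]
    return np.minimum(D, np.minimum(lo, hi))


def limit_cross_terms(D: Dict[str, np.ndarray],
                      bcs: Tuple["AxisBC", "AxisBC", "AxisBC"]) -> Dict[str, np.ndarray]:
    """Flux-limit the mixed tensor coefficients at strong material contrasts.

    The continuum tensor is positive definite cell by cell, but the discrete
    scheme damps the mixed flux d_ab only through the *harmonic-mean* face
    diffusivities of the two coupled axes, which collapse next to the sheath
    (five orders below the cell value).  A mixed coefficient larger than
    sqrt(min_a d_aa * min_b d_bb) over the neighbouring cells is therefore
    locally undamped and destabilises any time integrator and violates the
    discrete maximum principle.  This limiter clips |d_ab| to that bound; it
    is inactive wherever the tensor field is smooth.
    """
    per = [bc.periodic for bc in bcs]
    mins = {a: _neighbour_min(D[_NORMAL_NAMES[a]], a, per[a]) for a in range(3)}
    out = dict(D)
    for name, a, b in (("dxy", 0, 1), ("dxz", 0, 2), ("dyz", 1, 2)):
        Dab = D[name]
        if not np.any(Dab):
            continue
        bound = np.sqrt(mins[a] * mins[b])
        out[name] = np.clip(Dab, -bound, bound)
    return out


# ---------------------------------------------------------------------------
# exact backward-Euler path (sparse LU)
# ---------------------------------------------------------------------------

class TransportOperator:
    """Backward-Euler transport on one grid via a cached sparse LU.

    Assembles the full finite-volume operator (7-point normal part plus
    symmetrised central-difference cross terms) and factorises
    A = (1/dt + k) I - L with SuperLU.  The factorisation is reused across
    steps until dt, k or the phase field changes materially.  Intended for
    grids up to a few tens of thousands of cells; memory for the LU factors
    grows super-linearly beyond that.
    """

    def __init__(self, grid: RVEGrid, bcs: Tuple[AxisBC, AxisBC, AxisBC],
                 options: SolverOptions = SolverOptions()):
        self.grid = grid
        self.bcs = bcs
        self.options = options
        self.shape = grid.shape
        self.N = grid.n_cells
        self.h = (grid.geometry.hx, grid.geometry.hy, grid.geometry.hz)
        self._idx = np.arange(self.N).reshape(self.shape)
        c1 = [_cdiff_matrix_1d(n, h, bc.periodic)
              for n, h, bc in zip(self.shape, self.h, bcs)]
        eye = [sp.identity(n, format="csr") for n in self.shape]
        self._C = (
            sp.kron(sp.kron(c1[0], eye[1]), eye[2], format="csr"),
            sp.kron(sp.kron(eye[0], c1[1]), eye[2], format="csr"),
            sp.kron(sp.kron(eye[0], eye[1]), c1[2], format="csr"),
        )
        self._lu = None
        self._rhs_const = None
        self._cache_key = None
        self._phi_at_build: Optional[np.ndarray] = None

    # -- assembly ----------------------------------------------------------

    def _normal_part(self, D: Dict[str, np.ndarray]):
        """7-point part from the tensor diagonal; returns (COO parts, rhs)."""
        rows: List[np.ndarray] = []
        cols: List[np.ndarray] = []
        vals: List[np.ndarray] = []
        rhs = np.zeros(self.N)
        for axis in range(3):
            Da = np.moveaxis(D[_NORMAL_NAMES[axis]], axis, -1)
            idx = np.moveaxis(self._idx, axis, -1)
            wl, wu, extra, bval = _face_weights(Da, self.h[axis], self.bcs[axis])
            i = idx[..., :-1].ravel()
            j = idx[..., 1:].ravel()
            w = wu[..., :-1].ravel()
            rows += [i, j, i, j]
            cols += [j, i, i, j]
            vals += [w, w, -w, -w]
            if self.bcs[axis].periodic:
                i = idx[..., -1].ravel()
                j = idx[..., 0].ravel()
                w = wu[..., -1].ravel()
                rows += [i, j, i, j]
                cols += [j, i, i, j]
                vals += [w, w, -w, -w]
            else:
                ii = idx.ravel()
                rows.append(ii)
                cols.append(ii)
                vals.append(-extra.ravel())
                rhs[ii] += bval.ravel()
        return rows, cols, vals, rhs

    def _cross_part(self, D: Dict[str, np.ndarray]) -> Optional[sp.csr_matrix]:
        """Symmetrised central-difference discretisation of the cross terms."""
        pairs = (("dxy", 0, 1), ("dxz", 0, 2), ("dyz", 1, 2))
        L = None
        for name, a, b in pairs:
            Dab = D[name]
            if not np.any(Dab):
                continue
            diag = sp.diags(Dab.ravel())
            term = self._C[a] @ (diag @ self._C[b]) + self._C[b] @ (diag @ self._C[a])
            L = term if L is None else L + term
        return L

    def build_matrix(self, D: Dict[str, np.ndarray], k: float, dt: float):
        """System matrix A = (1/dt + k) I - L and constant inflow vector."""
        rows, cols, vals, rhs = self._normal_part(D)
        L = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.N, self.N),
        ).tocsr()
        Lc = self._cross_part(D)
        if Lc is not None:
            L = L + Lc
        A = sp.identity(self.N, format="csr") * (1.0 / dt + k) - L
        return A.tocsc(), rhs

    # -- solving -----------------------------------------------------------

    def step(self, H: np.ndarray, D: Dict[str, np.ndarray], kin: KineticsParams,
             dt: float, Phi: Optional[np.ndarray] = None) -> np.ndarray:
        """One backward-Euler step of the transport equation."""
        Hf = H.ravel()
        drift = (
            np.inf if self._phi_at_build is None or Phi is None
            else float(np.max(np.abs(Phi.ravel() - self._phi_at_build)))
        )
        key = (dt, kin.k)
        if (self._lu is None or self._cache_key != key
                or drift > self.options.phi_drift_refresh):
            A, rhs_const = self.build_matrix(limit_cross_terms(D, self.bcs), kin.k, dt)
            self._lu = spla.splu(A)
            self._rhs_const = rhs_const
            self._cache_key = key
            self._phi_at_build = None if Phi is None else Phi.ravel().copy()
        b = Hf / dt + kin.k * kin.Hc + self._rhs_const
        x = self._lu.solve(b)
        _clip_negative(x)
        return x.reshape(self.shape)


def _cdiff_matrix_1d(n: int, h: float, periodic: bool) -> sp.csr_matrix:
    """Cell-centred first-derivative matrix (central; one-sided at bounded ends)."""
    if periodic and n > 2:
        main = sp.diags([np.full(n - 1, 1.0), np.full(n - 1, -1.0)], [1, -1], format="lil")
        main[0, n - 1] = -1.0
        main[n - 1, 0] = 1.0
        return (main.tocsr()) / (2.0 * h)
    C = sp.lil_matrix((n, n))
    for i in range(n):
        if 0 < i < n - 1:
            C[i, i + 1] = 0.5
            C[i, i - 1] = -0.5
        elif i == 0:
            C[0, 1] = 1.0
            C[0, 0] = -1.0
        else:
            C[n - 1, n - 1] = 1.0
            C[n - 1, n - 2] = -1.0
    return C.tocsr() / h


# ---------------------------------------------------------------------------
# Douglas ADI path (large grids)
# ---------------------------------------------------------------------------

class ADITransport:
    """Operator-split (locally one-dimensional) implicit transport integrator.

    Each sub-step first adds the mixed-flux and reaction contributions
    explicitly (the flux-limited cross coefficients are always dominated by
    the implicit axis damping, see :func:`limit_cross_terms`), then solves
    the three axis operators sequentially with batched (cyclic) Thomas
    sweeps -- Lie splitting of backward Euler.  Every factor is an
    unconditional contraction, so the scheme is robust at any sub-step; the
    splitting bias is first order in the sub-step and is controlled by
    capping the per-axis stiffness dt * (w_lo + w_hi + w_dirichlet) at
    ``adi_rate_cap``.  The direct backward-Euler path is the accuracy
    reference; the two are compared in the test suite.
    """

    def __init__(self, grid: RVEGrid, bcs: Tuple[AxisBC, AxisBC, AxisBC],
                 options: SolverOptions = SolverOptions()):
        self.grid = grid
        self.bcs = bcs
        self.options = options
        self.shape = grid.shape
        self.N = grid.n_cells
        self.h = (grid.geometry.hx, grid.geometry.hy, grid.geometry.hz)

    def _axis_data(self, D: Dict[str, np.ndarray]):
        out = []
        for a in range(3):
            Da = np.moveaxis(D[_NORMAL_NAMES[a]], a, -1)
            out.append(_face_weights(Da, self.h[a], self.bcs[a]))
        return out

    def _axis_apply(self, H, a, ax):
        """Homogeneous part of the axis-a operator applied to H."""
        wl, wu, extra, _ = ax
        Hm = np.moveaxis(H, a, -1)
        acc = -extra * Hm
        acc[..., :-1] += wu[..., :-1] * (Hm[..., 1:] - Hm[..., :-1])
        acc[..., 1:] += wl[..., 1:] * (Hm[..., :-1] - Hm[..., 1:])
        if self.bcs[a].periodic:
            acc[..., -1] += wu[..., -1] * (Hm[..., 0] - Hm[..., -1])
            acc[..., 0] += wl[..., 0] * (Hm[..., -1] - Hm[..., 0])
        return np.moveaxis(acc, -1, a)

    def _axis_solve(self, rhs, a, ax, dt):
        """Solve (I - dt A_a) x = rhs + dt b_a by a batched tridiagonal sweep."""
        wl, wu, extra, bval = ax
        r = np.moveaxis(rhs, a, -1) + dt * bval
        dm = 1.0 + dt * (wl + wu + extra)
        if self.bcs[a].periodic:
            x = _cyclic_thomas(-dt * wl, dm, -dt * wu, r)
        else:
            x = _thomas(-dt * wl, dm, -dt * wu, r)
        return np.moveaxis(x, -1, a)

    def _mixed_rhs(self, H, D, kin: KineticsParams):
        """Explicit part of one sub-step: cross fluxes and reaction."""
        out = kin.k * (kin.Hc - H)
        per = [bc.periodic for bc in self.bcs]
        for a in range(3):
            for b in range(3):
                if a == b:
                    continue
                Dab = D[_ROW_NAMES[a][b]]
                if not np.any(Dab):
                    continue
                out += _cdiff(Dab * _cdiff(H, b, self.h[b], per[b]),
                              a, self.h[a], per[a])
        return out

    def step(self, H: np.ndarray, D: Dict[str, np.ndarray], kin: KineticsParams,
             dt: float, Phi: Optional[np.ndarray] = None) -> np.ndarray:
        """Advance H by dt, sub-stepping to respect the stiffness cap."""
        D = limit_cross_terms(D, self.bcs)
        axdata = self._axis_data(D)
        rate = max(float((ax[0] + ax[1] + ax[2]).max()) for ax in axdata)
        n_sub = max(1, int(math.ceil(dt * rate / self.options.adi_rate_cap)))
        dt_s = dt / n_sub
        if n_sub > 1:
            logger.debug("ADI transport sub-cycling: %d sub-steps of %.3g s", n_sub, dt_s)
        has_mixed = any(np.any(D[n]) for n in ("dxy", "dxz", "dyz")) or kin.k > 0
        X = H
        for _ in range(n_sub):
            Y = X + dt_s * self._mixed_rhs(X, D, kin) if has_mixed else X
            for a in range(3):
                Y = self._axis_solve(Y, a, axdata[a], dt_s)
            X = Y
        X = X.copy() if X is H else X
        _clip_negative(X)
        return X


def make_transport_stepper(grid: RVEGrid, bcs: Tuple[AxisBC, AxisBC, AxisBC],
                           options: SolverOptions = SolverOptions()):
    """Pick the transport integrator for this grid size per ``options.method``."""
    if options.method == "direct" or (
            options.method == "auto" and grid.n_cells <= options.direct_limit):
        return TransportOperator(grid, bcs, options)
    return ADITransport(grid, bcs, options)


# ---------------------------------------------------------------------------
# level-set step
# ---------------------------------------------------------------------------

def resolve_levelset(params: LevelSetParams, diffusivity: LocalDiffusivity,
                     geometry: GeometryConfig) -> Tuple[float, float]:
    """Concrete (gamma, eps) after applying the documented defaults."""
    eps = params.eps if params.eps is not None else min(geometry.hx, geometry.hy, geometry.hz)
    gamma = params.gamma if params.gamma is not None else 0.01 * diffusivity.d_fast / geometry.L
    return gamma, eps


def step_level_set(state: SimState, config: SimulationConfig, dt: Optional[float] = None,
                   grid: Optional[RVEGrid] = None) -> SimState:
    """Advance the phase parameter by ``dt`` (default ``config.dt_s``).

    Applies (i) the acid trigger -- exponential decay of Phi at
    ``demin_rate`` in rod and interrod cells whose H exceeds the critical
    concentration (sheath cells are acid-resistant and frozen) -- and
    (ii) the explicit stabilisation flux, sub-cycled to its CFL limit.
    Phi is clipped to [0, 1] and never increases.
    """
    if dt is None:
        dt = config.dt_s
    if grid is None:
        grid = build_rve(config.geometry)
    ls = config.levelset
    gamma, eps = resolve_levelset(ls, config.diffusivity, config.geometry)
    bcs = axis_boundaries(config)
    h = (config.geometry.hx, config.geometry.hy, config.geometry.hz)

    Phi0 = state.Phi
    Phi = Phi0.copy()

    # (i) trigger: irreversible decay where the local pH is under threshold
    trigger = state.H > config.kinetics.trigger_concentration
    erodible = grid.region_3d() != REGION_CODES["sheath"]
    mask = trigger & erodible
    if np.any(mask):
        Phi[mask] *= math.exp(-ls.demin_rate * dt)

    # (ii) stabilisation; skipped while the field is still uniform
    if Phi.max() - Phi.min() > 1e-12 and gamma > 0:
        hmin = min(h)
        dt_cfl = ls.cfl_safety * min(hmin * hmin / (6.0 * gamma * eps), hmin / gamma)
        n_sub = max(1, int(math.ceil(dt / dt_cfl)))
        if n_sub > 1:
            logger.debug("level-set CFL sub-cycling: %d sub-steps of %.3g s", n_sub, dt / n_sub)
        dt_s = dt / n_sub
        per = [bc.periodic for bc in bcs]
        for _ in range(n_sub):
            g = [_cdiff(Phi, a, h[a], per[a]) for a in range(3)]
            norm = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
            norm = np.maximum(norm, ls.grad_floor)
            comp = Phi * (1.0 - Phi)
            rhs = np.zeros_like(Phi)
            for a in range(3):
                flux = eps * g[a] - comp * g[a] / norm
                rhs += _cdiff(flux, a, h[a], per[a])
            Phi += (gamma * dt_s) * rhs
            np.clip(Phi, 0.0, 1.0, out=Phi)
    np.minimum(Phi, Phi0, out=Phi)  # dissolution only
    Phi[~erodible] = Phi0[~erodible]  # the sheath phase is inert
    return SimState(H=state.H, Phi=Phi, t=state.t + dt)


def step_transport(state: SimState, field2d: DiffusivityField, config: SimulationConfig,
                   operator=None, grid: Optional[RVEGrid] = None,
                   dt: Optional[float] = None) -> SimState:
    """One implicit transport step; returns a new state at t + dt.

    Convenience wrapper for one-off use; for time loops construct the
    stepper once with :func:`make_transport_stepper` and reuse it (see
    :func:`run_simulation`).
    """
    if dt is None:
        dt = config.dt_s
    if grid is None:
        grid = build_rve(config.geometry)
    if operator is None:
        operator = make_transport_stepper(grid, axis_boundaries(config), config.solver)
    kin = config.kinetics
    local = _corrected_local(config)
    D = effective_diffusivity(field2d, state.Phi, local)
    H = operator.step(state.H, D, kin, dt, Phi=state.Phi)
    return SimState(H=H, Phi=state.Phi, t=state.t + dt)


def _corrected_local(config: SimulationConfig) -> LocalDiffusivity:
    """Apply the porosity correction factor to every local diffusivity."""
    kin = config.kinetics
    f = kin.porosity_eps_t * kin.constrictivity_delta / kin.tortuosity_tau
    if f == 1.0:
        return config.diffusivity
    d = config.diffusivity
    return LocalDiffusivity(
        d_fast=d.d_fast * f, d_trans=d.d_trans * f,
        d_sheath=d.d_sheath * f, d_demin=d.d_demin * f,
    )


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Time series emitted by :func:`run_simulation`."""

    config: SimulationConfig
    grid: RVEGrid
    times: List[float]
    profiles: List["MineralProfile"]  # noqa: F821 (defined in rodemin.analysis)
    final_state: SimState
    states: List[SimState]


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run the coupled transport / phase-change simulation.

    Starts from H = ``H_initial`` (near-neutral pore fluid) and Phi = 1
    (pristine mineral) and alternates the implicit transport step with the
    level-set step until ``duration_s``.  Mineral-content profiles along the
    attack axis are recorded every ``snapshot_every_s`` seconds (and always
    at t = 0 and the final time).  The run is deterministic: there is no
    randomness anywhere in the model.
    """
    from .analysis import mineral_profile  # local import to avoid a cycle

    grid = build_rve(config.geometry)
    bcs = axis_boundaries(config)
    op = make_transport_stepper(grid, bcs, config.solver)
    local = _corrected_local(config)
    field2d = assemble_diffusivity_field(grid, config.orientation, local)
    kin = config.kinetics

    state = SimState(
        H=np.full(grid.shape, float(config.H_initial)),
        Phi=np.ones(grid.shape),
        t=0.0,
    )
    axis = config.attack_axis

    times: List[float] = [0.0]
    profiles = [mineral_profile(state, grid, axis=axis)]
    states: List[SimState] = [state.copy()] if config.store_states else []

    t_end = float(config.duration_s)
    cadence = config.snapshot_every_s
    next_snap = cadence if cadence else np.inf
    t = 0.0
    while t < t_end - 1e-9:
        dt = min(config.dt_s, t_end - t)
        D = effective_diffusivity(field2d, state.Phi, local)
        H = op.step(state.H, D, kin, dt, Phi=state.Phi)
        state = SimState(H=H, Phi=state.Phi, t=t)
        state = step_level_set(state, config, dt=dt, grid=grid)
        t += dt
        state.t = t
        if t >= min(next_snap, t_end) - 1e-9:
            times.append(t)
            profiles.append(mineral_profile(state, grid, axis=axis))
            if config.store_states:
                states.append(state.copy())
            while next_snap <= t + 1e-9:
                next_snap += cadence if cadence else np.inf
    state.validate()
    return SimulationResult(
        config=config, grid=grid, times=times, profiles=profiles,
        final_state=state, states=states,
    )
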