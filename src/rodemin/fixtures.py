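"""Synthetic observations and analytic/brute-force reference solutions.

Everything here exists so the simulator can be exercised and validated with
no external data: a generator of synthetic observed mineral-content
profiles that emulate a micro-CT depth profile (smooth sigmoidal recovery
with a sharp cliff, missing data in the detached shallow zone, additive
noise), the erfc solution of 1-D semi-infinite diffusion, and a deliberately
naive explicit finite-difference stepper used as an independent oracle for
the implicit solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.special import erfc

from .analysis import MineralProfile
from .solver import AxisBC

__all__ = [
    "SyntheticProfileSpec",
    "make_synthetic_profile",
    "erfc_solution",
    "brute_force_step",
]


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Shape of a synthetic observed mineral-content depth profile.

    The mean curve sits near zero up to ``sharp_drop_um`` (the cliff where
    the interrod is completely lost), then recovers smoothly to the pristine
    level over ``transition_um`` around ``plateau_um``; ``floor`` is the
    residual mineral fraction of the demineralised zone (the acid-resistant
    sheath).  Depths shallower than ``sharp_drop_um`` are omitted, mimicking
    the detached, unmeasurable surface zone of the real scan.
    """

    length_um: float = 250.0
    n_depths: int = 200
    plateau_um: float = 70.0
    transition_um: float = 20.0
    floor: float = 0.05
    sharp_drop_um: float = 40.0
    noise_sd: float = 0.0
    seed: int = 0
    truncate: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.sharp_drop_um <= self.length_um
                and 0 <= self.plateau_um <= self.length_um):
            raise ValueError("depths must lie within [0, length_um]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.floor < 1):
            raise ValueError("floor must lie in [0, 1)")
        if self.transition_um <= 0:
            raise ValueError("transition_um must be positive")


def synthetic_mean_curve(spec: SyntheticProfileSpec, z: np.ndarray) -> np.ndarray:
    """Noise-free double-sigmoid mineral curve of the spec."""
    gate = 1.0 / (1.0 + np.exp(-(z - spec.sharp_drop_um) / 1.0))   # 1 µm cliff
    rise = 1.0 / (1.0 + np.exp(-(z - spec.plateau_um) / (spec.transition_um / 4.0)))
    M = gate * (spec.floor + (1.0 - spec.floor) * rise)
    return np.clip(M, 0.0, 1.0)


def make_synthetic_profile(spec: SyntheticProfileSpec, t: float = 21 * 86400.0) -> MineralProfile:
    """Deterministic (per seed) synthetic observed profile.

    Additive Gaussian noise of sd ``noise_sd`` on the mineral fraction,
    truncated to [0, 1].
    """
    z = np.linspace(0.0, spec.length_um, spec.n_depths + 1)[1:]
    if spec.truncate:
        z = z[z >= spec.sharp_drop_um]
    M = synthetic_mean_curve(spec, z)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        M = M + rng.normal(0.0, spec.noise_sd, size=M.shape)
    return MineralProfile(z=z, M=np.clip(M, 0.0, 1.0), t=t)


def erfc_solution(z, t: float, D: float, H0: float):
    """1-D semi-infinite diffusion: H(z, t) = H0 erfc(z / (2 sqrt(D t)))."""
    if t <= 0 or D <= 0:
        raise ValueError("t and D must be positive")
    z = np.asarray(z, dtype=float)
    return H0 * erfc(z / (2.0 * math.sqrt(D * t)))


def brute_force_step(H: np.ndarray, D: Dict[str, np.ndarray],
                     bcs: Tuple[AxisBC, AxisBC, AxisBC],
                     spacings: Tuple[float, float, float],
                     dt_small: float, k: float = 0.0, Hc: float = 0.0) -> np.ndarray:
    """One explicit Euler step of the transport equation, naive differencing.

    Independent of the sparse implicit machinery: fluxes are formed by
    shifting arrays (harmonic-mean faces for normal terms, central
    differences for cross terms) and the update is fully explicit.  Intended
    for oracle tests only; grids larger than 10 x 10 x 20 are rejected, and
    ``dt_small`` must respect the explicit stability limit.
    """
    if any(n > m for n, m in zip(H.shape, (10, 10, 20))):
        raise ValueError("brute-force oracle is restricted to grids <= 10 x 10 x 20")
    Dmax = max(float(np.max(np.abs(D[c]))) for c in ("dxx", "dyy", "dzz"))
    limit = 1.0 / (2.0 * Dmax * sum(1.0 / h ** 2 for h in spacings))
    if dt_small > limit * 1.0000001:
        raise ValueError(f"dt {dt_small:.3g} s violates the explicit stability limit {limit:.3g} s")

    def grad(arr, axis):
        h = spacings[axis]
        if bcs[axis].periodic:
            return (np.roll(arr, -1, axis) - np.roll(arr, 1, axis)) / (2 * h)
        out = np.zeros_like(arr)
        sl = [slice(None)] * 3

        def s(v):
            q = sl.copy()
            q[axis] = v
            return tuple(q)

        out[s(slice(1, -1))] = (arr[s(slice(2, None))] - arr[s(slice(0, -2))]) / (2 * h)
        out[s(0)] = (arr[s(1)] - arr[s(0)]) / h
        out[s(-1)] = (arr[s(-1)] - arr[s(-2)]) / h
        return out

    names = (("dxx", "dxy", "dxz"), ("dxy", "dyy", "dyz"), ("dxz", "dyz", "dzz"))
    dHdt = np.zeros_like(H)
    for axis in range(3):
        h = spacings[axis]
        Dn = D[names[axis][axis]]
        # normal flux divergence via face differences
        if bcs[axis].periodic:
            Hp = np.roll(H, -1, axis)
            Dp = np.roll(Dn, -1, axis)
            wp = 2 * Dn * Dp / (Dn + Dp) / h ** 2
            dHdt += wp * (Hp - H)
            Hm = np.roll(H, 1, axis)
            Dm = np.roll(Dn, 1, axis)
            wm = 2 * Dn * Dm / (Dn + Dm) / h ** 2
            dHdt += wm * (Hm - H)
        else:
            sl = [slice(None)] * 3

            def s(v):
                q = sl.copy()
                q[axis] = v
                return tuple(q)

            w = 2 * Dn[s(slice(0, -1))] * Dn[s(slice(1, None))] / (
                Dn[s(slice(0, -1))] + Dn[s(slice(1, None))]) / h ** 2
            inc = np.zeros_like(H)
            inc[s(slice(0, -1))] += w * (H[s(slice(1, None))] - H[s(slice(0, -1))])
            inc[s(slice(1, None))] += w * (H[s(slice(0, -1))] - H[s(slice(1, None))])
            dHdt += inc
            bc = bcs[axis]
            if bc.kind_lo == "dirichlet":
                w0 = 2 * Dn[s(0)] / h ** 2
                dHdt[s(0)] += w0 * (bc.value_lo - H[s(0)])
            if bc.kind_hi == "dirichlet":
                w1 = 2 * Dn[s(-1)] / h ** 2
                dHdt[s(-1)] += w1 * (bc.value_hi - H[s(-1)])
        # cross terms: d/d axis of sum_b D_ab dH/d b, central differences
        for b in range(3):
            if b == axis:
                continue
            Dab = D[names[axis][b]]
            if not np.any(Dab):
                continue
            dHdt += grad(Dab * grad(H, b), axis)
    return H + dt_small * (dHdt + k * (Hc - H))
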