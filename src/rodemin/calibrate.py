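"""Inverse calibration of transport parameters against an observed profile.

The unknowns of the forward model -- the crystal-frame diffusivities
``d_fast``, ``d_trans``, the sheath diffusivity ``d_sheath`` and the
reaction rate ``k`` -- are not directly measurable, so they are fitted by
error minimisation: the forward simulation is run at trial parameters, its
final mineral-content profile is compared with an observed profile over a
depth window, and the RMSE is minimised with a derivative-free simplex in
log-parameter space (the parameters span about five decades, and the
forward model is non-smooth at cell-crossing events, so gradients are
neither available nor trustworthy).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize

from .analysis import MineralProfile
from .orientation import LocalDiffusivity
from .solver import SimulationConfig, run_simulation

logger = logging.getLogger(__name__)

__all__ = ["CalibrationProblem", "CalibrationResult", "objective", "fit",
           "FREE_PARAMETERS"]

FREE_PARAMETERS = ("d_fast", "d_trans", "d_sheath", "k")

_DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "d_fast": (1e-4, 1.0),
    "d_trans": (1e-7, 1e-2),
    "d_sheath": (1e-9, 1e-4),
    "k": (1e-10, 1e-4),
}


@dataclass(frozen=True)
class CalibrationProblem:
    """Observed profile, free parameters with bounds, and the fixed config.

    ``fit_window`` (µm) restricts the RMSE to the depth range where the
    observation is trustworthy (default 40-100 µm: below it the material is
    detached and unmeasured, beyond it the profile is pristine and carries
    no information).
    """

    observed: MineralProfile
    free_params: Tuple[str, ...]
    config: SimulationConfig
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    fit_window: Tuple[float, float] = (40.0, 100.0)

    def __post_init__(self) -> None:
        if len(self.free_params) == 0:
            raise ValueError("at least one free parameter is required")
        for p in self.free_params:
            if p not in FREE_PARAMETERS:
                raise ValueError(f"unknown free parameter {p!r}")
        merged = dict(_DEFAULT_BOUNDS)
        merged.update(self.bounds)
        for p in self.free_params:
            lo, hi = merged[p]
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {p} must be positive with lower < upper")
        object.__setattr__(self, "bounds", merged)
        zlo, zhi = self.fit_window
        if zhi <= zlo:
            raise ValueError("fit window must have positive width")
        if zlo > self.observed.z[-1] or zhi < self.observed.z[0]:
            raise ValueError("fit window lies outside the observed profile support")


@dataclass
class CalibrationResult:
    """Point estimates, objective value and the evaluation trace."""

    estimates: Dict[str, float]
    objective: float
    n_evaluations: int
    converged: bool
    trace: List[Tuple[Dict[str, float], float]]


def _apply_params(config: SimulationConfig, params: Dict[str, float]) -> SimulationConfig:
    d = config.diffusivity
    kin = config.kinetics
    dd = {n: params.get(n, getattr(d, n)) for n in ("d_fast", "d_trans", "d_sheath")}
    # d_demin is defined relative to the fastest mineral axis, so it scales
    # with a trial d_fast; otherwise the dissolved zone would relay the acid
    # at a fixed rate and mask the parameter being fitted
    demin = d.d_demin * dd["d_fast"] / d.d_fast
    new_d = LocalDiffusivity(d_demin=demin, **dd)
    new_k = replace(kin, k=params.get("k", kin.k)) if "k" in params else kin
    return replace(config, diffusivity=new_d, kinetics=new_k)


def objective(problem: CalibrationProblem, params: Dict[str, float]) -> float:
    """RMSE of simulated vs observed mineral fraction over the fit window.

    The forward simulation is run up to the observed time stamp; the
    simulated profile is linearly interpolated at the observed depths inside
    the window.  Forward failures return +inf with a logged warning so the
    optimiser can route around them.
    """
    for p, v in params.items():
        lo, hi = problem.bounds[p]
        if not (lo <= v <= hi):
            raise ValueError(f"parameter {p}={v:.3g} outside bounds [{lo:.3g}, {hi:.3g}]")
    cfg = _apply_params(problem.config, params)
    cfg = replace(cfg, duration_s=float(problem.observed.t), snapshot_every_s=None)
    try:
        result = run_simulation(cfg)
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("forward simulation failed at %s: %s", params, exc)
        return float("inf")
    sim = result.profiles[-1]
    zlo, zhi = problem.fit_window
    sel = (problem.observed.z >= zlo) & (problem.observed.z <= zhi)
    z_obs = problem.observed.z[sel]
    m_obs = problem.observed.M[sel]
    m_sim = np.interp(z_obs, sim.z, sim.M)
    return float(np.sqrt(np.mean((m_sim - m_obs) ** 2)))


def fit(problem: CalibrationProblem, start: Optional[Dict[str, float]] = None,
        maxiter: int = 120, xatol: float = 1e-3, fatol: float = 1e-10,
        simplex_scale: float = 0.4) -> CalibrationResult:
    """Nelder-Mead minimisation of the profile RMSE in log10-parameter space.

    Bounds are enforced by clipping inside the transform, so every reported
    estimate lies within its bounds.  Deterministic for a fixed start point
    (the default start is the geometric mean of the bounds, or the current
    config value if it lies inside them).  The initial simplex spans
    ``simplex_scale`` decades per parameter: the defaults are tuned for
    parameters known only to order of magnitude, where scipy's tiny default
    simplex would crawl along the log axes.
    """
    names = list(problem.free_params)
    cfg_vals = {
        "d_fast": problem.config.diffusivity.d_fast,
        "d_trans": problem.config.diffusivity.d_trans,
        "d_sheath": problem.config.diffusivity.d_sheath,
        "k": problem.config.kinetics.k,
    }
    x0 = []
    for p in names:
        lo, hi = problem.bounds[p]
        if start and p in start:
            v = start[p]
        elif lo < cfg_vals[p] < hi:
            v = cfg_vals[p]
        else:
            v = math.sqrt(lo * hi)
        x0.append(math.log10(min(max(v, lo), hi)))
    trace: List[Tuple[Dict[str, float], float]] = []

    def to_params(x) -> Dict[str, float]:
        out = {}
        for p, xi in zip(names, x):
            lo, hi = problem.bounds[p]
            out[p] = float(np.clip(10.0 ** xi, lo, hi))
        return out

    def f(x) -> float:
        params = to_params(x)
        val = objective(problem, params)
        trace.append((params, val))
        return val

    x0 = np.asarray(x0)
    simplex = np.vstack([x0] + [x0 + simplex_scale * e
                                for e in np.eye(len(names))])
    res = minimize(
        f, x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol,
                 "adaptive": len(names) > 2, "initial_simplex": simplex},
    )
    best = to_params(res.x)
    return CalibrationResult(
        estimates=best,
        objective=float(res.fun),
        n_evaluations=len(trace),
        converged=bool(res.success),
        trace=trace,
    )
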