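"""Reduction of simulation states to lesion observables.

The observables mirror what micro-CT provides experimentally: the
cross-section-averaged mineral content as a function of depth,
M(z, t) = mean over the cross-section of Phi (1 = pristine), the depth of
the demineralisation front, and the Silverstone etch-pattern type (Type 1:
preferential loss of the rod core; Type 2: loss of the rod periphery with
the core intact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import REGION_CODES, RVEGrid
from .solver import SimState, SimulationConfig

__all__ = [
    "MineralProfile",
    "FrontSurface",
    "mineral_profile",
    "front_depth",
    "drop_depth",
    "extract_front",
    "ph_sweep",
    "PHSweepResult",
    "threshold_onset_ph",
    "classify_etch_pattern",
    "transverse_regions",
]


@dataclass(frozen=True)
class MineralProfile:
    """Depth (µm) vs cross-sectional mineral fraction at one time (s)."""

    z: np.ndarray
    M: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        M = np.asarray(self.M, dtype=float)
        if z.shape != M.shape or z.ndim != 1:
            raise ValueError("z and M must be 1-D arrays of equal length")
        if np.any(np.diff(z) <= 0):
            raise ValueError("depths must be strictly increasing")
        if M.min() < -1e-9 or M.max() > 1 + 1e-9:
            raise ValueError("mineral fraction must lie in [0, 1]")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "M", np.clip(M, 0.0, 1.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "z_um": self.z, "M_fraction": self.M})


@dataclass(frozen=True)
class FrontSurface:
    """Per-transverse-cell depth (µm) of the Phi = 0.5 crossing."""

    depth: np.ndarray
    axis: int


def mineral_profile(state: SimState, grid: RVEGrid, axis: int = 2) -> MineralProfile:
    """Cross-section average of Phi along the attack axis (midpoint rule).

    The integral of Phi over each cross-section is stored normalised by the
    section area, so a pristine section gives exactly 1.
    """
    transverse = tuple(a for a in range(3) if a != axis)
    M = state.Phi.mean(axis=transverse)
    coords = (grid.x, grid.y, grid.z)[axis]
    return MineralProfile(z=coords, M=M, t=state.t)


def front_depth(profile: MineralProfile, fraction: float) -> float:
    """Shallowest depth at which M rises through ``fraction``.

    Linear interpolation between cell centres; returns 0 if the profile
    already starts at or above the fraction, and the axis length (last
    depth) if the fraction is never reached.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    z, M = profile.z, profile.M
    if M[0] >= fraction:
        return 0.0
    above = np.nonzero(M >= fraction)[0]
    if above.size == 0:
        return float(z[-1])
    i = int(above[0])
    z0, z1, m0, m1 = z[i - 1], z[i], M[i - 1], M[i]
    if m1 == m0:
        return float(z1)
    return float(z0 + (fraction - m0) * (z1 - z0) / (m1 - m0))


def drop_depth(profile: MineralProfile) -> float:
    """Depth of the abrupt mineral loss (the complete-interrod-loss cliff).

    Finds the steepest rise of M with depth among cell interfaces whose
    shallow side still has M < 0.5, i.e. the steepest loss of mineral seen
    walking toward the surface from inside the lesion.  Returns the midpoint
    depth of that interface; ties break to the shallowest.  Returns NaN when
    M never falls below 0.5 (no lesion cliff).
    """
    z, M = profile.z, profile.M
    if M.min() >= 0.5:
        return math.nan
    dM = np.diff(M)
    ok = M[:-1] < 0.5
    dM = np.where(ok, dM, -np.inf)
    i = int(np.argmax(dM))  # argmax takes the first (shallowest) maximum
    return float(0.5 * (z[i] + z[i + 1]))


def extract_front(state: SimState, grid: RVEGrid, axis: int = 2) -> FrontSurface:
    """Per-transverse-cell depth of the deepest Phi = 0.5 crossing.

    For each line of cells along the attack axis, finds the deepest
    transition from dissolved (Phi < 0.5) to intact (Phi >= 0.5) and
    interpolates the crossing linearly.  Lines that are intact everywhere
    get depth 0; fully dissolved lines get the axis length.
    """
    Phi = np.moveaxis(state.Phi, axis, -1)
    coords = (grid.x, grid.y, grid.z)[axis]
    n = Phi.shape[-1]
    below = Phi < 0.5
    any_below = below.any(axis=-1)
    # deepest index that is still below 0.5
    last_below = n - 1 - np.argmax(below[..., ::-1], axis=-1)
    depth = np.zeros(Phi.shape[:-1])
    length = float(coords[-1])
    it = np.ndindex(depth.shape)
    for ix in it:
        if not any_below[ix]:
            continue
        i = int(last_below[ix])
        if i == n - 1:
            depth[ix] = length
            continue
        p0, p1 = Phi[ix + (i,)], Phi[ix + (i + 1,)]
        z0, z1 = coords[i], coords[i + 1]
        depth[ix] = z0 + (0.5 - p0) * (z1 - z0) / (p1 - p0)
    return FrontSurface(depth=depth, axis=axis)


def transverse_regions(grid: RVEGrid, axis: int = 2) -> np.ndarray:
    """Region label for each transverse cell of an attack along ``axis``.

    For the axial attack the cross-section is the (x, y) plane and labels
    are the in-plane region map.  For an in-plane attack each line of cells
    crosses several regions; the line is labelled by the region it has at
    the head-centre coordinate of the attack axis, which tags lines through
    the rod core as rod-head and flanking lines as interrod/sheath.
    """
    if axis == 2:
        return grid.region
    g = grid.geometry
    nz = g.nz
    if axis == 1:
        iy = int(np.clip(g.head_center[1] / g.hy, 0, g.ny - 1))
        col = grid.region[:, iy]
        return np.broadcast_to(col[:, None], (g.nx, nz))
    ix = int(np.clip(g.head_center[0] / g.hx, 0, g.nx - 1))
    row = grid.region[ix, :]
    return np.broadcast_to(row[:, None], (g.ny, nz))


def classify_etch_pattern(front: FrontSurface, grid: RVEGrid, margin: float = 0.10) -> str:
    """Silverstone etch-pattern type from the front surface.

    ``Type1`` when the mean front depth over rod-head cells exceeds the mean
    over interrod cells by more than ``margin`` times the overall mean depth
    (preferential loss of the rod core), ``Type2`` for the reverse, and
    ``Indeterminate`` when the contrast is within the margin (e.g. a flat
    front).
    """
    labels = transverse_regions(grid, front.axis)
    if labels.shape != front.depth.shape:
        raise ValueError("front and grid do not share transverse geometry")
    head = front.depth[labels == REGION_CODES["rod_head"]]
    inter = front.depth[labels == REGION_CODES["interrod"]]
    if head.size == 0 or inter.size == 0:
        return "Indeterminate"
    overall = float(front.depth.mean())
    if overall <= 0:
        return "Indeterminate"
    contrast = float(head.mean() - inter.mean())
    if contrast > margin * overall:
        return "Type1"
    if contrast < -margin * overall:
        return "Type2"
    return "Indeterminate"


def threshold_onset_ph(base_config: SimulationConfig, lo: float = 4.0,
                       hi: float = 7.0, tol: float = 0.05) -> float:
    """Boundary pH at which demineralisation just ceases to initiate.

    Bisects the acid boundary pH between ``lo`` (demineralising) and ``hi``
    (inert), running one short simulation per trial and testing whether the
    phase parameter decreased anywhere.  Converges to the critical pH of the
    dissolution trigger; the returned value is the bracket midpoint at
    tolerance ``tol``.
    """
    from dataclasses import replace

    from .solver import run_simulation

    def demineralises(pH: float) -> bool:
        res = run_simulation(replace(base_config, pH_acid=pH))
        return bool(res.final_state.Phi.min() < 1.0 - 1e-9)

    if not demineralises(lo):
        raise ValueError(f"no demineralisation even at pH {lo}; cannot bracket onset")
    if demineralises(hi):
        raise ValueError(f"demineralisation at pH {hi}; cannot bracket onset")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if demineralises(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class PHSweepResult:
    """Front depths vs boundary pH plus the linear fit over a sub-range."""

    table: pd.DataFrame
    slope: float
    intercept: float
    r_squared: float
    fit_range: tuple

    def depths(self) -> np.ndarray:
        return self.table["front_depth_um"].to_numpy()


def ph_sweep(base_config: SimulationConfig, pH_list: Sequence[float],
             fraction: float = 0.8, fit_range: tuple = (2.0, 5.0)) -> PHSweepResult:
    """Run one full simulation per boundary pH and record the lesion depth.

    The depth recorded for each pH is the depth at which the final mineral
    profile has recovered to ``fraction`` (default 80%) of the pristine
    content.  A least-squares line of depth vs pH is fitted over
    ``fit_range`` (inclusive).
    """
    from dataclasses import replace

    rows = []
    for pH in pH_list:
        if not (0 < pH < 14):
            raise ValueError(f"pH {pH} outside (0, 14)")
        from .solver import run_simulation

        cfg = replace(base_config, pH_acid=float(pH))
        result = run_simulation(cfg)
        depth = front_depth(result.profiles[-1], fraction)
        rows.append((float(pH), depth))
    table = pd.DataFrame(rows, columns=["pH", "front_depth_um"])
    sel = (table["pH"] >= fit_range[0]) & (table["pH"] <= fit_range[1])
    x = table.loc[sel, "pH"].to_numpy()
    y = table.loc[sel, "front_depth_um"].to_numpy()
    if x.size >= 2:
        slope, intercept = np.polyfit(x, y, 1)
        pred = slope * x + intercept
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    else:
        slope = intercept = r2 = float("nan")
    return PHSweepResult(table=table, slope=float(slope), intercept=float(intercept),
                         r_squared=float(r2), fit_range=fit_range)
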