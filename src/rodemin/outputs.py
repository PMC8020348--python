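"""Result serialisation: CSV profiles, VTK snapshots, JSON summary, manifest.

A run directory contains::

    profiles.csv        all mineral profiles, header t_s,z_um,M_fraction
    snapshot_*.vtk      per-snapshot cell fields H, Phi, region (if states kept)
    summary.json        front depth per snapshot, drop depth, etch type
    manifest.json       verbatim config snapshot, version, timestamps,
                        file inventory with sha256 checksums
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    MineralProfile,
    classify_etch_pattern,
    drop_depth,
    extract_front,
    front_depth,
)
from .config import config_to_dict
from .solver import SimulationResult
from .vtkio import write_vtk_image

__all__ = ["write_outputs", "profiles_to_csv", "read_profile_csv",
           "export_region_vtk", "export_diffusivity_vtk"]

PROFILE_HEADER = ["t_s", "z_um", "M_fraction"]


def profiles_to_csv(profiles: List[MineralProfile], path) -> None:
    """Write profiles as CSV with the canonical header ``t_s,z_um,M_fraction``."""
    frames = [p.to_frame() for p in profiles]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=PROFILE_HEADER)
    df.to_csv(path, index=False, float_format="%.12g")


def read_profile_csv(path, t: Optional[float] = None) -> MineralProfile:
    """Read one profile back (the latest time stamp unless ``t`` is given)."""
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"profile CSV {path} lacks columns {missing}")
    pick = df["t_s"].max() if t is None else t
    sub = df[df["t_s"] == pick]
    return MineralProfile(z=sub["z_um"].to_numpy(), M=sub["M_fraction"].to_numpy(),
                          t=float(pick))


def export_region_vtk(grid, path) -> None:
    """Write the region labels as VTK ImageData for visual inspection."""
    g = grid.geometry
    region = np.ascontiguousarray(
        np.broadcast_to(grid.region[:, :, None], (g.nx, g.ny, 1))).astype(np.int32)
    write_vtk_image(path, {"region": region}, spacing=(g.hx, g.hy, g.hz),
                    title="RVE region labels")


def export_diffusivity_vtk(field, grid, path) -> None:
    """Write the six global-tensor components as VTK cell arrays."""
    g = grid.geometry
    arrays = {
        name: np.ascontiguousarray(
            np.broadcast_to(field.component(name)[:, :, None], (g.nx, g.ny, 1)))
        for name in ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")
    }
    write_vtk_image(path, arrays, spacing=(g.hx, g.hy, g.hz),
                    title="global diffusivity tensor (um2/s)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(result: SimulationResult, out_dir, front_fraction: float = 0.8) -> Dict:
    """Write the full run output set; returns the manifest mapping."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    files: List[str] = []

    profile_path = out / "profiles.csv"
    profiles_to_csv(result.profiles, profile_path)
    files.append(profile_path.name)

    g = result.grid.geometry
    spacing = (g.hx, g.hy, g.hz)
    region3d = np.ascontiguousarray(result.grid.region_3d()).astype(np.int32)
    for i, state in enumerate(result.states):
        p = out / f"snapshot_{i:04d}.vtk"
        write_vtk_image(
            p,
            {"H": state.H, "Phi": state.Phi, "region": region3d},
            spacing=spacing,
            title=f"t={state.t:.6g}s",
        )
        files.append(p.name)

    axis = result.config.attack_axis
    front = extract_front(result.final_state, result.grid, axis=axis)
    final = result.profiles[-1]
    dd = drop_depth(final)
    summary = {
        "scenario": result.config.scenario,
        "pH_acid": result.config.pH_acid,
        "duration_s": result.config.duration_s,
        "times_s": [float(t) for t in result.times],
        "front_depth_um": {
            f"{t:.6g}": front_depth(p, front_fraction)
            for t, p in zip(result.times, result.profiles)
        },
        "front_fraction": front_fraction,
        "drop_depth_um": None if np.isnan(dd) else float(dd),
        "etch_pattern": classify_etch_pattern(front, result.grid),
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    files.append(summary_path.name)

    manifest = {
        "software": {"name": "rodemin", "version": __version__},
        "config": config_to_dict(result.config),
        "started": started,
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": {},
    }
    for name in files:
        manifest["files"][name] = _sha256(out / name)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
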