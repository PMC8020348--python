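"""Minimal legacy-ASCII VTK ImageData (STRUCTURED_POINTS) writer.

Snapshots are written as cell data on the structured RVE grid so they can
be inspected in ParaView or any VTK-based viewer.  Only the small subset of
the legacy format needed here is implemented (no compression, ASCII only);
:func:`read_vtk_image` parses the files back for round-trip checks.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

__all__ = ["write_vtk_image", "read_vtk_image"]


def write_vtk_image(path, cell_arrays: Dict[str, np.ndarray],
                    spacing: Tuple[float, float, float],
                    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0),
                    title: str = "rodemin snapshot") -> None:
    """Write cell-centred arrays of common shape (nx, ny, nz) to ``path``.

    Point dimensions are (nx+1, ny+1, nz+1); VTK expects x to vary fastest,
    so arrays are flattened in Fortran order.
    """
    arrays = {k: np.asarray(v) for k, v in cell_arrays.items()}
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError("all cell arrays must share one shape")
    nx, ny, nz = shapes.pop()
    with open(path, "w", encoding="ascii") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        fh.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        fh.write(f"SPACING {spacing[0]:.9g} {spacing[1]:.9g} {spacing[2]:.9g}\n")
        fh.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in arrays.items():
            is_int = np.issubdtype(arr.dtype, np.integer)
            vtk_type = "int" if is_int else "double"
            fh.write(f"SCALARS {name} {vtk_type} 1\n")
            fh.write("LOOKUP_TABLE default\n")
            flat = arr.ravel(order="F")
            fmt = "%d" if is_int else "%.9e"
            np.savetxt(fh, flat.reshape(-1, 1), fmt=fmt)


def read_vtk_image(path):
    """Parse a file written by :func:`write_vtk_image`.

    Returns ``(cell_arrays, spacing, origin)`` with arrays of shape
    (nx, ny, nz).
    """
    with open(path, "r", encoding="ascii") as fh:
        lines = fh.read().splitlines()
    it = iter(lines)
    dims = spacing = origin = None
    n_cells = None
    arrays: Dict[str, np.ndarray] = {}
    line = next(it)
    if not line.startswith("# vtk DataFile"):
        raise ValueError("not a legacy VTK file")
    for line in it:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "DIMENSIONS":
            dims = tuple(int(v) - 1 for v in tok[1:4])
        elif tok[0] == "SPACING":
            spacing = tuple(float(v) for v in tok[1:4])
        elif tok[0] == "ORIGIN":
            origin = tuple(float(v) for v in tok[1:4])
        elif tok[0] == "CELL_DATA":
            n_cells = int(tok[1])
        elif tok[0] == "SCALARS":
            name, vtk_type = tok[1], tok[2]
            next(it)  # LOOKUP_TABLE line
            vals = []
            while len(vals) < n_cells:
                vals.extend(next(it).split())
            data = np.array(vals, dtype=int if vtk_type == "int" else float)
            arrays[name] = data.reshape(dims, order="F")
    return arrays, spacing, origin
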