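"""Lattice snapshots as ASCII VTK legacy structured-points files.

Point data fields written per site, x index varying fastest: ``ECM``,
``MDF``, ``G``, ``stress`` (kPa, signed) and the integer codes
``occupant`` (0 none, 1 cSMC, 2 sSMC, 3 EC) and ``domain`` (0 outside,
1 lumen, 2 wall).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .lattice import Lattice

_FLOAT_FIELDS = ("ECM", "MDF", "G", "stress")
_INT_FIELDS = ("occupant", "domain")


def write_snapshot_vtk(lat: Lattice, path) -> None:
    nx, ny, nz = lat.dims
    n = nx * ny * nz
    arrays = {
        "ECM": lat.ecm, "MDF": lat.mdf, "G": lat.g, "stress": lat.stress,
        "occupant": lat.occupant, "domain": lat.domain,
    }
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("stentsim lattice snapshot\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        ox, oy, oz = lat.origin + 0.5 * lat.dl  # site centers
        fh.write(f"ORIGIN {ox:.17g} {oy:.17g} {oz:.17g}\n")
        fh.write(f"SPACING {lat.dl:.17g} {lat.dl:.17g} {lat.dl:.17g}\n")
        fh.write(f"POINT_DATA {n}\n")
        for name in _FLOAT_FIELDS:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arrays[name].ravel(order="F"), fmt="%.12g")
        for name in _INT_FIELDS:
            fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arrays[name].ravel(order="F"), fmt="%d")


def read_snapshot_vtk(path) -> Lattice:
    """Read a snapshot back into a Lattice (stress/fields restored; useful
    for recomputing metrics from stored snapshots)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# vtk"):
        raise ValueError(f"{path}: not a VTK legacy file")
    dims = origin = spacing = None
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        kw = parts[0].upper()
        if kw == "DIMENSIONS":
            dims = tuple(int(v) for v in parts[1:4])
        elif kw == "ORIGIN":
            origin = np.array([float(v) for v in parts[1:4]])
        elif kw == "SPACING":
            spacing = float(parts[1])
        elif kw == "POINT_DATA":
            break
    if dims is None or origin is None or spacing is None:
        raise ValueError(f"{path}: missing structured-points header")
    n = dims[0] * dims[1] * dims[2]
    lat = Lattice.empty(dims, origin - 0.5 * spacing, spacing)
    target = {
        "ECM": lat.ecm, "MDF": lat.mdf, "G": lat.g, "stress": lat.stress,
        "occupant": lat.occupant, "domain": lat.domain,
    }
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts or parts[0].upper() != "SCALARS":
            continue
        name = parts[1]
        i += 1  # LOOKUP_TABLE line
        vals = np.array([float(lines[i + t]) for t in range(n)])
        i += n
        if name in target:
            arr = vals.reshape(dims, order="F")
            target[name][:] = arr.astype(target[name].dtype)
    return lat
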