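"""Hexahedral stress meshes and their mapping onto the lattice.

A post-expansion finite-element result enters the simulation as a mesh of
8-node hexahedra with one minimum-principal-stress value per element
(kPa, compression negative). Two on-disk representations are supported:

Neutral text format (units declared in the header)::

    # stentsim stress mesh v1
    UNITS mm kPa
    NODES <n>
    <id> <x> <y> <z>          # ids 0-based, consecutive
    ELEMENTS <m>
    <id> <n1> ... <n8>        # VTK hexahedron node ordering
    STRESS <m>
    <id> <value>

and ASCII VTK legacy unstructured grids (cell type 12) carrying a cell
data scalar named ``min_principal_stress``.

Lattice sites inside an element are found with an axis-aligned bounding
box pre-filter followed by a six-face half-space test; each quadrilateral
face is treated as its best-fit plane with inward-pointing normal, so
mildly warped faces are handled approximately (sites within a thin
boundary shell may be attributed to either neighbouring element).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .lattice import Lattice, WALL
from .params import ConfigurationError


class MeshFormatError(ValueError):
    """A stress-mesh file is malformed."""


class GeometryError(ValueError):
    """A mesh element is degenerate."""


# VTK hexahedron: nodes 0-3 the bottom quad, 4-7 the top quad
_HEX_FACES = np.array([
    (0, 3, 2, 1),
    (4, 5, 6, 7),
    (0, 1, 5, 4),
    (1, 2, 6, 5),
    (2, 3, 7, 6),
    (3, 0, 4, 7),
])

# 5-tetrahedron decomposition of the hexahedron (used for volume and as
# the independent point-containment oracle in the tests)
HEX_TETS = np.array([
    (0, 1, 3, 4),
    (1, 2, 3, 6),
    (1, 4, 5, 6),
    (3, 4, 6, 7),
    (1, 3, 4, 6),
])


@dataclass
class StressMesh:
    nodes: np.ndarray           # (n, 3) float, mm
    elements: np.ndarray        # (m, 8) int node indices
    element_stress: np.ndarray  # (m,) float, kPa (compression negative)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.elements = np.asarray(self.elements, dtype=np.int64).reshape(-1, 8)
        self.element_stress = np.asarray(self.element_stress, dtype=float).ravel()
        if len(self.element_stress) != len(self.elements):
            raise MeshFormatError(
                f"{len(self.element_stress)} stress values for "
                f"{len(self.elements)} elements"
            )
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise MeshFormatError("element refers to a node index out of range")

    def element_volume(self, e: int) -> float:
        v = self.nodes[self.elements[e]]
        total = 0.0
        for t in HEX_TETS:
            a, b, c, d = v[t]
            total += abs(np.linalg.det(np.stack([b - a, c - a, d - a]))) / 6.0
        return total


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_stress_mesh(path) -> StressMesh:
    """Read a stress mesh, dispatching on the file's first line."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.lstrip().startswith("# vtk"):
        return read_stress_mesh_vtk(path)
    return read_stress_mesh_neutral(path)


def read_stress_mesh_neutral(path) -> StressMesh:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    pos = 0

    def expect(keyword):
        nonlocal pos
        if pos >= len(lines):
            raise MeshFormatError(f"{path}: unexpected end of file, expected {keyword}")
        parts = lines[pos].split()
        if parts[0].upper() != keyword:
            raise MeshFormatError(f"{path}: expected {keyword}, got {lines[pos]!r}")
        pos += 1
        return parts[1:]

    units = expect("UNITS")
    if [u.lower() for u in units] != ["mm", "kpa"]:
        raise MeshFormatError(f"{path}: unsupported UNITS {' '.join(units)!r}")

    (n_nodes,) = map(int, expect("NODES"))
    nodes = np.empty((n_nodes, 3))
    for i in range(n_nodes):
        parts = lines[pos].split()
        pos += 1
        if len(parts) != 4 or int(parts[0]) != i:
            raise MeshFormatError(f"{path}: bad node record {lines[pos - 1]!r}")
        nodes[i] = [float(v) for v in parts[1:]]

    (n_elems,) = map(int, expect("ELEMENTS"))
    elements = np.empty((n_elems, 8), dtype=np.int64)
    for i in range(n_elems):
        parts = lines[pos].split()
        pos += 1
        if len(parts) != 9 or int(parts[0]) != i:
            raise MeshFormatError(f"{path}: bad element record {lines[pos - 1]!r}")
        elements[i] = [int(v) for v in parts[1:]]

    (n_stress,) = map(int, expect("STRESS"))
    if n_stress != n_elems:
        raise MeshFormatError(
            f"{path}: STRESS count {n_stress} != ELEMENTS count {n_elems}"
        )
    stress = np.empty(n_elems)
    for i in range(n_elems):
        parts = lines[pos].split()
        pos += 1
        if len(parts) != 2 or int(parts[0]) != i:
            raise MeshFormatError(f"{path}: bad stress record {lines[pos - 1]!r}")
        stress[i] = float(parts[1])

    return StressMesh(nodes, elements, stress)


def write_stress_mesh_neutral(mesh: StressMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("# stentsim stress mesh v1\n")
        fh.write("UNITS mm kPa\n")
        fh.write(f"NODES {len(mesh.nodes)}\n")
        for i, (x, y, z) in enumerate(mesh.nodes):
            fh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
        fh.write(f"ELEMENTS {len(mesh.elements)}\n")
        for i, el in enumerate(mesh.elements):
            fh.write(f"{i} " + " ".join(str(int(n)) for n in el) + "\n")
        fh.write(f"STRESS {len(mesh.element_stress)}\n")
        for i, s in enumerate(mesh.element_stress):
            fh.write(f"{i} {s:.17g}\n")


def read_stress_mesh_vtk(path) -> StressMesh:
    """ASCII VTK legacy unstructured grid with hexahedral cells and a cell
    data scalar named ``min_principal_stress``."""
    tokens: list[str] = []
    text = Path(path).read_text().splitlines()
    if len(text) < 4 or not text[0].lstrip().startswith("# vtk"):
        raise MeshFormatError(f"{path}: not a VTK legacy file")
    if text[2].strip().upper() != "ASCII":
        raise MeshFormatError(f"{path}: only ASCII VTK files are supported")
    for ln in text[3:]:
        tokens.extend(ln.split())
    tok = iter(tokens)

    def take(n=1):
        out = []
        try:
            for _ in range(n):
                out.append(next(tok))
        except StopIteration:
            raise MeshFormatError(f"{path}: truncated VTK file") from None
        return out if n > 1 else out[0]

    if take().upper() != "DATASET" or take().upper() != "UNSTRUCTURED_GRID":
        raise MeshFormatError(f"{path}: expected DATASET UNSTRUCTURED_GRID")
    kw = take().upper()
    if kw != "POINTS":
        raise MeshFormatError(f"{path}: expected POINTS, got {kw}")
    n_pts = int(take())
    take()  # dtype
    nodes = np.array([float(take()) for _ in range(3 * n_pts)]).reshape(-1, 3)

    kw = take().upper()
    if kw != "CELLS":
        raise MeshFormatError(f"{path}: expected CELLS, got {kw}")
    n_cells = int(take())
    int(take())  # total list size
    elements = np.empty((n_cells, 8), dtype=np.int64)
    for c in range(n_cells):
        npts = int(take())
        if npts != 8:
            raise MeshFormatError(f"{path}: cell {c} has {npts} nodes, expected 8")
        elements[c] = [int(take()) for _ in range(8)]

    kw = take().upper()
    if kw != "CELL_TYPES":
        raise MeshFormatError(f"{path}: expected CELL_TYPES, got {kw}")
    int(take())
    for c in range(n_cells):
        ct = int(take())
        if ct != 12:
            raise MeshFormatError(
                f"{path}: cell {c} has VTK type {ct}, expected 12 (hexahedron)"
            )

    stress = None
    try:
        while True:
            kw = take().upper()
            if kw == "CELL_DATA":
                int(take())
            elif kw == "SCALARS":
                name = take()
                take()  # dtype
                nxt = take()
                ncomp = 1
                if nxt.upper() != "LOOKUP_TABLE":
                    ncomp = int(nxt)
                    lk = take()
                    if lk.upper() != "LOOKUP_TABLE":
                        raise MeshFormatError(f"{path}: malformed SCALARS {name}")
                take()  # table name
                vals = np.array([float(take()) for _ in range(ncomp * n_cells)])
                if name == "min_principal_stress":
                    stress = vals[::ncomp]
            else:
                continue
    except MeshFormatError:
        pass
    if stress is None:
        raise MeshFormatError(
            f"{path}: no cell data scalar named min_principal_stress"
        )
    return StressMesh(nodes, elements, stress)


def write_stress_mesh_vtk(mesh: StressMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("stentsim stress mesh\n")
        fh.write("ASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(mesh.nodes)} double\n")
        for x, y, z in mesh.nodes:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        m = len(mesh.elements)
        fh.write(f"CELLS {m} {9 * m}\n")
        for el in mesh.elements:
            fh.write("8 " + " ".join(str(int(n)) for n in el) + "\n")
        fh.write(f"CELL_TYPES {m}\n")
        for _ in range(m):
            fh.write("12\n")
        fh.write(f"CELL_DATA {m}\n")
        fh.write("SCALARS min_principal_stress double 1\n")
        fh.write("LOOKUP_TABLE default\n")
        for s in mesh.element_stress:
            fh.write(f"{s:.17g}\n")


def write_stress_mesh(mesh: StressMesh, path, fmt: str | None = None) -> None:
    if fmt is None:
        fmt = "vtk" if str(path).endswith(".vtk") else "neutral"
    if fmt == "vtk":
        write_stress_mesh_vtk(mesh, path)
    elif fmt == "neutral":
        write_stress_mesh_neutral(mesh, path)
    else:
        raise ValueError(f"unknown stress-mesh format {fmt!r}")


# ---------------------------------------------------------------------------
# Point location and mapping
# ---------------------------------------------------------------------------

def _face_planes(verts: np.ndarray):
    """Best-fit plane (Newell normal, face centroid) for each hexahedron
    face, normals oriented inward."""
    centroid = verts.mean(axis=0)
    normals = np.empty((6, 3))
    centers = np.empty((6, 3))
    for f, face in enumerate(_HEX_FACES):
        pts = verts[face]
        n = np.zeros(3)
        for i in range(4):
            p, q = pts[i], pts[(i + 1) % 4]
            n[0] += (p[1] - q[1]) * (p[2] + q[2])
            n[1] += (p[2] - q[2]) * (p[0] + q[0])
            n[2] += (p[0] - q[0]) * (p[1] + q[1])
        c = pts.mean(axis=0)
        if np.dot(n, centroid - c) < 0:
            n = -n
        normals[f] = n
        centers[f] = c
    return normals, centers


def locate_lattice_sites_in_element(mesh: StressMesh, elem: int,
                                    lat: Lattice) -> np.ndarray:
    """Indices (p, 3) of lattice sites whose centers lie inside (or on the
    boundary of) hexahedron ``elem``."""
    verts = mesh.nodes[mesh.elements[elem]]
    scale = np.linalg.norm(verts.max(axis=0) - verts.min(axis=0))
    if mesh.element_volume(elem) < 1e-9 * max(scale, 1e-30) ** 3:
        raise GeometryError(f"element {elem} is degenerate (near-zero volume)")

    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    # candidate index ranges from the bounding box
    i0 = np.maximum(np.ceil((lo - lat.origin) / lat.dl - 0.5 - 1e-12).astype(int), 0)
    i1 = np.minimum(np.floor((hi - lat.origin) / lat.dl - 0.5 + 1e-12).astype(int),
                    np.array(lat.dims) - 1)
    if np.any(i1 < i0):
        return np.empty((0, 3), dtype=np.int64)

    ii, jj, kk = np.meshgrid(*(np.arange(a, b + 1) for a, b in zip(i0, i1)),
                             indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    pts = lat.origin + (idx + 0.5) * lat.dl

    normals, centers = _face_planes(verts)
    tol = 1e-9 * max(scale, 1.0)
    inside = np.ones(len(pts), dtype=bool)
    for n, c in zip(normals, centers):
        inside &= (pts - c) @ n >= -tol
        if not inside.any():
            break
    return idx[inside]


def annulus_hex_mesh(geometry, n_r: int = 2, n_theta: int = 24,
                     n_z: int = 40) -> StressMesh:
    """Structured hexahedral mesh of the artery-wall annulus (stress 0).

    Nodes on a cylindrical grid (n_r+1 radial layers, n_theta angular
    sectors wrapping around, n_z+1 axial planes); elements in VTK
    hexahedron ordering.
    """
    if n_r < 1 or n_theta < 3 or n_z < 1:
        raise ConfigurationError("annulus mesh needs n_r>=1, n_theta>=3, n_z>=1")
    rs = np.linspace(geometry.r_inner, geometry.r_outer, n_r + 1)
    thetas = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    zs = np.linspace(0.0, geometry.length, n_z + 1)

    def nid(i, j, k):
        return (k * n_theta + (j % n_theta)) * (n_r + 1) + i

    nodes = np.empty(((n_r + 1) * n_theta * (n_z + 1), 3))
    for k, z in enumerate(zs):
        for j, th in enumerate(thetas):
            for i, r in enumerate(rs):
                nodes[nid(i, j, k)] = (r * np.cos(th), r * np.sin(th), z)

    elements = []
    for k in range(n_z):
        for j in range(n_theta):
            for i in range(n_r):
                elements.append((
                    nid(i, j, k), nid(i + 1, j, k),
                    nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ))
    elements = np.array(elements, dtype=np.int64)
    return StressMesh(nodes, elements, np.zeros(len(elements)))


def synthetic_stress_mesh(spec, geometry, n_r: int = 2, n_theta: int = 24,
                          n_z: int = 40) -> StressMesh:
    """Annulus mesh carrying the synthetic stent field, sampled at element
    centroids (signed: compression negative)."""
    from .injury import synthetic_stress_field

    mesh = annulus_hex_mesh(geometry, n_r, n_theta, n_z)
    dr = (geometry.r_outer - geometry.r_inner) / n_r
    dth = 2.0 * np.pi / n_theta
    dz = geometry.length / n_z
    stress = np.empty(len(mesh.elements))
    e = 0
    for k in range(n_z):
        zc = (k + 0.5) * dz
        for j in range(n_theta):
            thc = (j + 0.5) * dth
            for i in range(n_r):
                rc = geometry.r_inner + (i + 0.5) * dr
                stress[e] = -float(
                    synthetic_stress_field(spec, geometry,
                                           np.array(rc), np.array(thc),
                                           np.array(zc))
                )
                e += 1
    mesh.element_stress = stress
    return mesh


def map_stress_to_lattice(mesh: StressMesh, lat: Lattice) -> int:
    """Initialise the lattice from the mesh: every site located inside an
    element becomes a wall site with intact ECM and that element's stress.
    Elements are processed in file order, so sites claimed by several
    elements keep the last element's value. Returns the wall-site count."""
    touched = 0
    any_hit = False
    for e in range(len(mesh.elements)):
        sites = locate_lattice_sites_in_element(mesh, e, lat)
        if len(sites) == 0:
            continue
        any_hit = True
        i, j, k = sites[:, 0], sites[:, 1], sites[:, 2]
        lat.domain[i, j, k] = WALL
        lat.ecm[i, j, k] = 1.0
        lat.stress[i, j, k] = mesh.element_stress[e]
        touched += len(sites)
    if not any_hit and len(mesh.elements):
        raise ConfigurationError("stress mesh lies entirely outside the lattice")
    return int((lat.domain == WALL).sum())
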