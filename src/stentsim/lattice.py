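"""Voxelized artery domain: a regular orthogonal lattice of sites.

Each site carries a domain flag (outside / lumen / wall), scalar fields
ECM (matrix, in [0,1]), MDF (matrix-degrading factors, >= 0), G (growth
stimulus, >= 0), the mapped minimum principal stress (kPa, compression
negative), and at most one occupant cell (none / cSMC / sSMC / EC).

Site centers sit at ``origin + (i+1/2, j+1/2, k+1/2) * dl``; z is the
artery axis. Indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .params import ConfigurationError, Geometry

# domain codes
OUTSIDE, LUMEN, WALL = 0, 1, 2
# occupant codes
OCC_NONE, OCC_CSMC, OCC_SSMC, OCC_EC = 0, 1, 2, 3

#: tolerance below which a field value is snapped to exactly zero, and
#: within which ECM counts as exactly 1 for the contractile test
FIELD_TOL = 1e-9


def _build_offsets() -> dict[int, np.ndarray]:
    off = np.array(
        [(dx, dy, dz)
         for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if (dx, dy, dz) != (0, 0, 0)],
        dtype=np.int64,
    )
    order = np.abs(off).sum(axis=1)
    return {
        6: off[order == 1],
        18: off[order <= 2],
        26: off,
    }


#: neighbourhood offset tables keyed by connectivity (6 / 18 / 26)
OFFSETS = _build_offsets()


@dataclass
class Lattice:
    dims: tuple[int, int, int]
    origin: np.ndarray          # mm, (3,)
    dl: float                   # mm
    domain: np.ndarray          # uint8 (nx, ny, nz)
    ecm: np.ndarray             # float64
    mdf: np.ndarray
    g: np.ndarray
    stress: np.ndarray          # signed min principal stress, kPa
    occupant: np.ndarray        # uint8

    @classmethod
    def empty(cls, dims, origin, dl) -> "Lattice":
        shape = tuple(int(n) for n in dims)
        return cls(
            dims=shape,
            origin=np.asarray(origin, dtype=float),
            dl=float(dl),
            domain=np.zeros(shape, dtype=np.uint8),
            ecm=np.zeros(shape),
            mdf=np.zeros(shape),
            g=np.zeros(shape),
            stress=np.zeros(shape),
            occupant=np.zeros(shape, dtype=np.uint8),
        )

    def site_centers(self):
        """Coordinate arrays (x[i], y[j], z[k]) of site centers, mm."""
        nx, ny, nz = self.dims
        ox, oy, oz = self.origin
        x = ox + (np.arange(nx) + 0.5) * self.dl
        y = oy + (np.arange(ny) + 0.5) * self.dl
        z = oz + (np.arange(nz) + 0.5) * self.dl
        return x, y, z

    def in_bounds(self, site) -> bool:
        return all(0 <= s < n for s, n in zip(site, self.dims))

    def copy(self) -> "Lattice":
        return Lattice(
            dims=self.dims, origin=self.origin.copy(), dl=self.dl,
            domain=self.domain.copy(), ecm=self.ecm.copy(), mdf=self.mdf.copy(),
            g=self.g.copy(), stress=self.stress.copy(), occupant=self.occupant.copy(),
        )


def build_artery_lattice(geometry: Geometry, dl: float, pad_sites: int = 1) -> Lattice:
    """Voxelize a hollow-cylinder artery.

    A site is ``wall`` iff its center's radial distance r from the axis
    satisfies r_inner <= r < r_outer, ``lumen`` iff r < r_inner, else
    ``outside``. Wall sites start with intact matrix (ECM = 1).
    """
    geometry.validate()
    if dl <= 0:
        raise ConfigurationError(f"dl must be > 0, got {dl}")
    if geometry.r_outer <= 0:
        raise ConfigurationError("r_outer must be > 0")

    half = geometry.r_outer + pad_sites * dl
    n_half = int(np.ceil(half / dl))
    nx = ny = 2 * n_half
    nz = int(np.ceil(geometry.length / dl))
    origin = np.array([-n_half * dl, -n_half * dl, 0.0])
    lat = Lattice.empty((nx, ny, nz), origin, dl)

    x, y, _ = lat.site_centers()
    r = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
    section = np.full((nx, ny), OUTSIDE, dtype=np.uint8)
    section[r < geometry.r_inner] = LUMEN
    section[(r >= geometry.r_inner) & (r < geometry.r_outer)] = WALL
    lat.domain[:] = section[:, :, None]
    lat.ecm[lat.domain == WALL] = 1.0
    return lat


def neighbors(lat: Lattice, site, stencil: int = 26) -> list[tuple[int, int, int]]:
    """Neighbour sites of ``site`` under the given connectivity, clipped to
    the grid, in deterministic (offset-table) order."""
    i, j, k = site
    if not lat.in_bounds(site):
        raise IndexError(f"site {site} outside lattice dims {lat.dims}")
    out = []
    nx, ny, nz = lat.dims
    for dx, dy, dz in OFFSETS[stencil]:
        a, b, c = i + dx, j + dy, k + dz
        if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz:
            out.append((a, b, c))
    return out


def local_cell_concentration(lat: Lattice, site, stencil: int = 26) -> float:
    """Fraction of the site-plus-neighbours stencil (restricted to
    non-``outside`` sites) occupied by SMCs of either phenotype."""
    sites = [tuple(site)] + neighbors(lat, site, stencil)
    n_dom = 0
    n_smc = 0
    for s in sites:
        if lat.domain[s] != OUTSIDE:
            n_dom += 1
            if lat.occupant[s] in (OCC_CSMC, OCC_SSMC):
                n_smc += 1
    return n_smc / n_dom if n_dom else 0.0


def seed_cells(lat: Lattice, params, rng: np.random.Generator) -> int:
    """Scatter contractile SMCs over the wall: each wall site independently
    receives a cSMC with probability c_smc_init / c_max. Returns the count."""
    p = params.seed_fraction
    if p > 1 + 1e-12:
        raise ConfigurationError(
            f"c_smc_init={params.c_smc_init:g} exceeds c_max={params.c_max:g}"
        )
    p = min(p, 1.0)
    wall = lat.domain == WALL
    draw = rng.random(lat.dims) < p
    place = wall & draw & (lat.occupant == OCC_NONE)
    lat.occupant[place] = OCC_CSMC
    return int(place.sum())


def lumen_surface_mask(lat: Lattice, stencil: int = 26) -> np.ndarray:
    """Lumen sites with no ECM that are adjacent to a site with ECM > 0 —
    the sites an intact endothelium occupies."""
    structure = np.zeros((3, 3, 3), dtype=bool)
    structure[1, 1, 1] = True
    for dx, dy, dz in OFFSETS[stencil]:
        structure[dx + 1, dy + 1, dz + 1] = True
    has_ecm = lat.ecm > 0
    near_ecm = ndimage.binary_dilation(has_ecm, structure=structure)
    return (lat.domain == LUMEN) & (~has_ecm) & near_ecm


def seed_endothelium(lat: Lattice, stent_z: tuple[float, float],
                     stencil: int = 26) -> int:
    """Cover the lumen surface with ECs outside the stented axial extent
    (total denudation under the stent). Returns the EC count placed."""
    z_lo, z_hi = stent_z
    _, _, z = lat.site_centers()
    z_min, z_max = lat.origin[2], lat.origin[2] + lat.dims[2] * lat.dl
    if z_lo < z_min - lat.dl or z_hi > z_max + lat.dl:
        raise ConfigurationError(
            f"stent extent {stent_z} outside lattice axial range [{z_min}, {z_max}]"
        )
    surf = lumen_surface_mask(lat, stencil)
    outside_stent = (z < z_lo) | (z > z_hi)
    place = surf & outside_stent[None, None, :] & (lat.occupant == OCC_NONE)
    lat.occupant[place] = OCC_EC
    return int(place.sum())
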