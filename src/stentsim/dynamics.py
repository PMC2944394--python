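"""Per-cell behavioural rules (reference implementation).

These functions express the model's rules one cell at a time on a
:class:`~stentsim.lattice.Lattice` and are convenient for unit tests and
micro-scenarios. The production scheduler runs the same rules through the
numba kernels in :mod:`stentsim._kernels`; the two are cross-checked in
the test suite.

Rules, in brief:

* An SMC is *contractile* (quiescent) iff its own site carries intact
  matrix (ECM = 1), no site in its sampling stencil carries partially
  degraded matrix (0 < ECM < 1, the signature of an active injury or
  remodelling zone), and the local SMC concentration is below
  ``c_smc_crit``; otherwise it is *synthetic*. The switch is reversible.
* Synthetic SMCs random-walk through sites that carry or are adjacent to
  matrix, divide while the growth stimulus at their site exceeds
  ``g_crit`` (each division consumes ``g_crit``), and deposit matrix at
  their site at rate ``c_ecm``.
* ECs divide onto matrix-free sites adjacent to matrix — the lumen
  surface — and are impenetrable barriers to SMCs.
* Wherever ECM and MDF coexist, both decay at ``c_deg`` per day.
"""

from __future__ import annotations

import numpy as np

from .lattice import (
    FIELD_TOL,
    Lattice,
    OCC_CSMC,
    OCC_EC,
    OCC_NONE,
    OCC_SSMC,
    OUTSIDE,
    local_cell_concentration,
    neighbors,
)


def _has_ecm_neighbor(lat: Lattice, site, stencil: int) -> bool:
    return any(lat.ecm[s] > 0.0 for s in neighbors(lat, site, stencil))


def valid_migration_destination(lat: Lattice, site, stencil: int = 26) -> bool:
    """A site an sSMC may move to / spawn into: in the tissue domain,
    unoccupied, and carrying or adjacent to ECM."""
    if not lat.in_bounds(site):
        return False
    site = tuple(site)
    if lat.domain[site] == OUTSIDE or lat.occupant[site] != OCC_NONE:
        return False
    return lat.ecm[site] > 0.0 or _has_ecm_neighbor(lat, site, stencil)


def valid_ec_destination(lat: Lattice, site, stencil: int = 26) -> bool:
    """A site an EC daughter may occupy: unoccupied, matrix-free, adjacent
    to matrix (i.e. on the lumen surface)."""
    if not lat.in_bounds(site):
        return False
    site = tuple(site)
    if lat.domain[site] == OUTSIDE or lat.occupant[site] != OCC_NONE:
        return False
    if lat.ecm[site] != 0.0:
        return False
    return _has_ecm_neighbor(lat, site, stencil)


def update_phenotype(lat: Lattice, site, params) -> int:
    """Re-evaluate the phenotype of the SMC at ``site``; returns and
    applies the new occupant code (OCC_CSMC or OCC_SSMC)."""
    site = tuple(site)
    occ = lat.occupant[site]
    if occ not in (OCC_CSMC, OCC_SSMC):
        raise ValueError(f"update_phenotype: no SMC at {site} (occupant={occ})")
    contractile = abs(lat.ecm[site] - 1.0) <= FIELD_TOL
    if contractile:
        for s in neighbors(lat, site, params.stencil):
            if lat.domain[s] == OUTSIDE:
                continue
            e = lat.ecm[s]
            if FIELD_TOL < e < 1.0 - FIELD_TOL:
                contractile = False
                break
    if contractile:
        conc = local_cell_concentration(lat, site, params.stencil)
        if conc >= params.c_smc_crit:
            contractile = False
    new = OCC_CSMC if contractile else OCC_SSMC
    lat.occupant[site] = new
    return new


def attempt_migration(lat: Lattice, site, params,
                      rng: np.random.Generator):
    """One random-walk attempt of the sSMC at ``site``: a single candidate
    neighbour drawn uniformly; returns the new site on success, None on a
    rejected draw."""
    site = tuple(site)
    if lat.occupant[site] != OCC_SSMC:
        raise ValueError(f"attempt_migration: no sSMC at {site}")
    off = _draw_offset(params.stencil, rng)
    cand = (site[0] + off[0], site[1] + off[1], site[2] + off[2])
    if not valid_migration_destination(lat, cand, params.stencil):
        return None
    lat.occupant[site] = OCC_NONE
    lat.occupant[cand] = OCC_SSMC
    return cand


def attempt_proliferation_smc(lat: Lattice, site, params,
                              rng: np.random.Generator):
    """One division attempt of the sSMC at ``site``. Succeeds iff the local
    growth stimulus exceeds ``g_crit`` and the single uniformly drawn
    candidate site is a valid destination; on success the daughter sSMC is
    placed there and G at the parent's site drops by ``g_crit`` (floored
    at 0). Returns the daughter site or None."""
    site = tuple(site)
    if lat.occupant[site] != OCC_SSMC:
        raise ValueError(f"attempt_proliferation_smc: no sSMC at {site}")
    if not lat.g[site] > params.g_crit:
        return None
    off = _draw_offset(params.stencil, rng)
    cand = (site[0] + off[0], site[1] + off[1], site[2] + off[2])
    if not valid_migration_destination(lat, cand, params.stencil):
        return None
    lat.occupant[cand] = OCC_SSMC
    lat.g[site] = max(0.0, lat.g[site] - params.g_crit)
    return cand


def attempt_proliferation_ec(lat: Lattice, site, params,
                             rng: np.random.Generator):
    """One division attempt of the EC at ``site``: single uniform candidate
    draw, accepted iff the candidate is a valid lumen-surface site.
    Returns the daughter site or None."""
    site = tuple(site)
    if lat.occupant[site] != OCC_EC:
        raise ValueError(f"attempt_proliferation_ec: no EC at {site}")
    off = _draw_offset(params.stencil, rng)
    cand = (site[0] + off[0], site[1] + off[1], site[2] + off[2])
    if not valid_ec_destination(lat, cand, params.stencil):
        return None
    lat.occupant[cand] = OCC_EC
    return cand


def produce_ecm(lat: Lattice, site, params) -> None:
    """The sSMC at ``site`` deposits matrix: ECM += c_ecm, clamped to 1."""
    site = tuple(site)
    if lat.occupant[site] != OCC_SSMC:
        raise ValueError(f"produce_ecm: no sSMC at {site}")
    e = lat.ecm[site] + params.c_ecm
    lat.ecm[site] = 1.0 if e > 1.0 - FIELD_TOL else e


def degrade_matrix(lat: Lattice, params) -> int:
    """Daily matrix turnover: wherever ECM and MDF are both present, each
    drops by ``c_deg`` (floored at 0; values below tolerance snap to 0 so
    that exact-zero tests stay meaningful). Returns the site count."""
    m = (lat.ecm > 0.0) & (lat.mdf > 0.0)
    lat.ecm[m] -= params.c_deg
    lat.mdf[m] -= params.c_deg
    np.clip(lat.ecm, 0.0, None, out=lat.ecm)
    np.clip(lat.mdf, 0.0, None, out=lat.mdf)
    lat.ecm[lat.ecm < FIELD_TOL] = 0.0
    lat.mdf[lat.mdf < FIELD_TOL] = 0.0
    return int(m.sum())


def _draw_offset(stencil: int, rng: np.random.Generator):
    from .lattice import OFFSETS

    table = OFFSETS[stencil]
    return table[int(rng.integers(len(table)))]
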