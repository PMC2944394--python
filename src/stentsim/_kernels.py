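"""Numba kernels for the per-day cell dynamics.

These are the hot loops: one asynchronous pass over every active cell per
simulated day, with stochastic rounding of the per-day attempt counts.
The pure-Python single-cell rules in :mod:`stentsim.dynamics` express the
same behaviour and are cross-checked against these kernels in the tests.

Randomness inside kernels uses numba's internal RNG, seeded once per call
with a value drawn from the simulation's master stream, so runs are
bit-reproducible for a fixed master seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# codes mirrored from stentsim.lattice (numba-friendly plain ints)
OUTSIDE, LUMEN, WALL = 0, 1, 2
OCC_NONE, OCC_CSMC, OCC_SSMC, OCC_EC = 0, 1, 2, 3

TOL = 1e-9


@njit(cache=True)
def stoch_round(mean):
    """Integer attempts with exact expectation: floor + Bernoulli(frac)."""
    base = int(np.floor(mean))
    frac = mean - base
    if frac > 0.0 and np.random.random() < frac:
        base += 1
    return base


@njit(cache=True)
def _has_ecm_neighbor(ecm, a, b, c, offsets):
    nx, ny, nz = ecm.shape
    for o in range(offsets.shape[0]):
        x = a + offsets[o, 0]
        y = b + offsets[o, 1]
        z = c + offsets[o, 2]
        if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
            if ecm[x, y, z] > 0.0:
                return True
    return False


@njit(cache=True)
def _valid_smc_dest(domain, ecm, occupant, a, b, c, offsets):
    """Migration/daughter destination: in-grid, not outside the tissue
    domain, unoccupied (an EC is an impenetrable barrier), and carrying or
    adjacent to matrix."""
    nx, ny, nz = domain.shape
    if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz):
        return False
    if domain[a, b, c] == OUTSIDE:
        return False
    if occupant[a, b, c] != OCC_NONE:
        return False
    if ecm[a, b, c] > 0.0:
        return True
    return _has_ecm_neighbor(ecm, a, b, c, offsets)


@njit(cache=True)
def _valid_ec_dest(domain, ecm, occupant, a, b, c, offsets):
    """EC daughter site: in-grid, inside the tissue domain, unoccupied,
    matrix-free, and adjacent to matrix (the lumen surface)."""
    nx, ny, nz = domain.shape
    if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz):
        return False
    if domain[a, b, c] == OUTSIDE:
        return False
    if occupant[a, b, c] != OCC_NONE:
        return False
    if ecm[a, b, c] != 0.0:
        return False
    return _has_ecm_neighbor(ecm, a, b, c, offsets)


@njit(cache=True)
def phenotype_update(domain, ecm, occupant, ci, cj, ck, kind, n_cells,
                     offsets, c_smc_crit):
    """Re-evaluate every SMC's phenotype.

    Contractile iff the cell's own site carries intact matrix (ECM = 1
    within tolerance), no site in the sampling stencil carries partially
    degraded matrix (0 < ECM < 1 marks an active injury/remodelling zone),
    and the local SMC concentration is below c_smc_crit. Synthetic
    otherwise. The switch is applied both ways.
    """
    nx, ny, nz = domain.shape
    for t in range(n_cells):
        kd = kind[t]
        if kd != OCC_CSMC and kd != OCC_SSMC:
            continue
        a, b, c = ci[t], cj[t], ck[t]
        own = ecm[a, b, c]
        contractile = abs(own - 1.0) <= TOL
        n_dom = 1
        n_smc = 1
        for o in range(offsets.shape[0]):
            x = a + offsets[o, 0]
            y = b + offsets[o, 1]
            z = c + offsets[o, 2]
            if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
                if domain[x, y, z] != OUTSIDE:
                    n_dom += 1
                    occ = occupant[x, y, z]
                    if occ == OCC_CSMC or occ == OCC_SSMC:
                        n_smc += 1
                    e = ecm[x, y, z]
                    if e > TOL and e < 1.0 - TOL:
                        contractile = False
        if n_smc >= c_smc_crit * n_dom:
            contractile = False
        new_kd = OCC_CSMC if contractile else OCC_SSMC
        kind[t] = new_kd
        occupant[a, b, c] = new_kd


@njit(cache=True)
def _ec_attempt(domain, ecm, occupant, ci, cj, ck, kind, n, a, b, c,
                offsets, ec_choose_valid, cand):
    """One EC division attempt from site (a,b,c). Returns the new cell
    count (n or n+1)."""
    n_off = offsets.shape[0]
    if ec_choose_valid:
        # enumerate valid surface sites, pick uniformly among them
        m = 0
        for o in range(n_off):
            x = a + offsets[o, 0]
            y = b + offsets[o, 1]
            z = c + offsets[o, 2]
            if _valid_ec_dest(domain, ecm, occupant, x, y, z, offsets):
                cand[m, 0] = x
                cand[m, 1] = y
                cand[m, 2] = z
                m += 1
        if m == 0:
            return n
        u = np.random.randint(0, m)
        x, y, z = cand[u, 0], cand[u, 1], cand[u, 2]
    else:
        # single uniform draw with rejection
        o = np.random.randint(0, n_off)
        x = a + offsets[o, 0]
        y = b + offsets[o, 1]
        z = c + offsets[o, 2]
        if not _valid_ec_dest(domain, ecm, occupant, x, y, z, offsets):
            return n
    occupant[x, y, z] = OCC_EC
    ci[n], cj[n], ck[n] = x, y, z
    kind[n] = OCC_EC
    return n + 1


@njit(cache=True)
def day_turns(domain, ecm, g, occupant, ci, cj, ck, kind, n_cells,
              ec_rem, ec_born, offsets, mig_mean, p_smc, p_ec, g_crit,
              ec_choose_valid, ec_mode, seed):
    """One day of cell activity.

    Pass A runs over all cells present at day start in freshly shuffled
    order: each sSMC takes its migration attempts then its division
    attempts (daughter sSMCs act from the next day); each cSMC is
    quiescent; each EC draws its per-day attempt budget and takes either
    all of it (``ec_mode`` 0/1) or its first attempt (``ec_mode`` 2).

    EC daughter scheduling, ``ec_mode``:
      0  next_day — daughters first act tomorrow;
      1  same_day — daughters take their full budget at the end of the
         current sweep (unbounded within-day chains);
      2  rounds   — the day consists of max-budget rounds, one attempt per
         EC per round, daughters first acting in the round after their
         birth (within-day chain depth limited to the round count).

    Returns (new n_cells, SMC divisions, EC divisions, migration steps).
    """
    np.random.seed(seed)
    n_off = offsets.shape[0]
    n0 = n_cells
    order = np.arange(n0)
    for t in range(n0 - 1, 0, -1):  # Fisher-Yates
        u = np.random.randint(0, t + 1)
        tmp = order[t]
        order[t] = order[u]
        order[u] = tmp

    n = n_cells
    n_div_smc = 0
    n_div_ec = 0
    n_steps = 0
    cand = np.empty((n_off, 3), dtype=np.int64)
    max_budget = 0

    for t in range(n0):
        idx = order[t]
        kd = kind[idx]
        if kd == OCC_SSMC:
            a, b, c = ci[idx], cj[idx], ck[idx]
            n_mig = stoch_round(mig_mean)
            for _ in range(n_mig):
                o = np.random.randint(0, n_off)
                x = a + offsets[o, 0]
                y = b + offsets[o, 1]
                z = c + offsets[o, 2]
                if _valid_smc_dest(domain, ecm, occupant, x, y, z, offsets):
                    occupant[a, b, c] = OCC_NONE
                    occupant[x, y, z] = OCC_SSMC
                    a, b, c = x, y, z
                    n_steps += 1
            ci[idx], cj[idx], ck[idx] = a, b, c
            n_pro = stoch_round(p_smc)
            for _ in range(n_pro):
                if g[a, b, c] > g_crit:
                    o = np.random.randint(0, n_off)
                    x = a + offsets[o, 0]
                    y = b + offsets[o, 1]
                    z = c + offsets[o, 2]
                    if _valid_smc_dest(domain, ecm, occupant, x, y, z, offsets):
                        occupant[x, y, z] = OCC_SSMC
                        ci[n], cj[n], ck[n] = x, y, z
                        kind[n] = OCC_SSMC
                        ec_rem[n] = 0
                        ec_born[n] = 0
                        n += 1
                        gv = g[a, b, c] - g_crit
                        g[a, b, c] = gv if gv > 0.0 else 0.0
                        n_div_smc += 1
        elif kd == OCC_EC:
            a, b, c = ci[idx], cj[idx], ck[idx]
            budget = stoch_round(p_ec)
            if ec_mode == 2:
                if budget > max_budget:
                    max_budget = budget
                ec_rem[idx] = budget
                ec_born[idx] = -1
                if budget >= 1:
                    n_new = _ec_attempt(domain, ecm, occupant, ci, cj, ck,
                                        kind, n, a, b, c, offsets,
                                        ec_choose_valid, cand)
                    ec_rem[idx] = budget - 1
                    if n_new > n:
                        ec_rem[n] = stoch_round(p_ec)
                        ec_born[n] = 0
                        n = n_new
                        n_div_ec += 1
            else:
                for _ in range(budget):
                    n_new = _ec_attempt(domain, ecm, occupant, ci, cj, ck,
                                        kind, n, a, b, c, offsets,
                                        ec_choose_valid, cand)
                    if n_new > n:
                        ec_rem[n] = 0
                        ec_born[n] = 0
                        n = n_new
                        n_div_ec += 1

    if ec_mode == 1:
        # same_day: appended EC daughters take their full budget, chaining
        d = n0
        while d < n:
            if kind[d] == OCC_EC:
                budget = stoch_round(p_ec)
                for _ in range(budget):
                    a, b, c = ci[d], cj[d], ck[d]
                    n_new = _ec_attempt(domain, ecm, occupant, ci, cj, ck,
                                        kind, n, a, b, c, offsets,
                                        ec_choose_valid, cand)
                    if n_new > n:
                        n = n_new
                        n_div_ec += 1
            d += 1
    elif ec_mode == 2:
        for r in range(1, max_budget):
            # reshuffle the cells present at round start
            n_round = n
            sub = np.arange(n_round)
            for t in range(n_round - 1, 0, -1):
                u = np.random.randint(0, t + 1)
                tmp = sub[t]
                sub[t] = sub[u]
                sub[u] = tmp
            for t in range(n_round):
                idx = sub[t]
                if kind[idx] != OCC_EC:
                    continue
                if ec_rem[idx] <= 0 or ec_born[idx] >= r:
                    continue
                a, b, c = ci[idx], cj[idx], ck[idx]
                n_new = _ec_attempt(domain, ecm, occupant, ci, cj, ck,
                                    kind, n, a, b, c, offsets,
                                    ec_choose_valid, cand)
                ec_rem[idx] -= 1
                if n_new > n:
                    ec_rem[n] = stoch_round(p_ec)
                    ec_born[n] = r
                    n = n_new
                    n_div_ec += 1
    return n, n_div_smc, n_div_ec, n_steps


@njit(cache=True)
def any_active_ssmc(domain, ecm, g, occupant, ci, cj, ck, kind, n_cells,
                    offsets, g_crit):
    """True if some sSMC can still act: growth stimulus above threshold at
    its site, or any valid migration/daughter destination."""
    for t in range(n_cells):
        if kind[t] != OCC_SSMC:
            continue
        a, b, c = ci[t], cj[t], ck[t]
        if g[a, b, c] > g_crit:
            return True
        for o in range(offsets.shape[0]):
            x = a + offsets[o, 0]
            y = b + offsets[o, 1]
            z = c + offsets[o, 2]
            if _valid_smc_dest(domain, ecm, occupant, x, y, z, offsets):
                return True
    return False
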