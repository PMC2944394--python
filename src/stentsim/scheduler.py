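"""Daily time stepping and run orchestration.

The model advances in one-day increments. Continuous rates are converted
to integer per-day attempt counts by stochastic rounding (floor plus a
Bernoulli draw on the fractional part), so the expectation is exact:
migration at ``v_smc`` mm/day yields on average ``v_smc/dl`` lattice steps
per day, proliferation at rate p yields p attempts per day.

Within each day the order is fixed: (1) matrix degradation, (2) phenotype
re-evaluation of every SMC, (3) one pass over all active cells in freshly
shuffled order — each sSMC takes its migration then its division
attempts, each EC its p_EC division attempts, cSMCs are quiescent —
(4) every sSMC deposits matrix once, (5) metrics. Daughters act from the
next day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .dynamics import degrade_matrix
from .injury import StentSpec, apply_injury, generate_synthetic_stent_stress
from .lattice import (
    FIELD_TOL,
    Lattice,
    LUMEN,
    OCC_CSMC,
    OCC_EC,
    OCC_NONE,
    OCC_SSMC,
    OFFSETS,
    build_artery_lattice,
    lumen_surface_mask,
    seed_cells,
    seed_endothelium,
)
from .metrics import (
    MetricsRecord,
    cumulative_population_doubling,
    neointimal_areas,
    lesion_volume,
    series_to_frame,
    slice_ecm_counts,
    write_metrics_csv,
)
from .params import ConfigurationError, Params
from .stressmesh import StressMesh, map_stress_to_lattice

RUNNING = "running"
HEALED_EQUILIBRIUM = "healed_equilibrium"
OCCLUDED = "occluded"
TIME_LIMIT = "time_limit"


def rate_to_attempts(rate: float, unit: str, rng: np.random.Generator,
                     dl: float | None = None) -> int:
    """Per-day attempt count for a continuous rate, by stochastic rounding.

    ``unit='per_day'`` uses the rate directly (proliferation);
    ``unit='speed'`` converts a speed in mm/day to steps of length ``dl``
    (migration). The expectation equals the continuous rate exactly.
    """
    if rate < 0:
        raise ConfigurationError(f"rate must be >= 0, got {rate}")
    if unit == "per_day":
        mean = rate
    elif unit == "speed":
        if dl is None or dl <= 0:
            raise ConfigurationError("unit='speed' needs a positive dl")
        mean = rate / dl
    else:
        raise ConfigurationError(f"unknown rate unit {unit!r}")
    base = math.floor(mean)
    frac = mean - base
    if frac > 0 and rng.random() < frac:
        base += 1
    return int(base)


@dataclass
class SimulationState:
    lattice: Lattice
    params: Params
    rng: np.random.Generator
    day: int = 0
    # parallel cell arrays; valid entries are [:n_cells]
    ci: np.ndarray = dc_field(default_factory=lambda: np.empty(0, np.int64))
    cj: np.ndarray = dc_field(default_factory=lambda: np.empty(0, np.int64))
    ck: np.ndarray = dc_field(default_factory=lambda: np.empty(0, np.int64))
    kind: np.ndarray = dc_field(default_factory=lambda: np.empty(0, np.uint8))
    n_cells: int = 0
    baseline_slice_counts: np.ndarray | None = None
    counters: dict = dc_field(default_factory=dict)
    _surface_cache: np.ndarray | None = None
    _ec_sites_cache: np.ndarray | None = None
    _ecm_dirty: bool = True
    _ec_rem: np.ndarray = dc_field(default_factory=lambda: np.zeros(0, np.int64))
    _ec_born: np.ndarray = dc_field(default_factory=lambda: np.zeros(0, np.int64))

    # -- cell bookkeeping ---------------------------------------------------

    def collect_cells(self) -> None:
        """Rebuild the cell arrays from the lattice occupancy (C order,
        hence deterministic)."""
        sites = np.argwhere(self.lattice.occupant != OCC_NONE)
        self.n_cells = len(sites)
        cap = max(16, 2 * self.n_cells)
        self.ci = np.empty(cap, np.int64)
        self.cj = np.empty(cap, np.int64)
        self.ck = np.empty(cap, np.int64)
        self.kind = np.empty(cap, np.uint8)
        self._ec_rem = np.zeros(cap, np.int64)
        self._ec_born = np.zeros(cap, np.int64)
        if self.n_cells:
            self.ci[: self.n_cells] = sites[:, 0]
            self.cj[: self.n_cells] = sites[:, 1]
            self.ck[: self.n_cells] = sites[:, 2]
            self.kind[: self.n_cells] = self.lattice.occupant[
                sites[:, 0], sites[:, 1], sites[:, 2]
            ]

    def _ensure_capacity(self, needed: int) -> None:
        if needed <= len(self.ci):
            return
        cap = max(needed, 2 * len(self.ci), 16)
        for name in ("ci", "cj", "ck", "kind", "_ec_rem", "_ec_born"):
            arr = getattr(self, name)
            new = np.zeros(cap, arr.dtype)
            new[: self.n_cells] = arr[: self.n_cells]
            setattr(self, name, new)

    def counts(self) -> tuple[int, int, int]:
        kd = self.kind[: self.n_cells]
        return (
            int((kd == OCC_CSMC).sum()),
            int((kd == OCC_SSMC).sum()),
            int((kd == OCC_EC).sum()),
        )

    def check_consistency(self) -> None:
        """The cell list and the lattice occupancy must agree exactly."""
        occ_sites = np.argwhere(self.lattice.occupant != OCC_NONE)
        if len(occ_sites) != self.n_cells:
            raise RuntimeError(
                f"inconsistent state: {len(occ_sites)} occupied sites vs "
                f"{self.n_cells} cells"
            )
        a = {tuple(s) for s in occ_sites}
        b = {
            (int(self.ci[t]), int(self.cj[t]), int(self.ck[t]))
            for t in range(self.n_cells)
        }
        if a != b:
            raise RuntimeError("inconsistent state: cell list != occupancy")
        for t in range(self.n_cells):
            s = (self.ci[t], self.cj[t], self.ck[t])
            if self.lattice.occupant[s] != self.kind[t]:
                raise RuntimeError(f"inconsistent state: kind mismatch at {s}")

    # -- cached lumen surface ----------------------------------------------

    def surface_mask(self) -> np.ndarray:
        if self._ecm_dirty or self._surface_cache is None:
            self._surface_cache = lumen_surface_mask(
                self.lattice, self.params.stencil
            )
            self._ec_sites_cache = self._ec_reachable_sites()
            self._ecm_dirty = False
        return self._surface_cache

    def _ec_reachable_sites(self) -> np.ndarray:
        """All matrix-free, non-outside sites adjacent to matrix — every
        site an EC daughter could ever occupy (a superset of the lumen
        surface: degraded wall sites qualify too)."""
        from scipy import ndimage

        structure = np.zeros((3, 3, 3), dtype=bool)
        structure[1, 1, 1] = True
        for dx, dy, dz in OFFSETS[self.params.stencil]:
            structure[dx + 1, dy + 1, dz + 1] = True
        lat = self.lattice
        has_ecm = lat.ecm > 0.0
        near = ndimage.binary_dilation(has_ecm, structure=structure)
        return (lat.domain != 0) & (~has_ecm) & near

    def ec_fill_bound(self) -> int:
        """Upper bound on EC daughters placeable today."""
        self.surface_mask()  # refresh caches if dirty
        free = self._ec_sites_cache & (self.lattice.occupant == OCC_NONE)
        return int(free.sum())


def initialize(params: Params, stent_spec: StentSpec | None = None,
               mesh: StressMesh | None = None, seed: int | None = None,
               with_smcs: bool = True, with_ecs: bool = True) -> SimulationState:
    """Build the initial condition: voxelized artery, stress field, random
    cSMC seeding, stress-threshold injury, endothelium outside the stent."""
    rng = np.random.default_rng(params.rng_seed if seed is None else seed)
    lat = build_artery_lattice(params.geometry, params.dl)
    if mesh is not None:
        map_stress_to_lattice(mesh, lat)
    elif stent_spec is not None:
        generate_synthetic_stent_stress(stent_spec, lat, params.geometry, rng)
    if with_smcs:
        seed_cells(lat, params, rng)
    apply_injury(lat, params)
    if with_ecs:
        seed_endothelium(lat, params.geometry.stent_z, params.stencil)
    state = SimulationState(lattice=lat, params=params, rng=rng)
    state.collect_cells()
    state.baseline_slice_counts = slice_ecm_counts(lat)
    return state


def step_day(state: SimulationState) -> MetricsRecord:
    """Advance the state by one day and return the day's metrics."""
    p = state.params
    lat = state.lattice
    if state.day >= p.days_max:
        raise RuntimeError(f"day {state.day} already at days_max={p.days_max}")
    prev_smc = state.counts()[0] + state.counts()[1]

    # (1) matrix turnover wherever ECM and MDF coexist
    degraded = degrade_matrix(lat, p)
    if degraded:
        state._ecm_dirty = True

    off = OFFSETS[p.stencil]
    # (2) phenotype re-evaluation of every SMC
    _kernels.phenotype_update(
        lat.domain, lat.ecm, lat.occupant,
        state.ci, state.cj, state.ck, state.kind, state.n_cells,
        off, p.c_smc_crit,
    )

    # (3) shuffled asynchronous pass over all active cells
    kd = state.kind[: state.n_cells]
    n_ssmc = int((kd == OCC_SSMC).sum())
    n_ec = int((kd == OCC_EC).sum())
    worst_new = n_ssmc * (int(p.p_smc) + 1)
    if n_ec:
        if p.ec_scheduling == "next_day":
            worst_new += n_ec * (int(p.p_ec) + 1)
        else:
            # within-day chains: capped by the reachable matrix-free surface
            worst_new += state.ec_fill_bound()
    state._ensure_capacity(state.n_cells + worst_new)
    ec_mode = {"next_day": 0, "same_day": 1, "rounds": 2}[p.ec_scheduling]
    day_seed = int(state.rng.integers(2 ** 31))
    n, div_smc, div_ec, steps = _kernels.day_turns(
        lat.domain, lat.ecm, lat.g, lat.occupant,
        state.ci, state.cj, state.ck, state.kind, state.n_cells,
        state._ec_rem, state._ec_born,
        off, p.migration_attempts_per_day, p.p_smc, p.p_ec, p.g_crit,
        p.ec_placement == "valid", ec_mode, day_seed,
    )
    state.n_cells = int(n)

    # (4) matrix deposition by every sSMC
    kd = state.kind[: state.n_cells]
    ss = np.nonzero(kd == OCC_SSMC)[0]
    if len(ss):
        i = state.ci[: state.n_cells][ss]
        j = state.cj[: state.n_cells][ss]
        k = state.ck[: state.n_cells][ss]
        e = lat.ecm[i, j, k] + p.c_ecm
        e[e > 1.0 - FIELD_TOL] = 1.0
        lat.ecm[i, j, k] = e
        state._ecm_dirty = True

    state.day += 1
    state.counters["divisions_smc"] = state.counters.get("divisions_smc", 0) + div_smc
    state.counters["divisions_ec"] = state.counters.get("divisions_ec", 0) + div_ec
    state.counters["migration_steps"] = (
        state.counters.get("migration_steps", 0) + steps
    )
    state.counters["last_divisions_smc"] = div_smc
    state.counters["last_divisions_ec"] = div_ec
    state.counters["last_migration_steps"] = steps

    # (5) metrics
    return record_metrics(state, prev_smc)


def record_metrics(state: SimulationState, prev_smc: int | None = None) -> MetricsRecord:
    lat = state.lattice
    n_csmc, n_ssmc, n_ec = state.counts()
    areas = neointimal_areas(lat, state.baseline_slice_counts)
    smc = n_csmc + n_ssmc
    doubling = (
        float("nan") if prev_smc is None
        else cumulative_population_doubling(smc, prev_smc)
    )
    return MetricsRecord(
        day=state.day,
        area_by_slice=areas,
        lesion_volume=lesion_volume(areas, lat.dl),
        n_csmc=n_csmc,
        n_ssmc=n_ssmc,
        n_ec=n_ec,
        doubling=doubling,
    )


# ---------------------------------------------------------------------------
# Termination
# ---------------------------------------------------------------------------

def endothelium_covered(state: SimulationState) -> bool:
    """True when every current lumen-surface site holds an EC."""
    surf = state.surface_mask()
    uncovered = surf & (state.lattice.occupant != OCC_EC)
    return not bool(uncovered.any())


def lumen_occluded(state: SimulationState) -> bool:
    """True when some cross-sectional slice inside the stent has no open
    lumen site (matrix-free and unoccupied) left."""
    lat = state.lattice
    z_lo, z_hi = state.params.geometry.stent_z
    _, _, z = lat.site_centers()
    ks = np.nonzero((z >= z_lo) & (z <= z_hi))[0]
    if len(ks) == 0:
        return False
    open_site = (
        (lat.domain[:, :, ks] == LUMEN)
        & (lat.ecm[:, :, ks] == 0.0)
        & (lat.occupant[:, :, ks] == OCC_NONE)
    )
    return not bool(open_site.any(axis=(0, 1)).all())


def ssmc_active(state: SimulationState) -> bool:
    """True if some sSMC can still divide (G above threshold at its site)
    or has a valid migration destination."""
    return bool(
        _kernels.any_active_ssmc(
            state.lattice.domain, state.lattice.ecm, state.lattice.g,
            state.lattice.occupant,
            state.ci, state.cj, state.ck, state.kind, state.n_cells,
            OFFSETS[state.params.stencil], state.params.g_crit,
        )
    )


def check_termination(state: SimulationState) -> str:
    if endothelium_covered(state) and not ssmc_active(state):
        return HEALED_EQUILIBRIUM
    if lumen_occluded(state):
        return OCCLUDED
    if state.day >= state.params.days_max:
        return TIME_LIMIT
    return RUNNING


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    metrics: pd.DataFrame
    termination: str
    state: SimulationState


def run_simulation(params: Params, stent_spec: StentSpec | None = None,
                   mesh: StressMesh | None = None, seed: int | None = None,
                   out_dir=None, snapshot_every: int = 0,
                   progress: bool = False) -> SimulationResult:
    """Run from the initial condition until healed equilibrium, occlusion
    or the day limit; fully reproducible for a fixed seed.

    If ``out_dir`` is given, writes ``metrics.csv`` and (if
    ``snapshot_every`` > 0) VTK snapshots ``snapshot_d{day}.vtk``.
    """
    from .vtkio import write_snapshot_vtk  # local import: optional output path

    state = initialize(params, stent_spec=stent_spec, mesh=mesh, seed=seed)
    records = [record_metrics(state)]
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        if snapshot_every > 0:
            write_snapshot_vtk(state.lattice, out / "snapshot_d0.vtk")
    while True:
        status = check_termination(state)
        if status != RUNNING:
            break
        rec = step_day(state)
        records.append(rec)
        if out is not None and snapshot_every > 0 and state.day % snapshot_every == 0:
            write_snapshot_vtk(state.lattice, out / f"snapshot_d{state.day}.vtk")
        if progress:
            print(
                f"day {state.day:4d}  cSMC {rec.n_csmc:7d}  sSMC {rec.n_ssmc:6d}  "
                f"EC {rec.n_ec:7d}  lesion {rec.lesion_volume:.4f} mm^3"
            )
    frame = series_to_frame(records)
    if out is not None:
        write_metrics_csv(frame, out / "metrics.csv")
    return SimulationResult(metrics=frame, termination=status, state=state)
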