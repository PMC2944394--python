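# Model and methods

`stentsim` simulates neointima formation (in-stent restenosis) in an
idealised stented coronary artery with a cell-centred, lattice-based
cellular automaton. This note records the model, its assumptions, the
numerical conventions, and the design choices made where the rule set is
genuinely open.

## The model

The artery is a hollow cylinder (baseline: 14 mm long, inner/outer
diameters 2.5/3.75 mm) voxelized on a regular orthogonal lattice with
spacing `dl` = 0.01825 mm. One lattice site holds at most one cell, so the
spacing encodes the maximum packing density `c_max = dl^-3 ≈ 1.64e5`
cells/mm³. Each site carries three scalar fields — extracellular matrix
ECM ∈ [0, 1] (1 = intact tissue), matrix-degrading factors MDF ≥ 0, and a
growth stimulus G ≥ 0 — plus the minimum principal stress mapped from a
stent-expansion stress field (kPa, compression negative).

**Injury.** Sites whose compressive stress magnitude strictly exceeds
`sigma_crit` = 35 kPa lose their cell and receive the acute post-injury
initial conditions MDF = 1 and G = 3. The matrix itself is *not* removed
instantaneously: wherever ECM and MDF coexist, both decay at
`c_deg` = 0.05/day, so fully damaged tissue resorbs in exactly 20 daily
increments. The MDF/G initial conditions stand in for the inflammatory
response (platelets, macrophages) rather than modelling those cells
explicitly.

**Smooth muscle cells.** SMCs have two phenotypes. A cell is *contractile*
(quiescent) iff

1. its own site carries intact matrix (ECM = 1 within 1e-9),
2. no site in its sampling stencil carries *partially degraded* matrix
   (0 < ECM < 1), and
3. the local SMC concentration over the site-plus-stencil block is below
   `c_smc_crit`;

otherwise it is *synthetic*, and the switch is reversible. Condition 2 is
the recruitment mechanism: partially degraded matrix marks an active
injury/remodelling zone and modulates the neighbouring contractile cells.
Matrix-free sites (ECM = 0, e.g. the lumen) do not trigger condition 2 —
absence of matrix is not degraded matrix — which is what keeps the
uninjured artery wall, including its lumen-facing cell layer, a fixed
point of the dynamics. An own-site-only reading of condition 1+2 would
leave the model inert: injury removes the cells at the very sites whose
matrix degrades, so no surviving cell would ever observe ECM < 1.

Synthetic SMCs, per day: take `v_smc/dl ≈ 13.15` random-walk attempts
(steps of one site at 0.24 mm/day), `p_smc` = 0.24 division attempts, and
deposit matrix once (`c_ecm` = 0.20/day, clamped at 1) at their end-of-day
position. A migration/daughter destination must be inside the tissue
domain, unoccupied (an EC is an impenetrable barrier), and carry or be
adjacent to matrix. A division succeeds only while the growth stimulus at
the parent's site strictly exceeds `g_crit`; each success consumes
`g_crit`, so G is a strictly decreasing budget and total divisions are
bounded by the injury's initial stimulus.

**Endothelium.** ECs initially cover the lumen surface outside the
stented axial extent (total denudation under the stent). Each EC makes
`p_ec` division attempts per day; a daughter may only occupy a matrix-free
site adjacent to matrix — the healing front crawls along the lumen
surface. A healed endothelium arrests lesion growth purely as a physical
barrier.

**Scheduling.** Time advances in one-day increments:
(1) matrix degradation; (2) phenotype re-evaluation of every SMC;
(3) a pass over all cells in freshly shuffled order (asynchronous update,
reshuffled daily to avoid sweep artifacts) in which each sSMC takes its
migration then its division attempts and each EC its division attempts;
(4) matrix deposition by every sSMC; (5) metrics. Fractional per-day
attempt counts use stochastic rounding (floor plus a Bernoulli draw on the
fraction), making the expectation exact. A run terminates at healed
equilibrium (every lumen-surface site EC-covered and no sSMC able to act),
at lumen occlusion (some stented cross-section has no open lumen site), or
at the day limit (default 320 days).

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `dl` | lattice spacing | 0.01825 | mm |
| `sigma_crit` | injury threshold (compressive) | 35 | kPa |
| `c_smc_init` | initial SMC concentration | 3.16e4 | cells/mm³ |
| `v_smc` | sSMC migration speed | 0.24 | mm/day |
| `p_smc` | sSMC division rate | 0.24 | 1/day |
| `p_ec` | EC division attempts | 2 | 1/cell/day |
| `mdf_init` | MDF at injured sites | 1 | — |
| `c_deg` | ECM/MDF degradation rate | 0.05 | 1/day |
| `c_ecm` | ECM production rate | 0.20 | 1/day |
| `g_init` | growth stimulus at injured sites | 3 | — |
| `g_crit` | stimulus consumed per division | 1 | — |
| `c_smc_crit` | crowding threshold (contractile test) | 0.5 | fraction |

`g_crit` and `c_smc_crit` are structural parameters of the rule set with
no measured value; the defaults are chosen so that one injured site funds
a small burst of local divisions (G budget 3 at `g_crit` = 1) and a
half-crowded, fully restored neighbourhood re-quiesces (`c_smc_crit` =
0.5). Both are exposed in the configuration. Seeding is parameterised by
the occupancy fraction `c_smc_init / c_max` (baseline 0.192), which is
held fixed when the lattice is coarsened — at `dl` = 0.0365 mm the
baseline volumetric concentration would exceed one cell per site.

## Neighbourhood and EC-front calibration

The lattice neighbourhood (migration draws, adjacency tests, the local
concentration stencil) is configurable: 6 (face), 18 (face+edge) or 26
(Moore) connected; the default is 26. Within-day scheduling of EC
daughters is also configurable (`ec_scheduling`): `same_day` (daughters
are appended to the current sweep and take their own turn — the default,
and what a list-iteration implementation does naturally), `next_day`, or
`rounds` (one attempt per sweep, daughters starting the following sweep).
EC daughter siting (`ec_placement`) is a single uniform draw over the
neighbourhood with rejection (default), or a uniform choice among the
currently valid surface sites.

These options exist because the endothelial front speed — the model's one
quantitative calibration anchor, full re-endothelialization of an 8 mm
denuded segment in ≈ 180 days at `p_ec` = 2 — depends on them strongly,
and in a structurally interesting way. With next-day daughter activation
the front can advance at most one lattice slice per day per front (every
daughter is adjacent to a previous-day EC), which bounds healing of
8 mm/dl = 438 slices from two margins below by 219 days. With same-day
chaining the within-day chain of daughter-of-daughter placements behaves
like a branching process; its offspring ratio crosses 1 between the
available configurations, so measured front speeds jump from ≤ 1.0 to
≈ 1.6–2.2 slices/day with nothing attainable in between. The 180-day
point (1.22 slices/day) falls in that critical gap: the shipped default
(same-day, rejection, Moore) heals the 8 mm segment in ≈ 134 days (median
of 3 seeds), the nearest faithful configuration to the published
calibration. `scripts/acceptance.py` reports this measured value; the
corresponding assertion in the test suite states the 180 ± 15% window and
fails honestly by ≈ 25%.

## Stress input

Either a hexahedral stress mesh (neutral text format or ASCII VTK legacy
unstructured grid with a `min_principal_stress` cell scalar) mapped onto
the lattice — axis-aligned bounding-box pre-filter, then a six-face
half-space test treating each quadrilateral face as its best-fit plane
(warped faces are approximate; sites in a thin boundary shell may fall to
either neighbouring element, and multi-element claims resolve
last-writer-wins in file order) — or the built-in parametric generator,
which emulates the injury pattern of a four-crowned corrugated-ring
stent: compressive stress in sinusoidal strut bands, decaying
exponentially into the wall, with the end rings carrying the full peak
magnitude and interior crown junctions 80% of the end amplification (so
the global maximum sits on the end rings). The generator is deterministic
given its specification; optional multiplicative jitter uses the run's
seeded generator. These readers/writers are implemented in-package as
plain-text ASCII formats.

## Metrics

Per day: neointimal area per axial slice ((count of ECM-containing sites
minus the day-0 count, floored at 0) × dl²), lesion volume (slice areas
summed × dl, i.e. a Riemann sum with slice thickness dl to give mm³),
cell counts per type, and the population-doubling rate
log₂(N/N₀) of consecutive daily SMC counts (NaN when N₀ = 0 rather than
an exception). Areas are floored at zero per slice because the metric
measures in-growth; degradation-only transients would otherwise count
negative. "Containing ECM" means ECM > 0 throughout.

## Numerical conventions

- Field values below 1e-9 snap to exact 0 after degradation, and values
  within 1e-9 of 1 clamp to exact 1 after production, so the exact-zero
  and exact-one tests in the rules are robust to float dust (e.g. twenty
  0.05 subtractions from 1.0).
- Injury uses a strict inequality (stress < −`sigma_crit`); boundary
  equality is uninjured. Division likewise requires G strictly above
  `g_crit`.
- Voxel classification is by site-centre radius: wall iff
  r_inner ≤ r < r_outer.
- A single seeded generator drives everything; per-day kernel seeds are
  drawn from it, so runs are bit-reproducible for a fixed seed and any
  two runs with the same configuration produce byte-identical metrics
  files. The hot per-day loops are numba kernels; the per-cell rules also
  exist as pure-Python reference functions, cross-checked against the
  kernels in the tests.

## What the synthetic stress field does and does not emulate

The generator reproduces the qualitative post-expansion pattern — injury
concentrated under struts, maximal at stent ends and crown junctions,
decaying through the wall — but not the magnitudes or spatial statistics
of a finite-element expansion of a specific stent in a specific (possibly
stenosed, heterogeneous) artery. Runs driven by it therefore support
qualitative conclusions (lesion growth dynamics, the effect of the
endothelial healing rate, lesion distribution along the stent) and not
patient- or device-specific predictions. The same applies to the
idealised cylinder geometry and to the endothelium-as-rigid-barrier
assumption: sub-endothelial growth and EC displacement are outside the
rule set.

## Problem sizes used in the shipped checks

The full-geometry baseline (14 mm artery at dl = 0.01825, ≈ 33 M sites,
320 days) is runnable but slow; the package's own test battery uses a
reduced configuration — 3.5 mm artery at dl = 0.0365 with a four-crown
synthetic field for 160 days — for the lesion-phenomenology checks, and
the full-resolution 8 mm denuded-segment problem (≈ 10 M sites) for the
endothelial calibration. The re-endothelialization run uses a thin-walled
cylinder (wall 4·dl): front propagation happens on the lumen surface, so
wall thickness does not enter, and the thin wall keeps memory modest.
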