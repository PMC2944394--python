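# stentsim

Cell-centred, lattice-based simulation of **neointima formation in a
stented artery** (in-stent restenosis), for researchers in computational
mechanobiology and vascular device design who want a rule-based,
cell-level alternative to continuum growth models.

Coronary stenting injures the vessel wall: tissue compressed beyond a
viability threshold dies, matrix-degrading factors resorb the damaged
extracellular matrix, and the surrounding smooth muscle cells (SMCs)
switch from the quiescent *contractile* phenotype to a *synthetic* one —
migrating into the injured zone, proliferating on the local growth
stimulus, and depositing new matrix that narrows the lumen. Meanwhile the
endothelium, denuded under the stent, regrows from the stent margins;
once it seals the surface, lesion growth stops. `stentsim` implements
this as a 3D cellular automaton: one cell per lattice site, per-site
scalar fields, and daily stochastic update rules.

## Model in brief

On a lattice of spacing *dl* = 0.01825 mm (max density *dl*⁻³ ≈ 1.64×10⁵
cells mm⁻³), each site carries ECM ∈ [0,1], MDF ≥ 0, growth stimulus
G ≥ 0, and the minimum principal stress σ from stent expansion:

- **injury**: σ < −σ_crit (35 kPa compressive) removes the cell and sets
  MDF = 1, G = 3; wherever ECM and MDF coexist both decay at
  c_deg = 0.05 d⁻¹ (full resorption in 20 days);
- **phenotype**: an SMC is contractile iff its site has intact matrix
  (ECM = 1), no partially degraded matrix (0 < ECM < 1) lies in its
  neighbourhood, and local SMC occupancy < c_SMC,crit; synthetic
  otherwise (reversible);
- **synthetic SMCs**: random-walk at v_SMC = 0.24 mm d⁻¹ (≈ 13 site
  steps/day), divide at p_SMC = 0.24 d⁻¹ while G > G_crit (each division
  consumes G_crit), produce matrix at c_ECM = 0.20 d⁻¹;
- **endothelium**: ECs make p_EC = 2 division attempts per cell per day
  onto matrix-free sites adjacent to matrix (the lumen surface) and are
  impenetrable barriers to SMCs.

Outputs per day: neointimal area per axial slice (ECM-containing sites
minus the initial cross-section, × *dl*²), lesion volume (Σ areas × *dl*),
cell counts, and the population doubling rate log₂(N/N₀) of consecutive
daily SMC counts. See `docs/methods.md` for the full rule set, parameter
table and numerical conventions.

## Worked example

A reduced-scale run — 3.5 mm artery segment, coarsened lattice
(*dl* = 0.0365 mm), synthetic four-crown stent stress field, baseline
endothelial healing rate:

```python
import stentsim as ss

geo = ss.Geometry(length=3.5, r_inner=1.25, r_outer=1.875, stent_z=(0.75, 2.75))
params = ss.Params(dl=0.0365, c_smc_init=0.192 * 0.0365**-3, p_ec=2.0,
                   days_max=160, rng_seed=3, geometry=geo)
stent = ss.StentSpec(n_crowns=4, n_rings=4, peak_stress=60.0, end_factor=1.5)
result = ss.run_simulation(params, stent_spec=stent)

m = result.metrics
print(f"termination: {result.termination} at day {int(m.iloc[-1]['day'])}")
print(f"final lesion volume: {m.iloc[-1]['lesion_volume']:.4f} mm^3")
```

prints

```
termination: healed_equilibrium at day 146
final lesion volume: 0.0967 mm^3
```

i.e. the stent-induced injury produced a 0.097 mm³ neointimal lesion that
stopped growing when the endothelium healed over it on day 146; all
synthetic SMCs had reverted to the contractile phenotype (final counts:
83 965 cSMC, 0 sSMC, 66 914 EC). Raising `p_ec` to 4 shrinks the final
lesion (0.013 mm³); setting it to 0 lets the lesion grow for the whole
run (0.64 mm³), focused at the stent-end slices — the healing-rate
dependence that makes the endothelium the decisive variable in this
model.

The same run from the shell:

```sh
stentsim run --config examples/reduced.yaml --out out/ --snapshot-every 40
stentsim make-stress --config examples/reduced.yaml --out out/field.vtk
stentsim metrics out/snapshot_d*.vtk --baseline out/snapshot_d0.vtk --out out/recomputed.csv
```

`out/metrics.csv` has one row per day (day, lesion volume, counts,
doubling, per-slice areas); snapshots are ASCII VTK structured-points
files with ECM/MDF/G/stress/occupant/domain fields.

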