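# Reduced-scale demonstration run: 3.5 mm artery segment, coarsened
# lattice, synthetic four-crown stent stress field, 160 days.
params:
  dl: 0.0365
  c_smc_init: 3950.0        # 0.192 occupancy at this spacing
  p_ec: 2.0
  days_max: 160
  rng_seed: 3
  geometry:
    length: 3.5
    r_inner: 1.25
    r_outer: 1.875
    stent_z: [0.75, 2.75]
stent:
  n_crowns: 4
  n_rings: 4
  peak_stress: 60.0
  end_factor: 1.5
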