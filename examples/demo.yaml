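# Demo pipeline configuration: beads confined in an 18 µm spherical pore,
# tracked every 5 s, analyzed end to end.
simulate:
  geometry: sphere
  diameter_um: 18.0
  bead_um: 1.0
  temperature_k: 300.0
  viscosity_pa_s: 0.001
  interval_s: 5.0
  steps: 250
  beads: 60
pores:
  min_track_length: 10
sem:
  volume_budget_um3: 300000
  min_diameter_um: 1.0
  min_area_um2: 10.0
render:
  mode: packed
  gap_um: 10.0
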