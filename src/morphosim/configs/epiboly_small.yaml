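# Reduced-scale epiboly variant for fast tests and parameter sweeps:
# fewer particles, shorter settling and run, division retained.
schema: 1
name: epiboly
extends: epiboly
geometry:
  kind: blastoderm
  R_yolk: 52.0
  n_deep: 160
  n_evl: 200
  n_yolk_membrane: 430
  cap_angle: 0.95
  cell_radius: 5.5
  evl_radius: 6.0
  yolk_particle_radius: 6.0
  dome_height: 44.0
  spacing: 9.9
sim:
  dt: 0.5
  duration: 72.0
  settle_min: 30.0
  lambda: 1.0
  seed: 0
  snapshot_every: 4.0
  genetics_substeps: 1
mechanics:
  k_rep: 2.0
  c_eq: 0.9
  c_max: 1.3
  k_plan: 1.0
  cone_half_angle: 1.0
  adhesion:
    default: 0.5
    pairs:
      "EVL:EVL": 0.5
      "EVL:M": 0.7
      "EVL:I": 0.7
      "M:yolk_membrane": 1.3
      "I:yolk_membrane": 1.3
      "EVL:yolk_membrane": 0.8
behaviour:
  phi: 1.5
  lambda_ran: 0.0
  repolarization_period: 7.5
division:
  enabled: true
  mean_cycle: 160.0
  jitter: 0.15
  growth_rate: 0.012
anchored_bodies: [yolk_membrane, yolk_interior]
transport:
  Lig: {D: 120.0, gamma: 0.08, clamp_body: EVL, clamp_value: 1.0}
grn:
  species:
    - {name: Ubi, kind: protein, degradation_rate: 0.0}
    - {name: Lig, kind: diffusible_ligand, degradation_rate: 0.0}
  genes: []
  reactions: []
  secretions: []
  transductions: []
  outputs:
    archetype_M: "Ubi>=0.5"
    archetype_E: []
    behaviour:
      protrusion_polarity: bi
      phi: 1.5
      polarization_mode: chemotactic
      guidance_ligand: Lig
init:
  - {species: Ubi, value: 1.0}
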