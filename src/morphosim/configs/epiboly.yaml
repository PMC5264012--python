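# First phase of zebrafish epiboly (oblong -> 50%-epiboly).
# A lens-shaped blastoderm of mesenchymal deep cells sits on a spherical
# yolk, sealed at the margin by an EVL shell.  The EVL releases a guidance
# ligand (Dirichlet-clamped at the EVL particles) whose inward radial
# gradient orients the deep cells' bipolar protrusion axes; radial
# intercalation plus division-driven growth flatten the deep-cell mass and
# push the margin toward the vegetal pole.  EVL and yolk take part only in
# passive relaxation forces; the yolk membrane is anchored.  A passive
# settling phase relaxes the carved lattice before the behavioural clock
# starts.
schema: 1
name: epiboly
geometry:
  kind: blastoderm
  R_yolk: 60.0
  n_deep: 240
  n_evl: 260
  n_yolk_membrane: 560
  cap_angle: 0.95
  cell_radius: 5.5
  evl_radius: 6.0
  yolk_particle_radius: 6.0
  dome_height: 48.0
  spacing: 9.9
sim:
  dt: 0.5
  duration: 96.0
  settle_min: 60.0
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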