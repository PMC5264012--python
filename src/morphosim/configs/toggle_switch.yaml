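# Tissue patterning by a signal-mediated toggle switch.
# A ball-shaped tissue of idle cells; Wnt production is switched on at
# t = 20 min in a central subregion (~10% of cells).  Secreted Wnt ligand
# diffuses across the contact graph; transduction releases beta-catenin and
# XIAP, which tip the Tcf+/Tcf- activation/repression balance so that cells
# receiving enough ligand switch the Target gene ON.  Cells divide
# sporadically (mean cycle tuned so ~880 cells grow to ~1125 over 95 min).
schema: 1
name: toggle_switch
geometry:
  kind: lattice_ball
  n_cells: 880
  spacing: 11.0
  jitter: 0.4
  cell_radius: 6.0
sim:
  dt: 0.5
  duration: 95.0
  lambda: 1.0
  seed: 0
  snapshot_every: 5.0
  genetics_substeps: 5
mechanics:
  k_rep: 2.0
  c_eq: 0.9
  c_max: 1.3
  k_plan: 1.0
  cone_half_angle: 1.0
  adhesion:
    default: 0.5
division:
  enabled: true
  mean_cycle: 268.0
  jitter: 0.2
behaviour:
  lambda_ran: 0.0
transport:
  WntLig: {D: 60.0, gamma: 0.3}
grn:
  species:
    - {name: SourceMark, kind: protein, degradation_rate: 0.0}
    - {name: Wnt, kind: protein, degradation_rate: 0.1}
    - {name: WntLig, kind: diffusible_ligand, degradation_rate: 0.0}
    - {name: Rec, kind: receptor, degradation_rate: 0.0}
    - {name: Bcat, kind: messenger, degradation_rate: 0.2}
    - {name: XIAP, kind: messenger, degradation_rate: 0.2}
    - {name: Tcf, kind: protein, degradation_rate: 0.05}
    - {name: Gro, kind: protein, degradation_rate: 0.05}
    - {name: TcfPlus, kind: complex, degradation_rate: 0.1}
    - {name: TcfMinus, kind: complex, degradation_rate: 0.05}
    - {name: Target, kind: protein, degradation_rate: 0.05}
    - {name: One, kind: protein, degradation_rate: 0.0}
  genes:
    - {name: WntGene, product: Wnt, logic: "SourceMark>=0.5", rate: 1.0}
    - {name: TcfGene, product: Tcf, logic: "One>=0.5", rate: 0.3}
    - {name: GroGene, product: Gro, logic: "One>=0.5", rate: 0.2}
    - {name: TargetGene, product: Target,
       logic: "(TcfPlus>=1.0) & !(TcfMinus>=0.3)", rate: 1.0}
  reactions:
    - {reactants: [Tcf, Bcat], product: TcfPlus, rate: 0.5}
    - {reactants: [Tcf, Gro], product: TcfMinus, rate: 0.15}
    # XIAP catalyses the ubiquitination and degradation of Gro (pure loss)
    - {reactants: [XIAP, Gro], product: null, rate: 2.0, consume: [false, true]}
  secretions:
    - {protein: Wnt, ligand: WntLig, rate: 0.5, mode: diffusible}
  transductions:
    - {ligand: WntLig, receptor: Rec, messenger: Bcat, rate: 1.0, source: local_field}
    - {ligand: WntLig, receptor: Rec, messenger: XIAP, rate: 0.3, source: local_field}
  outputs:
    archetype_M: never
    archetype_E: []
    behaviour: {protrusion_polarity: bi, phi: 0.0, polarization_mode: chemotactic}
init:
  # Gro, Tcf, Tcf- and receptors ubiquitously present at t = 0
  - {species: One, value: 1.0}
  - {species: Rec, value: 1.0}
  - {species: Tcf, value: 1.0}
  - {species: Gro, value: 1.0}
  - {species: TcfMinus, value: 1.0}
schedule:
  - time: 20.0
    set_species:
      species: SourceMark
      value: 1.0
      region: {ball: {center: [0.0, 0.0, 0.0], radius: 30.0}}
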