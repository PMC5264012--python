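# Compartment formation by mutual induction and epithelialization.
# A cubic domain of ~12^3 idle cells; the anterior half (x < 0) receives a
# short pulse of protein X.  X switches on the self-activating Anterior
# gene; Anterior drives synthesis of the transmembrane ligand Delta.
# Delta-Notch transduction induces Epi only outside the Anterior domain
# (Anterior represses Epi), hence only in the posterior border row; Epi
# cells in turn present the ligand Delto, whose transduction induces Epi2
# only inside the Anterior domain, hence only in the anterior border row.
# Both rows epithelialize (with lateral reinforcement), orient toward the
# inducing ligand and flatten under planarity-conservation forces.
# Cells do not divide here.
schema: 1
name: delta_notch
geometry:
  kind: cube
  n_side: 12
  spacing: 11.0
  jitter: 0.3
  cell_radius: 6.0
sim:
  dt: 0.5
  duration: 60.0
  lambda: 1.0
  seed: 0
  snapshot_every: 5.0
  genetics_substeps: 5
mechanics:
  k_rep: 2.0
  c_eq: 0.9
  c_max: 1.3
  k_plan: 0.6
  cone_half_angle: 1.0
  adhesion:
    default: 0.5
division:
  enabled: false
behaviour:
  lambda_ran: 0.0
grn:
  species:
    - {name: X, kind: protein, degradation_rate: 0.3}
    - {name: Anterior, kind: protein, degradation_rate: 0.1}
    - {name: DeltaP, kind: protein, degradation_rate: 0.2}
    - {name: Delta, kind: surface_ligand, degradation_rate: 0.1}
    - {name: Notch, kind: receptor, degradation_rate: 0.0}
    - {name: EpiInd, kind: messenger, degradation_rate: 0.3}
    - {name: Epi, kind: protein, degradation_rate: 0.1}
    - {name: DeltoP, kind: protein, degradation_rate: 0.2}
    - {name: Delto, kind: surface_ligand, degradation_rate: 0.1}
    - {name: Epi2Ind, kind: messenger, degradation_rate: 0.3}
    - {name: Epi2, kind: protein, degradation_rate: 0.1}
  genes:
    - {name: AnteriorGene, product: Anterior,
       logic: "(X>=0.5) | (Anterior>=0.3)", rate: 0.5}
    - {name: DeltaGene, product: DeltaP, logic: "Anterior>=0.3", rate: 0.5}
    - {name: EpiGene, product: Epi,
       logic: "(EpiInd>=0.15) & !(Anterior>=0.3)", rate: 0.5}
    - {name: DeltoGene, product: DeltoP, logic: "Epi>=0.3", rate: 0.5}
    - {name: Epi2Gene, product: Epi2,
       logic: "(Epi2Ind>=0.15) & (Anterior>=0.3)", rate: 0.5}
  secretions:
    - {protein: DeltaP, ligand: Delta, rate: 0.5, mode: surface}
    - {protein: DeltoP, ligand: Delto, rate: 0.5, mode: surface}
  transductions:
    - {ligand: Delta, receptor: Notch, messenger: EpiInd, rate: 1.0,
       source: neighbour_surface}
    - {ligand: Delto, receptor: Notch, messenger: Epi2Ind, rate: 1.0,
       source: neighbour_surface}
  outputs:
    archetype_M: never
    archetype_E:
      - {name: Epi, logic: "Epi>=0.3", guidance_ligand: Delta,
         guidance_source: neighbour_surface}
      - {name: Epi2, logic: "Epi2>=0.3", guidance_ligand: Delto,
         guidance_source: neighbour_surface}
    behaviour: {protrusion_polarity: bi, phi: 0.0, polarization_mode: chemotactic}
init:
  - {species: Notch, value: 1.0}
  # the X pulse: initial bolus in the anterior half, decaying within ~10 min
  - {species: X, value: 2.0, region: {halfspace: {axis: x, below: 0.0}}}
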