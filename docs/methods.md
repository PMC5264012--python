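# Methods

`morphosim` simulates early embryogenesis as a population of particle cells
whose mechanics and gene regulation are coupled in both directions: gene
expression selects a cell's archetype and active behaviour (which forces it
exerts), and the resulting rearrangement of the tissue changes each cell's
signalling environment (which genes it expresses). This note records the
model equations as implemented, the units and default parameters, the
numerical choices, what the synthetic scenarios do and do not emulate, and
the known limitations.

Units throughout: micrometres (um), minutes (min), arbitrary concentration
units (a.u.). Forces are expressed in units of `lambda * um / min` so the
overdamped update is dimensionally closed; `lambda = 1` by convention and all
stiffnesses are quoted in these force units.

## Mechanics

Each cell is one particle with position `x_i` and radius `r_i` (two
semi-axes are stored, but only the mean radius enters the force laws; cells
are spheres by default). Motion is overdamped:

    dx_i/dt = F_i / lambda

Inertia is neglected — cells are small, densely packed and sticky, so the
dynamics is friction-dominated. `F_i` sums pairwise contributions over the
topological neighbourhood `N_i`.

**Contact graph.** `N_i` is the 3D Delaunay adjacency filtered by (a) a
metric cutoff `d_ij <= c_max (r_i + r_j)` and (b) the Gabriel criterion (no
third particle strictly inside the sphere with diameter `ij`). A purely
metric neighbourhood collapses at high adhesion because second-shell cells
attract through their common neighbours; plain Delaunay instead invents
arbitrarily long hull-spanning contacts. Gabriel + cutoff is the standard
center-based-model remedy, and because every Gabriel edge is a Delaunay
edge, the construction is provably identical to the brute-force "cutoff +
empty diametral sphere" definition that the test suite uses as an oracle.
Defaults: `c_max = 1.3`, `c_eq = 0.9` (cells slightly compressed at rest, as
in packed tissue). Exactly regular lattices are disambiguated with a
deterministic 1e-6 um jitter before triangulation; filters are evaluated on
the unjittered coordinates.

**Contact-area proxy.** Diffusion and adhesion are weighted per edge by
`s_ij` (um^2): the exact circle-of-intersection area of the two spheres for
compressed contacts (`d <= d_eq = c_eq (r_i + r_j)`), saturating at
`pi * min(r)^2` when the circle passes the smaller sphere's equator, and a
linear ramp from the `d_eq` value to 0 at the cutoff for stretched contacts.
Continuous everywhere in `d`.

**Passive forces.** Attraction-repulsion along each edge, derived from an
elastic-like pair potential with adhesion coefficient `w_ij`:

    f(d) = -k_rep (d_eq - d)/d_eq                      d < d_eq   (repulsion)
    f(d) =  w_ij (d - d_eq)(d_c - d)/(d_c - d_eq)^2    d_eq <= d <= d_c
    f(d) =  0                                          d > d_c

(signed magnitude along i->j; `d_c = c_max (r_i + r_j)`). The attraction
branch vanishes continuously at both ends. `k_rep = 2` and base `w = 0.5`
set the relaxation timescale to a few minutes at cell scale. The functional
form is a design choice isolated behind `attraction_repulsion` so
alternatives are drop-in.

`w_ij` is the archetype/body-class table entry, optionally scaled by
adhesion molecules: the mean over molecule names declared by either cell of
`min(density_i, density_j)/ref_density` — homophilic binding limited by the
scarcer side. With two populations carrying disjoint molecules this yields
`w_AB = 0` and the tissue shows the differential-adhesion sorting tendency.

**Planarity conservation.** A behaviourally epithelial cell `i` with
apicobasal axis `a_i` exerts, on each same-population epithelial neighbour
`j`, the pair `-k_plan h a_i` on `j` and `+k_plan h a_i` on itself, where
`h = (x_j - x_i) . a_i` is the out-of-plane offset. This is a gradient flow
of `sum h^2`: sheets flatten and stay flat. `a_i` is the smallest-eigenvalue
eigenvector of the covariance of offsets to same-population epithelial
neighbours (>= 3 required), sign-oriented toward the side with fewer
neighbours (the free surface), with a lexicographic tie-break. Restricting
the covariance to same-population neighbours is a deliberate choice: for a
monolayer embedded in a 3D tissue the full neighbourhood is isotropic and
carries no plane.

**Protrusion.** Mesenchymal motility is modelled as force pairs, not shape
change. A protruding cell acts only on the cell neighbours inside the polar
domain around its (noisy) polarization axis `u_i`: a cone of half-angle
`cone_half_angle` (default 1 rad) around `+u_i`, and also `-u_i` in bipolar
mode. For a neighbour on side `sigma = +/-1` the intrinsic force on the
actor is `sigma * phi * w_ij * u_i` and the extrinsic force on the neighbour
is its exact negative. Monopolar protrusion at `2*phi` therefore doubles the
per-pair magnitudes, which is why it reproduces bipolar trajectories at
`phi` (checked in the acceptance suite). Bodies (yolk, EVL) are never
protrusion targets — they take part only in passive relaxation.

**Integration.** Explicit Euler, `dt = 0.5 min` in the bundled scenarios.
Stability guard: per-particle displacement capped at `0.1 r` per step, with
cap events counted (a step capping > 10 % of particles flags dt as too
large). The cap acts on single particles, so while it fires it trades exact
pairwise momentum balance for robustness; in normal operation it never
fires.

**Division.** `cycle_phase` advances as `dt / cycle_len`, with per-cell
cycle lengths `mean_cycle (1 + jitter * N(0,1))` (floored at 20 % of the
mean). At phase 1 the mother splits into daughters at `+/- 0.5 r` along a
random (or polarization) axis, radii scaled by `2^(-1/3)` so the division
itself conserves volume, concentrations (not amounts) inherited. Daughters
then regrow toward the mother's pre-division radius at rate
`growth_rate` (default 0.012/min), so a dividing tissue gains volume over a
cycle — without regrowth, division would only subdivide a fixed mass and
could not drive spreading.

## Gene regulation, secretion, transduction, transport

Each cell carries protein concentrations `p`, gene activities `g`, receptor
densities `rho` and membrane-bound surface-ligand amounts; each particle
(cells and bodies) carries extracellular concentrations `q` of each
diffusible ligand.

**Transcription** is Boolean: a gene produces its protein at a constant rate
while its cis-regulatory logic — AND/OR/NOT over `(species >= threshold)`
atoms — is true, and not at all otherwise. Hard-threshold gating (not Hill
functions) keeps the regulatory layer discrete while concentrations remain
continuous.

**Reactions** are mass action: `A + B -> C` at rate `k p_A p_B`, with
per-reactant consumption flags so catalysed degradation (an enzyme
ubiquitinating a substrate) consumes only the substrate. Every species
decays at its first-order `degradation_rate`.

**Secretion** moves intracellular protein into the cell's own extracellular
compartment (diffusible mode) or onto its membrane (surface mode, e.g.
Delta), by default as a conversion (the protein is decremented, so the step
conserves total amount).

**Transduction** produces an intracellular messenger at rate
`kappa * q * rho`. For juxtacrine rules (`neighbour_surface`, Delta-Notch)
`q` is replaced by the contact-proxy-weighted mean of the neighbours'
surface-ligand amounts, `sum_j s_ij L_j / sum_j s_ij`. Ligand is not
consumed by default (switchable per rule).

**Transport** is a graph Laplacian on the same contact graph as the
mechanics (no background grid — extracellular ligand lives in per-cell
compartments): flux over edge `(i,j)` is `D s_ij (q_j - q_i)/d_ij`, divided
by the nominal compartment volume `V_i = 4/3 pi r_i^3`, plus uniform decay
`gamma`. Fluxes are antisymmetric, so total mass `sum q_i V_i` is conserved
exactly at `gamma = 0`. The explicit scheme is kept inside its stability
bound by automatic sub-stepping (half the bound per substep). Dirichlet
sources are supported by clamping `q` on a body population (the EVL in the
epiboly scenario).

Genetics runs `genetics_substeps` Euler substeps per mechanics step (default
5) because chemical rates can be stiffer than motion; both layers converge
at first order in dt (tested).

## The coupling (cell behaviour ontology)

Per step, in a fixed documented order: archetype -> polarization axis ->
polarization noise -> apicobasal axis -> behaviour flags.

Archetypes: epithelial output nodes win over the mesenchymal node; a cell
whose epithelial logic is true but that lacks *lateral reinforcement* — at
least two neighbours expressing the same epithelial population — reverts to
idle (an isolated epithelial cell cannot maintain polarity). Reinforcement
counts only the same population, so two abutting epithelial monolayers
remain distinct compartments.

Polarization modes: **chemotactic** (the implemented driver of all three
case studies) sets `u_i` along the local gradient estimate
`sum_j (q_j - q_i)(x_j - x_i)/|x_j - x_i|^2`, normalized; flat-field cells
keep their previous axis. For juxtacrine guidance the same estimator runs on
neighbours' surface-ligand amounts over the cell-cell subgraph.
**propagation** (contact-weighted mean of neighbour axes),
**protrusion-induced** (align with the strongest incoming extrinsic force)
and **blebbing** (pure noise) are implemented minimally and covered by unit
tests only.

Polarization noise: the effective axis is `normalize(u + lambda_ran * xi)`
with `xi` uniform in the unit ball, redrawn per cell every
`repolarization_period` (default 7.5 min) and held constant in between.
Draws are counter-based — keyed by (master seed, cell substream, interval
index) — so they are independent of cell iteration order and bitwise
reproducible. `lambda_ran = 0` returns `u` exactly; `lambda_ran -> inf`
gives axes uniform on the sphere.

A mechanotransduction hook exists (production of a configured species
proportional to the summed repulsive force magnitudes on the cell); it is
off in every bundled scenario.

## Randomness and reproducibility

All randomness flows from one master seed through `SeedSequence` spawn keys:
per-cell substreams for noise, division timing/axes and initial cycle
phases. The initial geometry jitter uses the *geometry's own* seed
(`geometry.seed`, default 0), so the starting tissue is a property of the
scenario, not of the run — with noise and division off, runs with different
seeds are bitwise identical, which the test suite asserts. Snapshot HDF5
files are written without HDF5 timestamps and CSVs with repr-exact floats,
so re-running a manifest reproduces every output byte.

## Scenarios (what the synthetic conditions emulate)

**Toggle switch** (tissue patterning). A ball of 880 idle cells (lattice,
11 um spacing). At t = 20 min, Wnt production switches on in a central ball
(~10 % of cells). Secreted ligand (D = 60 um^2/min, gamma = 0.3/min; decay
length about one cell spacing) diffuses outward; transduction releases
beta-catenin and XIAP; complexes Tcf+ (activator) and Tcf- (repressor)
compete for Tcf; XIAP catalyses Groucho degradation, silencing the
repressor arm. Cells with enough ligand flip Target ON; the ON region is
connected, contains every source cell, and among founder cells the
ON/OFF partition is a clean threshold in time-averaged exposure. Division
(mean cycle 268 min with uniform random initial phase) grows 880 cells by
the factor `2^(95/268) ~ 1.28` over the 95-min run. Reaction and
transduction rates were calibrated once so that the repressor arm dominates
at low exposure and the activator arm at high exposure; thresholds sit well
inside the resulting gap.

**Delta-Notch** (compartment formation). A 12^3 jittered cubic lattice
(6^3 in the test variant); the anterior half receives an initial bolus of X
that decays within ~10 min — a pulse. X ignites the self-sustaining
Anterior gene; Anterior drives membrane Delta; Delta-Notch transduction
induces Epi only outside the Anterior domain, hence exactly in the first
posterior layer (second-layer cells receive exactly zero juxtacrine signal
on a lattice, so any positive threshold separates the layers); Epi cells
present Delto, which induces Epi2 only inside the Anterior domain — the
first anterior layer. Both rows epithelialize under lateral reinforcement,
orient toward the inducing ligand and flatten under planarity forces. No
division.

**Epiboly** (tissue tectonics, 3.7 -> 5.3 hpf). Desk-scale embryo: yolk
sphere of radius 60 um (anchored body particles at cell-scale spacing —
coarser substrate particles corrugate the adhesion landscape and pin the
margin), and a lens-shaped blastoderm: deep cells fill the volume between
the yolk and an outer spherical envelope through the dome apex
(60 + 48 um) and the margin circle (polar angle 0.95 rad), so the mass is
~4 layers thick at the animal pole and tapers to a sealed wedge at the
margin where the EVL meets the yolk. EVL particles cover the envelope and
take part only in passive forces. The EVL is a Dirichlet source of the
guidance ligand; its inward gradient orients the deep cells' bipolar
protrusion radially (chemotactic mode). Radial intercalation plus
division-driven growth (mean cycle 160 min with regrowth) flatten the mass
and push the margin vegetally: margin height falls and margin diameter
rises monotonically at the default `phi = 1.5`, while `phi = 0` changes the
margin height by < 2 % (no epiboly). A 60-min passive settling phase
(protrusion and division off) relaxes the carved lattice before the
behavioural clock starts, so initial-condition relaxation is not mistaken
for epiboly. At substantially higher `phi` the margin metric degrades while
the diameter metric improves — the deep cells abrupt from the yolk — the
same trade-off reported for the strong-protrusion region of the landscape.

**Reference curves and fitness.** The live-embryo landmark curves are not
available in tabular form, so `synthetic_reference_curves` generates
logistic stand-ins (normalized yolk height and margin diameter rising,
margin height falling), explicitly labelled synthetic. Their amplitudes are
set to a modest first-phase course at the bundled scenario's scale; a
fitness landscape is only informative when the reference is attainable
within the swept family, exactly as a real-embryo reference is by
construction. Fitness per metric is the mean absolute difference on the
reference time grid (linear interpolation), and `F` their average; lower is
better; `F = 0` iff the curves coincide on the grid.

**Sweep.** The bundled sweep varies protrusion intensity
`phi in {0.7, 1.0, 1.4, 2.0}` and polarization noise
`lambda_ran in {0, 0.3, 0.6, 0.9}` over >= 3 seeds at reduced scale
(160 deep cells, 72 min). In this moderate-noise regime the best `phi` per
noise row drifts upward with noise — noisier polarity cues are compensated
by stronger protrusive adhesion (checked as a Kendall rank statistic over
the argmin sequence). At much larger noise the trend inverts: protrusion
with near-random axes only fluidizes the tissue, so *less* of it is better;
the bundled grid deliberately covers the partial-degradation regime where
the compensation operates.

## Numerical choices and degenerate inputs

- Explicit Euler throughout (first-order, convergence tested); stiff cases
  handled by sub-stepping (transport automatic, genetics configured).
- Delaunay degeneracies: < 5 particles or rank-deficient point sets fall
  back to brute-force cutoff pairs; exact lattices get deterministic 1e-6 um
  jitter.
- Apicobasal axis: undefined (error, never NaN) for < 3 neighbours or
  collinear neighbourhoods; such cells are not behaviourally epithelial.
- Zero-gradient chemotaxis keeps the previous axis; cells that never saw a
  gradient stay unpolarized and exert no protrusion.
- Ties (extremal landmarks, axis sign) break deterministically by particle
  id or lexicographic sign.

## What passing tests do and do not show

The scenarios are generated conditions, not data: lattice tissues with
uniform radii, a single diffusible species per pathway, sharp Boolean
thresholds, a rigid (anchored) yolk. Passing the suite shows the coupled
machinery reproduces the *qualitative* developmental logic — threshold
patterning by a diffusing signal, exact boundary-layer epithelialization by
juxtacrine induction, protrusion-driven margin descent with a
noise/intensity trade-off — under controlled conditions. It does not show
quantitative agreement with any real embryo: normalized landmark magnitudes
depend on the synthetic geometry (e.g. yolk height is constant here because
the yolk cannot bulge into the blastoderm), and the fitness values are
relative to synthetic reference curves.

## Known limitations

- No yolk doming: the anchored yolk membrane fixes YH, so the rise of
  YH/EH is carried entirely by EH. A volume-conserving deformable yolk is
  the natural next step.
- Apical constriction and explicit cell shapes are out of scope; all active
  behaviour is force pairs between centres.
- Mechanotransduction is a stub hook (off everywhere).
- The epiboly scale is ~6x smaller than the modelled embryo in cell count;
  margin-metric changes are correspondingly a few percent rather than the
  tens of percent a full-scale run would produce.
- Stochastic chemical kinetics, delays and SBML semantics are out of scope.
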