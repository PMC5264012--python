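"""Domain types and (de)serialization for the coupled mechano-genetic model.

Units throughout the package: lengths in micrometres (um), time in minutes,
concentrations and surface densities in arbitrary units (a.u.).  Forces are
expressed in units of ``viscosity * um / min`` so that the overdamped update
``x += (F / lambda) * dt`` is dimensionally closed.

The central containers are :class:`Cell` (one particle per cell carrying the
full molecular state), :class:`BodyParticle` (extraembryonic structures such
as the yolk membrane and the enveloping layer, which have no archetype and no
gene-regulatory state), :class:`Tissue` (cells + bodies + time), and
:class:`GRNSpec` (the gene regulatory network with Boolean cis-regulatory
logic, mass-action reactions, secretion and transduction rules, plus the
output nodes that drive archetype selection and behaviour).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import h5py
import numpy as np

ARCHETYPES = ("M", "E", "I")
BODY_KINDS = ("yolk_membrane", "yolk_interior", "EVL")
SPECIES_KINDS = (
    "protein",
    "complex",
    "messenger",
    "surface_ligand",
    "diffusible_ligand",
    "receptor",
)
POLARIZATION_MODES = ("chemotactic", "propagation", "protrusion_induced", "blebbing")


# ---------------------------------------------------------------------------
# Boolean cis-regulatory logic
# ---------------------------------------------------------------------------


class Logic:
    """Base class for Boolean expression trees over (species, threshold) atoms."""

    def evaluate(self, p: Mapping[str, float]) -> bool:
        raise NotImplementedError

    def evaluate_array(self, P: np.ndarray, index: Mapping[str, int]) -> np.ndarray:
        """Vectorised evaluation over a (n_cells, n_species) concentration matrix."""
        raise NotImplementedError

    def atoms(self) -> list["Atom"]:
        raise NotImplementedError


@dataclass(frozen=True)
class Atom(Logic):
    """True iff the concentration of ``species`` is >= ``threshold``."""

    species: str
    threshold: float

    def evaluate(self, p):
        if self.species not in p:
            raise KeyError(
                f"logic atom references species {self.species!r} absent from state"
            )
        return p[self.species] >= self.threshold

    def evaluate_array(self, P, index):
        return P[:, index[self.species]] >= self.threshold

    def atoms(self):
        return [self]

    def __str__(self):
        return f"({self.species}>={self.threshold:g})"


@dataclass(frozen=True)
class Not(Logic):
    child: Logic

    def evaluate(self, p):
        return not self.child.evaluate(p)

    def evaluate_array(self, P, index):
        return ~self.child.evaluate_array(P, index)

    def atoms(self):
        return self.child.atoms()

    def __str__(self):
        return f"!{self.child}"


@dataclass(frozen=True)
class And(Logic):
    children: tuple[Logic, ...]

    def evaluate(self, p):
        return all(c.evaluate(p) for c in self.children)

    def evaluate_array(self, P, index):
        out = self.children[0].evaluate_array(P, index)
        for c in self.children[1:]:
            out = out & c.evaluate_array(P, index)
        return out

    def atoms(self):
        return [a for c in self.children for a in c.atoms()]

    def __str__(self):
        return "(" + " & ".join(str(c) for c in self.children) + ")"


@dataclass(frozen=True)
class Or(Logic):
    children: tuple[Logic, ...]

    def evaluate(self, p):
        return any(c.evaluate(p) for c in self.children)

    def evaluate_array(self, P, index):
        out = self.children[0].evaluate_array(P, index)
        for c in self.children[1:]:
            out = out | c.evaluate_array(P, index)
        return out

    def atoms(self):
        return [a for c in self.children for a in c.atoms()]

    def __str__(self):
        return "(" + " | ".join(str(c) for c in self.children) + ")"


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<and>&)|(?P<or>\|)|(?P<not>!)"
    r"|(?P<atom>[A-Za-z_][A-Za-z0-9_+\-]*\s*>=\s*[0-9.eE+\-]+))"
)


def parse_logic(text: str) -> Logic:
    """Parse the textual logic DSL, e.g. ``"(TcfPlus>=0.5) & !(TcfMinus>=0.5)"``.

    Grammar (precedence low to high): OR ``|``, AND ``&``, NOT ``!``, atoms
    ``name >= number`` and parenthesised sub-expressions.
    """
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ValueError(f"logic parse error at position {pos}: {text[pos:]!r}")
        pos = m.end()
        for kind, val in m.groupdict().items():
            if val is not None:
                tokens.append((kind, val))
    tokens.append(("end", ""))
    i = 0

    def peek():
        return tokens[i][0]

    def take(kind):
        nonlocal i
        if tokens[i][0] != kind:
            raise ValueError(f"logic parse error: expected {kind}, got {tokens[i]}")
        tok = tokens[i]
        i += 1
        return tok

    def parse_or():
        terms = [parse_and()]
        while peek() == "or":
            take("or")
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and():
        terms = [parse_unary()]
        while peek() == "and":
            take("and")
            terms.append(parse_unary())
        return terms[0] if len(terms) == 1 else And(tuple(terms))

    def parse_unary():
        if peek() == "not":
            take("not")
            return Not(parse_unary())
        if peek() == "lpar":
            take("lpar")
            node = parse_or()
            take("rpar")
            return node
        kind, val = take("atom")
        name, thr = val.split(">=")
        return Atom(name.strip(), float(thr))

    node = parse_or()
    take("end")
    return node


def logic_to_str(logic: Optional[Logic]) -> str:
    return "never" if logic is None else str(logic)


def logic_from_str(text: str) -> Optional[Logic]:
    text = text.strip()
    return None if text == "never" else parse_logic(text)


# ---------------------------------------------------------------------------
# Particles and tissue
# ---------------------------------------------------------------------------


def _unit_or_none(v) -> Optional[np.ndarray]:
    if v is None:
        return None
    a = np.asarray(v, dtype=float)
    return a


@dataclass
class Cell:
    """One simulated cell: a particle carrying spatial and molecular state."""

    id: int
    position: np.ndarray
    radii: tuple[float, float] = (6.0, 6.0)
    archetype: str = "I"
    polarization_axis: Optional[np.ndarray] = None
    apicobasal_axis: Optional[np.ndarray] = None
    proteins: dict[str, float] = field(default_factory=dict)
    gene_activity: dict[str, int] = field(default_factory=dict)
    receptors: dict[str, float] = field(default_factory=dict)
    surface_ligands: dict[str, float] = field(default_factory=dict)
    adhesion_density: dict[str, float] = field(default_factory=dict)
    cycle_phase: float = 0.0
    rng_stream: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.polarization_axis = _unit_or_none(self.polarization_axis)
        self.apicobasal_axis = _unit_or_none(self.apicobasal_axis)

    @property
    def radius(self) -> float:
        """Mean radius; the only radius entering force laws (spheres by default)."""
        return 0.5 * (self.radii[0] + self.radii[1])


@dataclass
class BodyParticle:
    """Extraembryonic particle (yolk membrane/interior, EVL): no archetype, no GRN."""

    id: int
    position: np.ndarray
    body: str
    radius: float

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class LigandField:
    """Per-cell extracellular concentrations of one diffusible species."""

    name: str
    q: dict[int, float]
    D: float  # um^2/min
    gamma: float  # 1/min extracellular decay


@dataclass
class Tissue:
    cells: list[Cell]
    bodies: list[BodyParticle] = field(default_factory=list)
    time: float = 0.0
    contact_graph: object = None  # rebuilt per step; cached here
    ligand_fields: dict[str, LigandField] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def positions(self, include_bodies: bool = True) -> np.ndarray:
        ps = [c.position for c in self.cells]
        if include_bodies:
            ps += [b.position for b in self.bodies]
        return np.array(ps, dtype=float).reshape(-1, 3)

    def radii_array(self, include_bodies: bool = True) -> np.ndarray:
        rs = [c.radius for c in self.cells]
        if include_bodies:
            rs += [b.radius for b in self.bodies]
        return np.array(rs, dtype=float)


# ---------------------------------------------------------------------------
# GRN specification
# ---------------------------------------------------------------------------


@dataclass
class SpeciesDef:
    name: str
    kind: str = "protein"
    degradation_rate: float = 0.0  # 1/min


@dataclass
class GeneDef:
    name: str
    product_species: str
    logic: Optional[Logic]  # None == never expressed
    production_rate: float  # a.u./min


@dataclass
class ReactionDef:
    """Mass-action reaction A + B -> product (or pure loss when product is None).

    ``consume`` flags whether each reactant is decremented; a catalysed
    degradation (enzyme E degrading substrate S) sets consume=(False, True).
    """

    reactants: tuple[str, str]
    product: Optional[str]
    rate: float  # 1/(a.u. * min)
    consume: tuple[bool, bool] = (True, True)


@dataclass
class SecretionDef:
    protein: str
    ligand: str
    rate: float  # 1/min
    mode: str = "diffusible"  # or "surface"
    conversion: bool = True  # decrement the intracellular protein


@dataclass
class TransductionDef:
    ligand: str
    receptor: str
    messenger: str
    rate: float  # kappa, 1/(a.u. * min)
    source: str = "local_field"  # or "neighbour_surface"
    consume_ligand: bool = False


@dataclass
class EpithelialPopulation:
    """One epithelial output node: which cells express it and what guides them."""

    name: str
    logic: Optional[Logic]
    guidance_ligand: Optional[str] = None
    guidance_source: str = "neighbour_surface"  # or "local_field"


@dataclass
class BehaviourSpec:
    protrusion_polarity: str = "bi"  # or "mono"
    phi: float = 0.0
    polarization_mode: str = "chemotactic"
    guidance_ligand: Optional[str] = None


@dataclass
class OutputsSpec:
    archetype_M: Optional[Logic] = None
    archetype_E: list[EpithelialPopulation] = field(default_factory=list)
    behaviour: BehaviourSpec = field(default_factory=BehaviourSpec)


@dataclass
class GRNSpec:
    species: list[SpeciesDef] = field(default_factory=list)
    genes: list[GeneDef] = field(default_factory=list)
    reactions: list[ReactionDef] = field(default_factory=list)
    secretions: list[SecretionDef] = field(default_factory=list)
    transductions: list[TransductionDef] = field(default_factory=list)
    outputs: OutputsSpec = field(default_factory=OutputsSpec)

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def diffusible_names(self) -> list[str]:
        return [s.name for s in self.species if s.kind == "diffusible_ligand"]


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass
class MechanicsParams:
    k_rep: float = 2.0
    c_eq: float = 0.9
    c_max: float = 1.3
    w: dict[str, float] = field(default_factory=dict)  # "A:B" sorted-pair keys
    w_default: float = 0.5
    k_plan: float = 1.0
    cone_half_angle: float = 1.0  # radians

    def w_pair(self, a: str, b: str) -> float:
        key = ":".join(sorted((a, b)))
        return self.w.get(key, self.w_default)


@dataclass
class BehaviourParams:
    # phi / protrusion_polarity default to the GRN output-node values; a
    # non-None value here overrides them (the sweep dials).
    phi: Optional[float] = None
    protrusion_polarity: Optional[str] = None
    lambda_ran: float = 0.0
    repolarization_period: float = 7.5  # min


@dataclass
class DivisionParams:
    enabled: bool = False
    mean_cycle: float = 268.0  # min
    jitter: float = 0.2  # relative s.d. of cycle length
    oriented: bool = False  # divide along the polarization axis when present
    growth_rate: float = 0.02  # 1/min, radius relaxation toward the target size


@dataclass
class DiffusibleParams:
    D: float = 60.0  # um^2/min
    gamma: float = 0.05  # 1/min
    clamp_body: Optional[str] = None  # Dirichlet source on a body population
    clamp_value: float = 0.0


@dataclass
class MechanotransductionHook:
    """Optional coupling from compressive stress to a species' production.

    The production rate of ``species`` is ``coefficient`` times the summed
    repulsive force magnitudes on the cell.  Disabled (None species) in all
    bundled scenarios.
    """

    species: Optional[str] = None
    coefficient: float = 0.0


@dataclass
class SimConfig:
    dt: float = 0.5  # min
    duration: float = 60.0  # min
    lam: float = 1.0  # viscosity coefficient (force*min/um)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    behaviour: BehaviourParams = field(default_factory=BehaviourParams)
    division: DivisionParams = field(default_factory=DivisionParams)
    transport: dict[str, DiffusibleParams] = field(default_factory=dict)
    mechanotransduction: MechanotransductionHook = field(
        default_factory=MechanotransductionHook
    )
    seed: int = 0
    snapshot_every: float = 5.0  # min
    genetics_substeps: int = 5
    anchored_bodies: list[str] = field(default_factory=list)
    init: list[dict] = field(default_factory=list)
    schedule: list[dict] = field(default_factory=list)


@dataclass
class Trajectory:
    snapshots: list[Tissue]
    config: SimConfig
    grn: GRNSpec
    seed: int
    provenance: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class Diagnostic:
    path: str
    message: str

    def __str__(self):
        return f"{self.path}: {self.message}"


def validate_config(config: SimConfig, grn: GRNSpec) -> list[Diagnostic]:
    """Check type invariants and cross-references; returns [] iff all hold.

    Pure: neither argument is mutated.  Problems are reported as diagnostics
    carrying the offending field path, never raised.
    """
    out: list[Diagnostic] = []
    if not config.dt > 0:
        out.append(Diagnostic("config.dt", "dt must be > 0"))
    if not config.lam > 0:
        out.append(Diagnostic("config.lam", "viscosity lambda must be > 0"))
    if not config.mechanics.c_eq < config.mechanics.c_max:
        out.append(Diagnostic("config.mechanics", "c_eq must be < c_max"))
    if config.behaviour.lambda_ran < 0:
        out.append(Diagnostic("config.behaviour.lambda_ran", "lambda_ran must be >= 0"))
    if config.genetics_substeps < 1:
        out.append(Diagnostic("config.genetics_substeps", "must be >= 1"))

    declared = set(grn.species_names())
    kinds = {s.name: s.kind for s in grn.species}
    for i, s in enumerate(grn.species):
        if s.kind not in SPECIES_KINDS:
            out.append(Diagnostic(f"grn.species[{i}]", f"unknown kind {s.kind!r}"))
        if s.degradation_rate < 0:
            out.append(Diagnostic(f"grn.species[{i}]", "degradation_rate must be >= 0"))

    def check_logic(logic: Optional[Logic], path: str):
        if logic is None:
            return
        for atom in logic.atoms():
            if atom.species not in declared:
                out.append(
                    Diagnostic(path, f"atom {atom} references undeclared species "
                                     f"{atom.species!r}")
                )

    for i, g in enumerate(grn.genes):
        if g.product_species not in declared:
            out.append(
                Diagnostic(f"grn.genes[{i}]",
                           f"product species {g.product_species!r} undeclared")
            )
        if g.production_rate < 0:
            out.append(Diagnostic(f"grn.genes[{i}]", "production_rate must be >= 0"))
        check_logic(g.logic, f"grn.genes[{i}].logic")
    for i, r in enumerate(grn.reactions):
        for s in r.reactants:
            if s not in declared:
                out.append(Diagnostic(f"grn.reactions[{i}]", f"reactant {s!r} undeclared"))
        if r.product is not None and r.product not in declared:
            out.append(Diagnostic(f"grn.reactions[{i}]", f"product {r.product!r} undeclared"))
        if r.rate < 0:
            out.append(Diagnostic(f"grn.reactions[{i}]", "rate must be >= 0"))
    for i, s in enumerate(grn.secretions):
        if s.protein not in declared:
            out.append(Diagnostic(f"grn.secretions[{i}]", f"protein {s.protein!r} undeclared"))
        if s.ligand not in declared:
            out.append(Diagnostic(f"grn.secretions[{i}]", f"ligand {s.ligand!r} undeclared"))
        elif s.mode == "diffusible" and kinds.get(s.ligand) != "diffusible_ligand":
            out.append(Diagnostic(f"grn.secretions[{i}]",
                                  f"{s.ligand!r} is not a diffusible_ligand"))
        elif s.mode == "surface" and kinds.get(s.ligand) != "surface_ligand":
            out.append(Diagnostic(f"grn.secretions[{i}]",
                                  f"{s.ligand!r} is not a surface_ligand"))
        if s.rate < 0:
            out.append(Diagnostic(f"grn.secretions[{i}]", "rate must be >= 0"))
    for i, t in enumerate(grn.transductions):
        for nm, what in ((t.ligand, "ligand"), (t.receptor, "receptor"),
                         (t.messenger, "messenger")):
            if nm not in declared:
                out.append(Diagnostic(f"grn.transductions[{i}]", f"{what} {nm!r} undeclared"))
        if t.source not in ("local_field", "neighbour_surface"):
            out.append(Diagnostic(f"grn.transductions[{i}]", f"unknown source {t.source!r}"))
        if t.rate < 0:
            out.append(Diagnostic(f"grn.transductions[{i}]", "rate must be >= 0"))
    check_logic(grn.outputs.archetype_M, "grn.outputs.archetype_M")
    for i, pop in enumerate(grn.outputs.archetype_E):
        check_logic(pop.logic, f"grn.outputs.archetype_E[{i}].logic")
        if pop.guidance_ligand is not None and pop.guidance_ligand not in declared:
            out.append(Diagnostic(f"grn.outputs.archetype_E[{i}]",
                                  f"guidance ligand {pop.guidance_ligand!r} undeclared"))
    b = grn.outputs.behaviour
    if b.protrusion_polarity not in ("mono", "bi"):
        out.append(Diagnostic("grn.outputs.behaviour", f"polarity {b.protrusion_polarity!r}"))
    if b.polarization_mode not in POLARIZATION_MODES:
        out.append(Diagnostic("grn.outputs.behaviour",
                              f"unknown polarization_mode {b.polarization_mode!r}"))
    if b.guidance_ligand is not None and b.guidance_ligand not in declared:
        out.append(Diagnostic("grn.outputs.behaviour",
                              f"guidance ligand {b.guidance_ligand!r} undeclared"))
    for name in config.transport:
        if name not in declared:
            out.append(Diagnostic(f"config.transport[{name}]", "species undeclared"))
        elif kinds.get(name) != "diffusible_ligand":
            out.append(Diagnostic(f"config.transport[{name}]", "not a diffusible_ligand"))
    return out


def validate_tissue(tissue: Tissue) -> list[Diagnostic]:
    out: list[Diagnostic] = []
    seen = set()
    for c in tissue.cells:
        if c.id in seen:
            out.append(Diagnostic(f"cells[{c.id}]", "duplicate cell id"))
        seen.add(c.id)
        if c.archetype not in ARCHETYPES:
            out.append(Diagnostic(f"cells[{c.id}].archetype", f"{c.archetype!r}"))
        if min(c.radii) <= 0:
            out.append(Diagnostic(f"cells[{c.id}].radii", "radii must be > 0"))
        for ax, nm in ((c.polarization_axis, "polarization_axis"),
                       (c.apicobasal_axis, "apicobasal_axis")):
            if ax is not None and abs(np.linalg.norm(ax) - 1.0) > 1e-9:
                out.append(Diagnostic(f"cells[{c.id}].{nm}", "axis not unit length"))
        for dct, nm in ((c.proteins, "proteins"), (c.receptors, "receptors"),
                        (c.surface_ligands, "surface_ligands")):
            for k, v in dct.items():
                if v < 0:
                    out.append(Diagnostic(f"cells[{c.id}].{nm}[{k}]", "negative concentration"))
    for b in tissue.bodies:
        if b.body not in BODY_KINDS:
            out.append(Diagnostic(f"bodies[{b.id}]", f"unknown body kind {b.body!r}"))
    return out


# ---------------------------------------------------------------------------
# Snapshot I/O (HDF5 container + CSV export)
# ---------------------------------------------------------------------------

_ARCH_CODE = {a: i for i, a in enumerate(ARCHETYPES)}
_BODY_CODE = {b: i for i, b in enumerate(BODY_KINDS)}


def _dict_matrix(dicts: Sequence[Mapping[str, float]]) -> tuple[list[str], np.ndarray]:
    keys = sorted({k for d in dicts for k in d})
    mat = np.zeros((len(dicts), len(keys)))
    for i, d in enumerate(dicts):
        for j, k in enumerate(keys):
            mat[i, j] = d.get(k, 0.0)
    return keys, mat


def _axis_matrix(axes: Sequence[Optional[np.ndarray]]) -> np.ndarray:
    out = np.full((len(axes), 3), np.nan)
    for i, a in enumerate(axes):
        if a is not None:
            out[i] = a
    return out


def save_snapshot(tissue: Tissue, path) -> None:
    """Write the tissue to an HDF5 container (groups /cells, /bodies, /ligands, /meta).

    Round-trip is bit-exact for all float fields; dataset creation disables
    HDF5 timestamp tracking so identical states produce identical files.
    """
    with h5py.File(path, "w", track_order=True) as f:

        def ds(group, name, data):
            group.create_dataset(name, data=data, track_times=False)

        meta = f.create_group("meta")
        meta.attrs["schema"] = 1
        meta.attrs["time"] = float(tissue.time)

        g = f.create_group("cells")
        cells = tissue.cells
        ds(g, "id", np.array([c.id for c in cells], dtype=np.int64))
        ds(g, "position", np.array([c.position for c in cells]).reshape(-1, 3))
        ds(g, "radii", np.array([c.radii for c in cells]).reshape(-1, 2))
        ds(g, "archetype", np.array([_ARCH_CODE[c.archetype] for c in cells], dtype=np.int8))
        ds(g, "polarization_axis", _axis_matrix([c.polarization_axis for c in cells]))
        ds(g, "apicobasal_axis", _axis_matrix([c.apicobasal_axis for c in cells]))
        ds(g, "cycle_phase", np.array([c.cycle_phase for c in cells]))
        ds(g, "rng_stream", np.array([c.rng_stream for c in cells], dtype=np.int64))
        for attr in ("proteins", "receptors", "surface_ligands", "adhesion_density",
                     "gene_activity"):
            keys, mat = _dict_matrix([getattr(c, attr) for c in cells])
            sub = g.create_group(attr)
            sub.attrs["names"] = json.dumps(keys)
            ds(sub, "values", mat)

        b = f.create_group("bodies")
        bodies = tissue.bodies
        ds(b, "id", np.array([p.id for p in bodies], dtype=np.int64))
        ds(b, "position", np.array([p.position for p in bodies]).reshape(-1, 3))
        ds(b, "body", np.array([_BODY_CODE[p.body] for p in bodies], dtype=np.int8))
        ds(b, "radius", np.array([p.radius for p in bodies]))

        lg = f.create_group("ligands")
        for name, fld in sorted(tissue.ligand_fields.items()):
            sub = lg.create_group(name)
            sub.attrs["D"] = fld.D
            sub.attrs["gamma"] = fld.gamma
            ids = np.array(sorted(fld.q), dtype=np.int64)
            ds(sub, "node_id", ids)
            ds(sub, "q", np.array([fld.q[i] for i in ids]))


def load_snapshot(path) -> Tissue:
    arch_rev = {v: k for k, v in _ARCH_CODE.items()}
    body_rev = {v: k for k, v in _BODY_CODE.items()}
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise IOError(f"cannot read snapshot {path!r}: {e}") from None
    with f:
        try:
            g = f["cells"]
            n = len(g["id"])
            dicts = {}
            for attr in ("proteins", "receptors", "surface_ligands",
                         "adhesion_density", "gene_activity"):
                names = json.loads(g[attr].attrs["names"])
                vals = g[attr]["values"][()]
                dicts[attr] = [
                    {k: vals[i, j] for j, k in enumerate(names)} for i in range(n)
                ]
            cells = []
            for i in range(n):
                pol = g["polarization_axis"][i]
                api = g["apicobasal_axis"][i]
                cells.append(Cell(
                    id=int(g["id"][i]),
                    position=g["position"][i],
                    radii=tuple(g["radii"][i]),
                    archetype=arch_rev[int(g["archetype"][i])],
                    polarization_axis=None if np.isnan(pol).any() else pol,
                    apicobasal_axis=None if np.isnan(api).any() else api,
                    proteins=dicts["proteins"][i],
                    gene_activity={k: int(v) for k, v in dicts["gene_activity"][i].items()},
                    receptors=dicts["receptors"][i],
                    surface_ligands=dicts["surface_ligands"][i],
                    adhesion_density=dicts["adhesion_density"][i],
                    cycle_phase=float(g["cycle_phase"][i]),
                    rng_stream=int(g["rng_stream"][i]),
                ))
            b = f["bodies"]
            bodies = [
                BodyParticle(id=int(b["id"][i]), position=b["position"][i],
                             body=body_rev[int(b["body"][i])], radius=float(b["radius"][i]))
                for i in range(len(b["id"]))
            ]
            fields = {}
            for name in f["ligands"]:
                sub = f["ligands"][name]
                ids = sub["node_id"][()]
                qs = sub["q"][()]
                fields[name] = LigandField(
                    name=name, q={int(i): float(v) for i, v in zip(ids, qs)},
                    D=float(sub.attrs["D"]), gamma=float(sub.attrs["gamma"]),
                )
            return Tissue(cells=cells, bodies=bodies, time=float(f["meta"].attrs["time"]),
                          ligand_fields=fields)
        except KeyError as e:
            raise IOError(f"corrupt or truncated snapshot {path!r}: missing {e}") from None


def tissues_equal(a: Tissue, b: Tissue) -> bool:
    """Field-by-field, bit-exact equality (used by round-trip tests)."""

    def arr_eq(x, y):
        if x is None or y is None:
            return x is None and y is None
        return np.array_equal(np.asarray(x), np.asarray(y))

    if a.time != b.time or len(a.cells) != len(b.cells) or len(a.bodies) != len(b.bodies):
        return False
    for ca, cb in zip(a.cells, b.cells):
        if (ca.id != cb.id or not arr_eq(ca.position, cb.position)
                or tuple(ca.radii) != tuple(cb.radii) or ca.archetype != cb.archetype
                or not arr_eq(ca.polarization_axis, cb.polarization_axis)
                or not arr_eq(ca.apicobasal_axis, cb.apicobasal_axis)
                or ca.proteins != cb.proteins or ca.gene_activity != cb.gene_activity
                or ca.receptors != cb.receptors or ca.surface_ligands != cb.surface_ligands
                or ca.adhesion_density != cb.adhesion_density
                or ca.cycle_phase != cb.cycle_phase or ca.rng_stream != cb.rng_stream):
            return False
    for pa, pb in zip(a.bodies, b.bodies):
        if (pa.id != pb.id or not arr_eq(pa.position, pb.position)
                or pa.body != pb.body or pa.radius != pb.radius):
            return False
    if set(a.ligand_fields) != set(b.ligand_fields):
        return False
    for k in a.ligand_fields:
        fa, fb = a.ligand_fields[k], b.ligand_fields[k]
        if fa.q != fb.q or fa.D != fb.D or fa.gamma != fb.gamma:
            return False
    return True


def export_cells_csv(tissue: Tissue, path) -> None:
    """One row per cell: id,x,y,z,r,archetype,ux,uy,uz,ax,ay,az + species columns.

    Floats are written with repr-exact formatting so identical states produce
    byte-identical files.
    """
    species = sorted({k for c in tissue.cells for k in c.proteins})
    with open(path, "w") as fh:
        cols = ["id", "x", "y", "z", "r", "archetype",
                "ux", "uy", "uz", "ax", "ay", "az"] + species
        fh.write(",".join(cols) + "\n")
        for c in tissue.cells:
            u = c.polarization_axis if c.polarization_axis is not None else [np.nan] * 3
            a = c.apicobasal_axis if c.apicobasal_axis is not None else [np.nan] * 3
            vals = ([str(c.id)] + [repr(float(v)) for v in c.position]
                    + [repr(float(c.radius)), c.archetype]
                    + [repr(float(v)) for v in u] + [repr(float(v)) for v in a]
                    + [repr(float(c.proteins.get(s, 0.0))) for s in species])
            fh.write(",".join(vals) + "\n")


def export_vtk(tissue: Tissue, path) -> None:
    """Legacy VTK polydata export of particle positions for external viewers."""
    pos = tissue.positions()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmorphosim particles\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pos)} double\n")
        for p in pos:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def config_hash(config_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def cell_rng(master_seed: int, stream: int, *tags: int) -> np.random.Generator:
    """Counter-based per-cell RNG: independent of cell iteration order.

    Streams are derived from the master seed by spawn-key splitting so that a
    cell's randomness depends only on its own substream id (and optional tags
    such as the repolarization interval index), never on how many other cells
    drew before it.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(stream, *tags))
    return np.random.default_rng(ss)
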