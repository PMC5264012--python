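"""Intracellular GRN dynamics, mass-action reactions, secretion, transduction.

The transcriptional layer is Boolean: a gene produces its protein at a
constant rate while its cis-regulatory logic f(p) evaluates true, and not at
all otherwise (hard-threshold gating, not Hill functions).  Around that
Boolean core the concentration dynamics are ordinary mass-action ODEs
integrated with explicit Euler:

    dp[s]/dt = production * [logic true]
             + sum(reaction gains) - sum(reaction losses)
             - degradation_rate * p[s]
             + messenger input from ligand-receptor transduction

Transduction converts extracellular ligand (from the local diffusible field,
or from neighbours' membrane-bound surface ligand for juxtacrine species such
as Delta) into an intracellular messenger at rate kappa * q * rho.  Secretion
moves intracellular protein into the extracellular compartment (diffusible
mode) or onto the cell's own membrane (surface mode).

The engine evaluates everything vectorised over cells; the per-cell functions
exposed here wrap the same code paths on single-row matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy import sparse

from .state_core import Cell, GRNSpec, Logic


def evaluate_logic(logic: Logic, p: Mapping[str, float]) -> int:
    """Evaluate a Boolean cis-regulatory expression against concentrations.

    An atom (s, theta) is true iff p[s] >= theta; AND/OR/NOT compose exactly.
    A ``None`` logic ("never") evaluates to 0.
    """
    if logic is None:
        return 0
    return int(logic.evaluate(p))


@dataclass
class CompiledGRN:
    """Index-based view of a GRNSpec for vectorised evaluation."""

    spec: GRNSpec
    species: list[str] = field(default_factory=list)
    index: dict[str, int] = field(default_factory=dict)
    degradation: np.ndarray = None
    diffusible: list[str] = field(default_factory=list)
    diffusible_index: dict[str, int] = field(default_factory=dict)

    @classmethod
    def compile(cls, spec: GRNSpec) -> "CompiledGRN":
        species = spec.species_names()
        index = {s: i for i, s in enumerate(species)}
        diffusible = spec.diffusible_names()
        c = cls(spec=spec, species=species, index=index,
                degradation=np.array([s.degradation_rate for s in spec.species]),
                diffusible=diffusible,
                diffusible_index={s: i for i, s in enumerate(diffusible)})
        return c

    @property
    def n_species(self) -> int:
        return len(self.species)


def neighbour_surface_mean(W: sparse.spmatrix, L: np.ndarray) -> np.ndarray:
    """Contact-proxy-weighted mean of neighbours' surface-ligand amounts.

    ``W`` is the (n_cells, n_cells) sparse matrix of contact proxies s_ij
    between cells; row i of the result is sum_j s_ij L_j / sum_j s_ij
    (zero for isolated cells).
    """
    tot = np.asarray(W.sum(axis=1)).ravel()
    num = W @ L
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, num / np.where(tot > 0, tot, 1.0), 0.0)
    return out


def transduction_rates(P: np.ndarray, Q: np.ndarray, grn: CompiledGRN,
                       W: Optional[sparse.spmatrix] = None) -> np.ndarray:
    """Messenger production rates (n_cells, n_species) from all transduction rules."""
    n = P.shape[0]
    rates = np.zeros_like(P)
    for t in grn.spec.transductions:
        rho = P[:, grn.index[t.receptor]]
        if t.source == "local_field":
            q = Q[:n, grn.diffusible_index[t.ligand]]
        else:  # neighbour_surface
            if W is None:
                q = np.zeros(n)
            else:
                q = neighbour_surface_mean(W, P[:, grn.index[t.ligand]])
        rates[:, grn.index[t.messenger]] += t.rate * q * rho
    return rates


def grn_substep(P: np.ndarray, Q: np.ndarray, grn: CompiledGRN, dt: float,
                W: Optional[sparse.spmatrix] = None,
                extra_production: Optional[np.ndarray] = None):
    """One explicit-Euler genetics substep over all cells, in place.

    Order within the substep: secretion, transduction, gene production,
    reactions, degradation, clip at zero.  Returns the (n_cells, n_genes)
    Boolean gene-activity matrix evaluated on the pre-update concentrations.
    """
    n = P.shape[0]
    spec = grn.spec

    # --- secretion (protein -> extracellular field or own membrane)
    for s in spec.secretions:
        amt = s.rate * P[:, grn.index[s.protein]] * dt
        if s.mode == "diffusible":
            Q[:n, grn.diffusible_index[s.ligand]] += amt
        else:
            P[:, grn.index[s.ligand]] += amt
        if s.conversion:
            P[:, grn.index[s.protein]] -= amt

    # --- transduction (ligand + receptor -> messenger)
    t_rates = transduction_rates(P, Q, grn, W)
    for t in spec.transductions:
        if t.consume_ligand and t.source == "local_field":
            j = grn.diffusible_index[t.ligand]
            Q[:n, j] = np.maximum(
                Q[:n, j] - dt * t.rate * Q[:n, j] * P[:, grn.index[t.receptor]], 0.0)
    P += dt * t_rates

    # --- transcription: Boolean-gated constant production
    G = np.zeros((n, len(spec.genes)), dtype=bool)
    for gi, gene in enumerate(spec.genes):
        if gene.logic is None:
            continue
        active = gene.logic.evaluate_array(P, grn.index)
        G[:, gi] = active
        P[:, grn.index[gene.product_species]] += dt * gene.production_rate * active

    if extra_production is not None:
        P += dt * extra_production

    # --- mass-action reactions
    for r in spec.reactions:
        a, b = (grn.index[x] for x in r.reactants)
        flux = r.rate * P[:, a] * P[:, b]
        if r.consume[0]:
            P[:, a] -= dt * flux
        if r.consume[1]:
            P[:, b] -= dt * flux
        if r.product is not None:
            P[:, grn.index[r.product]] += dt * flux

    # --- first-order degradation and positivity
    P -= dt * grn.degradation[None, :] * P
    np.maximum(P, 0.0, out=P)
    np.maximum(Q, 0.0, out=Q)
    return G


# ---------------------------------------------------------------------------
# Per-cell wrappers (the spec-shaped API; used heavily by the unit tests)
# ---------------------------------------------------------------------------


def _cell_state_row(cell: Cell, grn: CompiledGRN) -> np.ndarray:
    p = np.zeros(grn.n_species)
    for name, i in grn.index.items():
        for dct in (cell.proteins, cell.receptors, cell.surface_ligands):
            if name in dct:
                p[i] = dct[name]
    return p


def _writeback(cell: Cell, grn: CompiledGRN, row: np.ndarray, G: np.ndarray) -> None:
    kinds = {s.name: s.kind for s in grn.spec.species}
    for name, i in grn.index.items():
        k = kinds[name]
        if k == "receptor":
            cell.receptors[name] = float(row[i])
        elif k == "surface_ligand":
            cell.surface_ligands[name] = float(row[i])
        else:
            cell.proteins[name] = float(row[i])
    for gi, gene in enumerate(grn.spec.genes):
        cell.gene_activity[gene.name] = int(G[0, gi])


def grn_step(cell: Cell, grn: GRNSpec | CompiledGRN,
             local_signals: Mapping[str, float], dt: float) -> dict[str, float]:
    """Advance one cell's intracellular state by dt (single Euler step).

    ``local_signals`` maps diffusible-ligand names to the extracellular
    concentration seen by this cell.  The cell is updated in place and the
    new protein map returned.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    c = grn if isinstance(grn, CompiledGRN) else CompiledGRN.compile(grn)
    P = _cell_state_row(cell, c)[None, :]
    Q = np.zeros((1, len(c.diffusible)))
    for name, j in c.diffusible_index.items():
        Q[0, j] = local_signals.get(name, 0.0)
    G = grn_substep(P, Q, c, dt)
    _writeback(cell, c, P[0], G)
    return dict(cell.proteins)


def transduce(cell: Cell, grn: GRNSpec | CompiledGRN,
              ligand_sources: Mapping[str, float], dt: float) -> dict[str, float]:
    """Messenger amounts produced over dt from the supplied ligand exposures.

    ``ligand_sources`` maps each transduction rule's ligand name to the
    effective concentration (local field value, or contact-weighted neighbour
    surface mean for juxtacrine rules).  Pure: the cell is not modified.
    """
    c = grn if isinstance(grn, CompiledGRN) else CompiledGRN.compile(grn)
    p = _cell_state_row(cell, c)
    out: dict[str, float] = {}
    for t in c.spec.transductions:
        rho = p[c.index[t.receptor]]
        q = ligand_sources.get(t.ligand, 0.0)
        out[t.messenger] = out.get(t.messenger, 0.0) + dt * t.rate * q * rho
    return out


def secrete(cell: Cell, grn: GRNSpec | CompiledGRN, dt: float) -> dict[str, float]:
    """Apply secretion rules for one cell; returns diffusible emission amounts.

    Surface-mode rules increment the cell's membrane ligand store in place;
    diffusible-mode amounts are returned for the caller to deposit into the
    cell's extracellular compartment.  Conversion rules decrement the protein.
    """
    c = grn if isinstance(grn, CompiledGRN) else CompiledGRN.compile(grn)
    emitted: dict[str, float] = {}
    for s in c.spec.secretions:
        amt = s.rate * cell.proteins.get(s.protein, 0.0) * dt
        if amt == 0.0:
            continue
        if s.mode == "diffusible":
            emitted[s.ligand] = emitted.get(s.ligand, 0.0) + amt
        else:
            cell.surface_ligands[s.ligand] = cell.surface_ligands.get(s.ligand, 0.0) + amt
        if s.conversion:
            cell.proteins[s.protein] = max(cell.proteins.get(s.protein, 0.0) - amt, 0.0)
    return emitted
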