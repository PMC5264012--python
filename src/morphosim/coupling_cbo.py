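"""The Meca-Gen coupling: cell behaviour ontology (CBO) update pass.

Each cell is classified into one of three archetypes — mesenchymal (M),
epithelial (E) or the default, idle (I) — by Boolean output nodes of the GRN.
Epithelial identity is additionally conditioned on *lateral reinforcement*:
a candidate must have at least two neighbours expressing the same epithelial
population, otherwise it reverts to I (an isolated epithelial cell cannot
maintain its polarity).  The coupling pass then assigns polarization axes
(chemotactic by default: along the local ligand gradient), applies
polarization noise, computes apicobasal axes for reinforced epithelial cells,
and sets behaviour flags (protrusion for guided M cells, planarity for
reinforced E cells).

The per-step order is fixed and documented: archetype -> polarization axis ->
noise -> apicobasal axis -> behaviour flags.  All steps are pure functions of
the molecular state and the neighbourhood, so the pass is reproducible and
independent of cell iteration order.
"""

from __future__ import annotations

import numpy as np

from . import transport
from .neighbourhood import ContactGraph
from .state_core import GRNSpec, cell_rng

LATERAL_REINFORCEMENT_MIN = 2  # same-population E neighbours required


def determine_archetype(p: dict, grn: GRNSpec, n_same_population_neighbours: int = 0):
    """Archetype of one cell from its protein map and E-neighbour count.

    Returns (archetype, population): E wins over M when both output logics
    are true (documented precedence); an E-expressing cell without lateral
    reinforcement (fewer than two same-population epithelial neighbours)
    reverts to I.
    """
    for pop in grn.outputs.archetype_E:
        if pop.logic is not None and pop.logic.evaluate(p):
            if n_same_population_neighbours >= LATERAL_REINFORCEMENT_MIN:
                return "E", pop.name
            return "I", None
    m = grn.outputs.archetype_M
    if m is not None and m.evaluate(p):
        return "M", None
    return "I", None


def e_expression(P: np.ndarray, grn: GRNSpec, index: dict) -> np.ndarray:
    """Per-cell epithelial population index (-1 = none), first matching wins."""
    n = P.shape[0]
    pop = np.full(n, -1, dtype=int)
    for k, ep in enumerate(grn.outputs.archetype_E):
        if ep.logic is None:
            continue
        mask = ep.logic.evaluate_array(P, index) & (pop < 0)
        pop[mask] = k
    return pop


def lateral_reinforcement(pop_id: np.ndarray, graph: ContactGraph,
                          n_cells: int) -> np.ndarray:
    """True where a cell has >= 2 neighbours expressing its own E population."""
    counts = np.zeros(n_cells, dtype=int)
    for a, b in graph.edges:
        if a < n_cells and b < n_cells and pop_id[a] >= 0 and pop_id[a] == pop_id[b]:
            counts[a] += 1
            counts[b] += 1
    return (pop_id >= 0) & (counts >= LATERAL_REINFORCEMENT_MIN)


def chemotactic_axis(i: int, positions: np.ndarray, field_values: np.ndarray,
                     graph: ContactGraph, previous: np.ndarray = None) -> np.ndarray:
    """Polarization axis along the local gradient of a guidance field.

    ``field_values`` may be a diffusible-ligand field or (for juxtacrine
    guidance) the per-cell membrane-bound surface-ligand amounts.  Cells at a
    flat spot keep their previous axis (or stay unpolarized).
    """
    g = transport.ligand_gradient(i, positions, field_values, graph.neighbours(i))
    if np.linalg.norm(g) < 1e-12:
        return previous if previous is not None else np.zeros(3)
    return g


def propagation_axis(i: int, axes: np.ndarray, graph: ContactGraph,
                     proxies_by_edge: dict, previous: np.ndarray = None) -> np.ndarray:
    """Contact-weighted mean of neighbour polarization axes ("propagation" mode)."""
    acc = np.zeros(3)
    for j in graph.neighbours(i):
        key = (min(i, j), max(i, j))
        w = proxies_by_edge.get(key, 0.0)
        if j < len(axes) and np.isfinite(axes[j]).all():
            acc += w * axes[j]
    n = np.linalg.norm(acc)
    if n < 1e-12:
        return previous if previous is not None else np.zeros(3)
    return acc / n


def protrusion_induced_axis(i: int, extrinsic_forces: np.ndarray,
                            previous: np.ndarray = None) -> np.ndarray:
    """Align with the strongest incoming extrinsic protrusion force."""
    f = extrinsic_forces[i]
    n = np.linalg.norm(f)
    if n < 1e-12:
        return previous if previous is not None else np.zeros(3)
    return f / n


def apply_polarization_noise(u: np.ndarray, lambda_ran: float, master_seed: int,
                             stream: int, t: float, period: float = 7.5) -> np.ndarray:
    """Noisy effective polarization axis, redrawn every ``period`` minutes.

    The effective vector is normalize(u + lambda_ran * xi) with xi uniform in
    the unit ball.  xi is a counter-based draw keyed by (cell substream,
    interval index floor(t/period)), so it is constant between redraws, is
    identical across runs with the same master seed, and does not depend on
    the order cells are processed in.  lambda_ran = 0 returns u exactly.
    """
    u = np.asarray(u, dtype=float)
    if lambda_ran == 0.0:
        return u
    k = int(np.floor(t / period + 1e-9))
    rng = cell_rng(master_seed, stream, 1_000_000 + k)
    while True:
        xi = rng.uniform(-1.0, 1.0, size=3)
        if np.dot(xi, xi) <= 1.0:
            break
    v = u + lambda_ran * xi
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - zero resultant, redraw
        xi = rng.uniform(-1.0, 1.0, size=3)
        if np.dot(xi, xi) > 1.0:
            continue
        v = u + lambda_ran * xi
        n = np.linalg.norm(v)
    return v / n


def apicobasal_axis(i: int, positions: np.ndarray, neighbour_ids: np.ndarray,
                    all_neighbour_ids: np.ndarray = None) -> np.ndarray:
    """Apicobasal polarity from the local sheet geometry.

    The axis is the unit eigenvector with the smallest eigenvalue of the
    covariance of offsets to the given (same-population epithelial)
    neighbours — the normal of the local plane.  The sign is oriented toward
    the side with fewer neighbours (the free surface), falling back to a
    deterministic lexicographic rule on ties.  Requires >= 3 neighbours and a
    well-defined plane; degenerate (collinear) neighbourhoods raise.
    """
    if len(neighbour_ids) < 3:
        raise ValueError("apicobasal axis undefined: fewer than 3 epithelial neighbours")
    offs = positions[neighbour_ids] - positions[i]
    cov = offs.T @ offs / len(neighbour_ids)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-9 * max(evals[2], 1e-30):
        raise ValueError("apicobasal axis undefined: collinear neighbourhood")
    a = evecs[:, 0]
    ref_ids = neighbour_ids if all_neighbour_ids is None else all_neighbour_ids
    ref = positions[ref_ids] - positions[i]
    n_pos = int(np.count_nonzero(ref @ a > 0))
    n_neg = len(ref) - n_pos
    if n_pos < n_neg:
        pass  # already oriented toward the sparse side
    elif n_pos > n_neg:
        a = -a
    else:  # tie: lexicographic sign rule
        for comp in a:
            if abs(comp) > 1e-12:
                if comp < 0:
                    a = -a
                break
    return a / np.linalg.norm(a)


def adhesion_coefficient(class_i: str, class_j: str, w_table, density_i: dict = None,
                         density_j: dict = None, ref_density: float = 1.0) -> float:
    """Effective adhesion coefficient for one contact.

    Base value from the archetype/body-class pair table, scaled by the mean
    over declared adhesion-molecule names of min(density_i, density_j) /
    ref_density (homophilic binding limited by the scarcer side); factor 1
    when no molecules are declared.  Symmetric in i and j.
    """
    base = w_table.w_pair(class_i, class_j) if hasattr(w_table, "w_pair") else (
        w_table.get(":".join(sorted((class_i, class_j))))
    )
    if base is None:
        raise KeyError(f"no adhesion table entry for pair {class_i}:{class_j}")
    di = density_i or {}
    dj = density_j or {}
    names = sorted(set(di) | set(dj))
    if not names:
        return base
    factor = float(np.mean([
        min(di.get(nm, 0.0), dj.get(nm, 0.0)) / ref_density for nm in names
    ]))
    return base * factor
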