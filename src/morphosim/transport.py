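"""Extracellular ligand transport: graph-Laplacian diffusion and gradients.

Diffusion lives on the same topological contact graph as the mechanics — no
background voxel grid.  Each particle carries the extracellular concentration
of its own compartment; the flux over edge (i, j) is proportional to the
shared contact-area proxy and the concentration difference:

    flux_ij = D * s_ij * (q_j - q_i) / d_ij      (amount per minute into i)
    q_i <- q_i + dt * (sum_j flux_ij) / V_i - dt * gamma * q_i

Fluxes are antisymmetric, so total mass sum_i q_i V_i is conserved exactly
when gamma = 0.  The explicit scheme is kept inside its stability bound by
automatic sub-stepping.
"""

from __future__ import annotations

import numpy as np

from .neighbourhood import ContactGraph

STABILITY_SAFETY = 0.5  # fraction of the explicit-scheme bound used per substep


def nominal_volume(radius):
    """Nominal compartment volume of a particle (um^3)."""
    return 4.0 / 3.0 * np.pi * np.asarray(radius, dtype=float) ** 3


def diffusion_step(graph: ContactGraph, q: np.ndarray, D: float, gamma: float,
                   volumes: np.ndarray, dt: float) -> np.ndarray:
    """Advance one diffusion/decay step; sub-steps automatically for stability.

    ``q`` is the per-node concentration vector (a.u.); the return value is a
    new array (the input is not modified).
    """
    q = np.array(q, dtype=float)
    if len(q) != graph.n:
        raise ValueError("q length does not match graph node count")
    if len(graph.edges) == 0:
        if gamma:
            n_sub = max(1, int(np.ceil(dt * gamma / STABILITY_SAFETY)))
            h = dt / n_sub
            for _ in range(n_sub):
                q -= h * gamma * q
        return q
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    # conductance per edge: D * s_ij / d_ij (amount/min per unit concentration)
    g = D * graph.proxy / graph.dist
    rate = np.zeros(graph.n)
    np.add.at(rate, i, g)
    np.add.at(rate, j, g)
    rate = rate / volumes + gamma
    max_rate = rate.max()
    n_sub = max(1, int(np.ceil(dt * max_rate / STABILITY_SAFETY)))
    h = dt / n_sub
    for _ in range(n_sub):
        diff = q[j] - q[i]
        flux = g * diff  # into i
        dq = np.zeros(graph.n)
        np.add.at(dq, i, flux)
        np.add.at(dq, j, -flux)
        q += h * dq / volumes
        if gamma:
            q -= h * gamma * q
    return q


def ligand_gradient(i: int, positions: np.ndarray, q: np.ndarray,
                    neighbours: np.ndarray) -> np.ndarray:
    """Unit gradient estimate of a per-node field at node i.

    Sum over neighbours of (q_j - q_i) * (x_j - x_i) / |x_j - x_i|^2,
    normalised; the zero vector when all neighbour concentrations equal q_i.
    """
    if len(neighbours) == 0:
        return np.zeros(3)
    offs = positions[neighbours] - positions[i]
    d2 = np.sum(offs**2, axis=1)
    g = np.sum(((q[neighbours] - q[i]) / d2)[:, None] * offs, axis=0)
    n = np.linalg.norm(g)
    return g / n if n > 1e-12 else np.zeros(3)


def ligand_gradients_all(positions: np.ndarray, q: np.ndarray,
                         graph: ContactGraph, n_cells: int = None) -> np.ndarray:
    """Vectorised ``ligand_gradient`` for the first ``n_cells`` nodes."""
    n = graph.n if n_cells is None else n_cells
    out = np.zeros((n, 3))
    if len(graph.edges) == 0:
        return out
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    offs = positions[j] - positions[i]
    d2 = np.sum(offs**2, axis=1)
    contrib = ((q[j] - q[i]) / d2)[:, None] * offs
    acc = np.zeros((graph.n, 3))
    np.add.at(acc, i, contrib)
    np.add.at(acc, j, contrib)  # from j's view both dq and the offset flip sign
    norms = np.linalg.norm(acc[:n], axis=1)
    mask = norms > 1e-12
    out[mask] = acc[:n][mask] / norms[mask][:, None]
    return out


def total_mass(q: np.ndarray, volumes: np.ndarray) -> float:
    return float(np.sum(np.asarray(q) * np.asarray(volumes)))
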