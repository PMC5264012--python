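"""Passive and active forces and overdamped motion.

Cells obey an overdamped equation of motion: velocity = F / lambda, with
lambda a viscosity coefficient.  Passive relaxation forces comprise
attraction-repulsion pairs derived from an elastic-like interaction potential
with adhesion coefficients w, and planarity-conservation pairs expressed in
epithelial domains.  Active protrusion is modelled as pairs of equal and
opposite body forces between a protruding mesenchymal cell and the neighbours
in the polar domain around its polarization axis ("intrinsic" on the actor,
"extrinsic" on the target) — never as explicit shape change.  Every force in
the model is constructed pairwise, so internal forces sum to zero exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .state_core import Cell

DISPLACEMENT_CAP_FRACTION = 0.1  # max displacement per step, in cell radii


@dataclass
class ForceAccumulator:
    """Per-particle force channels; total = sum of channels by construction."""

    n: int
    F_ar: np.ndarray = field(default=None)
    F_plan: np.ndarray = field(default=None)
    F_pro_int: np.ndarray = field(default=None)
    F_pro_ext: np.ndarray = field(default=None)

    def __post_init__(self):
        for name in ("F_ar", "F_plan", "F_pro_int", "F_pro_ext"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros((self.n, 3)))

    @property
    def F_total(self) -> np.ndarray:
        return self.F_ar + self.F_plan + self.F_pro_int + self.F_pro_ext


def attraction_repulsion_magnitude(d, r_i, r_j, w_ij, k_rep, c_eq, c_max):
    """Signed force magnitude along the i->j direction (array-friendly).

    Negative = repulsive (pushes i away from j), positive = attractive.
    Repulsion below the equilibrium distance d_eq = c_eq*(r_i+r_j) is linear,
    k_rep*(d_eq-d)/d_eq; attraction between d_eq and the cutoff
    d_c = c_max*(r_i+r_j) is w_ij*(d-d_eq)*(d_c-d)/(d_c-d_eq)^2, vanishing
    continuously at both ends; zero beyond the cutoff.
    """
    d = np.asarray(d, dtype=float)
    d_eq = c_eq * (np.asarray(r_i) + np.asarray(r_j))
    d_c = c_max * (np.asarray(r_i) + np.asarray(r_j))
    rep = -k_rep * (d_eq - d) / d_eq
    att = np.asarray(w_ij) * (d - d_eq) * (d_c - d) / (d_c - d_eq) ** 2
    out = np.where(d < d_eq, rep, np.where(d <= d_c, att, 0.0))
    return out if out.shape else float(out)


def attraction_repulsion(d_ij: float, dir_ij: np.ndarray, r_i: float, r_j: float,
                         w_ij: float, k_rep: float, c_eq: float, c_max: float):
    """Force vector on i (the force on j is the exact negative).

    ``dir_ij`` is the unit vector from i towards j.
    """
    if d_ij <= 0:
        raise ValueError("attraction_repulsion: d_ij must be > 0 "
                         "(coincident centres indicate a broken integrator step)")
    if w_ij < 0:
        raise ValueError("adhesion coefficient w_ij must be >= 0")
    f = attraction_repulsion_magnitude(d_ij, r_i, r_j, w_ij, k_rep, c_eq, c_max)
    force_i = f * np.asarray(dir_ij, dtype=float)
    return force_i, -force_i


def pair_potential(d, r_i, r_j, w_ij, k_rep, c_eq, c_max):
    """Interaction energy whose derivative reproduces the pair force.

    Used by the energy-relaxation test: with passive forces only the summed
    pair potential is non-increasing over steps.  Minimum at d_eq; constant
    (zero) beyond the cutoff.
    """
    d = np.asarray(d, dtype=float)
    d_eq = c_eq * (r_i + r_j)
    d_c = c_max * (r_i + r_j)
    # repulsion branch: V = k_rep*(d_eq-d)^2/(2 d_eq), so -dV/dd = -k*(d_eq-d)/d_eq
    v_rep = k_rep * (d_eq - d) ** 2 / (2 * d_eq)
    # attraction branch: V(d) = -w * int_{d}^{d_c} (x-d_eq)(d_c-x) dx / (d_c-d_eq)^2
    span = d_c - d_eq

    def prim(x):  # antiderivative of (x-d_eq)(d_c-x)
        return (d_eq + d_c) * x**2 / 2 - x**3 / 3 - d_eq * d_c * x

    v_att = -w_ij * (prim(d_c) - prim(np.clip(d, d_eq, d_c))) / span**2
    v_well = -w_ij * (prim(d_c) - prim(d_eq)) / span**2  # depth at d_eq
    out = np.where(d < d_eq, v_rep + v_well, np.where(d <= d_c, v_att, 0.0))
    return out if out.shape else float(out)


def planarity_forces(offsets: np.ndarray, a_i: np.ndarray, k_plan: float):
    """Planarity-conservation force pairs for one epithelial cell.

    ``offsets`` is the (m, 3) array of neighbour offsets x_j - x_i and
    ``a_i`` the apicobasal axis.  For each neighbour j with out-of-plane
    offset h = offset . a_i, the force on j is -k_plan*h*a_i and the reaction
    +k_plan*h*a_i on i; the pair sum is zero and all forces vanish when the
    neighbours lie in i's tangent plane.
    """
    a_i = np.asarray(a_i, dtype=float)
    if a_i is None or not np.isfinite(a_i).all():
        raise ValueError("unpolarized epithelial cell: missing apicobasal axis")
    h = np.asarray(offsets, dtype=float) @ a_i  # (m,)
    f_on_neigh = -k_plan * h[:, None] * a_i[None, :]
    f_on_i = -f_on_neigh.sum(axis=0)
    return f_on_i, f_on_neigh


def polar_domain(u_i: np.ndarray, polarity: str, cone_half_angle: float,
                 offsets: np.ndarray):
    """Side signs of neighbours relative to the polarization cone(s).

    Returns an (m,) integer array: +1 for neighbours inside the +u cone,
    -1 inside the -u cone (bipolar only), 0 outside.  ``offsets`` are the
    x_j - x_i vectors.
    """
    u_i = np.asarray(u_i, dtype=float)
    offs = np.asarray(offsets, dtype=float).reshape(-1, 3)
    norms = np.linalg.norm(offs, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (offs @ u_i) / np.where(norms > 0, norms, 1.0)
    cos_cut = np.cos(cone_half_angle)
    side = np.zeros(len(offs), dtype=int)
    side[c >= cos_cut] = 1
    if polarity == "bi":
        side[-c >= cos_cut] = -1
    return side


def protrusion_forces(u_i: np.ndarray, side: np.ndarray, w_ij: np.ndarray,
                      phi: float):
    """Intrinsic/extrinsic protrusion force pairs along the polarization axis.

    For each polar-domain neighbour j with side sign sigma, the intrinsic
    force on the actor i is sigma*phi*w_ij*u_i and the extrinsic force on j
    is its exact negative, so every pair sums to zero.  A monopolar cell run
    at 2*phi exerts per-pair magnitudes twice those of the bipolar case, the
    basis of the mono/bi equivalence property.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    u_i = np.asarray(u_i, dtype=float)
    coef = np.asarray(side, dtype=float) * phi * np.asarray(w_ij, dtype=float)
    f_int = coef[:, None] * u_i[None, :]  # contribution to i per pair
    f_ext = -f_int  # on each neighbour
    return f_int, f_ext


def integrate_step(positions: np.ndarray, forces: np.ndarray, lam: float,
                   dt: float, radii: np.ndarray, mobile: np.ndarray = None):
    """Overdamped explicit-Euler update x <- x + (F/lambda)*dt.

    Per-particle displacement is capped at 0.1*r as a stability guard; the
    number of capped particles is returned so callers can warn when dt is too
    large (more than 10% capped).  Particles with mobile=False (anchored yolk
    interior, if configured) are skipped.
    """
    positions = np.asarray(positions, dtype=float)
    disp = forces / lam * dt
    maxd = DISPLACEMENT_CAP_FRACTION * np.asarray(radii, dtype=float)
    norms = np.linalg.norm(disp, axis=1)
    capped = norms > maxd
    scale = np.where(capped, maxd / np.where(norms > 0, norms, 1.0), 1.0)
    disp = disp * scale[:, None]
    if mobile is not None:
        disp = np.where(np.asarray(mobile)[:, None], disp, 0.0)
    return positions + disp, int(np.count_nonzero(capped))


def divide_cell(cell: Cell, axis: np.ndarray, rng: np.random.Generator,
                mean_cycle: float = 268.0, jitter: float = 0.2,
                next_stream: int = None) -> tuple[Cell, Cell]:
    """Split a mother cell into two daughters.

    Daughters sit at +-0.5*r*axis from the mother; radii scale by 2^(-1/3)
    (volume conserved); protein *concentrations* (not amounts) are inherited
    unchanged; cycle phases restart with independently jittered periods drawn
    from the supplied generator.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    r = cell.radius
    scale = 2.0 ** (-1.0 / 3.0)
    radii = (cell.radii[0] * scale, cell.radii[1] * scale)
    if next_stream is None:
        next_stream = cell.rng_stream
    daughters = []
    for k, sign in enumerate((+1.0, -1.0)):
        daughters.append(Cell(
            id=-1,  # caller assigns ids
            position=cell.position + sign * 0.5 * r * axis,
            radii=radii,
            archetype=cell.archetype,
            polarization_axis=None if cell.polarization_axis is None
            else cell.polarization_axis.copy(),
            apicobasal_axis=None if cell.apicobasal_axis is None
            else cell.apicobasal_axis.copy(),
            proteins=dict(cell.proteins),
            gene_activity=dict(cell.gene_activity),
            receptors=dict(cell.receptors),
            surface_ligands=dict(cell.surface_ligands),
            adhesion_density=dict(cell.adhesion_density),
            cycle_phase=float(-rng.normal(0.0, jitter)),  # jittered restart
            rng_stream=cell.rng_stream if k == 0 else next_stream,
        ))
    return daughters[0], daughters[1]


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - probability ~0
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n
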