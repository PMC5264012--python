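"""Simulation engine: array-based state and the fixed per-step operator order.

One step advances the tissue by dt minutes in this frozen order:

  1. rebuild the topological contact graph,
  2. CBO coupling pass (archetypes -> polarization axes -> noise ->
     apicobasal axes -> behaviour flags),
  3. genetics (secretion, transduction, Boolean-gated production, reactions,
     degradation) in ``genetics_substeps`` Euler substeps,
  4. extracellular diffusion/decay per ligand, with optional Dirichlet
     clamping on a body population (e.g. a constant source on the EVL),
  5. force assembly (attraction-repulsion, planarity, protrusion) and
     overdamped integration,
  6. cell division,
  7. scheduled events and time advance.

All randomness (polarization noise, division timing and axes) derives from
the single master seed through counter-based per-cell substreams, so a run
is bitwise reproducible and noise draws are independent of cell iteration
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from . import coupling_cbo, mechanics, transport
from .genetics import CompiledGRN, grn_substep
from .neighbourhood import ContactGraph, build_contact_graph
from .state_core import (ARCHETYPES, BodyParticle, Cell, GRNSpec, LigandField,
                         SimConfig, Tissue, Trajectory, cell_rng)

_NOISE_TAG = 1_000_000
_DIVISION_TAG = 2_000_000
_PHASE_TAG = 2_500_000


def _region_mask(region, positions: np.ndarray) -> np.ndarray:
    """Evaluate a region spec dict against cell positions."""
    n = len(positions)
    if region is None or region == "all" or region.get("all"):
        return np.ones(n, dtype=bool)
    if "ball" in region:
        c = np.asarray(region["ball"]["center"], dtype=float)
        r = float(region["ball"]["radius"])
        return np.linalg.norm(positions - c, axis=1) <= r
    if "halfspace" in region:
        hs = region["halfspace"]
        ax = {"x": 0, "y": 1, "z": 2}[hs.get("axis", "x")]
        if "below" in hs:
            return positions[:, ax] < float(hs["below"])
        return positions[:, ax] > float(hs["above"])
    raise ValueError(f"unknown region spec {region!r}")


@dataclass
class StepHealth:
    time: float
    max_displacement: float
    capped: int
    ligand_mass: dict
    archetype_census: dict


class SimState:
    """Mutable array-based simulation state (cells first, bodies after)."""

    def __init__(self, tissue: Tissue, grn: GRNSpec, config: SimConfig):
        self.config = config
        self.grn = CompiledGRN.compile(grn)
        self.master_seed = config.seed
        cells, bodies = tissue.cells, tissue.bodies
        self.n_bodies = len(bodies)
        self.pos = tissue.positions()
        self.radii = tissue.radii_array()
        self.body_kind = [b.body for b in bodies]
        self.cell_ids = np.array([c.id for c in cells], dtype=int)
        self.next_id = int(self.cell_ids.max()) + 1 if len(cells) else 0
        self.streams = np.array([c.rng_stream for c in cells], dtype=int)
        self.next_stream = int(self.streams.max()) + 1 if len(cells) else 0
        self.division_count = np.zeros(len(cells), dtype=int)
        self.radius_target = tissue.radii_array(include_bodies=False).copy()

        S = self.grn.n_species
        self.P = np.zeros((len(cells), S))
        kinds = {s.name: s.kind for s in grn.species}
        for i, c in enumerate(cells):
            for name, j in self.grn.index.items():
                for dct in (c.proteins, c.receptors, c.surface_ligands):
                    if name in dct:
                        self.P[i, j] = dct[name]
        self._kinds = kinds
        L = len(self.grn.diffusible)
        self.Q = np.zeros((len(self.pos), L))
        for name, j in self.grn.diffusible_index.items():
            fld = tissue.ligand_fields.get(name)
            if fld is not None:
                idx = {int(nid): k for k, nid in enumerate(self._node_ids())}
                for nid, v in fld.q.items():
                    if nid in idx:
                        self.Q[idx[nid], j] = v
        self.G = np.zeros((len(cells), len(grn.genes)), dtype=bool)

        nc = len(cells)
        self.archetype = np.array([c.archetype for c in cells], dtype=object)
        self.e_pop = np.full(nc, -1, dtype=int)
        self.U = np.full((nc, 3), np.nan)
        self.A = np.full((nc, 3), np.nan)
        for i, c in enumerate(cells):
            if c.polarization_axis is not None:
                self.U[i] = c.polarization_axis
            if c.apicobasal_axis is not None:
                self.A[i] = c.apicobasal_axis
        self.U_eff = self.U.copy()
        self.protruding = np.zeros(nc, dtype=bool)
        self.planar = np.zeros(nc, dtype=bool)

        self.cycle_phase = np.array([c.cycle_phase for c in cells])
        dv = config.division
        if dv.enabled:
            # fresh cells (phase exactly 0) start at a random point of the
            # cycle, drawn from the run seed via the cell's substream
            for i, c in enumerate(cells):
                if self.cycle_phase[i] == 0.0:
                    self.cycle_phase[i] = cell_rng(
                        self.master_seed, int(c.rng_stream), _PHASE_TAG
                    ).uniform(0.0, 1.0)
            self.cycle_len = np.array([
                self._draw_cycle_len(int(c.rng_stream), 0) for c in cells])
        else:
            self.cycle_len = np.full(nc, np.inf)

        # adhesion molecule matrices (declared-name presence + density)
        mols = sorted({m for c in cells for m in c.adhesion_density})
        self.adhesion_molecules = mols
        self.AD = np.zeros((nc, len(mols)))
        self.AD_declared = np.zeros((nc, len(mols)), dtype=bool)
        for i, c in enumerate(cells):
            for j, m in enumerate(mols):
                if m in c.adhesion_density:
                    self.AD[i, j] = c.adhesion_density[m]
                    self.AD_declared[i, j] = True

        self.time = float(tissue.time)
        self.graph: ContactGraph = None
        self.forces: mechanics.ForceAccumulator = None
        self._stress = None  # per-cell compressive stress, previous step
        self._noise_cache = {}  # (interval k) -> dict stream -> xi
        self._applied_events = set()
        self.health: list[StepHealth] = []
        self.cap_warnings = 0

        self._w_class_index = {a: i for i, a in enumerate(
            list(ARCHETYPES) + ["yolk_membrane", "yolk_interior", "EVL"])}
        mp = config.mechanics
        k = len(self._w_class_index)
        self._w_matrix = np.full((k, k), mp.w_default)
        for key, val in mp.w.items():
            a, b = key.split(":")
            ia, ib = self._w_class_index[a], self._w_class_index[b]
            self._w_matrix[ia, ib] = self._w_matrix[ib, ia] = val

        self.mobile = np.ones(len(self.pos), dtype=bool)
        for bi, kind in enumerate(self.body_kind):
            if kind in config.anchored_bodies:
                self.mobile[nc + bi] = False

        self._apply_events(config.init, force=True)

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def _node_ids(self):
        return np.concatenate([self.cell_ids,
                               np.arange(self.n_bodies) + 10_000_000])

    def _draw_cycle_len(self, stream: int, count: int) -> float:
        dv = self.config.division
        rng = cell_rng(self.master_seed, stream, _DIVISION_TAG + count)
        return max(0.2 * dv.mean_cycle,
                   dv.mean_cycle * (1.0 + dv.jitter * rng.standard_normal()))

    def _apply_events(self, events, force=False):
        for k, ev in enumerate(events):
            key = (id(events), k)
            if not force:
                if key in self._applied_events or self.time + 1e-9 < ev.get("time", 0.0):
                    continue
                self._applied_events.add(key)
            spec = ev.get("set_species", ev)
            name = spec["species"]
            mask = _region_mask(spec.get("region"), self.pos[: self.n_cells])
            self.P[mask, self.grn.index[name]] = float(spec["value"])

    # ------------------------------------------------------------------
    # CBO coupling pass
    # ------------------------------------------------------------------
    def _noise_xi(self, k: int) -> dict:
        cache = self._noise_cache.get(k)
        if cache is None:
            cache = {}
            self._noise_cache = {k: cache}  # keep only the current interval
        return cache

    def _effective_axis(self, i: int, u: np.ndarray) -> np.ndarray:
        lam = self.config.behaviour.lambda_ran
        if lam == 0.0:
            return u
        period = self.config.behaviour.repolarization_period
        k = int(np.floor(self.time / period + 1e-9))
        cache = self._noise_xi(k)
        stream = int(self.streams[i])
        xi = cache.get(stream)
        if xi is None:
            rng = cell_rng(self.master_seed, stream, _NOISE_TAG + k)
            while True:
                xi = rng.uniform(-1.0, 1.0, size=3)
                if xi @ xi <= 1.0:
                    break
            cache[stream] = xi
        v = u + lam * xi
        n = np.linalg.norm(v)
        return v / n if n > 1e-12 else u

    def cbo_update(self):
        """One full coupling pass (archetype -> axes -> noise -> flags)."""
        nc = self.n_cells
        grn = self.grn.spec
        pop = coupling_cbo.e_expression(self.P, grn, self.grn.index)
        reinforced = coupling_cbo.lateral_reinforcement(pop, self.graph, nc)
        arch = np.full(nc, "I", dtype=object)
        if grn.outputs.archetype_M is not None:
            m_mask = grn.outputs.archetype_M.evaluate_array(self.P, self.grn.index)
            arch[m_mask] = "M"
        arch[pop >= 0] = "I"  # unreinforced epithelial expression reverts to idle
        arch[reinforced] = "E"
        self.archetype = arch
        self.e_pop = np.where(reinforced, pop, -1)

        beh = grn.outputs.behaviour
        mode = beh.polarization_mode
        cfg = self.config.behaviour

        # --- polarization axes for mesenchymal cells
        m_idx = np.where(arch == "M")[0]
        if len(m_idx):
            if mode == "chemotactic" and beh.guidance_ligand is not None:
                qcol = self.Q[:, self.grn.diffusible_index[beh.guidance_ligand]]
                grads = transport.ligand_gradients_all(self.pos, qcol, self.graph, nc)
                for i in m_idx:
                    g = grads[i]
                    if np.linalg.norm(g) > 1e-12:
                        self.U[i] = g
            elif mode == "propagation":
                prox = {(min(a, b), max(a, b)): s
                        for (a, b), s in zip(self.graph.edges, self.graph.proxy)}
                newU = self.U.copy()
                for i in m_idx:
                    prev = self.U[i] if np.isfinite(self.U[i]).all() else None
                    ax = coupling_cbo.propagation_axis(i, self.U, self.graph, prox, prev)
                    if np.linalg.norm(ax) > 1e-12:
                        newU[i] = ax
                self.U = newU
            elif mode == "protrusion_induced" and self.forces is not None:
                for i in m_idx:
                    prev = self.U[i] if np.isfinite(self.U[i]).all() else None
                    ax = coupling_cbo.protrusion_induced_axis(
                        i, self.forces.F_pro_ext, prev)
                    if np.linalg.norm(ax) > 1e-12:
                        self.U[i] = ax
            elif mode == "blebbing":
                for i in m_idx:
                    if not np.isfinite(self.U[i]).all():
                        self.U[i] = np.array([0.0, 0.0, 1.0])
            # noise -> effective axes
            for i in m_idx:
                if np.isfinite(self.U[i]).all():
                    if mode == "blebbing":
                        # pure-noise axis: the lambda_ran-only limit
                        self.U_eff[i] = self._effective_axis(i, np.zeros(3)) \
                            if cfg.lambda_ran > 0 else self.U[i]
                    else:
                        self.U_eff[i] = self._effective_axis(i, self.U[i])

        # --- epithelial polarization (chemotactic along per-population guidance)
        cell_edges = self.graph.edges[(self.graph.edges < nc).all(axis=1)] \
            if len(self.graph.edges) else np.zeros((0, 2), dtype=int)
        cell_graph = ContactGraph(
            n=nc, edges=cell_edges,
            dist=np.linalg.norm(self.pos[cell_edges[:, 0]] - self.pos[cell_edges[:, 1]],
                                axis=1) if len(cell_edges) else np.zeros(0),
            proxy=np.zeros(len(cell_edges)))
        for popk, ep in enumerate(grn.outputs.archetype_E):
            idx = np.where((self.e_pop == popk))[0]
            if not len(idx) or ep.guidance_ligand is None:
                continue
            if ep.guidance_source == "local_field":
                vals = self.Q[:, self.grn.diffusible_index[ep.guidance_ligand]]
                g_graph = self.graph
            else:
                vals = self.P[:, self.grn.index[ep.guidance_ligand]]
                g_graph = cell_graph
            for i in idx:
                prev = self.U[i] if np.isfinite(self.U[i]).all() else None
                ax = coupling_cbo.chemotactic_axis(i, self.pos, vals, g_graph, prev)
                if np.linalg.norm(ax) > 1e-12:
                    self.U[i] = ax
                    self.U_eff[i] = ax

        # --- apicobasal axes for reinforced epithelial cells
        self.planar[:] = False
        adj = self.graph.adjacency()
        for i in np.where(arch == "E")[0]:
            same = np.array([j for j in adj[i]
                             if j < nc and self.e_pop[j] == self.e_pop[i]], dtype=int)
            if len(same) < 3:
                continue
            try:
                self.A[i] = coupling_cbo.apicobasal_axis(
                    i, self.pos, same, all_neighbour_ids=np.array(adj[i]))
                self.planar[i] = True
            except ValueError:
                continue

        phi = cfg.phi if cfg.phi is not None else beh.phi
        self.protruding = (arch == "M") & np.isfinite(self.U_eff).all(axis=1) & (phi > 0)

    # ------------------------------------------------------------------
    # genetics + transport
    # ------------------------------------------------------------------
    def _cell_proxy_matrix(self) -> sparse.csr_matrix:
        nc = self.n_cells
        e = self.graph.edges
        mask = (e < nc).all(axis=1) if len(e) else np.zeros(0, dtype=bool)
        e = e[mask]
        s = self.graph.proxy[mask]
        W = sparse.coo_matrix(
            (np.concatenate([s, s]),
             (np.concatenate([e[:, 0], e[:, 1]]),
              np.concatenate([e[:, 1], e[:, 0]]))), shape=(nc, nc))
        return W.tocsr()

    def genetics_step(self):
        if self.grn.n_species == 0:
            return
        m = self.config.genetics_substeps
        h = self.config.dt / m
        W = self._cell_proxy_matrix() if any(
            t.source == "neighbour_surface" for t in self.grn.spec.transductions) else None
        extra = None
        mt = self.config.mechanotransduction
        if mt.species is not None and self._stress is not None:
            extra = np.zeros_like(self.P)
            extra[:, self.grn.index[mt.species]] = mt.coefficient * self._stress
        for _ in range(m):
            self.G = grn_substep(self.P, self.Q, self.grn, h, W, extra)

    def transport_step(self):
        vols = transport.nominal_volume(self.radii)
        nc = self.n_cells
        for name, params in self.config.transport.items():
            j = self.grn.diffusible_index[name]
            if params.clamp_body is not None:
                mask = np.array([k == params.clamp_body for k in self.body_kind])
                idx = nc + np.where(mask)[0]
                self.Q[idx, j] = params.clamp_value
            self.Q[:, j] = transport.diffusion_step(
                self.graph, self.Q[:, j], params.D, params.gamma, vols, self.config.dt)
            if params.clamp_body is not None:
                self.Q[idx, j] = params.clamp_value

    # ------------------------------------------------------------------
    # mechanics
    # ------------------------------------------------------------------
    def _edge_w(self, edges: np.ndarray) -> np.ndarray:
        classes = np.array(
            [self._w_class_index[a] for a in self.archetype]
            + [self._w_class_index[k] for k in self.body_kind], dtype=int)
        base = self._w_matrix[classes[edges[:, 0]], classes[edges[:, 1]]]
        if self.adhesion_molecules:
            nc = self.n_cells
            cc = (edges < nc).all(axis=1)
            if cc.any():
                i, jj = edges[cc, 0], edges[cc, 1]
                mn = np.minimum(self.AD[i], self.AD[jj])
                decl = self.AD_declared[i] | self.AD_declared[jj]
                cnt = decl.sum(axis=1)
                fac = np.where(cnt > 0, (mn * decl).sum(axis=1) / np.maximum(cnt, 1), 1.0)
                base = base.copy()
                base[cc] = base[cc] * fac
        return base

    def assemble_forces(self) -> mechanics.ForceAccumulator:
        mp = self.config.mechanics
        nc = self.n_cells
        N = len(self.pos)
        acc = mechanics.ForceAccumulator(N)
        e = self.graph.edges
        if len(e) == 0:
            self.forces = acc
            return acc
        i, j = e[:, 0], e[:, 1]
        offs = self.pos[j] - self.pos[i]
        d = self.graph.dist
        dirs = offs / d[:, None]
        w = self._edge_w(e)
        f = mechanics.attraction_repulsion_magnitude(
            d, self.radii[i], self.radii[j], w, mp.k_rep, mp.c_eq, mp.c_max)
        fv = f[:, None] * dirs
        np.add.at(acc.F_ar, i, fv)
        np.add.at(acc.F_ar, j, -fv)
        if self._stress is not None or self.config.mechanotransduction.species:
            stress = np.zeros(nc)
            rep = np.where(f < 0, -f, 0.0)
            np.add.at(stress, i[i < nc], rep[i < nc])
            cm = j < nc
            np.add.at(stress, j[cm], rep[cm])
            self._stress = stress

        # planarity: directed actor->target pairs among same-population E cells
        if self.planar.any():
            de = np.concatenate([e, e[:, ::-1]])
            a_i, t_i = de[:, 0], de[:, 1]
            mask = (a_i < nc) & (t_i < nc)
            mask &= np.where(mask, self.planar[np.clip(a_i, 0, nc - 1)], False)
            sub_a, sub_t = a_i[mask], t_i[mask]
            same = (self.e_pop[sub_a] == self.e_pop[sub_t]) & (self.e_pop[sub_t] >= 0)
            sub_a, sub_t = sub_a[same], sub_t[same]
            if len(sub_a):
                A = self.A[sub_a]
                h = np.sum((self.pos[sub_t] - self.pos[sub_a]) * A, axis=1)
                fpl = -mp.k_plan * h[:, None] * A
                np.add.at(acc.F_plan, sub_t, fpl)
                np.add.at(acc.F_plan, sub_a, -fpl)

        # protrusion: actor M cells act on polar-domain cell neighbours
        if self.protruding.any():
            cfg = self.config.behaviour
            beh = self.grn.spec.outputs.behaviour
            phi = cfg.phi if cfg.phi is not None else beh.phi
            polarity = (cfg.protrusion_polarity if cfg.protrusion_polarity is not None
                        else beh.protrusion_polarity)
            de = np.concatenate([e, e[:, ::-1]])
            dw = np.concatenate([w, w])
            a_i, t_i = de[:, 0], de[:, 1]
            mask = (a_i < nc) & (t_i < nc)
            mask &= np.where(mask, self.protruding[np.clip(a_i, 0, nc - 1)], False)
            sub_a, sub_t, sub_w = a_i[mask], t_i[mask], dw[mask]
            if len(sub_a):
                u = self.U_eff[sub_a]
                offs2 = self.pos[sub_t] - self.pos[sub_a]
                nrm = np.linalg.norm(offs2, axis=1)
                c = np.sum(offs2 * u, axis=1) / np.where(nrm > 0, nrm, 1.0)
                cos_cut = np.cos(mp.cone_half_angle)
                side = np.zeros(len(sub_a))
                side[c >= cos_cut] = 1.0
                if polarity == "bi":
                    side[-c >= cos_cut] = -1.0
                coef = side * phi * sub_w
                fp = coef[:, None] * u
                np.add.at(acc.F_pro_int, sub_a, fp)
                np.add.at(acc.F_pro_ext, sub_t, -fp)
        self.forces = acc
        return acc

    def mechanics_step(self):
        acc = self.assemble_forces()
        newpos, capped = mechanics.integrate_step(
            self.pos, acc.F_total, self.config.lam, self.config.dt,
            self.radii, self.mobile)
        if capped > 0.1 * len(self.pos):
            self.cap_warnings += 1
        maxd = float(np.max(np.linalg.norm(newpos - self.pos, axis=1))) \
            if len(self.pos) else 0.0
        self.pos = newpos
        return maxd, capped

    # ------------------------------------------------------------------
    # division
    # ------------------------------------------------------------------
    def division_step(self):
        dv = self.config.division
        if not dv.enabled:
            return 0
        nc0 = self.n_cells
        # daughters regrow toward the mother's pre-division size, so the
        # tissue gains volume over a cycle (otherwise division would only
        # subdivide a fixed mass)
        if dv.growth_rate > 0:
            self.radii[:nc0] += dv.growth_rate * self.config.dt * (
                self.radius_target - self.radii[:nc0])
        self.cycle_phase += self.config.dt / self.cycle_len
        ready = np.where(self.cycle_phase >= 1.0)[0]
        for i in ready:
            stream = int(self.streams[i])
            count = int(self.division_count[i])
            rng = cell_rng(self.master_seed, stream, _DIVISION_TAG + 1 + count)
            if dv.oriented and np.isfinite(self.U[i]).all():
                axis = self.U[i]
            else:
                axis = mechanics.random_unit_vector(rng)
            r = self.radii[i]
            scale = 2.0 ** (-1.0 / 3.0)
            p1 = self.pos[i] + 0.5 * r * axis
            p2 = self.pos[i] - 0.5 * r * axis
            new_stream = self.next_stream
            self.next_stream += 1
            # daughter 1 replaces the mother row
            self.pos[i] = p1
            self.radii[i] *= scale
            self.cycle_phase[i] = 0.0
            self.division_count[i] = count + 1
            self.cycle_len[i] = self._draw_cycle_len(stream, count + 1)
            # daughter 2 appended at the end of the cell block
            nc = self.n_cells
            self.pos = np.insert(self.pos, nc, p2, axis=0)
            self.radii = np.insert(self.radii, nc, self.radii[i])
            self.mobile = np.insert(self.mobile, nc, True)
            self.Q = np.insert(self.Q, nc, self.Q[i], axis=0)
            self.P = np.vstack([self.P, self.P[i][None, :]])
            self.G = np.vstack([self.G, self.G[i][None, :]])
            self.radius_target = np.append(self.radius_target,
                                           self.radius_target[i])
            self.cell_ids = np.append(self.cell_ids, self.next_id)
            self.next_id += 1
            self.streams = np.append(self.streams, new_stream)
            self.division_count = np.append(self.division_count, 0)
            self.cycle_phase = np.append(self.cycle_phase, 0.0)
            self.cycle_len = np.append(self.cycle_len,
                                       self._draw_cycle_len(new_stream, 0))
            self.archetype = np.append(self.archetype, self.archetype[i])
            self.e_pop = np.append(self.e_pop, self.e_pop[i])
            self.U = np.vstack([self.U, self.U[i][None, :]])
            self.U_eff = np.vstack([self.U_eff, self.U_eff[i][None, :]])
            self.A = np.vstack([self.A, self.A[i][None, :]])
            self.protruding = np.append(self.protruding, self.protruding[i])
            self.planar = np.append(self.planar, False)
            if len(self.adhesion_molecules):
                self.AD = np.vstack([self.AD, self.AD[i][None, :]])
                self.AD_declared = np.vstack([self.AD_declared,
                                              self.AD_declared[i][None, :]])
        return len(ready)

    # ------------------------------------------------------------------
    def step(self):
        mp = self.config.mechanics
        self._apply_events(self.config.schedule)
        self.graph = build_contact_graph(self.pos, self.radii, mp.c_max, mp.c_eq)
        self.cbo_update()
        self.genetics_step()
        self.transport_step()
        maxd, capped = self.mechanics_step()
        self.division_step()
        self.time += self.config.dt
        return maxd, capped

    def record_health(self, maxd: float, capped: int):
        vols = transport.nominal_volume(self.radii)
        mass = {name: transport.total_mass(self.Q[:, j], vols)
                for name, j in self.grn.diffusible_index.items()}
        census = {a: int(np.count_nonzero(self.archetype == a)) for a in ARCHETYPES}
        self.health.append(StepHealth(self.time, maxd, capped, mass, census))

    # ------------------------------------------------------------------
    def to_tissue(self) -> Tissue:
        nc = self.n_cells
        cells = []
        for i in range(nc):
            proteins, receptors, surf = {}, {}, {}
            for name, j in self.grn.index.items():
                k = self._kinds[name]
                if k == "receptor":
                    receptors[name] = float(self.P[i, j])
                elif k == "surface_ligand":
                    surf[name] = float(self.P[i, j])
                else:
                    proteins[name] = float(self.P[i, j])
            ga = {g.name: int(self.G[i, gi])
                  for gi, g in enumerate(self.grn.spec.genes)}
            ad = {m: float(self.AD[i, j]) for j, m in enumerate(self.adhesion_molecules)
                  if self.AD_declared[i, j]}
            u = self.U[i] if np.isfinite(self.U[i]).all() else None
            a = self.A[i] if (np.isfinite(self.A[i]).all() and self.planar[i]) else None
            r = float(self.radii[i])
            cells.append(Cell(
                id=int(self.cell_ids[i]), position=self.pos[i].copy(),
                radii=(r, r), archetype=str(self.archetype[i]),
                polarization_axis=None if u is None else u / np.linalg.norm(u),
                apicobasal_axis=None if a is None else a / np.linalg.norm(a),
                proteins=proteins, gene_activity=ga, receptors=receptors,
                surface_ligands=surf, adhesion_density=ad,
                cycle_phase=float(self.cycle_phase[i] % 1.0),
                rng_stream=int(self.streams[i])))
        bodies = [BodyParticle(id=10_000_000 + bi, position=self.pos[nc + bi].copy(),
                               body=self.body_kind[bi],
                               radius=float(self.radii[nc + bi]))
                  for bi in range(self.n_bodies)]
        fields = {}
        node_ids = self._node_ids()
        for name, j in self.grn.diffusible_index.items():
            params = self.config.transport.get(name)
            fields[name] = LigandField(
                name=name,
                q={int(node_ids[k]): float(self.Q[k, j]) for k in range(len(node_ids))},
                D=params.D if params else 0.0,
                gamma=params.gamma if params else 0.0)
        return Tissue(cells=cells, bodies=bodies, time=self.time,
                      ligand_fields=fields)


def dump_forces_csv(state: SimState, path) -> None:
    """Debug export of per-particle force channels (id, channel, fx, fy, fz)."""
    acc = state.forces if state.forces is not None else state.assemble_forces()
    ids = state._node_ids()
    with open(path, "w") as fh:
        fh.write("id,channel,fx,fy,fz\n")
        for name in ("F_ar", "F_plan", "F_pro_int", "F_pro_ext"):
            arr = getattr(acc, name)
            for pid, f in zip(ids, arr):
                fh.write(f"{pid},{name},{f[0]!r},{f[1]!r},{f[2]!r}\n")


def run_simulation(tissue: Tissue, grn: GRNSpec, config: SimConfig,
                   progress=None) -> Trajectory:
    """Run the configured number of steps, collecting snapshots."""
    state = SimState(tissue, grn, config)
    n_steps = int(round(config.duration / config.dt))
    snap_stride = max(1, int(round(config.snapshot_every / config.dt)))
    snaps = [state.to_tissue()]
    for s in range(n_steps):
        maxd, capped = state.step()
        if (s + 1) % snap_stride == 0 or s == n_steps - 1:
            state.record_health(maxd, capped)
            snaps.append(state.to_tissue())
        if progress is not None:
            progress(s, n_steps)
    return Trajectory(snapshots=snaps, config=config, grn=grn, seed=config.seed,
                      provenance={"n_steps": n_steps,
                                  "cap_warnings": state.cap_warnings})
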