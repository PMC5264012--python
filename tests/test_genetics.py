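"""GRN dynamics: Boolean gating, mass action, secretion, transduction."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy import sparse

from morphosim import genetics
from morphosim.genetics import CompiledGRN, evaluate_logic, grn_step, secrete, transduce
from morphosim.state_core import (Cell, GeneDef, GRNSpec, ReactionDef,
                                  SecretionDef, SpeciesDef, TransductionDef,
                                  parse_logic)


def make_cell(**proteins):
    c = Cell(id=0, position=np.zeros(3))
    c.proteins.update(proteins)
    return c


class TestEvaluateLogic:
    def test_activator_repressor_switch(self):
        # upregulated by the Tcf+ complex, downregulated by Tcf-
        logic = parse_logic("(TcfPlus>=0.5) & !(TcfMinus>=0.3)")
        assert evaluate_logic(logic, {"TcfPlus": 1.0, "TcfMinus": 0.0}) == 1
        assert evaluate_logic(logic, {"TcfPlus": 1.0, "TcfMinus": 1.0}) == 0

    def test_positive_atoms_false_at_zero(self):
        logic = parse_logic("(A>=0.1) | (B>=0.2)")
        assert evaluate_logic(logic, {"A": 0.0, "B": 0.0}) == 0

    def test_missing_species_names_atom(self):
        with pytest.raises(KeyError, match="Gone"):
            evaluate_logic(parse_logic("Gone>=1.0"), {"A": 1.0})


class TestGrnStep:
    def test_pure_degradation_decays_to_zero(self):
        grn = GRNSpec(species=[SpeciesDef("A", degradation_rate=0.5)])
        cell = make_cell(A=1.0)
        for _ in range(400):
            grn_step(cell, grn, {}, 0.05)
        assert cell.proteins["A"] < 1e-4

    def test_mass_action_step_matches_hand_formula(self):
        grn = GRNSpec(species=[SpeciesDef("Tcf"), SpeciesDef("Bcat"),
                               SpeciesDef("TcfPlus", kind="complex")],
                      reactions=[ReactionDef(("Tcf", "Bcat"), "TcfPlus", 0.4)])
        cell = make_cell(Tcf=2.0, Bcat=1.5, TcfPlus=0.0)
        dt = 0.01
        grn_step(cell, grn, {}, dt)
        flux = 0.4 * 2.0 * 1.5 * dt
        assert cell.proteins["TcfPlus"] == pytest.approx(flux)
        assert cell.proteins["Tcf"] == pytest.approx(2.0 - flux)
        assert cell.proteins["Bcat"] == pytest.approx(1.5 - flux)

    def test_catalysed_degradation_spares_the_enzyme(self):
        grn = GRNSpec(species=[SpeciesDef("XIAP"), SpeciesDef("Gro")],
                      reactions=[ReactionDef(("XIAP", "Gro"), None, 1.0,
                                             consume=(False, True))])
        cell = make_cell(XIAP=1.0, Gro=1.0)
        grn_step(cell, grn, {}, 0.1)
        assert cell.proteins["XIAP"] == pytest.approx(1.0)
        assert cell.proteins["Gro"] == pytest.approx(0.9)

    def test_toggle_network_euler_matches_stiff_reference(self, toggle_parts):
        """Steady state of the full toggle network at fixed extracellular Wnt:
        explicit Euler at dt=0.01 vs an independent LSODA integration, < 1%."""
        _, cfg, grn = toggle_parts
        comp = CompiledGRN.compile(grn)
        q_wnt = 0.8
        init = {"One": 1.0, "Rec": 1.0, "Tcf": 1.0, "Gro": 1.0, "TcfMinus": 1.0}

        # --- independent right-hand side written directly from the rule set
        names = comp.species
        idx = comp.index

        def rhs(t, p):
            dp = np.zeros_like(p)
            for s in (s for s in grn.secretions):
                a = s.rate * p[idx[s.protein]]
                if s.conversion:
                    dp[idx[s.protein]] -= a
            for tr in grn.transductions:
                dp[idx[tr.messenger]] += tr.rate * q_wnt * p[idx[tr.receptor]]
            for g in grn.genes:
                if g.logic is not None and g.logic.evaluate(
                        {n: p[idx[n]] for n in names}):
                    dp[idx[g.product_species]] += g.production_rate
            for r in grn.reactions:
                a, b = idx[r.reactants[0]], idx[r.reactants[1]]
                flux = r.rate * p[a] * p[b]
                if r.consume[0]:
                    dp[a] -= flux
                if r.consume[1]:
                    dp[b] -= flux
                if r.product is not None:
                    dp[idx[r.product]] += flux
            dp -= comp.degradation * p
            return dp

        p0 = np.zeros(comp.n_species)
        for k, v in init.items():
            p0[idx[k]] = v
        T = 150.0
        ref = solve_ivp(rhs, (0, T), p0, method="LSODA", rtol=1e-8, atol=1e-10).y[:, -1]

        cell = make_cell(**init)
        cell.receptors["Rec"] = 1.0
        steps = int(T / 0.01)
        comp_cell = CompiledGRN.compile(grn)
        P = np.zeros((1, comp.n_species))
        for k, v in init.items():
            P[0, idx[k]] = v
        Q = np.zeros((1, len(comp.diffusible)))
        Q[0, comp.diffusible_index["WntLig"]] = q_wnt
        for _ in range(steps):
            genetics.grn_substep(P, Q, comp_cell, 0.01)
            Q[0, comp.diffusible_index["WntLig"]] = q_wnt  # clamped exposure
        for name in ("TcfPlus", "TcfMinus", "Target", "Gro"):
            r = ref[idx[name]]
            tol = max(0.01 * abs(r), 5e-3)
            assert abs(P[0, idx[name]] - r) < tol, name

    def test_first_order_convergence_in_dt(self):
        grn = GRNSpec(
            species=[SpeciesDef("A", degradation_rate=0.3), SpeciesDef("B",
                     degradation_rate=0.1), SpeciesDef("One")],
            genes=[GeneDef("gA", "A", parse_logic("One>=0.5"), 1.0)],
            reactions=[ReactionDef(("A", "A"), "B", 0.2)])

        def final(dt):
            cell = make_cell(One=1.0, A=0.1, B=0.0)
            for _ in range(int(round(20.0 / dt))):
                grn_step(cell, grn, {}, dt)
            return np.array([cell.proteins["A"], cell.proteins["B"]])

        exact = final(0.001)
        e1 = np.abs(final(0.08) - exact).max()
        e2 = np.abs(final(0.04) - exact).max()
        assert e2 < 0.65 * e1

    def test_non_negativity_under_dt_bound(self):
        grn = GRNSpec(species=[SpeciesDef("A", degradation_rate=2.0),
                               SpeciesDef("B", degradation_rate=0.0)],
                      reactions=[ReactionDef(("A", "B"), None, 3.0)])
        rng = np.random.default_rng(0)
        for _ in range(20):
            cell = make_cell(A=float(rng.uniform(0, 5)), B=float(rng.uniform(0, 5)))
            for _ in range(200):
                grn_step(cell, grn, {}, 0.05)
                assert all(v >= 0 for v in cell.proteins.values())


class TestTransduce:
    def grn(self):
        return GRNSpec(
            species=[SpeciesDef("Delta", kind="surface_ligand"),
                     SpeciesDef("Notch", kind="receptor"),
                     SpeciesDef("M", kind="messenger")],
            transductions=[TransductionDef("Delta", "Notch", "M", 2.0,
                                           source="neighbour_surface")])

    def test_no_receptor_no_messenger(self):
        cell = make_cell()
        cell.receptors["Notch"] = 0.0
        assert transduce(cell, self.grn(), {"Delta": 5.0}, 0.1)["M"] == 0.0

    def test_no_ligand_no_messenger(self):
        cell = make_cell()
        cell.receptors["Notch"] = 1.0
        assert transduce(cell, self.grn(), {"Delta": 0.0}, 0.1)["M"] == 0.0

    def test_single_neighbour_contact_weighted_mean(self):
        """One Delta-bearing neighbour with contact proxy s among several
        blank contacts: messenger input is s*Delta/sum(s) (hand summation)."""
        W = sparse.csr_matrix(np.array([[0.0, 3.0, 7.0], [3.0, 0, 0], [7.0, 0, 0]]))
        L = np.array([0.0, 4.0, 0.0])
        mean = genetics.neighbour_surface_mean(W, L)
        assert mean[0] == pytest.approx(3.0 * 4.0 / (3.0 + 7.0))

    def test_isolated_cell_sees_zero_surface_signal(self):
        W = sparse.csr_matrix(np.zeros((2, 2)))
        assert np.allclose(genetics.neighbour_surface_mean(W, np.array([1.0, 1.0])), 0)


class TestSecrete:
    def grn(self, rate=0.5, conversion=True):
        return GRNSpec(
            species=[SpeciesDef("Wnt"), SpeciesDef("WntLig", kind="diffusible_ligand")],
            secretions=[SecretionDef("Wnt", "WntLig", rate, conversion=conversion)])

    def test_zero_rate_changes_nothing(self):
        cell = make_cell(Wnt=2.0)
        assert secrete(cell, self.grn(rate=0.0), 0.5) == {}
        assert cell.proteins["Wnt"] == 2.0

    def test_conversion_conserves_total(self):
        cell = make_cell(Wnt=2.0)
        out = secrete(cell, self.grn(), 0.1)
        assert out["WntLig"] == pytest.approx(2.0 - cell.proteins["Wnt"])

    def test_surface_mode_loads_membrane(self):
        grn = GRNSpec(species=[SpeciesDef("P"), SpeciesDef("Delta",
                                                           kind="surface_ligand")],
                      secretions=[SecretionDef("P", "Delta", 0.5, mode="surface")])
        cell = make_cell(P=1.0)
        secrete(cell, grn, 0.2)
        assert cell.surface_ligands["Delta"] == pytest.approx(0.1)

    def test_linear_chain_reaches_analytic_steady_state(self):
        """Constant production beta, secretion sigma, protein decay delta_p and
        extracellular decay gamma: q* = beta*sigma/((sigma+delta_p)*gamma)."""
        beta, sigma, delta_p, gamma = 1.0, 0.4, 0.1, 0.2
        grn = GRNSpec(
            species=[SpeciesDef("One"), SpeciesDef("P", degradation_rate=delta_p),
                     SpeciesDef("L", kind="diffusible_ligand")],
            genes=[GeneDef("gP", "P", parse_logic("One>=0.5"), beta)],
            secretions=[SecretionDef("P", "L", sigma)])
        comp = CompiledGRN.compile(grn)
        P = np.zeros((1, 3))
        P[0, comp.index["One"]] = 1.0
        Q = np.zeros((1, 1))
        dt = 0.01
        for _ in range(int(400 / dt)):
            genetics.grn_substep(P, Q, comp, dt)
            Q *= 1.0 - gamma * dt  # extracellular decay handled by transport
        q_star = beta * sigma / ((sigma + delta_p) * gamma)
        assert Q[0, 0] == pytest.approx(q_star, rel=0.01)
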