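"""Force laws, overdamped integration, division."""

import numpy as np
import pytest

from morphosim import mechanics as mech
from morphosim.state_core import Cell, cell_rng

K = dict(k_rep=1.0, c_eq=0.9, c_max=1.3)
EX = np.array([1.0, 0.0, 0.0])
EZ = np.array([0.0, 0.0, 1.0])


class TestAttractionRepulsion:
    def test_zero_at_equilibrium_distance(self):
        d_eq = 0.9 * 12.0
        f_i, f_j = mech.attraction_repulsion(d_eq, EX, 6.0, 6.0, 0.5, **K)
        assert np.allclose(f_i, 0) and np.allclose(f_j, 0)

    def test_pure_repulsion_pair_never_attracts(self):
        f_i, _ = mech.attraction_repulsion(12.0, EX, 6.0, 6.0, 0.0, **K)
        assert np.allclose(f_i, 0)

    def test_half_equilibrium_distance_gives_half_krep(self):
        d = 0.5 * 0.9 * 12.0
        f_i, f_j = mech.attraction_repulsion(d, EX, 6.0, 6.0, 0.5, **K)
        assert f_i[0] == pytest.approx(-0.5)  # repulsive: away from j
        assert np.allclose(f_i, -f_j)

    def test_vanishes_beyond_cutoff(self):
        f_i, _ = mech.attraction_repulsion(1.3 * 12.0 + 0.1, EX, 6.0, 6.0, 2.0, **K)
        assert np.allclose(f_i, 0)

    @pytest.mark.parametrize("d", np.linspace(4.0, 16.5, 12))
    def test_matches_numerical_derivative_of_potential(self, d):
        """Finite-difference oracle: signed force = dV/dd of the pair potential."""
        h = 1e-6
        args = (6.0, 6.0, 0.7, 1.2, 0.9, 1.3)
        dV = (mech.pair_potential(d + h, *args) - mech.pair_potential(d - h, *args)) / (2 * h)
        f = mech.attraction_repulsion_magnitude(d, *args)
        assert f == pytest.approx(dV, abs=1e-5)

    def test_coincident_centres_raise(self):
        with pytest.raises(ValueError, match="d_ij"):
            mech.attraction_repulsion(0.0, EX, 6.0, 6.0, 0.5, **K)


class TestPlanarity:
    def test_coplanar_sheet_is_force_free(self):
        offs = np.array([[1.0, 0, 0], [0, 1.0, 0], [-1, -1, 0.0]]) * 10
        f_i, f_n = mech.planarity_forces(offs, EZ, 1.0)
        assert np.allclose(f_i, 0) and np.allclose(f_n, 0)

    def test_displaced_neighbour_feels_restoring_force(self):
        offs = np.array([[10.0, 0.0, 2.0]])
        f_i, f_n = mech.planarity_forces(offs, EZ, 1.0)
        assert np.allclose(f_n[0], [0, 0, -2.0])
        assert np.allclose(f_i, [0, 0, 2.0])
        assert np.allclose(f_i + f_n.sum(axis=0), 0)

    def test_monolayer_flattens_under_integration(self):
        """Sum of squared out-of-plane offsets strictly decreases over 500 steps."""
        rng = np.random.default_rng(0)
        xs = np.arange(6) * 10.0
        pos = np.array([[x, y, 0.0] for x in xs for y in xs])
        pos[:, 2] += rng.normal(0, 1.0, len(pos))
        lam, dt, k_plan = 1.0, 0.05, 1.0
        sq = []
        for step in range(500):
            F = np.zeros_like(pos)
            for i in range(len(pos)):
                offs = np.delete(pos, i, axis=0) - pos[i]
                near = offs[np.linalg.norm(offs, axis=1) < 15.0]
                if len(near) == 0:
                    continue
                f_i, f_n = mech.planarity_forces(near, EZ, k_plan)
                F[i] += f_i
                idx = [j for j in range(len(pos)) if j != i
                       and np.linalg.norm(pos[j] - pos[i]) < 15.0]
                for k, j in enumerate(idx):
                    F[j] += f_n[k]
            pos = pos + F / lam * dt
            sq.append(float(np.sum((pos[:, 2] - pos[:, 2].mean()) ** 2)))
        # strictly decreasing until numerically flat, and essentially flat at the end
        above = [v for v in sq if v > 1e-8]
        assert all(b < a for a, b in zip(above, above[1:]))
        assert sq[-1] < 1e-3 * sq[0]

    def test_missing_axis_raises(self):
        with pytest.raises(ValueError, match="unpolarized"):
            mech.planarity_forces(np.zeros((2, 3)), np.array([np.nan] * 3), 1.0)


class TestPolarDomain:
    def test_neighbour_along_axis_always_included(self):
        side = mech.polar_domain(EZ, "mono", 0.05, np.array([[0, 0, 9.0]]))
        assert side[0] == 1

    def test_antipodal_excluded_in_mono_included_in_bi(self):
        off = np.array([[0, 0, -9.0]])
        assert mech.polar_domain(EZ, "mono", 0.8, off)[0] == 0
        assert mech.polar_domain(EZ, "bi", 0.8, off)[0] == -1

    def test_random_neighbours_match_brute_force_angles(self):
        rng = np.random.default_rng(5)
        offs = rng.normal(0, 10, size=(50, 3))
        cone = np.radians(45)
        side = mech.polar_domain(EZ, "bi", cone, offs)
        for k in range(50):
            ang = np.arccos(offs[k] @ EZ / np.linalg.norm(offs[k]))
            if ang <= cone:
                assert side[k] == 1
            elif np.pi - ang <= cone:
                assert side[k] == -1
            else:
                assert side[k] == 0


class TestProtrusion:
    def test_phi_zero_gives_no_force(self):
        f_int, f_ext = mech.protrusion_forces(EZ, np.array([1]), np.array([0.5]), 0.0)
        assert np.allclose(f_int, 0) and np.allclose(f_ext, 0)

    def test_single_pair_is_equal_and_opposite(self):
        f_int, f_ext = mech.protrusion_forces(EZ, np.array([1]), np.array([1.0]), 1.0)
        assert np.allclose(f_int[0], EZ)
        assert np.allclose(f_int[0] + f_ext[0], 0)

    def test_three_neighbour_resultant_matches_summation_oracle(self):
        # two polar-domain neighbours on the +u side, one on the -u side
        side = np.array([1, 1, -1])
        w = np.array([0.5, 0.25, 0.5])
        phi = 2.0
        f_int, f_ext = mech.protrusion_forces(EZ, side, w, phi)
        resultant = f_int.sum(axis=0)
        expected = phi * (0.5 + 0.25 - 0.5) * EZ  # hand summation
        assert np.allclose(resultant, expected)
        assert resultant[2] > 0  # +u side outweighs -u side
        assert np.allclose((f_int + f_ext).sum(axis=0), 0)

    def test_monopolar_at_double_phi_doubles_pair_magnitudes(self):
        f_bi, _ = mech.protrusion_forces(EZ, np.array([1]), np.array([1.0]), 1.0)
        f_mono, _ = mech.protrusion_forces(EZ, np.array([1]), np.array([1.0]), 2.0)
        assert np.allclose(f_mono, 2 * f_bi)


class TestIntegrateStep:
    def test_zero_force_leaves_positions(self):
        pos = np.zeros((5, 3))
        new, capped = mech.integrate_step(pos, np.zeros((5, 3)), 1.0, 0.5,
                                          np.full(5, 6.0))
        assert np.array_equal(new, pos) and capped == 0

    def test_displacement_cap_and_count(self):
        pos = np.zeros((2, 3))
        F = np.array([[100.0, 0, 0], [0.01, 0, 0]])
        new, capped = mech.integrate_step(pos, F, 1.0, 1.0, np.full(2, 6.0))
        assert capped == 1
        assert np.linalg.norm(new[0]) == pytest.approx(0.6)  # 0.1 * r

    def test_anchored_particles_do_not_move(self):
        pos = np.zeros((2, 3))
        F = np.ones((2, 3)) * 0.01
        new, _ = mech.integrate_step(pos, F, 1.0, 1.0, np.full(2, 6.0),
                                     mobile=np.array([True, False]))
        assert np.allclose(new[1], 0) and not np.allclose(new[0], 0)

    def test_two_cell_relaxation_matches_closed_form_first_order(self):
        """Overdamped spring oracle: d(t) = d_eq - (d_eq - d0) exp(-2 k t/(lam d_eq));
        the explicit-Euler error halves when dt halves."""
        k_rep, lam, r = 1.0, 1.0, 6.0
        d_eq, d0, T = 0.9 * 2 * r, 0.8 * 0.9 * 2 * r, 10.0
        errs = []
        for dt in (0.1, 0.05):
            pos = np.array([[0.0, 0, 0], [d0, 0, 0]])
            steps = int(round(T / dt))
            for _ in range(steps):
                d = pos[1, 0] - pos[0, 0]
                f_i, f_j = mech.attraction_repulsion(d, EX, r, r, 0.5, k_rep, 0.9, 1.3)
                pos, _ = mech.integrate_step(pos, np.array([f_i, f_j]), lam, dt,
                                             np.full(2, r))
            exact = d_eq - (d_eq - d0) * np.exp(-2 * k_rep * T / (lam * d_eq))
            errs.append(abs((pos[1, 0] - pos[0, 0]) - exact))
        assert errs[1] < 0.75 * errs[0]  # first-order convergence

    def test_pairwise_forces_keep_centre_of_mass(self):
        rng = np.random.default_rng(1)
        F_half = rng.normal(size=(10, 3))
        F = np.vstack([F_half, -F_half])  # internal pairs
        pos = rng.uniform(0, 10, size=(20, 3))
        new, _ = mech.integrate_step(pos, F, 1.0, 0.01, np.full(20, 50.0))
        assert np.allclose(new.mean(axis=0), pos.mean(axis=0), atol=1e-9)


class TestDivision:
    def mother(self):
        return Cell(id=0, position=np.zeros(3), radii=(10.0, 10.0),
                    proteins={"A": 2.0}, cycle_phase=1.0, rng_stream=5)

    def test_daughter_radii_conserve_volume(self):
        d1, d2 = mech.divide_cell(self.mother(), EZ, cell_rng(0, 5))
        assert d1.radii[0] == pytest.approx(10 * 2 ** (-1 / 3))
        v_m = 10.0**3
        assert d1.radii[0] ** 3 + d2.radii[0] ** 3 == pytest.approx(v_m)

    def test_daughters_straddle_mother_along_axis(self):
        d1, d2 = mech.divide_cell(self.mother(), EZ, cell_rng(0, 5))
        assert np.allclose(d1.position, [0, 0, 5.0])
        assert np.allclose(d2.position, [0, 0, -5.0])

    def test_concentrations_inherited_not_split(self):
        d1, d2 = mech.divide_cell(self.mother(), EZ, cell_rng(0, 5))
        assert d1.proteins["A"] == 2.0 and d2.proteins["A"] == 2.0

    def test_fixed_seed_reproduces_placement(self):
        a = mech.divide_cell(self.mother(), EZ, cell_rng(3, 5))
        b = mech.divide_cell(self.mother(), EZ, cell_rng(3, 5))
        assert a[0].cycle_phase == b[0].cycle_phase
        assert np.array_equal(a[0].position, b[0].position)


def test_energy_relaxation_is_monotone_passive():
    """With passive forces only, the summed pair potential never increases."""
    from morphosim.neighbourhood import build_contact_graph

    rng = np.random.default_rng(2)
    pos = rng.uniform(0, 45, size=(60, 3))
    r, w, k_rep, lam, dt = 6.0, 0.5, 2.0, 1.0, 0.1
    energies = []
    for _ in range(150):
        g = build_contact_graph(pos, r, 1.3)
        F = np.zeros_like(pos)
        E = 0.0
        for (i, j), d in zip(g.edges, g.dist):
            dir_ij = (pos[j] - pos[i]) / d
            f_i, f_j = mech.attraction_repulsion(d, dir_ij, r, r, w, k_rep, 0.9, 1.3)
            F[i] += f_i
            F[j] += f_j
            E += mech.pair_potential(d, r, r, w, k_rep, 0.9, 1.3)
        energies.append(E)
        pos, _ = mech.integrate_step(pos, F, lam, dt, np.full(len(pos), r))
    diffs = np.diff(energies)
    assert np.all(diffs <= 1e-9)
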