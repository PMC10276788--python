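"""Lennard-Jones/Coulomb energetics, minimization, and interaction terms,
checked against closed forms and brute-force pair sums."""

import numpy as np
import pytest

from liece import (EnergyConfig, coulomb_energy, interaction_terms,
                   lj_energy, minimize_structure, combine)
from liece.energy import EnergyError
from liece.poisson import COULOMB_CONSTANT
from conftest import make_atom, make_structure


def _dimer(r, eps=0.5, rmin=None, q=(0.0, 0.0)):
    rmin = rmin if rmin is not None else r
    return make_structure([
        ("C", [0, 0, 0], dict(q=q[0], eps=eps, rmin=rmin)),
        ("C", [r, 0, 0], dict(q=q[1], eps=eps, rmin=rmin)),
    ])


class TestLennardJones:
    def test_pair_minimum_identity(self, config):
        """At r = rmin_ij the pair energy equals exactly -eps_ij."""
        s = _dimer(3.7, eps=0.5)
        assert lj_energy(s, s, config) == pytest.approx(-0.5, abs=1e-12)

    def test_beyond_cutoff_contributes_exactly_zero(self, config):
        s = _dimer(15.0, eps=0.5, rmin=3.7)
        assert lj_energy(s, s, config) == 0.0

    def test_matches_brute_force_double_loop(self, random_cluster, config):
        got = lj_energy(random_cluster, random_cluster, config)
        xyz = random_cluster.coords
        eps = random_cluster.lj_epsilons
        rmin = random_cluster.lj_rmins
        expected = 0.0
        for i in range(len(xyz)):
            for j in range(i + 1, len(xyz)):
                r = np.linalg.norm(xyz[i] - xyz[j])
                if r > config.vdw_cutoff:
                    continue
                e = np.sqrt(eps[i] * eps[j])
                rm = 0.5 * (rmin[i] + rmin[j])
                expected += e * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_intergroup_excludes_internal_pairs(self, config):
        a = _dimer(3.7)
        b = a.translated([20.0, 0, 0])
        # groups 20 Å apart: every cross pair beyond the 14 Å cutoff
        assert lj_energy(a, b, config) == 0.0

    def test_coincident_atoms_rejected(self, config):
        s = _dimer(0.0, rmin=3.7)
        with pytest.raises(EnergyError):
            lj_energy(s, s, config)


class TestCoulomb:
    def test_constant_definition(self, config):
        s = _dimer(COULOMB_CONSTANT, q=(1.0, 1.0))
        assert coulomb_energy(s, s, config) == pytest.approx(1.0, abs=1e-12)

    def test_zero_charges_give_zero(self, random_cluster, config):
        s = random_cluster.copy()
        for a in s.atoms:
            a.partial_charge = 0.0
        assert coulomb_energy(s, s, config) == 0.0

    def test_opposite_charges_at_3A(self, config):
        s = _dimer(3.0, q=(1.0, -1.0))
        assert coulomb_energy(s, s, config) == pytest.approx(-110.69, abs=0.005)

    def test_no_cutoff_applied(self, config):
        s = _dimer(50.0, q=(1.0, 1.0))
        assert coulomb_energy(s, s, config) == pytest.approx(
            COULOMB_CONSTANT / 50.0)

    def test_matches_brute_force(self, random_cluster, config):
        got = coulomb_energy(random_cluster, random_cluster, config)
        xyz = random_cluster.coords
        q = random_cluster.charges
        expected = sum(
            COULOMB_CONSTANT * q[i] * q[j] / np.linalg.norm(xyz[i] - xyz[j])
            for i in range(len(q)) for j in range(i + 1, len(q)))
        assert got == pytest.approx(expected, rel=1e-12)


class TestRigidInvariance:
    def test_translation_and_rotation_leave_energies_unchanged(
            self, random_cluster, config):
        e0 = lj_energy(random_cluster, random_cluster, config)
        c0 = coulomb_energy(random_cluster, random_cluster, config)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = random_cluster.rotated(R, [1.0, -2.0, 0.5]).translated([5, 6, 7])
        assert lj_energy(moved, moved, config) == pytest.approx(e0, abs=1e-6)
        assert coulomb_energy(moved, moved, config) == pytest.approx(c0, abs=1e-6)


class TestMinimizer:
    def test_lj_dimer_relaxes_to_pair_minimum(self):
        config = EnergyConfig(restraint_k=0.0)
        s = _dimer(1.3 * 3.7, eps=0.5, rmin=3.7)
        out, converged, grad = minimize_structure(s, config)
        r = np.linalg.norm(out.coords[1] - out.coords[0])
        assert converged
        assert r == pytest.approx(3.7, abs=1e-3)

    def test_structure_at_minimum_is_left_alone(self):
        config = EnergyConfig(restraint_k=0.0, grad_rms_tol=0.01)
        s = _dimer(3.7, eps=0.5)
        out, converged, _ = minimize_structure(s, config)
        assert converged
        assert np.max(np.abs(out.coords - s.coords)) < 1e-6

    def test_zero_step_budget_returns_input_unconverged(self, config):
        import dataclasses
        cfg = dataclasses.replace(config, sd_steps=0, cg_steps=0)
        s = _dimer(1.3 * 3.7)
        out, converged, _ = minimize_structure(s, cfg)
        assert not converged
        np.testing.assert_array_equal(out.coords, s.coords)

    def test_energy_non_increasing_and_immobile_atoms_fixed(self):
        config = EnergyConfig(restraint_k=0.0, sd_steps=20, cg_steps=50)
        rng = np.random.default_rng(3)
        s = make_structure([("C", 4.5 * rng.standard_normal(3),
                             dict(eps=0.2, rmin=3.5)) for _ in range(5)])
        mobile = np.array([True, True, True, False, False])
        from liece.energy import _objective
        x0 = s.coords.ravel()
        eps, rmin, q = s.lj_epsilons, s.lj_rmins, s.charges
        e_in, _ = _objective(x0, x0, eps, rmin, q, config)
        out, _, _ = minimize_structure(s, config, mobile=mobile)
        e_out, _ = _objective(out.coords.ravel(), x0, eps, rmin, q, config)
        assert e_out <= e_in + 1e-9
        np.testing.assert_array_equal(out.coords[3:], s.coords[3:])

    def test_restraints_hold_atoms_near_input(self):
        config = EnergyConfig(restraint_k=50.0)
        s = _dimer(1.2 * 3.7, eps=0.5, rmin=3.7)
        out, _, _ = minimize_structure(s, config)
        # strong restraints: displacement well below the unrestrained 0.3*rmin
        assert np.max(np.abs(out.coords - s.coords)) < 0.3


class TestInteractionTerms:
    def test_separated_limit(self, toy_system, config):
        from liece import separate_ligand
        _, prot, lig = toy_system
        cplx, prot, far = separate_ligand(prot, lig, 100.0)
        terms, _ = interaction_terms(cplx, prot, far, config,
                                     include_solvation=False)
        # every cross pair lies beyond the cutoff; only summation-order
        # noise of the cancelling internal terms remains
        assert terms.dE_vdw == pytest.approx(0.0, abs=1e-9)
        expected = coulomb_energy(prot, far, config)
        assert terms.dE_coul == pytest.approx(expected, rel=1e-9)

    def test_terms_equal_component_differences(self, toy_system, config):
        """Additivity: differences of independently computed component
        energies reproduce the packaged terms to numerical precision."""
        cplx, prot, lig = toy_system
        terms, comps = interaction_terms(cplx, prot, lig, config,
                                         include_solvation=False)
        assert terms.dE_vdw == pytest.approx(
            comps.complex[0] - comps.protein[0] - comps.ligand[0], abs=1e-9)
        assert terms.dE_coul == pytest.approx(
            comps.complex[1] - comps.protein[1] - comps.ligand[1], abs=1e-9)

    def test_identical_coordinates_reduce_to_intergroup_sums(
            self, toy_system, config):
        cplx, prot, lig = toy_system
        terms, _ = interaction_terms(cplx, prot, lig, config,
                                     include_solvation=False)
        assert terms.dE_vdw == pytest.approx(lj_energy(prot, lig, config),
                                             abs=1e-9)
        assert terms.dE_coul == pytest.approx(
            coulomb_energy(prot, lig, config), abs=1e-9)

    def test_atom_count_mismatch_rejected(self, toy_system, config):
        cplx, prot, lig = toy_system
        with pytest.raises(EnergyError, match="atom count"):
            interaction_terms(cplx, prot, prot, config)

    def test_cation_in_anionic_pocket_signs(self, toy_system, config):
        """Favorable Coulomb attraction and a positive desolvation penalty
        for a cationic ligand bound in an anionic pocket."""
        cplx, prot, lig = toy_system
        terms, _ = interaction_terms(cplx, prot, lig, config)
        assert terms.dE_coul < 0
        assert terms.dG_solv > 0
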