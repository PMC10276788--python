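"""Nonbonded energetics, Cartesian minimization, and interaction terms.

The three regressors of the binding model are assembled here: Lennard-Jones
van der Waals energy with a hard 14 Å cutoff, vacuum Coulomb electrostatics
(solvent screening lives entirely in the continuum solvation term), and the
finite-difference Poisson solvation energy, each taken as the difference

    dX = X(complex) - X(protein) - X(ligand).

Minimization follows the protocol of up to 500 steepest-descent steps then
up to 1000 Polak-Ribiere conjugate-gradient steps, stopping when the
gradient RMS falls below 0.001 kcal/mol/Å.  Bonded force-field terms are
replaced by harmonic positional restraints to the input coordinates, which
preserve the protocol's role (local strain relief) without a full covalent
force field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .chem_io import MolecularStructure
from .poisson import COULOMB_CONSTANT, solvation_energy


class EnergyError(ValueError):
    """Raised for invalid energy-evaluation inputs (overlapping atoms, ...)."""


@dataclass
class EnergyConfig:
    """All numeric knobs of the energy engine (units: Å, e, kcal/mol, K)."""

    vdw_cutoff: float = 14.0
    coulomb_constant: float = COULOMB_CONSTANT
    eps_interior: float = 1.0
    eps_exterior: float = 78.5
    grid_spacing_coarse: float = 1.0
    grid_spacing_fine: float = 0.4
    grid_margin: float = 10.0
    focus_margin: float = 4.0
    sd_steps: int = 500
    cg_steps: int = 1000
    grad_rms_tol: float = 0.001
    restraint_k: float = 10.0
    solver_tol: float = 1e-6
    solver_max_iter: int = 10000

    def __post_init__(self) -> None:
        if self.vdw_cutoff <= 0:
            raise EnergyError("vdw_cutoff must be > 0")
        if not (self.eps_exterior >= self.eps_interior >= 1.0):
            raise EnergyError("need eps_exterior >= eps_interior >= 1")
        if self.grid_spacing_fine >= self.grid_spacing_coarse:
            raise EnergyError("fine grid spacing must be below the coarse one")
        if self.solver_tol <= 0 or self.grad_rms_tol <= 0:
            raise EnergyError("tolerances must be positive")


@dataclass
class EnergyTerms:
    """The three regressors for one pose (complex - protein - ligand)."""

    dE_vdw: float
    dE_coul: float
    dG_solv: float


@dataclass
class ComponentEnergies:
    """Per-component single-point energies under one configuration."""

    complex: tuple[float, float, float]   # (E_vdw, E_coul, G_solv)
    protein: tuple[float, float, float]
    ligand: tuple[float, float, float]

    def differences(self) -> EnergyTerms:
        c, p, l = self.complex, self.protein, self.ligand
        return EnergyTerms(dE_vdw=c[0] - p[0] - l[0],
                           dE_coul=c[1] - p[1] - l[1],
                           dG_solv=c[2] - p[2] - l[2])


def _pair_arrays(group_a: MolecularStructure, group_b: MolecularStructure):
    """Distances and parameter combinations for inter- or intra-group sums.

    Returns (r, eps_ij, rmin_ij, qq) flattened over the relevant pairs:
    all a-b pairs when the groups are distinct objects, unique internal
    pairs when the same structure is passed twice.
    """
    same = group_a is group_b
    xa = group_a.coords
    xb = group_b.coords
    r = cdist(xa, xb)
    ea, eb = group_a.lj_epsilons, group_b.lj_epsilons
    ra, rb = group_a.lj_rmins, group_b.lj_rmins
    qa, qb = group_a.charges, group_b.charges
    eps = np.sqrt(np.outer(ea, eb))
    rmin = 0.5 * (ra[:, None] + rb[None, :])
    qq = np.outer(qa, qb)
    if same:
        iu = np.triu_indices(len(xa), k=1)
        return r[iu], eps[iu], rmin[iu], qq[iu]
    return r.ravel(), eps.ravel(), rmin.ravel(), qq.ravel()


def lj_energy(group_a: MolecularStructure, group_b: MolecularStructure,
              config: EnergyConfig) -> float:
    """Lennard-Jones energy in kcal/mol.

    Pairwise ``eps_ij [ (rmin_ij/r)^12 - 2 (rmin_ij/r)^6 ]`` with
    Lorentz-Berthelot combination, truncated (not shifted) at the cutoff.
    Pass the same structure twice for the total internal energy over unique
    pairs; two distinct structures give the inter-group energy.
    """
    if group_a.n_atoms == 0 or group_b.n_atoms == 0:
        return 0.0
    r, eps, rmin, _ = _pair_arrays(group_a, group_b)
    if np.any(r <= 0):
        raise EnergyError("coincident atoms (r = 0) in LJ evaluation")
    mask = r <= config.vdw_cutoff
    sr6 = (rmin[mask] / r[mask]) ** 6
    return float(np.sum(eps[mask] * (sr6 * sr6 - 2.0 * sr6)))


def coulomb_energy(group_a: MolecularStructure, group_b: MolecularStructure,
                   config: EnergyConfig) -> float:
    """Vacuum Coulomb energy ``k_e q_i q_j / r`` in kcal/mol, no cutoff."""
    if group_a.n_atoms == 0 or group_b.n_atoms == 0:
        return 0.0
    r, _, _, qq = _pair_arrays(group_a, group_b)
    if np.any(r <= 0):
        raise EnergyError("coincident atoms (r = 0) in Coulomb evaluation")
    return float(config.coulomb_constant * np.sum(qq / r))


# ---------------------------------------------------------------------------
# Minimization


def _objective(x: np.ndarray, x0: np.ndarray, eps: np.ndarray,
               rmin: np.ndarray, q: np.ndarray, config: EnergyConfig
               ) -> tuple[float, np.ndarray]:
    """Energy and gradient of LJ + Coulomb + harmonic restraints.

    Restraint energy is ``k * |x - x0|^2`` per atom (CHARMM CONS HARM
    convention); LJ pairs beyond the cutoff contribute zero energy and
    force.
    """
    n = len(q)
    xyz = x.reshape(n, 3)
    diff = xyz[:, None, :] - xyz[None, :, :]
    r2 = np.sum(diff * diff, axis=2)
    iu = np.triu_indices(n, k=1)
    r = np.sqrt(r2[iu])
    if np.any(r <= 1e-12):
        raise EnergyError("coincident atoms during minimization")

    eij = np.sqrt(np.outer(eps, eps))[iu]
    rij = (0.5 * (rmin[:, None] + rmin[None, :]))[iu]
    qq = np.outer(q, q)[iu]

    cut = r <= config.vdw_cutoff
    sr6 = np.where(cut, (rij / np.maximum(r, 1e-12)) ** 6, 0.0)
    e_lj = float(np.sum(eij * (sr6 * sr6 - 2.0 * sr6)))
    e_cl = float(config.coulomb_constant * np.sum(qq / r))
    disp = xyz - x0.reshape(n, 3)
    e_rs = float(config.restraint_k * np.sum(disp * disp))

    # dE/dr for each pair
    dlj = np.where(cut, 12.0 * eij * (sr6 - sr6 * sr6) / r, 0.0)
    dcl = -config.coulomb_constant * qq / (r * r)
    dEdr = dlj + dcl
    grad = 2.0 * config.restraint_k * disp
    unit = diff[iu] / r[:, None]
    pair_force = dEdr[:, None] * unit
    np.add.at(grad, iu[0], pair_force)
    np.add.at(grad, iu[1], -pair_force)
    return e_lj + e_cl + e_rs, grad.ravel()


def _line_search(f, x, fx, g, d, step0):
    """Backtracking Armijo line search; returns (x_new, f_new, step) or None."""
    gd = float(np.dot(g, d))
    if gd >= 0:
        return None
    step = step0
    for _ in range(40):
        try:
            xn = x + step * d
            fn, _ = f(xn)
        except EnergyError:
            step *= 0.5
            continue
        if fn <= fx + 1e-4 * step * gd:
            return xn, fn, step
        step *= 0.5
    return None


def minimize_structure(structure: MolecularStructure, config: EnergyConfig,
                       mobile: np.ndarray | None = None
                       ) -> tuple[MolecularStructure, bool, float]:
    """Relax a structure by steepest descent then conjugate gradients.

    The objective is LJ + Coulomb + harmonic positional restraints to the
    *input* coordinates.  ``mobile`` is a boolean per-atom mask; immobile
    atoms never move.  Returns (minimized structure, converged flag, final
    gradient RMS).  The energy is non-increasing across accepted steps.
    """
    structure.require_parameters()
    n = structure.n_atoms
    eps = structure.lj_epsilons
    rmin = structure.lj_rmins
    q = structure.charges
    x0 = structure.coords.ravel()
    if mobile is None:
        mobile = np.ones(n, dtype=bool)
    mmask = np.repeat(np.asarray(mobile, dtype=bool), 3)

    def f(x):
        e, g = _objective(x, x0, eps, rmin, q, config)
        g[~mmask] = 0.0
        return e, g

    x = x0.copy()
    e, g = f(x)
    if not np.isfinite(e):
        raise EnergyError("non-finite energy at input coordinates")

    def rms(g):
        nm = max(int(mmask.sum()), 1)
        return float(np.sqrt(np.sum(g[mmask] ** 2) / nm))

    converged = False
    budget = config.sd_steps + config.cg_steps
    if budget > 0 and rms(g) <= config.grad_rms_tol:
        converged = True

    # steepest descent
    step = 0.02
    it = 0
    while not converged and it < config.sd_steps:
        d = -g
        res = _line_search(f, x, e, g, d, step)
        if res is None:
            break
        x, e, used = res
        step = min(used * 2.0, 0.2)
        _, g = f(x)
        it += 1
        if rms(g) <= config.grad_rms_tol:
            converged = True

    # Polak-Ribiere conjugate gradients with restarts
    it = 0
    d = -g
    g_prev = g
    step = 0.02
    while not converged and it < config.cg_steps:
        res = _line_search(f, x, e, g_prev, d, step)
        if res is None:
            # restart along steepest descent once; stop if still stuck
            d = -g_prev
            res = _line_search(f, x, e, g_prev, d, step)
            if res is None:
                break
        x, e, used = res
        step = min(used * 2.0, 0.2)
        _, g = f(x)
        beta = max(0.0, float(np.dot(g, g - g_prev) /
                              max(np.dot(g_prev, g_prev), 1e-300)))
        d = -g + beta * d
        g_prev = g
        it += 1
        if rms(g) <= config.grad_rms_tol:
            converged = True

    out = structure.copy()
    out.set_coords(x.reshape(n, 3))
    return out, converged, rms(g_prev if not converged else g)


# ---------------------------------------------------------------------------
# Interaction terms


def component_energies(complex_s: MolecularStructure,
                       protein: MolecularStructure,
                       ligand: MolecularStructure,
                       config: EnergyConfig,
                       include_solvation: bool = True) -> ComponentEnergies:
    """Single-point (E_vdw, E_coul, G_solv) for each component."""
    vals = {}
    for name, s in (("complex", complex_s), ("protein", protein),
                    ("ligand", ligand)):
        ev = lj_energy(s, s, config)
        ec = coulomb_energy(s, s, config)
        gs = solvation_energy(s, config) if include_solvation else 0.0
        vals[name] = (ev, ec, gs)
    return ComponentEnergies(**vals)


def interaction_terms(complex_s: MolecularStructure,
                      protein: MolecularStructure,
                      ligand: MolecularStructure,
                      config: EnergyConfig,
                      minimize_first: bool = False,
                      include_solvation: bool = True
                      ) -> tuple[EnergyTerms, ComponentEnergies]:
    """The three binding-model regressors for one pose.

    When ``minimize_first`` is set, the complex and the two free components
    are each relaxed under the minimization protocol before the single-point
    evaluations (complex minimized as a whole; protein and ligand in their
    free forms).  Without minimization all components are evaluated at the
    input coordinates, in which case the vdW and Coulomb differences reduce
    exactly to the protein-ligand inter-group sums.
    """
    if complex_s.n_atoms != protein.n_atoms + ligand.n_atoms:
        raise EnergyError(
            f"complex atom count {complex_s.n_atoms} != protein "
            f"{protein.n_atoms} + ligand {ligand.n_atoms}")
    if minimize_first:
        complex_s, _, _ = minimize_structure(complex_s, config)
        protein, _, _ = minimize_structure(protein, config)
        ligand, _, _ = minimize_structure(ligand, config)
    comps = component_energies(complex_s, protein, ligand, config,
                               include_solvation=include_solvation)
    return comps.differences(), comps
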