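"""Synthetic inputs: linear energy tables, toy complexes, decoy poses.

Real inputs to a binding-free-energy model are docking poses scored with a
molecular-mechanics force field and affinities from radioligand competition
assays.  Neither is reproducible at desk scale, so this module generates
substitutes with *known* structure:

* :func:`gen_energy_table` draws the three energy terms uniformly from
  realistic ranges and builds the response from chosen coefficients plus
  Gaussian noise, so regression code can be checked against ground truth.
* :func:`gen_toy_complex` builds a rigid cup-shaped "binding pocket" of
  Lennard-Jones spheres carrying an anionic carboxylate-like anchor pair,
  with a small cationic ligand cluster seated inside — every component
  energy is brute-force checkable and the pose satisfies the geometric
  acceptance constraints by construction.
* :func:`gen_decoy_pose` deterministically transforms a pose so that it
  violates one named acceptance constraint (flipped orientation, stranded
  buried donor, solvent-exposed apolar tail).

All generators are pure functions of their spec: randomness comes from
numpy's PCG64 generator seeded with the spec's integer seed, so identical
specs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_io import (Atom, DEFAULT_PARAMETERS, EnergyTableRow,
                      MolecularStructure, ParameterTable, assign_parameters,
                      combine)

FLIP = "flip"
STRAND_DONOR = "strand_donor"
EXPOSE_APOLAR = "expose_apolar"
DECOY_MODES = (FLIP, STRAND_DONOR, EXPOSE_APOLAR)


class SyntheticError(ValueError):
    """Raised for invalid generator specs or unachievable decoy modes."""


# ---------------------------------------------------------------------------
# Energy-affinity tables


@dataclass
class TableSpec:
    """Generating parameters for a synthetic energy-affinity table.

    Defaults mirror the qualitative magnitudes of the application domain:
    the van der Waals term dominates (its coefficient is several-fold larger
    in magnitude than the electrostatic ones), vdW and Coulomb terms are
    negative (favorable) and the desolvation penalty positive, and the
    response lands in the -8 to -13 kcal/mol range typical of nanomolar
    binders.  Noise of 0.5 kcal/mol stands in for assay and pose error.
    """

    alpha: float = 0.12
    beta: float = -0.02
    gamma: float = -0.04
    delta: float = -2.0
    n: int = 50
    term_ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "dE_vdw": (-70.0, -30.0),
        "dE_coul": (-30.0, -5.0),
        "dG_solv": (5.0, 40.0),
    })
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SyntheticError("n must be >= 1")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")
        for k, (lo, hi) in self.term_ranges.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise SyntheticError(f"term range {k} must be finite with low < high")


def gen_energy_table(spec: TableSpec) -> list[EnergyTableRow]:
    """Energy rows whose response is exactly linear in the terms plus noise:

        dg_exp = alpha dE_vdw + beta dE_coul + gamma dG_solv + delta + N(0, sd)
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n):
        terms = {k: float(rng.uniform(lo, hi))
                 for k, (lo, hi) in spec.term_ranges.items()}
        dg = (spec.alpha * terms["dE_vdw"] + spec.beta * terms["dE_coul"]
              + spec.gamma * terms["dG_solv"] + spec.delta)
        if spec.noise_sd > 0:
            dg += float(rng.normal(0.0, spec.noise_sd))
        rows.append(EnergyTableRow(
            ligand_id=f"L{i + 1:03d}",
            dE_vdw=terms["dE_vdw"], dE_coul=terms["dE_coul"],
            dG_solv=terms["dG_solv"], dg_exp=dg,
            dataset_label="synthetic", docking_program="simulated",
            receptor_model="toy",
        ))
    return rows


# ---------------------------------------------------------------------------
# Toy pocket-ligand complexes


@dataclass
class ComplexSpec:
    """Geometry/charge spec for a toy cup-pocket plus cationic ligand.

    Atoms are free Lennard-Jones spheres, not a covalent molecule, so
    neighbor spacings (~3 Å) sit near the LJ well rather than at bond
    lengths.  The anchor carboxylate pair carries ``pocket_charge`` split
    over two oxygens; the ligand's amine-like nitrogen carries
    ``ligand_charge`` and sits 3.5 Å from the nearer anchor oxygen.
    """

    pocket_atoms: int = 41
    pocket_charge: float = -1.0
    ligand_atoms: int = 6
    ligand_charge: float = 1.0
    box: float = 40.0
    anchor_residue_number: int = 155
    jitter: float = 0.05
    seed: int = 0
    params: ParameterTable = field(default_factory=lambda: DEFAULT_PARAMETERS)

    def __post_init__(self) -> None:
        if self.pocket_atoms < 1 or self.ligand_atoms < 3:
            raise SyntheticError("need pocket_atoms >= 1 and ligand_atoms >= 3")
        if self.ligand_atoms > 12:
            raise SyntheticError("toy ligand supports at most 12 atoms")
        if self.box <= 2 * 14.0:
            raise SyntheticError("box must exceed twice the vdW cutoff")


def _ring(radius: float, z: float, count: int, phase: float = 0.0) -> list[np.ndarray]:
    ang = phase + 2 * np.pi * np.arange(count) / count
    return [np.array([radius * np.cos(a), radius * np.sin(a), z]) for a in ang]


def _pocket_sites() -> list[np.ndarray]:
    """Deterministic carbon positions forming an open cup around the origin
    (opening toward +z), listed bottom-up."""
    sites: list[np.ndarray] = [np.array([0.0, 0.0, -3.0])]
    sites += _ring(3.2, -3.0, 6)
    sites += _ring(5.6, -2.2, 10, phase=0.3)
    sites += _ring(6.5, -0.2, 12, phase=0.0)
    sites += _ring(6.5, 2.2, 12, phase=0.26)
    sites += _ring(6.5, 4.4, 12, phase=0.0)
    return sites


_BURIED_SITE = np.array([-2.6, -2.6, -1.4])  # apolar niche used by strand_donor


def _build_once(spec: ComplexSpec, seed: int
                ) -> tuple[MolecularStructure, MolecularStructure]:
    rng = np.random.default_rng(seed)
    sites = _pocket_sites()
    if spec.pocket_atoms > len(sites):
        raise SyntheticError(
            f"pocket_atoms at most {len(sites)} for the cup template")

    atoms: list[Atom] = []
    serial = 1
    for pos in sites[:spec.pocket_atoms]:
        pos = pos + rng.uniform(-spec.jitter, spec.jitter, size=3)
        atoms.append(Atom(serial, f"C{serial}", "C", pos, partial_charge=0.0,
                          residue_name="POC", residue_number=1))
        serial += 1
    # anchor carboxylate pair on the inner wall
    od1 = np.array([4.9, 0.0, 0.0])
    half_angle = np.arcsin(1.1 / 4.9)
    od2 = np.array([4.9 * np.cos(2 * half_angle), 4.9 * np.sin(2 * half_angle), 0.0])
    for name, pos in (("OD1", od1), ("OD2", od2)):
        atoms.append(Atom(serial, name, "O", pos,
                          partial_charge=spec.pocket_charge / 2.0,
                          residue_name="ASP",
                          residue_number=spec.anchor_residue_number))
        serial += 1
    pocket = MolecularStructure(atoms, title="toy-pocket", kind="receptor")

    lig_atoms: list[Atom] = []
    nitrogen = od1 + np.array([-3.5, 0.0, 0.0])
    lig_atoms.append(Atom(1, "N1", "N", nitrogen,
                          partial_charge=spec.ligand_charge,
                          residue_name="LIG"))
    n_tail = spec.ligand_atoms - 2
    for i in range(n_tail):
        theta = np.pi - np.deg2rad(45.0) * i
        pos = np.array([3.8 * np.cos(theta), 3.8 * np.sin(theta),
                        0.6 + 0.3 * i])
        pos = pos + rng.uniform(-spec.jitter, spec.jitter, size=3)
        q = 0.4 if i == 0 else 0.0   # counter-charge to the hydroxyl oxygen
        lig_atoms.append(Atom(2 + i, f"C{2 + i}", "C", pos, partial_charge=q,
                              residue_name="LIG"))
    lig_atoms.append(Atom(spec.ligand_atoms, f"O{spec.ligand_atoms}", "O",
                          np.array([0.0, -2.6, 2.6]), partial_charge=-0.4,
                          residue_name="LIG"))
    ligand = MolecularStructure(lig_atoms, title="toy-ligand", kind="ligand")
    return pocket, ligand


def gen_toy_complex(spec: ComplexSpec | None = None
                    ) -> tuple[MolecularStructure, MolecularStructure,
                               MolecularStructure]:
    """Build (complex, protein, ligand), all parameterized.

    The construction guarantees a salt bridge between the ligand nitrogen
    and the anchor carboxylate and a minimum interatomic separation of
    1.5 Å; if seeded jitter ever violates the separation the build retries
    with an incremented seed (up to 100 attempts).
    """
    spec = spec or ComplexSpec()
    for attempt in range(100):
        pocket, ligand = _build_once(spec, spec.seed + attempt)
        cplx = combine(pocket, ligand, title="toy-complex")
        xyz = cplx.coords
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() >= 1.5:
            pocket = assign_parameters(pocket, spec.params)
            ligand = assign_parameters(ligand, spec.params)
            cplx = combine(pocket, ligand, title="toy-complex")
            return cplx, pocket, ligand
    raise SyntheticError("could not build an overlap-free toy complex in "
                         "100 seed attempts")


def separate_ligand(protein: MolecularStructure, ligand: MolecularStructure,
                    distance: float = 100.0
                    ) -> tuple[MolecularStructure, MolecularStructure,
                               MolecularStructure]:
    """Rigidly translate the ligand away from the pocket (separated limit)."""
    lig = ligand.translated([distance, 0.0, 0.0])
    return combine(protein, lig, title="separated"), protein, lig


# ---------------------------------------------------------------------------
# Decoy poses


def _ligand_nitrogen(pose: MolecularStructure) -> int:
    for i, a in enumerate(pose.atoms):
        if a.element.upper() == "N":
            return i
    raise SyntheticError("pose has no nitrogen; decoy modes need the "
                         "cationic center")


def gen_decoy_pose(pose: MolecularStructure, mode: str) -> MolecularStructure:
    """Transform a pose so it fails one named acceptance constraint.

    * ``flip``: 180° rotation about the vertical (pocket) axis through the
      ligand centroid, swinging the cationic nitrogen away from the anchor
      (an exact involution: flipping twice restores the pose).
    * ``strand_donor``: the hydroxyl-like oxygen is relocated into a buried
      apolar niche of the cup with no hydrogen-bonding partner.
    * ``expose_apolar``: the carbon tail is rotated about the nitrogen to
      point solvent-ward, out of the cup.
    """
    if mode not in DECOY_MODES:
        raise SyntheticError(f"unknown decoy mode {mode!r}; choose from {DECOY_MODES}")
    if mode == FLIP:
        center = pose.coords.mean(axis=0)
        R = np.diag([-1.0, -1.0, 1.0])   # 180° about z
        return pose.rotated(R, center)
    if mode == STRAND_DONOR:
        oxy = [i for i, a in enumerate(pose.atoms) if a.element.upper() == "O"]
        if not oxy:
            raise SyntheticError("strand_donor needs an oxygen in the pose")
        out = pose.copy()
        out.atoms[oxy[-1]].coords = _BURIED_SITE.copy()
        return out
    # EXPOSE_APOLAR: rotate every carbon about the nitrogen so it points up
    ni = _ligand_nitrogen(pose)
    npos = pose.atoms[ni].coords
    out = pose.copy()
    for k, a in enumerate(out.atoms):
        if a.element.upper() != "C":
            continue
        rel = a.coords - npos
        r = np.linalg.norm(rel)
        # fan the carbons slightly so they do not stack on one line
        spread = np.deg2rad(12.0) * (k - ni)
        direction = np.array([np.sin(spread), 0.15 * np.cos(spread), 1.0])
        direction /= np.linalg.norm(direction)
        a.coords = npos + (r + 2.0) * direction
    return out
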