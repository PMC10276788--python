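"""Geometric acceptance tests for docking poses.

Aminergic-receptor pharmacology imposes hard constraints on plausible poses:
the ligand's protonated amine must salt-bridge the conserved binding-pocket
aspartate (D3.32 in Ballesteros-Weinstein numbering), polar atoms must not
end up buried without a hydrogen-bonding partner, and hydrophobic moieties
must not stick out into solvent.  This module turns those constraints into
deterministic geometric tests with configurable thresholds and produces
accept/reject decisions with complete reason codes.

Exposure is measured with a Shrake-Rupley-style numerical surface using a
fixed 92-point sphere sampling (seedless, so every call agrees exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem_io import MolecularStructure, combine

#: Reason codes emitted by :func:`filter_poses`.
NO_ANCHOR_CONTACT = "NO_ANCHOR_CONTACT"
STRANDED_POLAR = "STRANDED_POLAR"
EXPOSED_APOLAR = "EXPOSED_APOLAR"

_POLAR_ELEMENTS = {"N", "O"}
_PROBE_RADIUS = 1.4      # Å, water probe
_N_SPHERE_POINTS = 92    # fixed deterministic sampling


class FilterError(ValueError):
    """Raised when a filter precondition is violated (e.g. missing anchor)."""


@dataclass
class FilterRules:
    """Thresholds for the pose-acceptance tests.

    The underlying constraints are qualitative; these numeric defaults follow
    common structural-biology practice (4 Å salt bridge, 3.5 Å / 120°
    hydrogen bond on heavy atoms, 10 % exposure to count as buried, at most
    50 % of the apolar surface solvent-exposed) and are all configurable.
    """

    anchor_residue: int = 155          # residue number of the pocket aspartate
    ionic_max_dist: float = 4.0        # Å, N+ ... carboxylate O
    hbond_max_dist: float = 3.5        # Å, donor-acceptor heavy atoms
    hbond_min_angle: float = 120.0     # degrees, D-H...A when H present
    burial_threshold: float = 0.1      # fractional exposure below => buried
    exposed_apolar_max: float = 0.5    # max allowed exposed apolar fraction
    cation_min_charge: float = 0.5     # N partial charge to count as cationic

    def __post_init__(self) -> None:
        for f in ("ionic_max_dist", "hbond_max_dist", "hbond_min_angle",
                  "burial_threshold", "exposed_apolar_max"):
            if getattr(self, f) <= 0:
                raise FilterError(f"threshold {f} must be positive")
        if self.hbond_min_angle > 180:
            raise FilterError("hbond_min_angle must be <= 180 degrees")


@dataclass
class InteractionReport:
    ionic_contacts: list[tuple[int, str, float]] = field(default_factory=list)
    hbonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    stranded_polar: list[int] = field(default_factory=list)
    exposed_apolar_fraction: float = 0.0


def _unit_sphere_points(n: int = _N_SPHERE_POINTS) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def fractional_exposure(structure: MolecularStructure) -> np.ndarray:
    """Per-atom fraction of the probe-inflated sphere that is solvent
    accessible (Shrake-Rupley with a fixed 92-point sampling)."""
    xyz = structure.coords
    radii = structure.born_radii + _PROBE_RADIUS
    sphere = _unit_sphere_points()
    n = len(xyz)
    frac = np.empty(n)
    for i in range(n):
        pts = xyz[i] + radii[i] * sphere
        d2 = np.sum((pts[:, None, :] - xyz[None, :, :]) ** 2, axis=2)
        d2[:, i] = np.inf
        buried = np.any(d2 < (radii[None, :] - 1e-9) ** 2, axis=1)
        frac[i] = 1.0 - buried.mean()
    return frac


def _cationic_centers(ligand: MolecularStructure, rules: FilterRules) -> list[int]:
    """Indices of ligand nitrogens carrying a formal positive charge."""
    out = []
    for i, a in enumerate(ligand.atoms):
        if a.element.upper() == "N" and a.has_charge and \
                a.partial_charge >= rules.cation_min_charge:
            out.append(i)
    return out


def find_ionic_contacts(ligand: MolecularStructure,
                        receptor: MolecularStructure,
                        rules: FilterRules) -> list[tuple[int, str, float]]:
    """Salt-bridge contacts between ligand cationic nitrogens and the anchor
    residue's carboxylate oxygens.

    Returns at most one contact per (cationic center, anchor residue) pair,
    at the minimum oxygen-nitrogen distance, when that distance is within
    ``rules.ionic_max_dist``.
    """
    anchor_idx = [i for i, a in enumerate(receptor.atoms)
                  if a.residue_number == rules.anchor_residue]
    if not anchor_idx:
        raise FilterError(
            f"anchor residue {rules.anchor_residue} absent from receptor")
    oxy = [i for i in anchor_idx if receptor.atoms[i].element.upper() == "O"]
    if not oxy:
        raise FilterError(
            f"anchor residue {rules.anchor_residue} has no oxygen atoms")
    contacts = []
    rec_xyz = receptor.coords
    resid = f"{receptor.atoms[oxy[0]].residue_name}{rules.anchor_residue}"
    for ci in _cationic_centers(ligand, rules):
        d = np.linalg.norm(rec_xyz[oxy] - ligand.atoms[ci].coords, axis=1)
        dmin = float(d.min())
        if dmin <= rules.ionic_max_dist:
            contacts.append((ligand.atoms[ci].serial, resid, dmin))
    return contacts


def _polar_indices(s: MolecularStructure) -> list[int]:
    return [i for i, a in enumerate(s.atoms)
            if a.element.upper() in _POLAR_ELEMENTS]


def _attached_hydrogens(s: MolecularStructure, i: int,
                        max_bond: float = 1.2) -> list[int]:
    xyz = s.coords
    out = []
    for j, a in enumerate(s.atoms):
        if a.element.upper() == "H" and \
                np.linalg.norm(xyz[j] - xyz[i]) <= max_bond:
            out.append(j)
    return out


def _donor_angle(donor_s: MolecularStructure, di: int,
                 acceptor_pos: np.ndarray, rules: FilterRules) -> float | None:
    """Best D-H...A angle if atom di can donate toward acceptor_pos.

    An atom donates when it carries an attached hydrogen satisfying the
    angle threshold.  In structures without any explicit hydrogens the
    distance criterion alone applies, but strongly anionic atoms (charge
    below -0.2 e, e.g. carboxylate oxygens) are treated as acceptor-only.
    Returns the angle (180 for the heavy-atom fallback) or None.
    """
    xyz = donor_s.coords
    hyds = _attached_hydrogens(donor_s, di)
    if hyds:
        best = 0.0
        for hi in hyds:
            v1 = xyz[di] - xyz[hi]
            v2 = acceptor_pos - xyz[hi]
            c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            best = max(best, float(np.degrees(np.arccos(np.clip(c, -1, 1)))))
        return best if best >= rules.hbond_min_angle else None
    has_h = any(a.element.upper() == "H" for a in donor_s.atoms)
    if has_h:
        return None   # explicit hydrogens exist, but none on this atom
    a = donor_s.atoms[di]
    if a.has_charge and a.partial_charge < -0.2:
        return None   # anionic: lone pairs only
    return 180.0


def find_hbonds(ligand: MolecularStructure, receptor: MolecularStructure,
                rules: FilterRules) -> list[tuple[int, int, float, float]]:
    """Hydrogen bonds between ligand and receptor polar heavy atoms.

    Donors and acceptors are N/O atoms.  Each (ligand, receptor) heavy-atom
    pair within the distance threshold is reported at most once, as
    (donor serial, acceptor serial, distance, angle): the ligand-as-donor
    direction is tried first, then receptor-as-donor.  When explicit
    hydrogens are present on the donor the D-H...A angle must reach
    ``hbond_min_angle``; hydrogen-free structures fall back to the
    heavy-atom distance criterion (angle reported as 180).
    """
    bonds = []
    l_xyz = ligand.coords
    r_xyz = receptor.coords
    for li in _polar_indices(ligand):
        for ri in _polar_indices(receptor):
            r = float(np.linalg.norm(r_xyz[ri] - l_xyz[li]))
            if r <= 1e-9 or r > rules.hbond_max_dist:
                continue
            angle = _donor_angle(ligand, li, r_xyz[ri], rules)
            if angle is not None:
                bonds.append((ligand.atoms[li].serial,
                              receptor.atoms[ri].serial, r, angle))
                continue
            angle = _donor_angle(receptor, ri, l_xyz[li], rules)
            if angle is not None:
                bonds.append((receptor.atoms[ri].serial,
                              ligand.atoms[li].serial, r, angle))
    return bonds


def interaction_report(ligand: MolecularStructure,
                       receptor: MolecularStructure,
                       rules: FilterRules) -> InteractionReport:
    """Full geometric analysis of one pose against the receptor."""
    contacts = find_ionic_contacts(ligand, receptor, rules)
    hbonds = find_hbonds(ligand, receptor, rules)
    cplx = combine(receptor, ligand)
    expo_cplx = fractional_exposure(cplx)[receptor.n_atoms:]
    expo_free = fractional_exposure(ligand)

    hbonded = {s for b in hbonds for s in (b[0], b[1])}
    ionic = {c[0] for c in contacts}
    stranded = []
    for k, i in enumerate(range(len(ligand.atoms))):
        a = ligand.atoms[i]
        if a.element.upper() not in _POLAR_ELEMENTS:
            continue
        if expo_cplx[i] >= rules.burial_threshold:
            continue
        if a.serial in hbonded or a.serial in ionic:
            continue
        stranded.append(a.serial)

    apolar = [i for i, a in enumerate(ligand.atoms)
              if a.element.upper() not in _POLAR_ELEMENTS and
              a.element.upper() != "H"]
    if apolar:
        free = float(np.sum(expo_free[apolar]))
        frac = float(np.sum(expo_cplx[apolar]) / free) if free > 0 else 0.0
    else:
        frac = 0.0
    return InteractionReport(
        ionic_contacts=contacts,
        hbonds=hbonds,
        stranded_polar=stranded,
        exposed_apolar_fraction=min(1.0, frac),
    )


def evaluate_pose(ligand: MolecularStructure, receptor: MolecularStructure,
                  rules: FilterRules) -> tuple[bool, list[str], InteractionReport]:
    """Accept/reject one pose; the reason list enumerates *every* failed
    constraint, not just the first."""
    report = interaction_report(ligand, receptor, rules)
    reasons = []
    if not report.ionic_contacts:
        reasons.append(NO_ANCHOR_CONTACT)
    if report.stranded_polar:
        reasons.append(STRANDED_POLAR)
    if report.exposed_apolar_fraction > rules.exposed_apolar_max:
        reasons.append(EXPOSED_APOLAR)
    return (not reasons), reasons, report


def filter_poses(poses: Sequence[tuple[MolecularStructure, MolecularStructure]],
                 rules: FilterRules | None = None
                 ) -> tuple[list[MolecularStructure],
                            list[tuple[MolecularStructure, list[str]]]]:
    """Partition (ligand pose, receptor) pairs into accepted and rejected.

    A pose is accepted iff it makes at least one ionic contact with the
    anchor residue, has no stranded buried polar atoms, and keeps its exposed
    apolar surface fraction within the threshold.
    """
    rules = rules or FilterRules()
    accepted: list[MolecularStructure] = []
    rejected: list[tuple[MolecularStructure, list[str]]] = []
    for ligand, receptor in poses:
        ok, reasons, _ = evaluate_pose(ligand, receptor, rules)
        if ok:
            accepted.append(ligand)
        else:
            rejected.append((ligand, reasons))
    return accepted, rejected
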