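"""Molecular structures, nonbonded parameters and tabular inputs.

Units are fixed package-wide: Ångström for lengths, elementary charge for
partial charges, kcal/mol for energies, Kelvin for temperature.

Structures are read through MDAnalysis (PDB, mol2) and RDKit (SDF) and held
in a light ordered-atom container that also carries the nonbonded parameters
(Lennard-Jones well depth and pair-minimum radius, Born radius) each energy
routine needs.  PDB files carry no partial charges; an optional sidecar CSV
keyed by atom serial supplies them.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3
#: Default temperature (K) for Ki -> free-energy conversion.
DEFAULT_TEMPERATURE = 298.0

KNOWN_ELEMENTS = {
    "H", "C", "N", "O", "F", "P", "S", "CL", "BR", "I", "NA", "K", "MG",
    "CA", "ZN", "FE", "SE", "B",
}


class ChemIOError(ValueError):
    """Raised for malformed structure or table inputs."""


class ParameterError(ValueError):
    """Raised when nonbonded parameter assignment fails."""


@dataclass
class Atom:
    """A point atom with coordinates, charge and nonbonded parameters.

    ``lj_epsilon``/``lj_rmin``/``born_radius`` are ``None`` until assigned;
    an unparameterized atom is detectable via :attr:`is_parameterized`
    rather than silently carrying zeros.  ``partial_charge`` is ``None``
    when no charge source (mol2/SDF/sidecar) supplied one.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    partial_charge: float | None = None
    lj_epsilon: float | None = None
    lj_rmin: float | None = None
    born_radius: float | None = None
    residue_name: str = "UNK"
    residue_number: int = 1
    chain: str = "A"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ChemIOError(
                f"atom {self.serial} ({self.name}): coordinates must be a finite 3-vector"
            )
        if self.partial_charge is not None and not np.isfinite(self.partial_charge):
            raise ChemIOError(f"atom {self.serial}: non-finite partial charge")
        if self.lj_epsilon is not None and self.lj_epsilon < 0:
            raise ChemIOError(f"atom {self.serial}: lj_epsilon must be >= 0")
        if self.lj_rmin is not None and self.lj_rmin <= 0:
            raise ChemIOError(f"atom {self.serial}: lj_rmin must be > 0")
        if self.born_radius is not None and self.born_radius <= 0:
            raise ChemIOError(f"atom {self.serial}: born_radius must be > 0")

    @property
    def is_parameterized(self) -> bool:
        return None not in (self.lj_epsilon, self.lj_rmin, self.born_radius)

    @property
    def has_charge(self) -> bool:
        return self.partial_charge is not None

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class MolecularStructure:
    """Ordered collection of atoms: a receptor, a ligand, or their complex."""

    atoms: list[Atom]
    title: str = ""
    kind: str = "ligand"  # receptor | ligand | complex

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            dup = sorted({s for s in serials if serials.count(s) > 1})
            raise ChemIOError(f"duplicate atom serial(s): {dup}")
        if self.kind not in ("receptor", "ligand", "complex"):
            raise ChemIOError(f"unknown structure kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float).reshape(len(self.atoms), 3)
        for a, x in zip(self.atoms, xyz):
            a.coords = x.copy()

    @property
    def charges(self) -> np.ndarray:
        missing = [a.serial for a in self.atoms if not a.has_charge]
        if missing:
            raise ParameterError(f"atoms without partial charge: {missing}")
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def require_parameters(self) -> None:
        missing = [a.serial for a in self.atoms if not a.is_parameterized]
        if missing:
            raise ParameterError(f"unparameterized atoms (serials): {missing}")

    @property
    def lj_epsilons(self) -> np.ndarray:
        self.require_parameters()
        return np.array([a.lj_epsilon for a in self.atoms], dtype=float)

    @property
    def lj_rmins(self) -> np.ndarray:
        self.require_parameters()
        return np.array([a.lj_rmin for a in self.atoms], dtype=float)

    @property
    def born_radii(self) -> np.ndarray:
        self.require_parameters()
        return np.array([a.born_radius for a in self.atoms], dtype=float)

    def copy(self) -> "MolecularStructure":
        return MolecularStructure(
            [a.copy() for a in self.atoms], title=self.title, kind=self.kind
        )

    def translated(self, shift: Sequence[float]) -> "MolecularStructure":
        out = self.copy()
        shift = np.asarray(shift, dtype=float)
        for a in out.atoms:
            a.coords = a.coords + shift
        return out

    def rotated(self, rotation: np.ndarray, center: Sequence[float]) -> "MolecularStructure":
        """Rigidly rotate all atoms about ``center`` by matrix ``rotation``."""
        out = self.copy()
        center = np.asarray(center, dtype=float)
        R = np.asarray(rotation, dtype=float)
        for a in out.atoms:
            a.coords = center + R @ (a.coords - center)
        return out

    def select(self, predicate) -> "MolecularStructure":
        return MolecularStructure(
            [a.copy() for a in self.atoms if predicate(a)],
            title=self.title, kind=self.kind,
        )


def combine(receptor: MolecularStructure, ligand: MolecularStructure,
            title: str = "complex") -> MolecularStructure:
    """Union of receptor and ligand atoms; ligand serials are offset past the
    receptor's maximum to keep serials unique.  Atom order is receptor first,
    then ligand, which downstream code relies on to split a complex."""
    offset = max((a.serial for a in receptor.atoms), default=0)
    atoms = [a.copy() for a in receptor.atoms]
    for a in ligand.atoms:
        b = a.copy()
        b.serial = a.serial + offset
        atoms.append(b)
    out = MolecularStructure(atoms, title=title, kind="complex")
    assert out.n_atoms == receptor.n_atoms + ligand.n_atoms
    return out


def split_complex(complex_structure: MolecularStructure, n_receptor: int
                  ) -> tuple[MolecularStructure, MolecularStructure]:
    """Inverse of :func:`combine` given the receptor atom count."""
    if not 0 < n_receptor < complex_structure.n_atoms:
        raise ChemIOError("n_receptor must split the complex into two non-empty parts")
    rec = MolecularStructure(
        [a.copy() for a in complex_structure.atoms[:n_receptor]],
        title=complex_structure.title, kind="receptor")
    lig = MolecularStructure(
        [a.copy() for a in complex_structure.atoms[n_receptor:]],
        title=complex_structure.title, kind="ligand")
    return rec, lig


# ---------------------------------------------------------------------------
# Nonbonded parameter table


@dataclass(frozen=True)
class NonbondedParams:
    lj_epsilon: float      # kcal/mol, >= 0
    lj_rmin: float         # Å, per-atom contribution to the pair minimum
    born_radius: float     # Å, dielectric-boundary radius

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0 or self.lj_rmin <= 0 or self.born_radius <= 0:
            raise ParameterError(
                f"invalid nonbonded parameters {self!r}: epsilon >= 0, radii > 0"
            )


@dataclass
class ParameterTable:
    """Mapping atom-type key -> nonbonded parameters."""

    params: dict[str, NonbondedParams] = field(default_factory=dict)

    def __getitem__(self, key: str) -> NonbondedParams:
        return self.params[key]

    def __contains__(self, key: str) -> bool:
        return key in self.params

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterTable":
        df = pd.read_csv(path, comment="#")
        required = {"type", "lj_epsilon", "lj_rmin", "born_radius"}
        if not required.issubset(df.columns):
            raise ChemIOError(
                f"parameter table {path}: need columns {sorted(required)}"
            )
        if df["type"].duplicated().any():
            dup = df.loc[df["type"].duplicated(), "type"].tolist()
            raise ChemIOError(f"duplicate parameter type keys: {dup}")
        params = {
            str(r["type"]): NonbondedParams(
                float(r["lj_epsilon"]), float(r["lj_rmin"]), float(r["born_radius"])
            )
            for _, r in df.iterrows()
        }
        return cls(params)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"type": k, "lj_epsilon": p.lj_epsilon, "lj_rmin": p.lj_rmin,
             "born_radius": p.born_radius}
            for k, p in self.params.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


#: Element-keyed defaults for toy systems (rough CHARMM-like magnitudes).
DEFAULT_PARAMETERS = ParameterTable({
    "H": NonbondedParams(0.046, 0.90, 1.00),
    "C": NonbondedParams(0.100, 4.00, 1.90),
    "N": NonbondedParams(0.170, 3.70, 1.70),
    "O": NonbondedParams(0.120, 3.40, 1.60),
    "S": NonbondedParams(0.450, 4.00, 2.00),
})


def assign_parameters(structure: MolecularStructure, table: ParameterTable,
                      overrides: Mapping[str, str] | None = None
                      ) -> MolecularStructure:
    """Attach LJ/Born parameters to every atom; returns a new structure.

    The type key defaults to the element symbol; ``overrides`` maps atom
    *names* to alternative type keys.  Assignment is all-or-nothing: if any
    atom has no matching key the structure is returned unchanged and the
    error lists every missing key.
    """
    overrides = dict(overrides or {})
    keys = []
    for a in structure.atoms:
        keys.append(overrides.get(a.name, a.element))
    missing = sorted({k for k in keys if k not in table})
    if missing:
        raise ParameterError(f"no nonbonded parameters for type key(s): {missing}")
    out = structure.copy()
    for a, k in zip(out.atoms, keys):
        p = table[k]
        a.lj_epsilon = p.lj_epsilon
        a.lj_rmin = p.lj_rmin
        a.born_radius = p.born_radius
    return out


# ---------------------------------------------------------------------------
# Structure file I/O


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "mol2", "sdf"):
        return suffix
    raise ChemIOError(f"cannot infer structure format from {path}")


def _element_from_mol2_type(t: str) -> str:
    return t.split(".")[0].capitalize()


def read_structure(path: str | Path, fmt: str | None = None,
                   kind: str = "ligand",
                   charge_csv: str | Path | None = None) -> MolecularStructure:
    """Read a PDB/mol2/SDF file into a :class:`MolecularStructure`.

    mol2 TRIPOS charges and SDF ``PartialCharges`` properties are honored;
    for PDB, ``charge_csv`` (columns serial,charge) optionally supplies them.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such structure file: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "sdf":
        structure = _read_sdf(path, kind)
    else:
        structure = _read_mda(path, fmt, kind)
    if charge_csv is not None:
        _apply_charge_sidecar(structure, charge_csv)
    for a in structure.atoms:
        if a.element.upper() not in KNOWN_ELEMENTS:
            raise ChemIOError(
                f"unknown element {a.element!r} for atom serial {a.serial} ({a.name})"
            )
    return structure


def _read_mda(path: Path, fmt: str, kind: str) -> MolecularStructure:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # MDA raises assorted types for bad records
            raise ChemIOError(f"cannot parse {fmt} file {path}: {exc}") from exc
        ag = u.atoms
        has_charges = hasattr(ag, "charges") and fmt == "mol2"
        if hasattr(ag, "elements"):
            elements = [str(e).capitalize() for e in ag.elements]
        elif fmt == "mol2":
            elements = [_element_from_mol2_type(t) for t in ag.types]
        else:
            elements = [str(n)[0].capitalize() for n in ag.names]
        try:
            serials = [int(s) for s in ag.ids]
        except Exception:
            serials = list(range(1, len(ag) + 1))
        atoms = []
        for i in range(len(ag)):
            atoms.append(Atom(
                serial=serials[i],
                name=str(ag.names[i]),
                element=elements[i],
                coords=np.asarray(ag.positions[i], dtype=float),
                partial_charge=float(ag.charges[i]) if has_charges else None,
                residue_name=str(ag.resnames[i]) if hasattr(ag, "resnames") else "UNK",
                residue_number=int(ag.resids[i]) if hasattr(ag, "resids") else 1,
                chain=str(ag.chainIDs[i]) if hasattr(ag, "chainIDs") else "A",
            ))
    try:
        return MolecularStructure(atoms, title=path.stem, kind=kind)
    except ChemIOError as exc:
        raise ChemIOError(f"{path}: {exc}") from exc


def _read_sdf(path: Path, kind: str) -> MolecularStructure:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mol = next(iter(supplier), None)
    if mol is None:
        raise ChemIOError(f"cannot parse SDF file {path}")
    conf = mol.GetConformer()
    charges: list[float | None]
    if mol.HasProp("PartialCharges"):
        charges = [float(x) for x in mol.GetProp("PartialCharges").split()]
        if len(charges) != mol.GetNumAtoms():
            raise ChemIOError(
                f"{path}: PartialCharges property length != atom count")
    else:
        charges = [None] * mol.GetNumAtoms()
    atoms = []
    for i, at in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        atoms.append(Atom(
            serial=i + 1,
            name=f"{at.GetSymbol()}{i + 1}",
            element=at.GetSymbol().capitalize(),
            coords=np.array([pos.x, pos.y, pos.z]),
            partial_charge=charges[i],
            residue_name="LIG",
        ))
    title = mol.GetProp("_Name") if mol.HasProp("_Name") else path.stem
    return MolecularStructure(atoms, title=title or path.stem, kind=kind)


def _apply_charge_sidecar(structure: MolecularStructure, path: str | Path) -> None:
    df = pd.read_csv(path, comment="#")
    if not {"serial", "charge"}.issubset(df.columns):
        raise ChemIOError(f"charge sidecar {path}: need columns serial,charge")
    lookup = dict(zip(df["serial"].astype(int), df["charge"].astype(float)))
    for a in structure.atoms:
        if a.serial in lookup:
            a.partial_charge = lookup[a.serial]


def write_structure(structure: MolecularStructure, path: str | Path,
                    fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "pdb":
        _write_pdb(structure, path)
    elif fmt == "mol2":
        _write_mol2(structure, path)
    elif fmt == "sdf":
        _write_sdf(structure, path)
    else:
        raise ChemIOError(f"unsupported output format {fmt}")


def _write_pdb(structure: MolecularStructure, path: Path) -> None:
    lines = [f"TITLE     {structure.title}"]
    for a in structure.atoms:
        x, y, z = a.coords
        lines.append(
            "ATOM  {serial:>5d} {name:<4s}{resn:>4s} {chain:1s}{resi:>4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}".format(
                serial=a.serial, name=a.name[:4], resn=a.residue_name[:4],
                chain=(a.chain or "A")[:1], resi=a.residue_number,
                x=x, y=y, z=z, occ=1.0, b=0.0, el=a.element[:2].upper(),
            )
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_charge_sidecar(structure: MolecularStructure, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["serial", "charge"])
        for a in structure.atoms:
            w.writerow([a.serial, "" if a.partial_charge is None else repr(a.partial_charge)])


_MOL2_TYPE = {"C": "C.3", "N": "N.4", "O": "O.3", "H": "H", "S": "S.3"}


def _write_mol2(structure: MolecularStructure, path: Path) -> None:
    n = structure.n_atoms
    lines = [
        "@<TRIPOS>MOLECULE",
        structure.title or "molecule",
        f"{n} 0 1",
        "SMALL",
        "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for a in structure.atoms:
        q = 0.0 if a.partial_charge is None else a.partial_charge
        t = _MOL2_TYPE.get(a.element.upper(), a.element)
        lines.append(
            f"{a.serial:>7d} {a.name:<8s} {a.coords[0]:>10.4f} {a.coords[1]:>10.4f}"
            f" {a.coords[2]:>10.4f} {t:<8s} {a.residue_number:>3d}"
            f" {a.residue_name:<8s} {q:>12.6f}"
        )
    lines.append("@<TRIPOS>BOND")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_sdf(structure: MolecularStructure, path: Path) -> None:
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    for a in structure.atoms:
        mol.AddAtom(Chem.Atom(a.element.capitalize()))
    conf = Chem.Conformer(structure.n_atoms)
    for i, a in enumerate(structure.atoms):
        conf.SetAtomPosition(i, Point3D(*a.coords))
    mol.AddConformer(conf)
    m = mol.GetMol()
    m.SetProp("_Name", structure.title)
    if all(a.has_charge for a in structure.atoms):
        m.SetProp("PartialCharges",
                  " ".join(repr(a.partial_charge) for a in structure.atoms))
    writer = Chem.SDWriter(str(path))
    writer.write(m)
    writer.close()


# ---------------------------------------------------------------------------
# Affinity tables


@dataclass
class AffinityRecord:
    """One ligand's measured affinity and its free-energy conversion.

    ``dg_exp = RT ln(Ki)`` on the 1 M standard state, T = 298 K by default.
    """

    ligand_id: str
    dg_exp: float
    ki_molar: float | None = None
    pki: float | None = None
    dataset_label: str = "other"
    assay_note: str = ""


def ki_to_dg(ki_molar: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Free energy of binding (kcal/mol) from an inhibition constant (mol/L)."""
    if not np.isfinite(ki_molar) or ki_molar <= 0:
        raise ValueError(f"Ki must be positive and finite, got {ki_molar}")
    return GAS_CONSTANT_KCAL * temperature * float(np.log(ki_molar))


def pki_to_dg(pki: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Free energy from pKi = -log10(Ki/M)."""
    return ki_to_dg(10.0 ** (-pki), temperature)


_KI_COLUMNS = ("ki_molar", "ki_nM", "pki")


def read_affinity_table(path: str | Path, ki_column: str | None = None,
                        temperature: float = DEFAULT_TEMPERATURE
                        ) -> list[AffinityRecord]:
    """Load a CSV of ligand affinities and convert to free energies.

    Exactly one of the columns ``ki_molar`` / ``ki_nM`` / ``pki`` must be
    present (or named via ``ki_column``).  Row order is preserved.
    """
    df = pd.read_csv(path, comment="#")
    if "ligand_id" not in df.columns:
        raise ChemIOError(f"{path}: missing ligand_id column")
    present = [c for c in _KI_COLUMNS if c in df.columns]
    if ki_column is not None:
        if ki_column not in df.columns:
            raise ChemIOError(f"{path}: declared ki column {ki_column!r} absent")
        present = [ki_column]
    if len(present) != 1:
        raise ChemIOError(
            f"{path}: need exactly one of {_KI_COLUMNS}, found {present}")
    col = present[0]
    if df["ligand_id"].duplicated().any():
        dup = df.loc[df["ligand_id"].duplicated(), "ligand_id"].tolist()
        raise ChemIOError(f"{path}: duplicate ligand_id(s): {dup}")
    records = []
    for i, row in df.iterrows():
        val = float(row[col])
        if col == "pki":
            ki = 10.0 ** (-val)
            pki = val
        else:
            ki = val * 1e-9 if col == "ki_nM" else val
            if ki <= 0:
                raise ChemIOError(f"{path} row {i}: nonpositive Ki {val}")
            pki = -float(np.log10(ki))
        records.append(AffinityRecord(
            ligand_id=str(row["ligand_id"]),
            ki_molar=ki,
            pki=pki,
            dg_exp=ki_to_dg(ki, temperature),
            dataset_label=str(row.get("dataset_label", "other")),
            assay_note=str(row.get("assay_note", "")),
        ))
    return records


# ---------------------------------------------------------------------------
# Energy-term tables


@dataclass
class EnergyTableRow:
    """One ligand pose's three interaction-energy regressors and response."""

    ligand_id: str
    dE_vdw: float
    dE_coul: float
    dG_solv: float
    dg_exp: float
    dataset_label: str = "other"
    docking_program: str = ""
    receptor_model: str = ""

    def __post_init__(self) -> None:
        for f in ("dE_vdw", "dE_coul", "dG_solv", "dg_exp"):
            if not np.isfinite(getattr(self, f)):
                raise ChemIOError(f"ligand {self.ligand_id}: non-finite {f}")


CANONICAL_ENERGY_COLUMNS = (
    "ligand_id", "dE_vdw", "dE_coul", "dG_solv", "dg_exp",
    "dataset_label", "docking_program", "receptor_model",
)


def read_energy_table(path: str | Path,
                      column_map: Mapping[str, str] | None = None
                      ) -> list[EnergyTableRow]:
    """Read an energy-term CSV.

    ``column_map`` maps *file* column names to canonical ones
    (``ligand_id, dE_vdw, dE_coul, dG_solv, dg_exp, dataset_label,
    docking_program, receptor_model``) so externally produced tables with
    arbitrary headers can be loaded.
    """
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    numeric = ("dE_vdw", "dE_coul", "dG_solv", "dg_exp")
    missing = [c for c in ("ligand_id",) + numeric if c not in df.columns]
    if missing:
        raise ChemIOError(f"{path}: missing mapped column(s) {missing}")
    rows = []
    for i, row in df.iterrows():
        vals = {}
        for c in numeric:
            try:
                vals[c] = float(row[c])
            except (TypeError, ValueError) as exc:
                raise ChemIOError(
                    f"{path} row {i}: non-numeric value {row[c]!r} in {c}") from exc
        rows.append(EnergyTableRow(
            ligand_id=str(row["ligand_id"]),
            dataset_label=str(row.get("dataset_label", "other")),
            docking_program=str(row.get("docking_program", "")),
            receptor_model=str(row.get("receptor_model", "")),
            **vals,
        ))
    seen = set()
    for r in rows:
        key = (r.ligand_id, r.docking_program, r.receptor_model)
        if key in seen:
            raise ChemIOError(f"{path}: duplicate energy row for {key}")
        seen.add(key)
    return rows


def filter_energy_rows(rows: Iterable[EnergyTableRow], *,
                       dataset_label: str | None = None,
                       docking_program: str | None = None,
                       receptor_model: str | None = None) -> list[EnergyTableRow]:
    out = []
    for r in rows:
        if dataset_label is not None and r.dataset_label != dataset_label:
            continue
        if docking_program is not None and r.docking_program != docking_program:
            continue
        if receptor_model is not None and r.receptor_model != receptor_model:
            continue
        out.append(r)
    return out


def write_energy_table(rows: Sequence[EnergyTableRow], path: str | Path,
                       header_comment: str | None = None) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in CANONICAL_ENERGY_COLUMNS}
                       for r in rows])
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
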