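import numpy as np
import pytest

from liece import (ComplexSpec, EnergyConfig, FilterRules, gen_toy_complex)
from liece.chem_io import Atom, MolecularStructure


@pytest.fixture(scope="session")
def toy_system():
    """Default toy pocket-ligand system (complex, protein, ligand)."""
    return gen_toy_complex(ComplexSpec(seed=0))


@pytest.fixture
def config():
    return EnergyConfig()


@pytest.fixture
def rules():
    return FilterRules()


def make_atom(serial, element, xyz, q=0.0, eps=0.1, rmin=4.0, born=1.9,
              name=None, resname="UNK", resnum=1):
    return Atom(serial, name or f"{element}{serial}", element,
                np.asarray(xyz, dtype=float), partial_charge=q,
                lj_epsilon=eps, lj_rmin=rmin, born_radius=born,
                residue_name=resname, residue_number=resnum)


def make_structure(atom_specs, kind="ligand", **kwargs):
    atoms = [make_atom(i + 1, el, xyz, **ats)
             for i, (el, xyz, ats) in enumerate(atom_specs)]
    return MolecularStructure(atoms, kind=kind, **kwargs)


@pytest.fixture
def random_cluster():
    """Seeded 8-atom cluster with mixed charges for brute-force oracles."""
    rng = np.random.default_rng(42)
    atoms = []
    for i in range(8):
        atoms.append(make_atom(
            i + 1, "C", rng.uniform(-4, 4, 3), q=float(rng.uniform(-0.5, 0.5)),
            eps=float(rng.uniform(0.05, 0.3)), rmin=float(rng.uniform(3.0, 4.5)),
            born=float(rng.uniform(1.5, 2.2))))
    return MolecularStructure(atoms)
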