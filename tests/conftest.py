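import numpy as np
import pytest

from somtool.core import Atom, Frame, FunctionalGroup, Molecule, Species, Topology
from somtool.synthetic import SyntheticSpec, make_system


def simple_molecule(atom_specs, species=Species.COSOLVENT, mol_id=0, base=0):
    """Build Atom objects for one molecule from (name, element, mass, charge,
    group) tuples."""
    atoms = []
    for k, (name, element, mass, charge, group) in enumerate(atom_specs):
        atoms.append(
            Atom(id=base + k, name=name, element=element, mass=mass,
                 charge=charge, functional_group=group, molecule_id=mol_id)
        )
    mol = Molecule(mol_id, species, [a.id for a in atoms],
                   sum(a.charge for a in atoms))
    return atoms, mol


@pytest.fixture
def acetate_topology():
    """One explicit-hydrogen acetate anion CH3COO-."""
    specs = [
        ("C1", "C", 12.011, 0.27, FunctionalGroup.CARBOXYL),
        ("O1", "O", 15.999, -0.635, FunctionalGroup.NONE),
        ("O2", "O", 15.999, -0.635, FunctionalGroup.NONE),
        ("C2", "C", 12.011, 0.0, FunctionalGroup.ALIPHATIC),
        ("H1", "H", 1.008, 0.0, FunctionalGroup.NONE),
        ("H2", "H", 1.008, 0.0, FunctionalGroup.NONE),
        ("H3", "H", 1.008, 0.0, FunctionalGroup.NONE),
    ]
    atoms, mol = simple_molecule(specs)
    return Topology(atoms, [mol])


@pytest.fixture
def water_box_spec():
    return SyntheticSpec(seed=42, box=4.0,
                         cosolvent_counts={"water": 40, "ca": 8, "cl": 16},
                         n_frames=20, dt=10.0)


@pytest.fixture
def small_protein_system():
    spec = SyntheticSpec(seed=7, box=6.0, n_protein_beads=8,
                         cosolvent_counts={"acetate": 10, "water": 10},
                         neutralize=True, n_frames=5)
    top, frame = make_system(spec)
    return spec, top, frame


@pytest.fixture
def rng():
    return np.random.default_rng(123)
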