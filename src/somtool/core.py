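"""Core domain types and composition accounting.

Unit conventions used throughout the package: lengths in nm, times in ps,
energies in kJ/mol, masses in amu, charges in units of the elementary
charge e.  File formats that use other units (PDB: Angstrom) are converted
at the I/O boundary only.

The central containers are :class:`Topology` (atoms grouped into molecules,
carrying charges, Lennard-Jones coefficients, hydrogen-bond donor/acceptor
annotations and functional-group labels), :class:`Frame` (one set of
periodic-box coordinates) and :class:`Trajectory` (an ordered sequence of
frames over one topology).  Functional-group labels follow the six carbon
categories used to characterise humic-substance building blocks: carbonyl,
carboxyl, aryl, acetal, heteroaliphatic and aliphatic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FunctionalGroup",
    "Species",
    "Atom",
    "Molecule",
    "Topology",
    "Frame",
    "Trajectory",
    "ATOMIC_MASSES",
    "carbon_fractions",
    "average_molecular_weight",
    "analysis_window",
    "CompositionError",
    "TopologyError",
]

#: Standard IUPAC atomic masses (amu) for the elements the toolkit handles.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "Ca": 40.078,
    "Cl": 35.45,
}


class CompositionError(ValueError):
    """Raised when a composition quantity is undefined (e.g. no carbon)."""


class TopologyError(ValueError):
    """Raised for inconsistent topology annotations."""


class FunctionalGroup(str, enum.Enum):
    """Carbon functional-group categories of organic co-solvent molecules."""

    CARBONYL = "carbonyl"
    CARBOXYL = "carboxyl"
    ARYL = "aryl"
    ACETAL = "acetal"
    HETEROALIPHATIC = "heteroaliphatic"
    ALIPHATIC = "aliphatic"
    NONE = "none"


class Species(str, enum.Enum):
    """Molecule-level species classes used for grouping analyses."""

    PROTEIN = "protein"
    SOM = "som"
    WATER = "water"
    CATION = "cation"
    ANION = "anion"
    COSOLVENT = "cosolvent"


@dataclass
class Atom:
    """One interaction site.

    United-atom sites (e.g. a CH3 group treated as one site) carry the mass
    of the whole group but element ``"C"``; hydrogens that matter for
    hydrogen bonding are explicit sites.
    """

    id: int
    name: str
    element: str
    mass: float
    charge: float = 0.0
    c6: float = 0.0   # kJ mol^-1 nm^6
    c12: float = 0.0  # kJ mol^-1 nm^12
    is_donor_heavy: bool = False
    attached_h_ids: list[int] = field(default_factory=list)
    is_acceptor: bool = False
    functional_group: FunctionalGroup = FunctionalGroup.NONE
    molecule_id: int = -1

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise TopologyError(f"atom {self.id}: mass must be positive")


@dataclass
class Molecule:
    id: int
    species: Species
    atom_ids: list[int]
    net_charge: float = 0.0


@dataclass
class Topology:
    """Atoms partitioned into molecules.

    Atom ids must be dense 0..N-1 and each atom must belong to exactly one
    molecule; ``validate`` enforces this together with the per-molecule
    net-charge bookkeeping.
    """

    atoms: list[Atom]
    molecules: list[Molecule]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.atoms)
        if [a.id for a in self.atoms] != list(range(n)):
            raise TopologyError("atom ids must be dense 0..N-1 in order")
        for a in self.atoms:
            if a.is_donor_heavy and not a.attached_h_ids:
                raise TopologyError(
                    f"atom {a.id}: donor heavy atom without attached hydrogens"
                )
            if a.attached_h_ids and not a.is_donor_heavy:
                raise TopologyError(
                    f"atom {a.id}: attached hydrogens but not flagged as donor"
                )
        seen: set[int] = set()
        for mol in self.molecules:
            for aid in mol.atom_ids:
                if aid in seen:
                    raise TopologyError(f"atom {aid} in more than one molecule")
                seen.add(aid)
                if self.atoms[aid].molecule_id != mol.id:
                    raise TopologyError(
                        f"atom {aid} molecule_id does not match molecule {mol.id}"
                    )
            q = sum(self.atoms[aid].charge for aid in mol.atom_ids)
            if abs(q - mol.net_charge) > 1e-6:
                raise TopologyError(
                    f"molecule {mol.id}: net_charge {mol.net_charge} != sum of "
                    f"atom charges {q}"
                )
        if len(seen) != n:
            raise TopologyError("every atom must belong to exactly one molecule")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def species_of_atom(self, atom_id: int) -> Species:
        return self.molecules[self.atoms[atom_id].molecule_id].species

    def atom_ids_of_species(self, *species: Species) -> np.ndarray:
        wanted = set(species)
        ids = [
            aid
            for mol in self.molecules
            if mol.species in wanted
            for aid in mol.atom_ids
        ]
        return np.asarray(sorted(ids), dtype=int)

    def molecules_of_species(self, *species: Species) -> list[Molecule]:
        wanted = set(species)
        return [m for m in self.molecules if m.species in wanted]

    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))


@dataclass
class Frame:
    """One snapshot: orthorhombic box edges (nm) and N x 3 coordinates (nm)."""

    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(self.box > 0):
            raise ValueError("box edge lengths must be positive")

    def copy(self) -> "Frame":
        return Frame(self.time, self.box.copy(), self.coords.copy())


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        for f in self.frames:
            if f.coords.shape[0] != self.topology.n_atoms:
                raise ValueError(
                    "frame coordinate count does not match topology atom count"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([f.time for f in self.frames])


# ---------------------------------------------------------------------------
# Composition accounting


def _filter_molecules(topology: Topology, species_filter) -> list[Molecule]:
    if species_filter is None:
        return list(topology.molecules)
    if isinstance(species_filter, (Species, str)):
        species_filter = {Species(species_filter)}
    else:
        species_filter = {Species(s) for s in species_filter}
    return [m for m in topology.molecules if m.species in species_filter]


def carbon_fractions(topology: Topology, species_filter=None) -> dict[FunctionalGroup, float]:
    """Fractions of carbon atoms per functional group among the filtered species.

    Only carbon atoms enter numerator and denominator, so the fractions sum
    to one.  Raises :class:`CompositionError` if the filtered molecules
    contain no carbon.
    """
    mols = _filter_molecules(topology, species_filter)
    counts: dict[FunctionalGroup, int] = {}
    n_carbon = 0
    for mol in mols:
        for aid in mol.atom_ids:
            atom = topology.atoms[aid]
            if atom.element != "C":
                continue
            n_carbon += 1
            counts[atom.functional_group] = counts.get(atom.functional_group, 0) + 1
    if n_carbon == 0:
        raise CompositionError("no carbon atoms in the filtered species")
    return {g: c / n_carbon for g, c in counts.items()}


def average_molecular_weight(topology: Topology, species_filter=None) -> float:
    """Mean molecular weight (g/mol) over the filtered molecules."""
    mols = _filter_molecules(topology, species_filter)
    if not mols:
        raise CompositionError("species filter matches no molecules")
    weights = [
        sum(topology.atoms[aid].mass for aid in mol.atom_ids) for mol in mols
    ]
    return float(np.mean(weights))


def analysis_window(trajectory: Trajectory, discard_fraction: float) -> Trajectory:
    """Drop the leading equilibration portion of a trajectory.

    ``discard_fraction`` is the fraction of frames discarded from the front
    (e.g. 0.2 keeps the trailing 80%, the convention of discarding the first
    fifth of a production run as equilibration).
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    n = len(trajectory.frames)
    start = int(np.floor(n * discard_fraction))
    frames = trajectory.frames[start:]
    if not frames:
        raise ValueError("analysis window is empty")
    return Trajectory(trajectory.topology, frames)
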