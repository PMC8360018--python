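"""Synthetic systems and trajectories with planted, known structure.

Every analysis stage of the toolkit (contact shells, hydrogen-bond
networks, Kirkwood-Buff limits, conformational ensembles) can be exercised
on data generated here, where the ground truth is planted by construction:

* *contact shells* — a chosen functional group or ion is placed each frame
  at a distance drawn from Normal(target, width) to its nearest protein
  site, so the minimum-distance function has a known distribution;
* *hydrogen-bond graphs* — molecules are laid out on a coarse grid and
  donor arms are oriented so that exactly the requested molecule pairs
  satisfy the geometric hydrogen-bond criterion;
* *ideal gas* — molecules are placed independently and uniformly each
  frame, so pair correlations vanish (g(r) = 1, Kirkwood-Buff integrals 0);
* *Gaussian ensembles* — conformations drawn from a specified multivariate
  normal, the ground truth for fluctuation and ensemble-similarity metrics.

Frames are statistical constructions, not dynamics: no forces, no sampling
weights.  All generators are pure functions of (spec, seed).

Molecule templates mirror the simple co-solvent systems used to probe
humic-substance chemistry: a 4-site acetate-like anion (one carboxyl and
one united-atom methyl carbon, two acceptor oxygens), a 9-site
benzoate-like anion (aromatic ring plus carboxylate), SPC-like 3-site
water, monatomic Ca2+/Cl-, a small humic fragment with one donor arm and
one acceptor, and an N-bead model protein chain with alternating donor and
acceptor beads.  United-atom carbon masses (CH3 15.035, aromatic CH
13.019) are used so the templates reproduce the molecular weights of the
real compounds (acetate 59 g/mol, benzoate 121 g/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    Atom,
    Frame,
    FunctionalGroup,
    Molecule,
    Species,
    Topology,
    Trajectory,
)
from .geometry import min_image_distance_matrix, wrap

__all__ = [
    "SyntheticSpec",
    "PackingError",
    "UnsatisfiableGraphError",
    "make_system",
    "make_trajectory",
    "make_gaussian_ensemble",
    "make_aggregation_trajectory",
    "TEMPLATES",
]


class PackingError(RuntimeError):
    """Raised when molecules cannot be placed at the required spacing."""


class UnsatisfiableGraphError(RuntimeError):
    """Raised when a planted hydrogen-bond graph cannot be realized."""


# ---------------------------------------------------------------------------
# Molecule templates

_LJ_C6 = 4 * 0.4 * 0.32**6   # epsilon=0.4 kJ/mol, sigma=0.32 nm
_LJ_C12 = 4 * 0.4 * 0.32**12


@dataclass
class _AtomTmpl:
    name: str
    element: str
    mass: float
    charge: float
    xyz: tuple[float, float, float]
    donor: bool = False
    acceptor: bool = False
    group: FunctionalGroup = FunctionalGroup.NONE
    h_of: int | None = None  # index (within template) of the donor heavy atom


def _heavy_lj(tmpl: _AtomTmpl) -> tuple[float, float]:
    if tmpl.element == "H":
        return 0.0, 0.0
    return _LJ_C6, _LJ_C12


_ACETATE = (
    Species.COSOLVENT,
    [
        _AtomTmpl("C1", "C", 12.011, 0.27, (0.0, 0.0, 0.0),
                  group=FunctionalGroup.CARBOXYL),
        _AtomTmpl("O1", "O", 15.999, -0.635, (0.0625, 0.1083, 0.0), acceptor=True),
        _AtomTmpl("O2", "O", 15.999, -0.635, (0.0625, -0.1083, 0.0), acceptor=True),
        _AtomTmpl("C2", "C", 15.035, 0.0, (-0.153, 0.0, 0.0),
                  group=FunctionalGroup.ALIPHATIC),
    ],
)

_RING = [
    (0.139 * np.cos(np.pi / 3 * k), 0.139 * np.sin(np.pi / 3 * k), 0.0)
    for k in range(6)
]
_BENZOATE = (
    Species.COSOLVENT,
    [
        # ipso carbon (bare C) followed by five aromatic CH united atoms
        _AtomTmpl("C1", "C", 12.011, 0.0, _RING[0], group=FunctionalGroup.ARYL),
    ]
    + [
        _AtomTmpl(f"C{k + 1}", "C", 13.019, 0.0, _RING[k],
                  group=FunctionalGroup.ARYL)
        for k in range(1, 6)
    ]
    + [
        _AtomTmpl("C7", "C", 12.011, 0.27, (0.287, 0.0, 0.0),
                  group=FunctionalGroup.CARBOXYL),
        _AtomTmpl("O1", "O", 15.999, -0.635, (0.3495, 0.1083, 0.0), acceptor=True),
        _AtomTmpl("O2", "O", 15.999, -0.635, (0.3495, -0.1083, 0.0), acceptor=True),
    ],
)

_WATER = (
    Species.WATER,
    [
        _AtomTmpl("OW", "O", 15.999, -0.82, (0.0, 0.0, 0.0),
                  donor=True, acceptor=True),
        _AtomTmpl("HW1", "H", 1.008, 0.41, (0.1, 0.0, 0.0), h_of=0),
        _AtomTmpl("HW2", "H", 1.008, 0.41, (-0.0334, 0.0943, 0.0), h_of=0),
    ],
)

# humic-fragment: one donor arm (C-OH) along +x, one acceptor oxygen on -x;
# the 180 deg H-D-A geometry keeps the arm from hydrogen-bonding its own
# acceptor under the angular criterion.
_SOM_FRAGMENT = (
    Species.SOM,
    [
        _AtomTmpl("C1", "C", 14.027, 0.15, (0.0, 0.0, 0.0),
                  group=FunctionalGroup.ALIPHATIC),
        _AtomTmpl("OD", "O", 15.999, -0.548, (0.143, 0.0, 0.0), donor=True),
        _AtomTmpl("HD", "H", 1.008, 0.398, (0.241, 0.0, 0.0), h_of=1),
        _AtomTmpl("OA", "O", 15.999, 0.0, (-0.143, 0.0, 0.0), acceptor=True),
    ],
)

_CA = (Species.CATION, [_AtomTmpl("CA", "Ca", 40.078, 2.0, (0.0, 0.0, 0.0))])
_CL = (Species.ANION, [_AtomTmpl("CL", "Cl", 35.45, -1.0, (0.0, 0.0, 0.0))])

TEMPLATES: dict[str, tuple[Species, list[_AtomTmpl]]] = {
    "acetate": _ACETATE,
    "benzoate": _BENZOATE,
    "water": _WATER,
    "som": _SOM_FRAGMENT,
    "ca": _CA,
    "cl": _CL,
}

_PROTEIN_BOND = 0.38  # bead spacing along the chain, nm
_HB_CONTACT = 0.25    # planted donor-acceptor heavy-atom distance, nm
_HB_OH = 0.098        # O-H bond length, nm
_GRID_SPACING = 1.5   # planted-graph lattice constant, nm


def _protein_template(n_beads: int, net_charge: float) -> list[_AtomTmpl]:
    """Chain of CA-like beads along x; odd beads donate (explicit H on +y),
    even beads accept.  Any net charge is placed on the first bead."""
    tmpl: list[_AtomTmpl] = []
    for i in range(n_beads):
        x = i * _PROTEIN_BOND
        donor = i % 2 == 1
        tmpl.append(
            _AtomTmpl(
                f"B{i + 1}", "C", 12.011,
                net_charge if i == 0 else 0.0,
                (x, 0.0, 0.0),
                donor=donor,
                acceptor=not donor,
            )
        )
    heavy_count = len(tmpl)
    hs = []
    for i, t in enumerate(tmpl):
        if t.donor:
            hs.append(
                _AtomTmpl(f"HB{i + 1}", "H", 1.008, 0.0,
                          (t.xyz[0], 0.1, 0.0), h_of=i)
            )
    return tmpl + hs


# ---------------------------------------------------------------------------
# Spec


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic system and its trajectory."""

    seed: int = 0
    box: float = 5.0  # nm, cubic
    n_protein_beads: int = 0
    protein_net_charge: float = 0.0
    cosolvent_counts: dict[str, int] = field(default_factory=dict)
    neutralize: bool = False
    planted_shell: tuple[str, float, float] | None = None
    planted_hbond_graph: dict[int, list[int]] | None = None
    n_frames: int = 10
    dt: float = 10.0  # ps
    min_spacing: float = 0.2  # nm, packing constraint in make_system


# ---------------------------------------------------------------------------
# System construction


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()


class _Builder:
    def __init__(self):
        self.atoms: list[Atom] = []
        self.molecules: list[Molecule] = []
        self.coords: list[np.ndarray] = []
        self.template_of: list[str] = []

    def add_molecule(self, name: str, species: Species,
                     tmpl: list[_AtomTmpl], placed: np.ndarray) -> int:
        mol_id = len(self.molecules)
        base = len(self.atoms)
        atom_ids = []
        for t, xyz in zip(tmpl, placed):
            aid = base + len(atom_ids)
            self.atoms.append(
                Atom(
                    id=aid, name=t.name, element=t.element, mass=t.mass,
                    charge=t.charge, c6=_heavy_lj(t)[0], c12=_heavy_lj(t)[1],
                    is_donor_heavy=t.donor,
                    attached_h_ids=[],
                    is_acceptor=t.acceptor,
                    functional_group=t.group,
                    molecule_id=mol_id,
                )
            )
            atom_ids.append(aid)
            self.coords.append(np.asarray(xyz, dtype=float))
        # wire hydrogens to their donor heavy atoms
        for t, aid in zip(tmpl, atom_ids):
            if t.h_of is not None:
                self.atoms[atom_ids[t.h_of]].attached_h_ids.append(aid)
        net = sum(t.charge for t in tmpl)
        self.molecules.append(Molecule(mol_id, species, atom_ids, net))
        self.template_of.append(name)
        return mol_id

    def finish(self, box: float, time: float = 0.0) -> tuple[Topology, Frame]:
        for a in self.atoms:
            if a.is_donor_heavy and not a.attached_h_ids:
                raise ValueError(f"donor atom {a.id} has no hydrogen")
        top = Topology(self.atoms, self.molecules)
        frame = Frame(time, np.full(3, box), np.asarray(self.coords))
        return top, frame


def _tmpl_coords(tmpl: list[_AtomTmpl]) -> np.ndarray:
    xyz = np.asarray([t.xyz for t in tmpl], dtype=float)
    return xyz - xyz.mean(axis=0)


def _place_packed(builder: _Builder, name: str, species: Species,
                  tmpl: list[_AtomTmpl], box: float, min_spacing: float,
                  rng: np.random.Generator, rotate: bool = True,
                  max_tries: int = 500) -> int:
    local = _tmpl_coords(tmpl)
    existing = (
        np.asarray(builder.coords) if builder.coords else np.empty((0, 3))
    )
    box3 = np.full(3, box)
    for _ in range(max_tries):
        center = rng.uniform(0.0, box, size=3)
        placed = local @ (_random_rotation(rng).T if rotate else np.eye(3))
        placed = wrap(placed + center, box3)
        if existing.size:
            dmin = min_image_distance_matrix(placed, existing, box3).min()
            if dmin < min_spacing:
                continue
        return builder.add_molecule(name, species, tmpl, placed)
    raise PackingError(
        f"could not place a {name} molecule at >= {min_spacing} nm spacing "
        f"in a {box} nm box"
    )


def make_system(spec: SyntheticSpec) -> tuple[Topology, Frame]:
    """Build the topology and an initial packed frame for a spec.

    The protein chain (if any) is placed through the box centre; co-solvent
    molecules are packed at random positions/orientations subject to the
    minimum-spacing constraint.  With ``neutralize`` set, Ca2+/Cl- counter
    ions are appended until the total charge vanishes.
    """
    rng = np.random.default_rng(spec.seed)
    b = _Builder()
    box3 = np.full(3, spec.box)
    if spec.n_protein_beads:
        tmpl = _protein_template(spec.n_protein_beads, spec.protein_net_charge)
        local = np.asarray([t.xyz for t in tmpl], dtype=float)
        span = local[:, 0].max() - local[:, 0].min()
        if span > spec.box:
            raise PackingError("protein chain longer than the box")
        center = np.full(3, spec.box / 2.0)
        placed = local - local.mean(axis=0) + center
        b.add_molecule("protein", Species.PROTEIN, tmpl, placed)
    for name, count in spec.cosolvent_counts.items():
        species, tmpl = TEMPLATES[name]
        for _ in range(count):
            _place_packed(b, name, species, tmpl, spec.box, spec.min_spacing, rng)
    if spec.neutralize:
        net = sum(m.net_charge for m in b.molecules)
        while net < -1e-9:
            _place_packed(b, "ca", *TEMPLATES["ca"], spec.box,
                          spec.min_spacing, rng, rotate=False)
            net += 2.0
        while net > 1e-9:
            _place_packed(b, "cl", *TEMPLATES["cl"], spec.box,
                          spec.min_spacing, rng, rotate=False)
            net -= 1.0
        if abs(net) > 1e-9:
            raise ValueError(f"cannot neutralize residual charge {net}")
    return b.finish(spec.box)


# ---------------------------------------------------------------------------
# Trajectories


def _group_instances(topology: Topology, label: str):
    """Atom-id groups for a functional-group label or ion species name.

    A functional-group instance is a contiguous run of same-labelled atoms
    within one molecule; an ion instance is the single ion atom.
    """
    instances: list[np.ndarray] = []
    if label in ("ca", "cl", "cation", "anion", "water"):
        species = {"ca": Species.CATION, "cation": Species.CATION,
                   "cl": Species.ANION, "anion": Species.ANION,
                   "water": Species.WATER}[label]
        for mol in topology.molecules_of_species(species):
            instances.append(np.asarray(mol.atom_ids))
        return instances
    group = FunctionalGroup(label)
    for mol in topology.molecules:
        run: list[int] = []
        for aid in mol.atom_ids:
            if topology.atoms[aid].functional_group is group:
                run.append(aid)
            elif run:
                instances.append(np.asarray(run))
                run = []
        if run:
            instances.append(np.asarray(run))
    return instances


def make_trajectory(spec: SyntheticSpec,
                    topology: Topology | None = None) -> Trajectory:
    """Generate frames with the planted structure requested by the spec.

    Exactly one of three behaviours applies: a planted contact shell, a
    planted hydrogen-bond graph, or (neither) independent uniform placement
    of every molecule each frame (the ideal-gas reference).
    """
    if topology is None:
        topology, frame0 = make_system(spec)
    else:
        _, frame0 = make_system(spec)
    rng = np.random.default_rng([spec.seed, 1])
    box3 = np.full(3, spec.box)
    if spec.planted_shell is not None:
        label, target, width = spec.planted_shell
        if target >= spec.box / 2:
            raise ValueError("planted distance must be below half the box")
        frames = [
            _shell_frame(spec, topology, frame0, label, target, width, rng, k)
            for k in range(spec.n_frames)
        ]
    elif spec.planted_hbond_graph is not None:
        coords = _realize_graph(spec, topology, spec.planted_hbond_graph,
                                frame0.coords)
        frames = [
            Frame(k * spec.dt, box3.copy(), coords.copy())
            for k in range(spec.n_frames)
        ]
    else:
        frames = [
            _ideal_gas_frame(spec, topology, frame0, rng, k)
            for k in range(spec.n_frames)
        ]
    return Trajectory(topology, frames)


def _ideal_gas_frame(spec, topology, frame0, rng, k) -> Frame:
    box3 = np.full(3, spec.box)
    coords = np.empty((topology.n_atoms, 3))
    for mol in topology.molecules:
        ids = np.asarray(mol.atom_ids)
        # rigid placement at a uniform centre with random orientation
        base = _local_coords(topology, mol, frame0.coords)
        R = _random_rotation(rng)
        coords[ids] = wrap(base @ R.T + rng.uniform(0, spec.box, 3), box3)
    return Frame(k * spec.dt, box3, coords)


def _local_coords(topology: Topology, mol: Molecule,
                  ref_coords: np.ndarray | None = None) -> np.ndarray:
    """Reference internal geometry of a molecule: its template if known,
    otherwise its (centred) coordinates in the reference frame."""
    tmpl = _TEMPLATE_LOOKUP.get(tuple(
        topology.atoms[a].name for a in mol.atom_ids))
    if tmpl is None:
        if ref_coords is None:
            raise ValueError(
                f"molecule {mol.id} has no template and no reference frame")
        xyz = ref_coords[np.asarray(mol.atom_ids)]
        return xyz - xyz.mean(axis=0)
    xyz = np.asarray([t.xyz for t in tmpl], dtype=float)
    return xyz - xyz.mean(axis=0)


_TEMPLATE_LOOKUP = {
    tuple(t.name for t in tmpl): tmpl for _, (sp, tmpl) in TEMPLATES.items()
}


def _shell_frame(spec, topology, frame0, label, target, width, rng, k) -> Frame:
    """Protein fixed; every labelled group instance placed at a sampled
    distance from its nearest protein bead, along a direction perpendicular
    to the chain so the chosen bead is provably the nearest protein atom."""
    box3 = np.full(3, spec.box)
    protein = topology.molecules_of_species(Species.PROTEIN)
    if not protein:
        raise ValueError("planted shells require a protein chain")
    heavy = [a for a in protein[0].atom_ids if topology.atoms[a].element != "H"]
    coords = frame0.coords.copy()
    placed_mols: set[int] = set()
    instances = _group_instances(topology, label)
    if not instances:
        raise ValueError(f"no instances of group {label!r} in the topology")
    for inst in instances:
        d = -1.0
        while d <= 0:
            d = rng.normal(target, width)
        bead = heavy[rng.integers(len(heavy))]
        phi = rng.uniform(np.pi / 2, 3 * np.pi / 2)  # keep away from the +y H beads
        direction = np.array([0.0, np.cos(phi), np.sin(phi)])
        anchor = coords[bead] + d * direction
        mol = topology.molecules[topology.atoms[inst[0]].molecule_id]
        ids = np.asarray(mol.atom_ids)
        local = _local_coords(topology, mol, frame0.coords)
        # orient so the labelled instance's first atom is nearest the protein
        ref = local[list(ids).index(inst[0])]
        shifted = local - ref
        # push all other atoms outward along the ray
        proj = shifted @ direction
        shifted = shifted + np.outer(np.maximum(-proj, 0.0) * 1.0, direction)
        coords[ids] = anchor + shifted
        placed_mols.add(mol.id)
    # molecules without the label: uniform background
    for mol in topology.molecules:
        if mol.id in placed_mols or mol.species is Species.PROTEIN:
            continue
        ids = np.asarray(mol.atom_ids)
        base = _local_coords(topology, mol, frame0.coords)
        coords[ids] = wrap(base @ _random_rotation(rng).T
                           + rng.uniform(0, spec.box, 3), box3)
    return Frame(k * spec.dt, box3, coords)


# ---------------------------------------------------------------------------
# Planted hydrogen-bond graphs

_CARDINAL = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=int,
)


def _realize_graph(spec, topology, adjacency, ref_coords) -> np.ndarray:
    """Coordinates in which exactly the requested molecule pairs hydrogen-bond.

    Molecules sit on a lattice (spacing 1.5 nm).  Each connected component
    of the planted graph is traversed breadth-first; a child molecule's
    donor arm (donor heavy atom + hydrogen) is relocated collinear with its
    parent's acceptor oxygen at 0.25 nm heavy-atom separation, well inside
    the detection criterion, while all other intermolecular donor-acceptor
    pairs stay beyond it by the lattice spacing.  For graphs with cycles
    only a spanning tree of each component is realized geometrically; the
    connected components (what the cluster analysis consumes) are identical.
    """
    box3 = np.full(3, spec.box)
    n_cells = int(spec.box // _GRID_SPACING)
    if n_cells < 1:
        raise UnsatisfiableGraphError("box too small for the placement lattice")
    all_ids = [m.id for m in topology.molecules]
    adj = {int(k): [int(v) for v in vs] for k, vs in adjacency.items()}
    for k, vs in list(adj.items()):
        for v in vs:
            adj.setdefault(v, [])
            if k not in adj[v]:
                adj[v].append(k)
    if len(all_ids) > n_cells**3:
        raise UnsatisfiableGraphError("more molecules than lattice cells")

    occupied: dict[tuple[int, int, int], int] = {}
    cell_of: dict[int, tuple[int, int, int]] = {}
    free_cells = [(i, j, k) for i in range(n_cells)
                  for j in range(n_cells) for k in range(n_cells)]

    def take(cell):
        free_cells.remove(cell)
        return cell

    coords = np.zeros((topology.n_atoms, 3))
    parent_of: dict[int, int] = {}
    # BFS each planted component
    visited: set[int] = set()
    for root in sorted(adj):
        if root in visited:
            continue
        cell = take(free_cells[0])
        occupied[cell] = root
        cell_of[root] = cell
        queue = [root]
        visited.add(root)
        while queue:
            node = queue.pop(0)
            for nb in sorted(adj[node]):
                if nb in visited:
                    continue
                placed = False
                for step in _CARDINAL:
                    cand = tuple(np.asarray(cell_of[node]) + step)
                    if all(0 <= c < n_cells for c in cand) and cand in free_cells:
                        take(cand)
                        occupied[cand] = nb
                        cell_of[nb] = cand
                        parent_of[nb] = node
                        visited.add(nb)
                        queue.append(nb)
                        placed = True
                        break
                if not placed:
                    raise UnsatisfiableGraphError(
                        f"no free lattice cell adjacent to molecule {node} "
                        f"for neighbour {nb}"
                    )
    # non-graph molecules take the remaining cells
    for mol in topology.molecules:
        if mol.id not in cell_of:
            if not free_cells:
                raise UnsatisfiableGraphError("more molecules than lattice cells")
            cell = take(free_cells[0])
            cell_of[mol.id] = cell

    def cell_center(cell):
        return (np.asarray(cell, dtype=float) + 0.5) * _GRID_SPACING

    for mol in topology.molecules:
        ids = np.asarray(mol.atom_ids)
        coords[ids] = (_local_coords(topology, mol, ref_coords)
                       + cell_center(cell_of[mol.id]))

    # realize the tree edges: child donates into the parent's acceptor
    used_donors: set[int] = set()
    for child, parent in parent_of.items():
        _plant_contact(topology, coords, donor_mol=child, acceptor_mol=parent,
                       used_donors=used_donors)
    return coords


def _plant_contact(topology, coords, donor_mol: int, acceptor_mol: int,
                   used_donors: set[int]) -> None:
    cmol = topology.molecules[donor_mol]
    pmol = topology.molecules[acceptor_mol]
    donors = [a for a in cmol.atom_ids
              if topology.atoms[a].is_donor_heavy and a not in used_donors]
    acceptors = [a for a in pmol.atom_ids if topology.atoms[a].is_acceptor]
    if not (donors and acceptors):
        # swap roles if only the other direction is chemically possible
        donors = [a for a in pmol.atom_ids
                  if topology.atoms[a].is_donor_heavy and a not in used_donors]
        acceptors = [a for a in cmol.atom_ids if topology.atoms[a].is_acceptor]
    if not donors or not acceptors:
        raise UnsatisfiableGraphError(
            f"molecules {donor_mol} and {acceptor_mol} lack a donor/acceptor pair"
        )
    d_atom = donors[0]
    used_donors.add(d_atom)
    a_atom = acceptors[0]
    h_atom = topology.atoms[d_atom].attached_h_ids[0]
    a_pos = coords[a_atom]
    child_center = coords[np.asarray(
        topology.molecules[topology.atoms[d_atom].molecule_id].atom_ids
    )].mean(axis=0)
    u = child_center - a_pos
    u /= np.linalg.norm(u)
    coords[d_atom] = a_pos + _HB_CONTACT * u
    coords[h_atom] = a_pos + (_HB_CONTACT - _HB_OH) * u


def make_aggregation_trajectory(
    spec: SyntheticSpec, topology: Topology, n_clusters_per_frame,
) -> Trajectory:
    """Frames whose hydrogen-bond cluster count follows a planted schedule.

    Frame k partitions the SOM (+protein) molecules into
    ``n_clusters_per_frame[k]`` chain-linked clusters.
    """
    _, frame0 = make_system(spec)
    nodes = [m.id for m in
             topology.molecules_of_species(Species.SOM, Species.PROTEIN)]
    frames = []
    box3 = np.full(3, spec.box)
    for k, n_clusters in enumerate(n_clusters_per_frame):
        n_clusters = int(n_clusters)
        if not 1 <= n_clusters <= len(nodes):
            raise ValueError("cluster count outside [1, n_molecules]")
        parts = np.array_split(np.asarray(nodes), n_clusters)
        adjacency: dict[int, list[int]] = {int(n): [] for n in nodes}
        for part in parts:
            for a, b_ in zip(part, part[1:]):
                adjacency[int(a)].append(int(b_))
        coords = _realize_graph(spec, topology, adjacency, frame0.coords)
        frames.append(Frame(k * spec.dt, box3.copy(), coords))
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# Gaussian ensembles


def make_gaussian_ensemble(mean, covariance, n_samples: int, seed: int) -> np.ndarray:
    """Sample conformations from a multivariate normal.

    ``mean`` may be an (M, 3) coordinate array or a flat d-vector; samples
    are returned with matching shape, (n_samples, M, 3) or (n_samples, d).
    The covariance (d x d with d = 3M) must be symmetric positive
    semi-definite.
    """
    mean = np.asarray(mean, dtype=float)
    shape = mean.shape
    mu = mean.reshape(-1)
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (mu.size, mu.size):
        raise ValueError(f"covariance must be {mu.size} x {mu.size}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    eigmin = np.linalg.eigvalsh(cov).min()
    if eigmin < -1e-10 * max(1.0, np.abs(cov).max()):
        raise ValueError("covariance must be positive semi-definite")
    rng = np.random.default_rng(seed)
    samples = rng.multivariate_normal(mu, cov, size=n_samples, method="eigh")
    return samples.reshape((n_samples,) + shape)
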