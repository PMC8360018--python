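"""Inflate/deflate protocol for inserting a protein into a condensed matrix.

The protocol embeds a solute into a dense organic matrix without tearing
it apart: (1) inflate the box by a fixed amount per dimension, moving each
matrix molecule rigidly so its fractional centre is preserved; (2) place
the protein at the box centre, deleting overlapping solvent molecules and
rebalancing ions to keep the system neutral; (3) deflate back to the
original box in equal steps, relaxing after every step while the protein
is held by stiff positional restraints.  Defaults follow the published
protocol: +1 nm inflation, 10 deflation steps of 0.1 nm, restraint force
constant 1e5 kJ mol^-1 nm^-2.

Relaxation is pluggable.  The built-in minimizer does steepest descent on
a purely repulsive soft-sphere potential

    U = sum_pairs eps (sigma / r)^12  +  sum_restrained k/2 |x - x0|^2

over intermolecular pairs (minimum image, cutoff 1.4 nm): enough to
resolve steric overlaps created by deflation, which is all the protocol
requires of its relaxation stage.  Users with an MD engine can substitute
any callable with the same signature for full force-field minimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .core import Atom, Frame, Molecule, Species, Topology
from .geometry import min_image_distance_matrix, wrap

__all__ = [
    "InsertionConfig",
    "SoftSphereParams",
    "DeflateStepReport",
    "MinimizationError",
    "inflate",
    "place_protein",
    "soft_sphere_minimize",
    "deflate_cycle",
    "merge_topologies",
    "remove_molecules",
    "min_intermolecular_heavy_distance",
]


class MinimizationError(RuntimeError):
    pass


@dataclass
class SoftSphereParams:
    epsilon: float = 1.0      # kJ/mol
    sigma: float = 0.3        # nm
    r_cut: float = 1.4        # nm
    sd_step0: float = 0.01    # nm, initial maximum displacement
    sd_max_iter: int = 500
    sd_force_tol: float = 10.0  # kJ mol^-1 nm^-1
    jitter: float = 1e-3      # nm, resolution of coincident atoms
    seed: int = 0


@dataclass
class InsertionConfig:
    inflate_amount: float = 1.0  # nm per dimension
    n_steps: int = 10
    step_size: float = 0.1       # nm per step
    restraint_k: float = 1e5     # kJ mol^-1 nm^-2
    removal_radius: float = 0.3  # nm, heavy-atom overlap on placement
    minimizer: str = "soft_sphere_sd"
    soft_sphere: SoftSphereParams = field(default_factory=SoftSphereParams)

    def __post_init__(self) -> None:
        if abs(self.n_steps * self.step_size - self.inflate_amount) > 1e-9:
            raise ValueError(
                "n_steps x step_size must equal inflate_amount "
                "(the box must return to its original size)"
            )


@dataclass
class DeflateStepReport:
    step: int
    box: np.ndarray
    min_heavy_distance: float  # intermolecular, nm
    iterations: int
    max_force: float
    energy: float


def _molecule_centers(topology: Topology, coords: np.ndarray) -> np.ndarray:
    return np.asarray([
        coords[np.asarray(m.atom_ids)].mean(axis=0) for m in topology.molecules
    ])


def _rescale_matrix(frame: Frame, topology: Topology,
                    new_box: np.ndarray) -> Frame:
    """Translate each non-protein molecule rigidly so its centre keeps the
    same box fraction; protein molecules are left untouched."""
    coords = frame.coords.copy()
    scale = new_box / frame.box
    for mol in topology.molecules:
        if mol.species is Species.PROTEIN:
            continue
        ids = np.asarray(mol.atom_ids)
        center = coords[ids].mean(axis=0)
        coords[ids] += center * (scale - 1.0)
    return Frame(frame.time, new_box, coords)


def inflate(frame: Frame, topology: Topology, amount: float) -> Frame:
    """Grow each box edge by ``amount`` nm, scaling molecule centres."""
    if amount < 0:
        raise ValueError("inflation amount must be non-negative")
    return _rescale_matrix(frame, topology, frame.box + amount)


def merge_topologies(a: Topology, b: Topology) -> Topology:
    """Concatenate two topologies, reindexing the second."""
    atom_off = len(a.atoms)
    mol_off = len(a.molecules)
    atoms = [replace(x) for x in a.atoms]
    for x in b.atoms:
        atoms.append(replace(
            x, id=x.id + atom_off,
            attached_h_ids=[h + atom_off for h in x.attached_h_ids],
            molecule_id=x.molecule_id + mol_off,
        ))
    molecules = [replace(m, atom_ids=list(m.atom_ids)) for m in a.molecules]
    for m in b.molecules:
        molecules.append(replace(
            m, id=m.id + mol_off, atom_ids=[i + atom_off for i in m.atom_ids]
        ))
    return Topology(atoms, molecules)


def remove_molecules(topology: Topology, drop: set[int],
                     ) -> tuple[Topology, np.ndarray]:
    """Drop molecules by id; returns the new topology and the surviving
    old atom indices (for slicing coordinate arrays)."""
    keep_atoms: list[int] = []
    atoms: list[Atom] = []
    molecules: list[Molecule] = []
    old_to_new: dict[int, int] = {}
    for m in topology.molecules:
        if m.id in drop:
            continue
        new_mid = len(molecules)
        new_ids = []
        for aid in m.atom_ids:
            old_to_new[aid] = len(atoms)
            a = topology.atoms[aid]
            atoms.append(replace(a, id=len(atoms), molecule_id=new_mid,
                                 attached_h_ids=list(a.attached_h_ids)))
            new_ids.append(old_to_new[aid])
            keep_atoms.append(aid)
        molecules.append(replace(m, id=new_mid, atom_ids=new_ids))
    for a in atoms:
        a.attached_h_ids = [old_to_new[h] for h in a.attached_h_ids]
    return Topology(atoms, molecules), np.asarray(keep_atoms, dtype=int)


def _ion_rebalance(topology: Topology, drop: set[int],
                   extra_charge: float = 0.0) -> dict[str, int]:
    """Extend ``drop`` with ions, and/or request added counter ions, so the
    remaining system (plus the charge about to be added, e.g. the
    protein's) is neutral.  Returns counts of ions to add by species."""
    net = extra_charge + sum(
        m.net_charge for m in topology.molecules if m.id not in drop)
    if abs(net) < 1e-9:
        return {}
    cations = [m for m in topology.molecules
               if m.species is Species.CATION and m.id not in drop]
    anions = [m for m in topology.molecules
              if m.species is Species.ANION and m.id not in drop]
    qc = cations[0].net_charge if cations else 2.0   # Ca2+ template
    qa = anions[0].net_charge if anions else -1.0    # Cl- template
    best = None
    # remove nc cations / na anions, add pc cations / pa anions
    for nc in range(len(cations) + 1):
        for na in range(len(anions) + 1):
            for pc in range(5):
                for pa in range(5):
                    resid = net - nc * qc - na * qa + pc * qc + pa * qa
                    cost = nc + na + pc + pa
                    if abs(resid) < 1e-9 and (best is None or cost < best[0]):
                        best = (cost, nc, na, pc, pa)
    if best is None:
        raise ValueError(
            f"cannot restore neutrality (net charge {net:+.3f}) by "
            "removing or adding ions"
        )
    _, nc, na, pc, pa = best
    drop.update(m.id for m in cations[:nc])
    drop.update(m.id for m in anions[:na])
    add = {}
    if pc:
        add["ca"] = pc
    if pa:
        add["cl"] = pa
    return add


def place_protein(frame: Frame, topology: Topology,
                  protein_topology: Topology, protein_coords: np.ndarray,
                  removal_radius: float = 0.3) -> tuple[Topology, Frame]:
    """Centre the protein in the box, delete overlapping matrix molecules
    and rebalance ions to neutrality.

    Returns the merged topology and frame (molecule deletion changes the
    topology, so both are returned).
    """
    protein_coords = np.asarray(protein_coords, dtype=float)
    extent = protein_coords.max(axis=0) - protein_coords.min(axis=0)
    if np.any(extent > frame.box):
        raise ValueError("protein does not fit in the box")
    centered = protein_coords - protein_coords.mean(axis=0) + frame.box / 2
    heavy_p = np.asarray(
        [i for i, a in enumerate(protein_topology.atoms) if a.element != "H"]
    )
    drop: set[int] = set()
    for mol in topology.molecules:
        if mol.species is Species.PROTEIN:
            continue
        ids = np.asarray([a for a in mol.atom_ids
                          if topology.atoms[a].element != "H"])
        d = min_image_distance_matrix(
            frame.coords[ids], centered[heavy_p], frame.box
        ).min()
        if d < removal_radius:
            drop.add(mol.id)
    add = _ion_rebalance(topology, drop,
                         extra_charge=protein_topology.total_charge())
    kept_top, keep_idx = remove_molecules(topology, drop)
    merged = merge_topologies(protein_topology, kept_top)
    coords = np.vstack([centered, frame.coords[keep_idx]])
    if add:
        merged, coords = _append_ions(merged, coords, frame.box, add)
    return merged, Frame(frame.time, frame.box.copy(), coords)


def _append_ions(topology: Topology, coords: np.ndarray, box: np.ndarray,
                 counts: dict[str, int], min_spacing: float = 0.25,
                 seed: int = 0) -> tuple[Topology, np.ndarray]:
    """Append counter ions at random positions clear of existing atoms."""
    from .synthetic import TEMPLATES, _Builder

    b = _Builder()
    rng = np.random.default_rng(seed)
    new_pos = []
    for name, n in counts.items():
        species, tmpl = TEMPLATES[name]
        for _ in range(n):
            for _try in range(2000):
                p = rng.uniform(0.0, box, size=3)
                pool = np.vstack([coords] + new_pos) if new_pos else coords
                if min_image_distance_matrix(
                        p[None, :], pool, box).min() >= min_spacing:
                    break
            else:
                raise ValueError("no room to re-add counter ions")
            b.add_molecule(name, species, tmpl, p[None, :])
            new_pos.append(p[None, :])
    merged = merge_topologies(topology, Topology(b.atoms, b.molecules))
    return merged, np.vstack([coords] + new_pos)


# ---------------------------------------------------------------------------
# Soft-sphere steepest descent


def _energy_forces(coords: np.ndarray, box: np.ndarray, mol_ids: np.ndarray,
                   params: SoftSphereParams,
                   restrained: np.ndarray, x0: np.ndarray, k: float,
                   ) -> tuple[float, np.ndarray, np.ndarray]:
    """Energy, forces, and the list of coincident pairs (for jitter)."""
    wrapped = wrap(coords, box)
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(params.r_cut, output_type="ndarray")
    if len(pairs):
        inter = mol_ids[pairs[:, 0]] != mol_ids[pairs[:, 1]]
        pairs = pairs[inter]
    energy = 0.0
    forces = np.zeros_like(coords)
    coincident = np.empty((0, 2), dtype=int)
    if len(pairs):
        d = wrapped[pairs[:, 1]] - wrapped[pairs[:, 0]]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
        coincident = pairs[r < 1e-6]
        ok = r >= 1e-6
        d, r, pr = d[ok], r[ok], pairs[ok]
        sr12 = (params.sigma / r) ** 12
        energy += params.epsilon * sr12.sum()
        # dU/dr = -12 eps sigma^12 / r^13 ; force on i points away from j
        fmag = 12 * params.epsilon * sr12 / r**2
        fvec = fmag[:, None] * d
        np.subtract.at(forces, pr[:, 0], fvec)
        np.add.at(forces, pr[:, 1], fvec)
    if restrained.size and k > 0:
        dx = coords[restrained] - x0
        energy += 0.5 * k * float((dx**2).sum())
        forces[restrained] -= k * dx
    return energy, forces, coincident


def soft_sphere_minimize(frame: Frame, topology: Topology,
                         restrained_ids=None, k: float = 0.0,
                         params: SoftSphereParams | None = None,
                         restraint_centers: np.ndarray | None = None,
                         ) -> tuple[Frame, dict]:
    """Steepest-descent relaxation of the soft-sphere + restraint energy.

    The step is a displacement bound (the steepest-descent direction is
    normalized to the maximum atomic force): doubled after an
    energy-lowering step, halved otherwise.  Terminates when the maximum
    force drops below ``sd_force_tol`` or iterations are exhausted; the
    energy never increases over accepted steps.
    """
    params = params or SoftSphereParams()
    if k < 0:
        raise ValueError("restraint force constant must be non-negative")
    restrained = (np.asarray(restrained_ids, dtype=int)
                  if restrained_ids is not None else np.empty(0, dtype=int))
    x = frame.coords.copy()
    x0 = (np.asarray(restraint_centers, dtype=float)
          if restraint_centers is not None else x[restrained].copy())
    mol_ids = np.asarray([a.molecule_id for a in topology.atoms])
    rng = np.random.default_rng(params.seed)
    jitter_count = 0

    def eval_at(c):
        nonlocal jitter_count
        for _ in range(20):
            e, f, coincident = _energy_forces(
                c, frame.box, mol_ids, params, restrained, x0, k)
            if not len(coincident):
                return e, f
            jitter_count += 1
            if jitter_count > 50:
                raise MinimizationError("recurrent coincident atoms")
            warnings.warn("coincident atoms jittered during minimization",
                          stacklevel=2)
            c[np.unique(coincident)] += rng.normal(0, params.jitter,
                                                   (len(np.unique(coincident)), 3))
        raise MinimizationError("could not resolve coincident atoms")

    energy, forces = eval_at(x)
    step = params.sd_step0
    it = 0
    fmax = float(np.abs(forces).max()) if forces.size else 0.0
    while it < params.sd_max_iter and fmax > params.sd_force_tol:
        it += 1
        trial = x + forces * (step / fmax)
        e_t, f_t = eval_at(trial)
        if e_t < energy:
            x, energy, forces = trial, e_t, f_t
            step *= 2.0
        else:
            step *= 0.5
            if step < 1e-9:
                break
        fmax = float(np.abs(forces).max()) if forces.size else 0.0
    info = {"iterations": it, "max_force": fmax, "energy": energy}
    return Frame(frame.time, frame.box.copy(), x), info


def min_intermolecular_heavy_distance(frame: Frame, topology: Topology) -> float:
    heavy = np.asarray([a.id for a in topology.atoms if a.element != "H"])
    mol = np.asarray([topology.atoms[a].molecule_id for a in heavy])
    wrapped = wrap(frame.coords[heavy], frame.box)
    tree = cKDTree(wrapped, boxsize=frame.box)
    best = np.inf
    r = 0.4
    while True:
        pairs = tree.query_pairs(r, output_type="ndarray")
        if len(pairs):
            inter = mol[pairs[:, 0]] != mol[pairs[:, 1]]
            pairs = pairs[inter]
        if len(pairs):
            d = wrapped[pairs[:, 1]] - wrapped[pairs[:, 0]]
            d -= frame.box * np.round(d / frame.box)
            best = float(np.linalg.norm(d, axis=1).min())
            return best
        r *= 2
        if r > frame.box.min():
            return float(np.inf)


def deflate_cycle(frame: Frame, topology: Topology,
                  config: InsertionConfig | None = None,
                  ) -> tuple[Frame, list[DeflateStepReport]]:
    """Shrink the box back in equal steps, relaxing after each one.

    Protein atoms are positionally restrained at their placed coordinates
    throughout; the final box equals the pre-inflation box exactly.  Raises
    :class:`MinimizationError` (with the step index) if a step leaves a
    heavy-atom pair closer than 0.1 nm.
    """
    config = config or InsertionConfig()
    protein_ids = topology.atom_ids_of_species(Species.PROTEIN)
    x0 = frame.coords[protein_ids].copy() if protein_ids.size else None
    current = frame
    reports: list[DeflateStepReport] = []
    for step in range(1, config.n_steps + 1):
        new_box = frame.box - step * config.step_size
        current = _rescale_matrix(current, topology, new_box)
        current, info = soft_sphere_minimize(
            current, topology,
            restrained_ids=protein_ids if protein_ids.size else None,
            k=config.restraint_k if protein_ids.size else 0.0,
            params=config.soft_sphere,
            restraint_centers=x0,
        )
        dmin = min_intermolecular_heavy_distance(current, topology)
        reports.append(DeflateStepReport(
            step, current.box.copy(), dmin,
            info["iterations"], info["max_force"], info["energy"],
        ))
        if dmin < 0.1:
            raise MinimizationError(
                f"step {step}: unresolved overlap (min heavy-atom distance "
                f"{dmin:.3f} nm)"
            )
    return current, reports
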