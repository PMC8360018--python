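"""Readers and writers for coordinate, trajectory and topology files.

Single-frame GRO and PDB files are parsed with MDAnalysis and converted to
the package's nm convention at this boundary (MDAnalysis stores positions
in Angstrom internally; GRO files themselves are nm, PDB files Angstrom).
Writers emit the fixed-width dialects directly.

Trajectories are stored as plain-text concatenated GRO frames whose title
lines carry ``t= <time in ps>`` — the conventional multi-frame GRO layout.
MDAnalysis's GRO reader is single-frame, so the frame iterator here splits
the concatenation and parses each block.

Topologies (charges, LJ coefficients, donor/acceptor flags, functional
groups) have no GRO/PDB representation and are serialized as a documented
JSON file.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

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

__all__ = [
    "GroParseError",
    "PdbParseError",
    "CoordinateSet",
    "read_gro",
    "write_gro",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "read_topology_json",
    "write_topology_json",
]


class GroParseError(ValueError):
    pass


class PdbParseError(ValueError):
    pass


@dataclass
class CoordinateSet:
    """Topology-less coordinates with per-atom file metadata.

    ``coords`` and ``box`` are in nm; ``box`` is ``None`` for formats that
    do not carry one (most PDB files).  ``resids``/``resnames``/``names``
    and (for PDB) ``chains``/``records`` retain the file metadata.
    """

    coords: np.ndarray
    box: np.ndarray | None
    names: list[str]
    resnames: list[str]
    resids: list[int]
    chains: list[str] | None = None
    records: list[str] | None = None
    time: float = 0.0


def _check_orthorhombic(dimensions: np.ndarray, path: str) -> None:
    angles = np.asarray(dimensions[3:6], dtype=float)
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise ValueError(
            f"{path}: triclinic boxes are not supported (angles {angles})"
        )


def _validate_gro_counts(path: str) -> None:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GroParseError(f"{path}: truncated file ({len(lines)} lines)")
    try:
        declared = int(lines[1].split()[0])
    except (ValueError, IndexError):
        raise GroParseError(f"{path}: line 2: malformed atom-count line {lines[1]!r}")
    available = len(lines) - 3  # title + count + box
    if available < declared:
        raise GroParseError(
            f"{path}: line 2 declares {declared} atoms but only {available} "
            f"atom records present"
        )


def read_gro(path: str) -> CoordinateSet:
    """Read a single-frame GRO file (positions already in nm)."""
    import MDAnalysis as mda

    _validate_gro_counts(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    _check_orthorhombic(u.dimensions, str(path))
    with open(path) as fh:
        title = fh.readline()
    return CoordinateSet(
        coords=u.atoms.positions.astype(float) / 10.0,
        box=np.asarray(u.dimensions[:3], dtype=float) / 10.0,
        names=list(u.atoms.names),
        resnames=list(u.atoms.resnames),
        resids=[int(r) for r in u.atoms.resids],
        time=_time_from_title(title),
    )


def _time_from_title(title: str) -> float:
    if "t=" in title:
        try:
            return float(title.split("t=")[1].split()[0])
        except (ValueError, IndexError):
            return 0.0
    return 0.0


def _format_gro_frame(
    coords: np.ndarray,
    box: np.ndarray,
    names: list[str],
    resnames: list[str],
    resids: list[int],
    time: float,
) -> str:
    lines = [f"somtool t= {time:.3f}", f"{len(coords):5d}"]
    for i, (xyz, name, resname, resid) in enumerate(
        zip(coords, names, resnames, resids)
    ):
        serial = (i + 1) % 100000  # GRO serials wrap at 5 digits
        lines.append(
            f"{resid % 100000:5d}{resname:<5.5s}{name:>5.5s}{serial:5d}"
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        )
    lines.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
    return "\n".join(lines) + "\n"


def _default_metadata(topology: Topology | None, n: int):
    if topology is None:
        return (["X"] * n, ["MOL"] * n, [1] * n)
    names = [a.name for a in topology.atoms]
    resnames = [topology.molecules[a.molecule_id].species.value[:5].upper()
                for a in topology.atoms]
    resids = [a.molecule_id + 1 for a in topology.atoms]
    return names, resnames, resids


def write_gro(path: str, frame: Frame, topology: Topology | None = None) -> None:
    names, resnames, resids = _default_metadata(topology, len(frame.coords))
    with open(path, "w") as fh:
        fh.write(
            _format_gro_frame(
                frame.coords, frame.box, names, resnames, resids, frame.time
            )
        )


def write_trajectory(path: str, trajectory: Trajectory) -> None:
    names, resnames, resids = _default_metadata(
        trajectory.topology, trajectory.topology.n_atoms
    )
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            fh.write(
                _format_gro_frame(
                    frame.coords, frame.box, names, resnames, resids, frame.time
                )
            )


def _parse_gro_block(lines: list[str], lineno0: int) -> Frame:
    try:
        n = int(lines[1].split()[0])
    except (ValueError, IndexError):
        raise GroParseError(
            f"line {lineno0 + 2}: malformed atom-count line {lines[1]!r}"
        )
    if len(lines) < n + 3:
        raise GroParseError(
            f"line {lineno0 + 2}: declares {n} atoms but block truncated"
        )
    coords = np.empty((n, 3))
    for i in range(n):
        rec = lines[2 + i]
        try:
            coords[i] = [float(rec[20:28]), float(rec[28:36]), float(rec[36:44])]
        except ValueError:
            raise GroParseError(f"line {lineno0 + 3 + i}: malformed coordinates")
    box_fields = lines[n + 2].split()
    if len(box_fields) > 3 and any(abs(float(v)) > 1e-12 for v in box_fields[3:]):
        raise ValueError("triclinic boxes are not supported")
    box = np.asarray([float(v) for v in box_fields[:3]])
    return Frame(_time_from_title(lines[0]), box, coords)


def read_trajectory(path: str, topology: Topology) -> Trajectory:
    """Read a concatenated-GRO plain-text trajectory."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Frame] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        if pos + 1 >= len(lines):
            raise GroParseError(f"line {pos + 1}: truncated frame header")
        n = int(lines[pos + 1].split()[0])
        frames.append(_parse_gro_block(lines[pos: pos + n + 3], pos))
        pos += n + 3
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# PDB

_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def read_pdb(path: str) -> CoordinateSet:
    """Read ATOM/HETATM coordinates from a PDB file, converting A to nm."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except ValueError as exc:
            raise PdbParseError(f"{path}: {exc}") from exc
    records = [
        "HETATM" if getattr(a, "record_type", "ATOM") == "HETATM" else "ATOM"
        for a in u.atoms
    ]
    resnames = list(u.atoms.resnames)
    if not any(rn in _PROTEIN_RESNAMES for rn in resnames):
        warnings.warn(
            f"{path}: no standard protein residues found; protein selection "
            "will be empty",
            stacklevel=2,
        )
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        _check_orthorhombic(u.dimensions, str(path))
        box = np.asarray(u.dimensions[:3], dtype=float) / 10.0
    try:
        chains = list(u.atoms.chainIDs)
    except AttributeError:
        chains = [""] * len(u.atoms)
    return CoordinateSet(
        coords=u.atoms.positions.astype(float) / 10.0,
        box=box,
        names=list(u.atoms.names),
        resnames=resnames,
        resids=[int(r) for r in u.atoms.resids],
        chains=chains,
        records=records,
    )


def write_pdb(path: str, coords_nm: np.ndarray, names=None, resnames=None,
              resids=None, chains=None, records=None) -> None:
    """Write coordinates (nm) as a minimal PDB file (converted to A)."""
    coords = np.asarray(coords_nm, dtype=float).reshape(-1, 3) * 10.0
    n = len(coords)
    names = names or ["CA"] * n
    resnames = resnames or ["GLY"] * n
    resids = resids or list(range(1, n + 1))
    chains = chains or ["A"] * n
    records = records or ["ATOM"] * n
    with open(path, "w") as fh:
        for i in range(n):
            name = names[i]
            # columns 13-16: pad 1-3 char names with a leading space
            name_f = f" {name:<3.3s}" if len(name) < 4 else name[:4]
            fh.write(
                f"{records[i]:<6.6s}{(i + 1) % 100000:5d} {name_f} "
                f"{resnames[i]:<3.3s} {chains[i]:1.1s}{resids[i] % 10000:4d}    "
                f"{coords[i, 0]:8.3f}{coords[i, 1]:8.3f}{coords[i, 2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Topology JSON


def write_topology_json(path: str, topology: Topology) -> None:
    data = {
        "atoms": [
            {
                "id": a.id,
                "name": a.name,
                "element": a.element,
                "mass": a.mass,
                "charge": a.charge,
                "c6": a.c6,
                "c12": a.c12,
                "is_donor_heavy": a.is_donor_heavy,
                "attached_h_ids": a.attached_h_ids,
                "is_acceptor": a.is_acceptor,
                "functional_group": a.functional_group.value,
                "molecule_id": a.molecule_id,
            }
            for a in topology.atoms
        ],
        "molecules": [
            {
                "id": m.id,
                "species": m.species.value,
                "atom_ids": m.atom_ids,
                "net_charge": m.net_charge,
            }
            for m in topology.molecules
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_topology_json(path: str) -> Topology:
    with open(path) as fh:
        data = json.load(fh)
    atoms = [
        Atom(
            id=d["id"],
            name=d["name"],
            element=d["element"],
            mass=d["mass"],
            charge=d["charge"],
            c6=d["c6"],
            c12=d["c12"],
            is_donor_heavy=d["is_donor_heavy"],
            attached_h_ids=list(d["attached_h_ids"]),
            is_acceptor=d["is_acceptor"],
            functional_group=FunctionalGroup(d["functional_group"]),
            molecule_id=d["molecule_id"],
        )
        for d in data["atoms"]
    ]
    molecules = [
        Molecule(
            id=d["id"],
            species=Species(d["species"]),
            atom_ids=list(d["atom_ids"]),
            net_charge=d["net_charge"],
        )
        for d in data["molecules"]
    ]
    return Topology(atoms, molecules)
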