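"""Pairwise nonbonded interaction energies with a reaction-field Coulomb term.

Electrostatics follow the truncated-Coulomb-plus-reaction-field convention
of GROMOS-style simulations: inside the cutoff R_c the pair energy is

    E_C(r) = f q_i q_j (1/r + k_rf r^2 - c_rf),
    k_rf = (eps_rf - eps1) / ((2 eps_rf + eps1) R_c^3),
    c_rf = 1/R_c + k_rf R_c^2,

with f = 138.935458 kJ mol^-1 nm e^-2, so E_C vanishes continuously at the
cutoff.  Defaults: R_c = 1.4 nm, reaction-field permittivity eps_rf = 61
(SPC water), eps1 = 1 inside the cutoff, no ionic screening.  The
Lennard-Jones term is the unshifted C12/r^12 - C6/r^6, zero beyond the
cutoff; pair coefficients combine geometrically.

The decomposition sums protein-atom x partner-atom energies per partner
molecule species (strictly intermolecular, which is what protein-solvent
energy groupings report).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Frame, Species, Topology, Trajectory
from .geometry import min_image_distance_matrix

__all__ = [
    "COULOMB_CONSTANT",
    "NonbondedParams",
    "EnergyDecomposition",
    "pair_energy",
    "frame_decompose",
    "decompose",
]

#: 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935458


@dataclass
class NonbondedParams:
    r_cut: float = 1.4    # nm
    eps_rf: float = 61.0  # reaction-field permittivity
    eps1: float = 1.0     # permittivity inside the cutoff
    coulomb_const: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.eps_rf < 1:
            raise ValueError("eps_rf must be >= 1")

    @property
    def k_rf(self) -> float:
        return (self.eps_rf - self.eps1) / (
            (2 * self.eps_rf + self.eps1) * self.r_cut**3
        )

    @property
    def c_rf(self) -> float:
        return 1.0 / self.r_cut + self.k_rf * self.r_cut**2


@dataclass
class EnergyDecomposition:
    """Per-species-class mean energies (kJ/mol) with replicate errors."""

    coulomb_mean: dict[str, float]
    lj_mean: dict[str, float]
    total_mean: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.total_mean:
            self.total_mean = {
                c: self.coulomb_mean[c] + self.lj_mean[c]
                for c in self.coulomb_mean
            }


def pair_energy(r: float, qi: float, qj: float, c6: float, c12: float,
                params: NonbondedParams | None = None) -> tuple[float, float]:
    """(Coulomb+RF, Lennard-Jones) energy of one pair at separation r (nm)."""
    params = params or NonbondedParams()
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r > params.r_cut:
        return 0.0, 0.0
    coul = params.coulomb_const * qi * qj * (
        1.0 / r + params.k_rf * r**2 - params.c_rf
    )
    lj = c12 / r**12 - c6 / r**6
    return float(coul), float(lj)


def _class_of(species: Species) -> str:
    return species.value


def frame_decompose(frame: Frame, topology: Topology,
                    protein_molecule_id: int,
                    params: NonbondedParams | None = None,
                    ) -> tuple[dict[str, float], dict[str, float]]:
    """Per-class (Coulomb, LJ) sums of protein-environment pairs in one frame."""
    params = params or NonbondedParams()
    prot = np.asarray(topology.molecules[protein_molecule_id].atom_ids)
    others = np.asarray(
        [a.id for a in topology.atoms
         if a.molecule_id != protein_molecule_id]
    )
    coulomb: dict[str, float] = {}
    lj: dict[str, float] = {}
    if others.size == 0:
        return coulomb, lj
    q = np.asarray([a.charge for a in topology.atoms])
    c6 = np.asarray([a.c6 for a in topology.atoms])
    c12 = np.asarray([a.c12 for a in topology.atoms])
    classes = np.asarray([_class_of(topology.species_of_atom(a)) for a in others])

    dist = min_image_distance_matrix(
        frame.coords[prot], frame.coords[others], frame.box
    )
    with np.errstate(divide="ignore"):
        inside = dist <= params.r_cut
        inv_r = np.where(dist > 0, 1.0 / dist, np.inf)
        qq = np.outer(q[prot], q[others])
        e_c = params.coulomb_const * qq * (
            inv_r + params.k_rf * dist**2 - params.c_rf
        )
        c6ij = np.sqrt(np.outer(c6[prot], c6[others]))
        c12ij = np.sqrt(np.outer(c12[prot], c12[others]))
        e_lj = c12ij * inv_r**12 - c6ij * inv_r**6
    e_c = np.where(inside, e_c, 0.0)
    e_lj = np.where(inside, e_lj, 0.0)
    for cls in np.unique(classes):
        mask = classes == cls
        coulomb[str(cls)] = float(e_c[:, mask].sum())
        lj[str(cls)] = float(e_lj[:, mask].sum())
    return coulomb, lj


def decompose(trajectory: Trajectory, protein_molecule_id: int,
              params: NonbondedParams | None = None) -> EnergyDecomposition:
    """Time-averaged protein-environment energy decomposition by species."""
    params = params or NonbondedParams()
    top = trajectory.topology
    missing = [a.id for a in top.atoms
               if a.charge is None or a.c6 is None or a.c12 is None]
    if missing:
        raise ValueError(f"atoms without nonbonded parameters: {missing[:5]}")
    acc_c: dict[str, float] = {}
    acc_l: dict[str, float] = {}
    for frame in trajectory.frames:
        fc, fl = frame_decompose(frame, top, protein_molecule_id, params)
        for cls in fc:
            acc_c[cls] = acc_c.get(cls, 0.0) + fc[cls]
            acc_l[cls] = acc_l.get(cls, 0.0) + fl[cls]
    n = len(trajectory.frames)
    return EnergyDecomposition(
        coulomb_mean={c: v / n for c, v in acc_c.items()},
        lj_mean={c: v / n for c, v in acc_l.items()},
    )
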