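"""Geometric hydrogen-bond detection and partner-type accounting.

A hydrogen bond D-H...A is counted when the donor-heavy-to-acceptor
distance is at most ``r_cut`` (default 0.35 nm, minimum image) and the
H-D-A angle is at most ``angle_cut`` (default 30 degrees) — the
conventional defaults of MD analysis suites.  A donor hydrogen may bond
several acceptors in one frame; no exclusivity is imposed.

Partner accounting classifies every bond involving at least one protein
atom by the species of the non-protein partner molecule, without
distinguishing whether the protein donates or accepts; bonds internal to
the protein count as protein-protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, Species, Topology, TopologyError, Trajectory
from .geometry import min_image_vectors

__all__ = [
    "HBond",
    "HBondSummary",
    "detect_hbonds",
    "count_by_partner",
    "summarize_replicates",
    "PARTNER_CLASSES",
]

PARTNER_CLASSES = ("protein_protein", "protein_som", "protein_water", "protein_ion")

_SPECIES_TO_CLASS = {
    Species.PROTEIN: "protein_protein",
    Species.SOM: "protein_som",
    Species.COSOLVENT: "protein_som",
    Species.WATER: "protein_water",
    Species.CATION: "protein_ion",
    Species.ANION: "protein_ion",
}


@dataclass(frozen=True)
class HBond:
    donor_heavy_id: int
    hydrogen_id: int
    acceptor_id: int
    frame_index: int
    donor_molecule: int
    acceptor_molecule: int

    @property
    def intramolecular(self) -> bool:
        return self.donor_molecule == self.acceptor_molecule


@dataclass
class HBondSummary:
    partner_class: str
    mean_count: float
    sd_over_replicates: float = 0.0


def detect_hbonds(frame: Frame, topology: Topology, r_cut: float = 0.35,
                  angle_cut: float = 30.0, frame_index: int = 0) -> list[HBond]:
    """All D-H...A triples satisfying the geometric criterion in one frame."""
    donors = [a for a in topology.atoms if a.is_donor_heavy]
    acceptors = [a.id for a in topology.atoms if a.is_acceptor]
    for d in donors:
        if not d.attached_h_ids:
            raise TopologyError(f"donor atom {d.id} has no attached hydrogen")
    if not donors or not acceptors:
        return []
    d_ids = np.asarray([d.id for d in donors])
    a_ids = np.asarray(acceptors)
    box = frame.box
    vec_da = min_image_vectors(frame.coords[d_ids], frame.coords[a_ids], box)
    dist_da = np.linalg.norm(vec_da, axis=-1)
    cos_cut = np.cos(np.deg2rad(angle_cut))
    bonds: list[HBond] = []
    for i, donor in enumerate(donors):
        close = np.nonzero((dist_da[i] <= r_cut) & (a_ids != donor.id))[0]
        if close.size == 0:
            continue
        for h_id in donor.attached_h_ids:
            vec_dh = min_image_vectors(
                frame.coords[donor.id][None, :], frame.coords[h_id][None, :], box
            )[0, 0]
            norm_dh = np.linalg.norm(vec_dh)
            for j in close:
                cos = float(vec_dh @ vec_da[i, j] / (norm_dh * dist_da[i, j]))
                if cos >= cos_cut:
                    bonds.append(
                        HBond(
                            donor_heavy_id=int(donor.id),
                            hydrogen_id=int(h_id),
                            acceptor_id=int(a_ids[j]),
                            frame_index=frame_index,
                            donor_molecule=donor.molecule_id,
                            acceptor_molecule=topology.atoms[a_ids[j]].molecule_id,
                        )
                    )
    return bonds


def count_by_partner(trajectory: Trajectory, protein_molecule_id: int,
                     r_cut: float = 0.35, angle_cut: float = 30.0,
                     ) -> list[HBondSummary]:
    """Per-frame average count of protein hydrogen bonds by partner class."""
    top = trajectory.topology
    if protein_molecule_id >= len(top.molecules):
        raise ValueError(f"no molecule {protein_molecule_id}")
    totals = {c: 0 for c in PARTNER_CLASSES}
    for k, frame in enumerate(trajectory.frames):
        for b in detect_hbonds(frame, top, r_cut, angle_cut, frame_index=k):
            mols = (b.donor_molecule, b.acceptor_molecule)
            if protein_molecule_id not in mols:
                continue
            partner = (
                b.acceptor_molecule
                if b.donor_molecule == protein_molecule_id
                else b.donor_molecule
            )
            cls = _SPECIES_TO_CLASS[top.molecules[partner].species]
            totals[cls] += 1
    n = len(trajectory.frames)
    return [HBondSummary(c, totals[c] / n) for c in PARTNER_CLASSES]


def summarize_replicates(per_replicate: list[list[HBondSummary]]) -> list[HBondSummary]:
    """Mean and standard deviation of class means across replicate runs."""
    out = []
    for i, cls in enumerate(PARTNER_CLASSES):
        vals = np.array([rep[i].mean_count for rep in per_replicate])
        out.append(HBondSummary(cls, float(vals.mean()),
                                float(vals.std(ddof=1)) if len(vals) > 1 else 0.0))
    return out
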