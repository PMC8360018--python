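import numpy as np
import pytest

from somtool.core import Atom, Frame, Molecule, Species, Topology
from somtool.hbonds import count_by_partner, detect_hbonds, summarize_replicates
from somtool.synthetic import SyntheticSpec, make_system, make_trajectory
from somtool.core import Trajectory


def _donor_acceptor_topology():
    """Molecule 0: O-H donor; molecule 1: O acceptor."""
    atoms = [
        Atom(0, "OD", "O", 15.999, is_donor_heavy=True, attached_h_ids=[1],
             molecule_id=0),
        Atom(1, "HD", "H", 1.008, molecule_id=0),
        Atom(2, "OA", "O", 15.999, is_acceptor=True, molecule_id=1),
    ]
    mols = [Molecule(0, Species.SOM, [0, 1], 0.0),
            Molecule(1, Species.SOM, [2], 0.0)]
    return Topology(atoms, mols)


def _frame(coords, box=10.0):
    return Frame(0.0, np.full(3, box), np.asarray(coords, dtype=float))


def _brute_force(frame, top, r_cut=0.35, angle_cut=30.0):
    """Independent triple loop over donor/H/acceptor with explicit geometry."""
    out = set()
    box = frame.box
    for d in top.atoms:
        if not d.is_donor_heavy:
            continue
        for h in d.attached_h_ids:
            for a in top.atoms:
                if not a.is_acceptor or a.id == d.id:
                    continue
                v_da = frame.coords[a.id] - frame.coords[d.id]
                v_da -= box * np.round(v_da / box)
                r = np.linalg.norm(v_da)
                if r > r_cut:
                    continue
                v_dh = frame.coords[h] - frame.coords[d.id]
                v_dh -= box * np.round(v_dh / box)
                cosang = v_dh @ v_da / (np.linalg.norm(v_dh) * r)
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if ang <= angle_cut:
                    out.add((d.id, h, a.id))
    return out


class TestDetect:
    def test_collinear_pair_inside_cutoffs_detected(self):
        top = _donor_acceptor_topology()
        f = _frame([[0, 0, 0], [0.098, 0, 0], [0.25, 0, 0]])
        bonds = detect_hbonds(f, top)
        assert [(b.donor_heavy_id, b.hydrogen_id, b.acceptor_id)
                for b in bonds] == [(0, 1, 2)]

    def test_distance_beyond_cutoff_not_detected(self):
        top = _donor_acceptor_topology()
        f = _frame([[0, 0, 0], [0.098, 0, 0], [0.36, 0, 0]])
        assert detect_hbonds(f, top) == []

    def test_angle_beyond_cutoff_not_detected(self):
        top = _donor_acceptor_topology()
        # acceptor at 45 degrees off the O-H axis
        f = _frame([[0, 0, 0], [0.098, 0, 0], [0.2, 0.2, 0]])
        assert detect_hbonds(f, top) == []

    def test_bond_across_periodic_boundary(self):
        top = _donor_acceptor_topology()
        f = _frame([[9.9, 0, 0], [9.998, 0, 0], [0.15, 0, 0]])
        assert len(detect_hbonds(f, top)) == 1

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_on_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        n_mol = 12
        atoms, mols = [], []
        for m in range(n_mol):
            base = len(atoms)
            atoms.append(Atom(base, "O", "O", 15.999, is_donor_heavy=True,
                              attached_h_ids=[base + 1], molecule_id=m))
            atoms.append(Atom(base + 1, "H", "H", 1.008, molecule_id=m))
            atoms.append(Atom(base + 2, "OA", "O", 15.999, is_acceptor=True,
                              molecule_id=m))
            mols.append(Molecule(m, Species.SOM, [base, base + 1, base + 2], 0.0))
        top = Topology(atoms, mols)
        centers = rng.uniform(0, 2.0, size=(n_mol, 3))
        coords = np.repeat(centers, 3, axis=0) + rng.normal(
            0, 0.15, size=(3 * n_mol, 3))
        f = _frame(coords, box=2.0)
        got = {(b.donor_heavy_id, b.hydrogen_id, b.acceptor_id)
               for b in detect_hbonds(f, top)}
        assert got == _brute_force(f, top)

    def test_invariant_under_rotation_and_translation(self, rng):
        from scipy.spatial.transform import Rotation

        top = _donor_acceptor_topology()
        coords = np.array([[0, 0, 0], [0.098, 0, 0], [0.24, 0.05, 0]])
        base = {(b.donor_heavy_id, b.acceptor_id)
                for b in detect_hbonds(_frame(coords + 4.0), top)}
        R = Rotation.random(random_state=3).as_matrix()
        moved = coords @ R.T + np.array([1.0, 2.0, 3.0])
        got = {(b.donor_heavy_id, b.acceptor_id)
               for b in detect_hbonds(_frame(moved + 4.0), top)}
        assert got == base == {(0, 2)}

    @pytest.mark.parametrize("seed", range(20))
    def test_detected_set_monotone_in_cutoffs(self, seed):
        rng = np.random.default_rng(seed)
        top = _donor_acceptor_topology()
        coords = rng.uniform(0, 1.0, size=(3, 3))
        f = _frame(coords, box=4.0)

        def key(bonds):
            return {(b.donor_heavy_id, b.acceptor_id) for b in bonds}

        tight = key(detect_hbonds(f, top, r_cut=0.3, angle_cut=20.0))
        loose = key(detect_hbonds(f, top, r_cut=0.4, angle_cut=45.0))
        assert tight <= loose


class TestPartnerCounting:
    def test_planted_protein_water_graph(self):
        spec = SyntheticSpec(seed=31, box=7.0, n_protein_beads=4,
                             cosolvent_counts={"water": 3}, n_frames=4,
                             planted_hbond_graph={0: [1, 2]})
        traj = make_trajectory(spec)
        assert traj.topology.molecules[0].species is Species.PROTEIN
        summary = {s.partner_class: s.mean_count
                   for s in count_by_partner(traj, 0)}
        assert summary["protein_water"] == pytest.approx(2.0)
        assert summary["protein_som"] == 0.0
        assert summary["protein_ion"] == 0.0

    def test_no_bonds_means_zero_everywhere(self):
        spec = SyntheticSpec(seed=32, box=6.0, n_protein_beads=4,
                             cosolvent_counts={"ca": 5}, n_frames=3)
        traj = make_trajectory(spec)
        assert all(s.mean_count == 0.0 for s in count_by_partner(traj, 0))

    def test_mean_over_frames_is_arithmetic(self):
        # 3 water partners, frames with planted graphs of 3, then static
        spec = SyntheticSpec(seed=33, box=7.0, n_protein_beads=6,
                             cosolvent_counts={"water": 5}, n_frames=2,
                             planted_hbond_graph={0: [1, 2, 3]})
        t1 = make_trajectory(spec)
        spec2 = SyntheticSpec(seed=33, box=7.0, n_protein_beads=6,
                              cosolvent_counts={"water": 5}, n_frames=2,
                              planted_hbond_graph={0: [1]})
        t2 = make_trajectory(spec2)
        frames = t1.frames + [
            type(f)(f.time + 100.0, f.box, f.coords) for f in t2.frames
        ]
        traj = Trajectory(t1.topology, frames)
        summary = {s.partner_class: s.mean_count
                   for s in count_by_partner(traj, 0)}
        assert summary["protein_water"] == pytest.approx((3 + 3 + 1 + 1) / 4)

    def test_replicate_summary_mean_and_sd(self):
        from somtool.hbonds import HBondSummary, PARTNER_CLASSES

        reps = []
        for v in (3.0, 5.0, 4.0):
            reps.append([HBondSummary(c, v if c == "protein_water" else 0.0)
                         for c in PARTNER_CLASSES])
        out = {s.partner_class: s for s in summarize_replicates(reps)}
        assert out["protein_water"].mean_count == pytest.approx(4.0)
        assert out["protein_water"].sd_over_replicates == pytest.approx(1.0)
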