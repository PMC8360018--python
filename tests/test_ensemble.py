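import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from somtool.core import Frame, Trajectory
from somtool.ensemble import (
    d_hes,
    d_hes_from_params,
    fit_ensemble_gaussian,
    gaussian_kl,
    kabsch_superpose,
    pairwise_dhes_matrix,
    rmsd,
    rmsd_series,
    rmsf,
    subsample_concatenate,
    superpose_ensembles,
)
from somtool.synthetic import SyntheticSpec, make_gaussian_ensemble, make_system


def _quaternion_kabsch(mobile, reference):
    """Independent superposition oracle (Horn's quaternion method)."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    S = x.T @ y
    K = np.array([
        [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1],
         S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
        [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2],
         S[0, 1] + S[1, 0], S[2, 0] + S[0, 2]],
        [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0],
         -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
        [S[0, 1] - S[1, 0], S[2, 0] + S[0, 2],
         S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
    ])
    w, v = np.linalg.eigh(K)
    q = v[:, -1]  # w, x, y, z
    R = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    fitted = x @ R.T + reference.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))


class TestKabsch:
    def test_rigid_copy_superposes_exactly(self, rng):
        ref = rng.normal(size=(12, 3))
        R = Rotation.random(random_state=7).as_matrix()
        mob = ref @ R.T + [1.0, -2.0, 0.5]
        assert rmsd(mob, ref) == pytest.approx(0.0, abs=1e-10)

    def test_rotation_is_proper(self, rng):
        ref = rng.normal(size=(10, 3))
        mob = ref.copy()
        mob[:, 0] *= -1  # reflection
        fitted, R = kabsch_superpose(mob, ref)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert rmsd(mob, ref) > 0.1

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        assert rmsd(a, b) == pytest.approx(_quaternion_kabsch(a, b), abs=1e-9)

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)

    def test_superposition_never_increases_rmsd(self, rng):
        for _ in range(20):
            a = rng.normal(size=(8, 3))
            b = rng.normal(size=(8, 3))
            assert rmsd(a, b) <= rmsd(a, b, superpose=False) + 1e-12


class TestRmsdSeries:
    @staticmethod
    def _static_traj(n_frames=5, n_beads=6, seed=1):
        top, frame = make_system(
            SyntheticSpec(seed=seed, box=6.0, n_protein_beads=n_beads))
        frames = [Frame(float(t), frame.box, frame.coords.copy())
                  for t in range(n_frames)]
        return Trajectory(top, frames), frame.coords.copy()

    def test_identical_frames_give_zero(self):
        traj, ref = self._static_traj()
        rep = rmsd_series(traj, ref)
        assert np.allclose(rep.rmsd_series, 0.0, atol=1e-10)

    def test_single_displaced_atom_closed_form(self):
        """Without superposition, displacing 1 of N atoms by d gives
        RMSD d/sqrt(N)."""
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(9, 3))
        moved = ref.copy()
        moved[0, 2] += 0.3
        assert rmsd(moved, ref, superpose=False) == pytest.approx(
            0.3 / np.sqrt(9))

    def test_atom_count_mismatch_rejected(self):
        traj, ref = self._static_traj()
        with pytest.raises(ValueError):
            rmsd_series(traj, ref[:-1])


class TestRmsf:
    def test_static_trajectory_is_flat_zero(self):
        traj, _ = TestRmsdSeries._static_traj()
        assert np.allclose(rmsf(traj), 0.0, atol=1e-12)

    def test_single_oscillating_atom_without_superposition(self):
        top, frame = make_system(SyntheticSpec(seed=3, box=6.0,
                                               n_protein_beads=4))
        a = 0.05
        frames = []
        for t in range(10):
            c = frame.coords.copy()
            c[0, 0] += a if t % 2 == 0 else -a
            frames.append(Frame(float(t), frame.box, c))
        fl = rmsf(Trajectory(top, frames), superpose=False)
        assert fl[0] == pytest.approx(a)
        assert np.allclose(fl[1:], 0.0, atol=1e-12)

    def test_planted_variances_recovered(self):
        """Isotropic per-atom Gaussian noise: RMSF_i -> sigma_i sqrt(3)."""
        top, frame = make_system(SyntheticSpec(seed=4, box=6.0,
                                               n_protein_beads=6))
        sel = np.arange(6)
        sig = np.linspace(0.01, 0.06, 6)
        rng = np.random.default_rng(5)
        frames = []
        for t in range(4000):
            c = frame.coords.copy()
            c[sel] += rng.normal(0, sig[:, None], (6, 3))
            frames.append(Frame(float(t), frame.box, c))
        fl = rmsf(Trajectory(top, frames), selection=sel, superpose=False)
        np.testing.assert_allclose(fl, sig * np.sqrt(3), rtol=0.05)

    def test_invariant_under_global_rigid_motion(self):
        top, frame = make_system(SyntheticSpec(seed=6, box=6.0,
                                               n_protein_beads=5))
        rng = np.random.default_rng(7)
        base = []
        for t in range(30):
            c = frame.coords.copy()
            c += rng.normal(0, 0.01, c.shape)
            base.append(c)
        traj1 = Trajectory(top, [Frame(float(t), frame.box, c)
                                 for t, c in enumerate(base)])
        R = Rotation.random(random_state=8).as_matrix()
        traj2 = Trajectory(top, [Frame(float(t), frame.box, c @ R.T + 2.0)
                                 for t, c in enumerate(base)])
        np.testing.assert_allclose(rmsf(traj1), rmsf(traj2), atol=1e-8)

    def test_single_frame_rejected(self):
        top, frame = make_system(SyntheticSpec(seed=8, box=6.0,
                                               n_protein_beads=4))
        with pytest.raises(ValueError):
            rmsf(Trajectory(top, [frame]))


class TestDhes:
    def test_identical_ensembles_give_zero(self):
        e = make_gaussian_ensemble(np.zeros((4, 3)), 0.01 * np.eye(12), 200, 1)
        assert d_hes(e, e.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        a = make_gaussian_ensemble(np.zeros(6), 0.02 * np.eye(6), 300, 2)
        b = make_gaussian_ensemble(np.full(6, 0.1), 0.03 * np.eye(6), 300, 3)
        assert d_hes(a, b) == pytest.approx(d_hes(b, a))

    def test_univariate_closed_form(self):
        """KL(N(0,1) || N(1,1)) = 1/2, and so is the symmetrized form."""
        assert gaussian_kl([0.0], [[1.0]], [1.0], [[1.0]]) == pytest.approx(0.5)
        assert d_hes_from_params([0.0], [[1.0]], [1.0], [[1.0]]) == (
            pytest.approx(0.5))

    def test_monotone_in_mean_separation(self):
        cov = 0.01 * np.eye(9)
        base = make_gaussian_ensemble(np.zeros(9), cov, 500, 4)
        vals = []
        for shift in (0.0, 0.05, 0.1, 0.2):
            other = make_gaussian_ensemble(np.full(9, shift), cov, 500, 5)
            vals.append(d_hes(base, other))
        assert vals == sorted(vals)

    def test_matrix_consistent_with_elementwise(self):
        es = [make_gaussian_ensemble(np.full(6, 0.1 * k), 0.02 * np.eye(6),
                                     200, k) for k in range(3)]
        m = pairwise_dhes_matrix(es, superpose=False)
        assert np.allclose(np.diag(m), 0.0)
        assert m[0, 1] == pytest.approx(d_hes(es[0], es[1]))
        assert m == pytest.approx(m.T)

    def test_two_identical_plus_one_shifted(self):
        e0 = make_gaussian_ensemble(np.zeros(6), 0.02 * np.eye(6), 300, 6)
        e2 = make_gaussian_ensemble(np.full(6, 0.5), 0.02 * np.eye(6), 300, 7)
        m = pairwise_dhes_matrix([e0, e0.copy(), e2], superpose=False)
        assert m[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert m[0, 2] > 1.0

    def test_nonnegative(self, rng):
        for k in range(10):
            a = rng.normal(size=(50, 6))
            b = rng.normal(size=(50, 6))
            assert d_hes(a, b) >= 0.0

    def test_subsample_stride(self):
        top, frame = make_system(SyntheticSpec(seed=9, box=6.0,
                                               n_protein_beads=4))
        frames = [Frame(10.0 * t, frame.box, frame.coords.copy())
                  for t in range(20)]  # dt = 10 ps
        traj = Trajectory(top, frames)
        ens = subsample_concatenate([traj, traj], stride_ps=40.0)
        assert len(ens) == 10  # every 4th frame from each of 2 replicates

    def test_superpose_ensembles_removes_rigid_motion(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(8, 3))
        a = np.array([base + rng.normal(0, 0.01, base.shape)
                      for _ in range(50)])
        R = Rotation.random(random_state=12).as_matrix()
        b = np.array([x @ R.T + 3.0 for x in a])
        sa, sb = superpose_ensembles(a, b)
        assert d_hes(sa, sb) < d_hes(a, b)
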