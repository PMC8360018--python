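import numpy as np
import pytest

from somtool.core import Species
from somtool.solvation import (
    RDF,
    kb_average,
    kb_integral,
    kb_running_integral,
    preferential_solvation,
    rdf,
)
from somtool.synthetic import SyntheticSpec, make_system, make_trajectory


def _tabulated(g_func, r_max=2.0, bin_width=0.005):
    centers = np.arange(bin_width / 2, r_max, bin_width)
    return RDF("water", "cation", centers, g_func(centers), rho_j=1.0,
               bin_width=bin_width)


class TestRdf:
    def test_two_fixed_particles_single_bin(self):
        spec = SyntheticSpec(seed=1, box=4.0,
                             cosolvent_counts={"ca": 1, "cl": 1}, n_frames=1)
        top, frame = make_system(spec)
        coords = frame.coords.copy()
        coords[0] = [1.0, 1.0, 1.0]
        coords[1] = [1.5, 1.0, 1.0]
        frame.coords[:] = coords
        from somtool.core import Trajectory

        traj = Trajectory(top, [frame])
        r = rdf(traj, Species.CATION, Species.ANION, bin_width=0.02)
        occupied = np.nonzero(r.g)[0]
        assert len(occupied) == 1
        assert abs(r.bin_centers[occupied[0]] - 0.5) <= 0.02

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_histogram(self, seed):
        """Cross-species histogram against an explicit O(N^2) pair count."""
        rng = np.random.default_rng(seed)
        spec = SyntheticSpec(seed=seed, box=4.0,
                             cosolvent_counts={"ca": 6, "cl": 9}, n_frames=1)
        top, frame = make_system(spec)
        traj_frames = [frame]
        from somtool.core import Trajectory

        traj = Trajectory(top, traj_frames)
        bw = 0.05
        r = rdf(traj, Species.CATION, Species.ANION, bin_width=bw)
        pos_i = frame.coords[:6]
        pos_j = frame.coords[6:15]
        counts = np.zeros_like(r.g)
        for a in pos_i:
            for b in pos_j:
                d = a - b
                d -= frame.box * np.round(d / frame.box)
                rr = np.sqrt((d**2).sum())
                k = int(rr // bw)
                if k < len(counts):
                    counts[k] += 1
        vol = float(np.prod(frame.box))
        edges = np.arange(0, bw * (len(counts) + 1), bw)[: len(counts) + 1]
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        expected = counts * vol / (6 * 9 * shell)
        np.testing.assert_allclose(r.g, expected, atol=1e-9)

    def test_ideal_gas_g_near_one(self):
        spec = SyntheticSpec(seed=3, box=5.0,
                             cosolvent_counts={"water": 40, "ca": 30},
                             n_frames=60)
        traj = make_trajectory(spec)
        r = rdf(traj, Species.WATER, Species.CATION, bin_width=0.05)
        sel = r.bin_centers > 0.3
        # per-bin counts ~ Poisson; allow 3 pooled standard errors
        mean_g = r.g[sel].mean()
        n_eff = 40 * 30 * 60
        se = 1.0 / np.sqrt(n_eff * (r.g[sel] > -1).sum() / len(r.g))
        assert abs(mean_g - 1.0) < 3 * max(se, 0.01)

    def test_same_species_excludes_self_pairs(self):
        spec = SyntheticSpec(seed=4, box=5.0,
                             cosolvent_counts={"water": 30}, n_frames=30)
        traj = make_trajectory(spec)
        r = rdf(traj, Species.WATER, Species.WATER, bin_width=0.05)
        assert np.isfinite(r.g).all()
        assert abs(r.g[r.bin_centers > 0.5].mean() - 1.0) < 0.1

    def test_r_max_beyond_half_box_rejected(self):
        spec = SyntheticSpec(seed=5, box=4.0,
                             cosolvent_counts={"ca": 2, "cl": 2}, n_frames=1)
        top, frame = make_system(spec)
        from somtool.core import Trajectory

        with pytest.raises(ValueError):
            rdf(Trajectory(top, [frame]), Species.CATION, Species.ANION,
                r_max=3.0)


class TestKbIntegral:
    def test_uniform_g_gives_zero(self):
        r = _tabulated(lambda x: np.ones_like(x))
        assert kb_integral(r, 1.5) == pytest.approx(0.0, abs=1e-12)
        assert kb_average(r) == pytest.approx(0.0, abs=1e-12)

    def test_hard_core_analytic_value(self):
        sigma = 0.3
        r = _tabulated(lambda x: (x >= sigma).astype(float), bin_width=0.005)
        expected = -4 * np.pi / 3 * sigma**3
        assert kb_integral(r, 1.5) == pytest.approx(expected, abs=1e-6)

    def test_smooth_g_matches_fine_simpson(self):
        from scipy.integrate import simpson

        def g(x):
            return 1.0 + 0.8 * np.exp(-((x - 0.4) ** 2) / 0.02)

        r = _tabulated(g, bin_width=0.0005)
        R = 1.2
        fine = np.linspace(0, R, 20001)
        expected = simpson(4 * np.pi * (g(fine) - 1) * fine**2, x=fine)
        assert kb_integral(r, R) == pytest.approx(expected, abs=1e-6)

    def test_linear_in_g_minus_one(self):
        base = _tabulated(lambda x: 1.0 + 0.3 * np.sin(x))
        doubled = _tabulated(lambda x: 1.0 + 0.6 * np.sin(x))
        assert kb_integral(doubled, 1.5) == pytest.approx(
            2 * kb_integral(base, 1.5), rel=1e-9)

    def test_trapezoid_option_agrees_on_smooth_g(self):
        r = _tabulated(lambda x: 1.0 + 0.5 * np.exp(-x), bin_width=0.001)
        # the two rules differ by half-bin boundary terms at 0 and R
        assert kb_integral(r, 1.0, method="trapezoid") == pytest.approx(
            kb_integral(r, 1.0, method="bins"), abs=2e-3)


class TestKbAverage:
    def test_linear_running_integral_averages_to_midpoint(self):
        # g such that G(R) is linear: contribution per unit R constant
        r = _tabulated(lambda x: 1.0 + 0.01 / (4 * np.pi / 3 * x**2 * 3),
                       bin_width=0.002)
        res = kb_running_integral(r)
        lo, hi = 1.0, 1.6
        mask = (res.R >= lo) & (res.R <= hi)
        g_lo, g_hi = res.G_of_R[mask][0], res.G_of_R[mask][-1]
        assert kb_average(r, lo, hi) == pytest.approx((g_lo + g_hi) / 2,
                                                      rel=5e-3)

    def test_empty_window_rejected(self):
        r = _tabulated(lambda x: np.ones_like(x), r_max=0.5)
        with pytest.raises(ValueError):
            kb_average(r, 1.0, 1.6)


class TestPreferentialSolvation:
    def test_equal_integrals_give_zero(self):
        assert preferential_solvation(0.4, 0.4, 0.3, 0.5) == 0.0

    def test_antisymmetric_under_swap(self):
        d1 = preferential_solvation(0.7, 0.2, 0.3, 0.5)
        d2 = preferential_solvation(0.2, 0.7, 0.5, 0.3)
        assert d1 == pytest.approx(-d2)

    def test_difference_convention(self):
        assert preferential_solvation(
            0.7, 0.2, 0.3, 0.5, convention="difference"
        ) == pytest.approx(0.5)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            preferential_solvation(0.1, 0.2, 0.7, 0.7)

    def test_ideal_gas_delta_near_zero(self):
        """Full chain: uncorrelated species mix homogeneously (delta ~ 0)."""
        spec = SyntheticSpec(seed=6, box=5.0,
                             cosolvent_counts={"water": 30, "ca": 15,
                                               "cl": 15},
                             n_frames=100)
        traj = make_trajectory(spec)
        from somtool.core import Trajectory

        deltas = []
        for k in range(5):
            chunk = Trajectory(traj.topology, traj.frames[k * 20:(k + 1) * 20])
            g_si = kb_average(rdf(chunk, Species.WATER, Species.CATION,
                                  bin_width=0.05, r_max=2.4), 1.0, 1.6)
            g_sj = kb_average(rdf(chunk, Species.WATER, Species.ANION,
                                  bin_width=0.05, r_max=2.4), 1.0, 1.6)
            deltas.append(preferential_solvation(g_si, g_sj, 0.25, 0.25))
        deltas = np.asarray(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 3 * se + 1e-3

    def test_demixed_blocks_give_large_delta(self):
        """Two spatial blocks of species: self-association drives delta
        far from zero with the expected sign."""
        from somtool.core import Frame, Trajectory

        spec = SyntheticSpec(seed=7, box=6.0,
                             cosolvent_counts={"ca": 40, "cl": 40}, n_frames=1)
        top, frame = make_system(spec)
        rng = np.random.default_rng(0)
        frames = []
        for k in range(30):
            coords = frame.coords.copy()
            # cations confined to the lower half, anions to the upper half
            coords[:40] = rng.uniform([0, 0, 0], [6, 6, 2.9], size=(40, 3))
            coords[40:] = rng.uniform([0, 0, 3.1], [6, 6, 6], size=(40, 3))
            frames.append(Frame(float(k), frame.box, coords))
        traj = Trajectory(top, frames)
        g_cc = kb_average(rdf(traj, Species.CATION, Species.CATION,
                              bin_width=0.05, r_max=2.9), 1.0, 1.6)
        g_ca = kb_average(rdf(traj, Species.CATION, Species.ANION,
                              bin_width=0.05, r_max=2.9), 1.0, 1.6)
        delta = preferential_solvation(g_cc, g_ca, 0.5, 0.5)
        assert delta > 0.1  # cations enrich around cations
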