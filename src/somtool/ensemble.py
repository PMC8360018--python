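"""Structural stability and conformational-ensemble similarity metrics.

Implements optimal rigid-body (Kabsch) superposition, RMSD time series
against a reference structure, per-atom RMSF about the trajectory-average
structure, and the harmonic ensemble similarity D_HES: each conformational
ensemble is modelled as a multivariate normal over its superposed
coordinates and two ensembles are compared by the symmetrized
Kullback-Leibler divergence between the fitted Gaussians,

    D_HES(a, b) = 1/2 [ KL(N_a || N_b) + KL(N_b || N_a) ],

using the closed form for multivariate normals.  Covariances are
regularized by adding a small diagonal (default 1e-6 nm^2) so the fits are
invertible even when the sample count is below the dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Trajectory

__all__ = [
    "EnsembleGaussian",
    "StabilityReport",
    "kabsch_superpose",
    "rmsd",
    "rmsd_series",
    "rmsf",
    "fit_ensemble_gaussian",
    "gaussian_kl",
    "d_hes",
    "d_hes_from_params",
    "pairwise_dhes_matrix",
    "superpose_ensembles",
    "subsample_concatenate",
]


@dataclass
class EnsembleGaussian:
    mean: np.ndarray        # (3M,) nm
    covariance: np.ndarray  # (3M, 3M) nm^2
    n_samples: int
    regularization: float


@dataclass
class StabilityReport:
    rmsd_series: np.ndarray       # nm, per frame
    rmsd_mean: float
    rmsd_sd_over_replicates: float
    rmsf_per_atom: np.ndarray | None = None


def _check_not_collinear(x: np.ndarray) -> None:
    centered = x - x.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if len(x) < 3 or s[1] < 1e-10 * max(1.0, s[0]):
        raise ValueError(
            "superposition undefined for fewer than 3 non-collinear points"
        )


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the transformed mobile coordinates and the proper rotation
    matrix (det +1; reflections are never used).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets must have the same shape")
    _check_not_collinear(reference)
    _check_not_collinear(mobile)
    w = None if weights is None else np.asarray(weights, dtype=float)
    mob_c = np.average(mobile, axis=0, weights=w)
    ref_c = np.average(reference, axis=0, weights=w)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c, weights=w)
    R = rot.as_matrix()
    return (mobile - mob_c) @ R.T + ref_c, R


def rmsd(a: np.ndarray, b: np.ndarray,
         superpose: bool = True) -> float:
    """RMSD (nm) between two conformations, after superposition by default."""
    a = np.asarray(a, dtype=float)
    if superpose:
        a, _ = kabsch_superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(trajectory: Trajectory, reference: np.ndarray,
                selection: np.ndarray | None = None) -> StabilityReport:
    """Per-frame RMSD of a selection against a reference structure."""
    sel = (np.arange(trajectory.topology.n_atoms)
           if selection is None else np.asarray(selection, dtype=int))
    reference = np.asarray(reference, dtype=float)
    if reference.shape[0] != sel.size:
        raise ValueError("reference atom count does not match the selection")
    vals = np.array([rmsd(f.coords[sel], reference) for f in trajectory.frames])
    return StabilityReport(vals, float(vals.mean()), 0.0)


def rmsf(trajectory: Trajectory, selection: np.ndarray | None = None,
         superpose: bool = True, n_iter: int = 3) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the average structure.

    Frames are superposed onto the trajectory-average structure (refined
    iteratively), then RMSF_i = sqrt(<|x_i - <x_i>|^2>).
    """
    if len(trajectory.frames) < 2:
        raise ValueError("RMSF requires at least two frames")
    sel = (np.arange(trajectory.topology.n_atoms)
           if selection is None else np.asarray(selection, dtype=int))
    frames = np.array([f.coords[sel] for f in trajectory.frames], dtype=float)
    if superpose:
        mean = frames[0]
        for _ in range(n_iter):
            aligned = np.array([kabsch_superpose(x, mean)[0] for x in frames])
            mean = aligned.mean(axis=0)
        frames = aligned
    mean = frames.mean(axis=0)
    return np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# Harmonic ensemble similarity


def fit_ensemble_gaussian(samples: np.ndarray,
                          regularization: float = 1e-6) -> EnsembleGaussian:
    """Fit a multivariate normal to ensemble coordinates.

    ``samples`` is (n, M, 3) or (n, d); the covariance gets
    ``regularization`` (nm^2) added to its diagonal.
    """
    x = np.asarray(samples, dtype=float)
    x = x.reshape(x.shape[0], -1)
    if x.shape[0] < 2:
        raise ValueError("need at least two samples to fit a covariance")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1).reshape(x.shape[1], x.shape[1])
    cov = cov + regularization * np.eye(x.shape[1])
    return EnsembleGaussian(mean, cov, x.shape[0], regularization)


def gaussian_kl(mu0, cov0, mu1, cov1) -> float:
    """KL(N0 || N1) for multivariate normals, in nats."""
    mu0 = np.atleast_1d(np.asarray(mu0, dtype=float))
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=float))
    cov0 = np.atleast_2d(np.asarray(cov0, dtype=float))
    cov1 = np.atleast_2d(np.asarray(cov1, dtype=float))
    k = mu0.size
    sign1, logdet1 = np.linalg.slogdet(cov1)
    sign0, logdet0 = np.linalg.slogdet(cov0)
    if sign0 <= 0 or sign1 <= 0:
        raise np.linalg.LinAlgError("singular covariance")
    diff = mu1 - mu0
    solve = np.linalg.solve(cov1, np.column_stack([cov0, diff]))
    tr = np.trace(solve[:, :k])
    maha = float(diff @ solve[:, k])
    return 0.5 * (tr + maha - k + logdet1 - logdet0)


def d_hes_from_params(mu_a, cov_a, mu_b, cov_b) -> float:
    """Symmetrized KL divergence between two explicit Gaussians."""
    return 0.5 * (gaussian_kl(mu_a, cov_a, mu_b, cov_b)
                  + gaussian_kl(mu_b, cov_b, mu_a, cov_a))


def d_hes(ensemble_a: np.ndarray, ensemble_b: np.ndarray,
          regularization: float = 1e-6, superpose: bool = False) -> float:
    """Harmonic ensemble similarity between two coordinate ensembles.

    Ensembles are assumed already superposed to a common reference (use
    :func:`superpose_ensembles`, or pass ``superpose=True`` to do it here).
    """
    if superpose:
        ensemble_a, ensemble_b = superpose_ensembles(ensemble_a, ensemble_b)
    ga = fit_ensemble_gaussian(ensemble_a, regularization)
    gb = fit_ensemble_gaussian(ensemble_b, regularization)
    return d_hes_from_params(ga.mean, ga.covariance, gb.mean, gb.covariance)


def superpose_ensembles(a: np.ndarray, b: np.ndarray, n_iter: int = 3,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Superpose both ensembles onto the mean structure of their union,
    removing rigid-body variance symmetrically before Gaussian fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    union = np.concatenate([a, b])
    mean = union[0]
    for _ in range(n_iter):
        union = np.array([kabsch_superpose(x, mean)[0] for x in union])
        mean = union.mean(axis=0)
    return union[: len(a)], union[len(a):]


def pairwise_dhes_matrix(ensembles: list[np.ndarray],
                         regularization: float = 1e-6,
                         superpose: bool = True) -> np.ndarray:
    """Symmetric matrix of pairwise D_HES values (zero diagonal)."""
    n = len(ensembles)
    if n < 2:
        raise ValueError("need at least two ensembles")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = d_hes(
                ensembles[i], ensembles[j], regularization, superpose=superpose
            )
    return out


def subsample_concatenate(trajectories: list[Trajectory],
                          selection: np.ndarray | None = None,
                          stride_ps: float = 40.0) -> np.ndarray:
    """Ensemble pre-processing: one snapshot per ``stride_ps`` from each
    replicate, concatenated into a single coordinate ensemble."""
    chunks = []
    for traj in trajectories:
        sel = (np.arange(traj.topology.n_atoms)
               if selection is None else np.asarray(selection, dtype=int))
        next_t = traj.frames[0].time
        for f in traj.frames:
            if f.time + 1e-9 >= next_t:
                chunks.append(f.coords[sel])
                next_t = f.time + stride_ps
    return np.asarray(chunks)
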