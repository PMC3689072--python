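"""Mass-weighted principal component analysis of trajectories.

The trajectory is first stripped of rigid-body motion (centre-of-mass
translation and least-squares rotation onto a reference, iterated with the
mean structure as reference), then the mass-weighted covariance

    F = ⟨ m¹ᐟ²(x − ⟨x⟩) · m¹ᐟ²(x − ⟨x⟩)ᵀ ⟩

is built and diagonalized.  Its eigenvalues Q² (Da Å²) are the variances of
the collective coordinates; under harmonic statistics Q² = kT/ω², which
assigns each principal component a pseudo-frequency so that every
normal-mode analysis downstream (entropy, B-factors, overlaps) runs
unchanged on PCA output.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .constants import ENM_EIGVAL_TO_S2, kT_kcal
from .modes import ModeSet
from .structure_io import Structure, Trajectory

__all__ = [
    "CovarianceMatrix",
    "ProjectionSeries",
    "kabsch_rotation",
    "superpose_frame",
    "remove_rigid_body",
    "compute_covariance",
    "pca_modes",
    "project_frames",
]


@dataclass
class CovarianceMatrix:
    """3N×3N mass-weighted covariance (Da Å²) and its mean coordinates."""

    array: np.ndarray
    mean_coords: np.ndarray  # (N, 3) Å
    n_frames: int
    weighting: str = "unit"
    superposition_reference: str = "mean"
    divisor: str = "n"  # "n" (population) or "n-1"

    @property
    def dim(self) -> int:
        return self.array.shape[0]


@dataclass
class ProjectionSeries:
    """Per-frame projections onto selected eigenvectors.

    ``values`` has shape (n_frames, n_modes_selected); ``mode_indices`` are
    the 0-based indices into the ModeSet the projections refer to.
    """

    values: np.ndarray
    mode_indices: np.ndarray
    frame_times: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def histograms(self, bins: int = 50):
        """Marginal distribution of each projection; list of (counts, edges)."""
        return [np.histogram(self.values[:, k], bins=bins)
                for k in range(self.values.shape[1])]


# ----------------------------------------------------------------------
# Rigid-body removal
# ----------------------------------------------------------------------

def kabsch_rotation(moving: np.ndarray, target: np.ndarray,
                    weights: np.ndarray) -> np.ndarray:
    """Weighted least-squares rotation matrix mapping moving → target.

    Both inputs must already be centred on their weighted centroids.
    Raises for degenerate (collinear) geometry where the rotation is
    underdetermined.
    """
    h = (weights[:, None] * moving).T @ target
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) frame: rotation underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose_frame(frame: np.ndarray, reference: np.ndarray,
                    masses: np.ndarray) -> np.ndarray:
    """Mass-weighted superposition of one frame onto a reference."""
    w = masses / masses.sum()
    com_f = (w[:, None] * frame).sum(axis=0)
    com_r = (w[:, None] * reference).sum(axis=0)
    rot = kabsch_rotation(frame - com_f, reference - com_r, masses)
    return (frame - com_f) @ rot.T + com_r


def remove_rigid_body(traj: Trajectory, structure: Structure,
                      reference: str = "mean", max_iter: int = 50,
                      tol: float = 1e-6) -> Trajectory:
    """Remove centre-of-mass motion and rigid rotations from every frame.

    With ``reference="mean"`` the superposition target is iterated: frames
    are fitted to the current mean structure until the mean moves by less
    than ``tol`` Å (RMS).  ``reference="first_frame"`` fits once to frame 0.
    Idempotent: applying it to already-superposed frames is a no-op.
    """
    if structure.n_atoms != traj.n_atoms:
        raise ValueError("structure/trajectory atom-count mismatch")
    masses = structure.masses
    frames = traj.frames.copy()

    if reference == "first_frame":
        ref = frames[0].copy()
        for t in range(traj.n_frames):
            frames[t] = superpose_frame(frames[t], ref, masses)
        return Trajectory(frames, traj.frame_times, traj.source_format)
    if reference != "mean":
        raise ValueError("reference must be 'mean' or 'first_frame'")

    ref = frames.mean(axis=0)
    for _ in range(max_iter):
        for t in range(traj.n_frames):
            frames[t] = superpose_frame(frames[t], ref, masses)
        new_ref = frames.mean(axis=0)
        shift = np.sqrt(((new_ref - ref) ** 2).sum(axis=1).mean())
        ref = new_ref
        if shift < tol:
            break
    return Trajectory(frames, traj.frame_times, traj.source_format)


# ----------------------------------------------------------------------
# Covariance and PCA (COVAR)
# ----------------------------------------------------------------------

def compute_covariance(traj: Trajectory, structure: Structure,
                       superpose: bool = True, reference: str = "mean",
                       divisor: str = "n") -> CovarianceMatrix:
    """Mass-weighted covariance of the trajectory fluctuations.

    F = (1/n) Σ_t m¹ᐟ²(x_t − ⟨x⟩)(x_t − ⟨x⟩)ᵀ m¹ᐟ², with the population
    divisor n by default (``divisor="n-1"`` for the sample estimator).
    Rigid-body motion is removed first unless ``superpose=False``.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for a covariance matrix")
    if superpose:
        traj = remove_rigid_body(traj, structure, reference=reference)
    n_frames = traj.n_frames
    mean = traj.frames.mean(axis=0)
    disp = (traj.frames - mean).reshape(n_frames, -1)
    sqrt_m = np.repeat(np.sqrt(structure.masses), 3)
    mw = disp * sqrt_m
    denom = n_frames if divisor == "n" else n_frames - 1
    if divisor not in ("n", "n-1"):
        raise ValueError("divisor must be 'n' or 'n-1'")
    f = (mw.T @ mw) / denom
    f = 0.5 * (f + f.T)
    weighting = (structure.selection.mass_mode if structure.selection else "unit")
    return CovarianceMatrix(f, mean_coords=mean, n_frames=n_frames,
                            weighting=weighting,
                            superposition_reference=reference, divisor=divisor)


def pca_modes(cov: CovarianceMatrix, temperature: float = 300.0) -> ModeSet:
    """Diagonalize the covariance matrix; modes ordered by descending
    variance Q².

    Pseudo-frequencies ω = √(kT/Q²) are available from the ModeSet
    (infinite, i.e. thermodynamically inert, for zero-variance modes).
    """
    lam, vec = scipy.linalg.eigh(cov.array)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order]
    n_zero = int(np.sum(lam <= 1e-12 * max(lam.max(), 1e-300)))
    warns = []
    if n_zero:
        msg = (f"{n_zero} zero-variance modes assigned infinite "
               f"pseudo-frequency; excluded from thermodynamic sums")
        warns.append(msg)
        _warnings.warn(msg)
    return ModeSet(lam, vec, kind="pca", weighting=cov.weighting,
                   n_zero_modes=n_zero, warnings=warns)


def project_frames(traj: Trajectory, modes: ModeSet, which_modes,
                   structure: Structure, mean_coords: np.ndarray | None = None
                   ) -> ProjectionSeries:
    """Project frames onto eigenvectors: p_v(t) = m¹ᐟ²(x_t − ⟨x⟩)·e(v).

    The trajectory must be superposed to the same reference the modes were
    computed in; ``mean_coords`` defaults to the trajectory mean.  Mode
    indices are 0-based.
    """
    which = np.asarray(which_modes, dtype=int)
    if np.any(which < 0) or np.any(which >= modes.n_modes):
        raise IndexError("mode index out of range")
    if modes.dim != 3 * traj.n_atoms:
        raise ValueError("mode/trajectory dimension mismatch")
    mean = (traj.frames.mean(axis=0) if mean_coords is None
            else np.asarray(mean_coords).reshape(traj.n_atoms, 3))
    sqrt_m = np.repeat(np.sqrt(structure.masses), 3)
    disp = (traj.frames - mean).reshape(traj.n_frames, -1) * sqrt_m
    values = disp @ modes.eigenvectors[:, which]
    return ProjectionSeries(values, which, traj.frame_times)
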