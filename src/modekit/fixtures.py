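"""Deterministic synthetic structures and harmonic trajectories.

Everything in the toolbox is testable without downloading structures: toy
geometries (two-body pairs, Cα chains at 3.8 Å spacing, ideal helices,
compact random blobs, deliberately disconnected two-cluster systems) and
equilibrium harmonic trajectories sampled from a known mode spectrum, so
that trajectory PCA can be validated against the generating network.

Harmonic frames are i.i.d. samples of the Boltzmann distribution of the
harmonic modes (amplitude variance kT/ω² per mode), not time-correlated
dynamics: the covariance analysis only needs the equilibrium distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import kT_kcal
from .modes import ModeSet
from .structure_io import (AtomRecord, Structure, Trajectory, write_pdb)

__all__ = ["FixtureSpec", "make_structure", "make_harmonic_trajectory"]

CA_SPACING = 3.8       # Å, consecutive Cα distance
HELIX_RISE = 1.5       # Å per residue
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # Å
MIN_SEPARATION = 3.8   # Å, random blob site exclusion distance

KINDS = ("two_body", "linear_chain", "helix_like", "random_blob",
         "disconnected_pair")


@dataclass
class FixtureSpec:
    """Recipe for a deterministic toy structure.

    The seed fully determines the output; ``separation`` (Å) is the
    centre-to-centre distance of the two clusters of a
    ``disconnected_pair`` and defaults to 30 Å, beyond twice the default
    12 Å cutoff.
    """

    kind: str = "random_blob"
    n_sites: int = 20
    seed: int = 0
    separation: float = 30.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")


def _blob(n: int, rng: np.random.Generator) -> np.ndarray:
    """Compact random sites with a minimum pairwise separation."""
    radius = max(5.0, 2.8 * n ** (1 / 3) + 1.5)
    pts = []
    while len(pts) < n:
        p = rng.uniform(-radius, radius, size=3)
        if p @ p > radius**2:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < MIN_SEPARATION:
            continue
        pts.append(p)
    return np.array(pts)


def make_structure(spec: FixtureSpec, pdb_path=None) -> Structure:
    """Build a toy Cα structure; optionally also write it as a PDB file.

    Geometries: ``two_body`` — two sites 5 Å apart on x; ``linear_chain`` —
    sites every 3.8 Å along x; ``helix_like`` — ideal helix (1.5 Å rise,
    100°/residue, 2.3 Å radius); ``random_blob`` — compact seeded blob;
    ``disconnected_pair`` — two blobs whose centres sit ``separation`` Å
    apart (chains A and B).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    chains = ["A"] * n

    if spec.kind == "two_body":
        coords = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        n = 2
        chains = ["A", "A"]
    elif spec.kind == "linear_chain":
        coords = np.zeros((n, 3))
        coords[:, 0] = CA_SPACING * np.arange(n)
    elif spec.kind == "helix_like":
        theta = np.deg2rad(HELIX_TWIST) * np.arange(n)
        coords = np.column_stack([
            HELIX_RADIUS * np.cos(theta),
            HELIX_RADIUS * np.sin(theta),
            HELIX_RISE * np.arange(n),
        ])
    elif spec.kind == "random_blob":
        coords = _blob(n, rng)
    else:  # disconnected_pair
        n_a = n // 2
        n_b = n - n_a
        blob_a = _blob(n_a, rng)
        blob_b = _blob(n_b, rng)
        blob_b = blob_b + np.array([spec.separation, 0.0, 0.0])
        coords = np.vstack([blob_a, blob_b])
        chains = ["A"] * n_a + ["B"] * n_b

    atoms = [
        AtomRecord(serial=i + 1, name="CA", alt_loc=" ", res_name="GLY",
                   chain_id=chains[i], res_seq=i + 1, insertion_code=" ",
                   coord=coords[i].astype(float), occupancy=1.0,
                   b_factor=0.0, element="C")
        for i in range(n)
    ]
    structure = Structure(atoms, np.ones(n))
    if pdb_path is not None:
        write_pdb(structure, pdb_path)
    return structure


def make_harmonic_trajectory(modes: ModeSet, structure: Structure,
                             temperature: float = 300.0,
                             n_frames: int = 10_000, seed: int = 0,
                             mode_indices=None) -> Trajectory:
    """Sample equilibrium frames from a harmonic mode spectrum.

    Frames are x_t = x₀ + Σ_v a_v(t)·m⁻¹ᐟ²·e(v) with independent Gaussian
    amplitudes of variance kT/ω_v² per mode.  By default all nonrigid modes
    (eigenvalue above 1e-9 of the spectral maximum) are excited; requesting
    a zero-frequency mode raises.
    """
    if modes.kind == "gnm":
        raise ValueError("harmonic trajectories require 3-D modes")
    lam = modes.eigenvalues
    if mode_indices is None:
        mode_indices = np.nonzero(lam > 1e-9 * max(lam.max(), 1e-300))[0]
    mode_indices = np.asarray(mode_indices, dtype=int)
    if np.any(lam[mode_indices] <= 1e-9 * max(lam.max(), 1e-300)):
        raise ValueError("cannot excite a zero-frequency mode")

    rng = np.random.default_rng(seed)
    kT = kT_kcal(temperature)
    sigma = np.sqrt(kT / lam[mode_indices]) if temperature > 0 else np.zeros(
        mode_indices.size)
    amps = rng.standard_normal((n_frames, mode_indices.size)) * sigma
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(structure.masses), 3)
    basis = modes.eigenvectors[:, mode_indices] * inv_sqrt_m[:, None]  # (3N, nv)
    disp = amps @ basis.T
    frames = structure.coords.reshape(1, -1) + disp
    return Trajectory(frames.reshape(n_frames, structure.n_atoms, 3),
                      source_format="generated")
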