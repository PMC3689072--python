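"""Post-analysis on a ModeSet: frequencies and thermodynamics, fluctuation
profiles and B-factors, collectivity, cross-correlations, pairwise distance
fluctuations, overlaps, structure differences, and mode-perturbed
structures.

All operations are agnostic to whether the modes came from an elastic
network, a GNM, or trajectory PCA: the ModeSet carries eigenvalues in its
native units and converts to frequencies/amplitude variances on demand.
Mode indices in public ranges are 1-based (the seventh mode is the first
nonrigid mode of a connected elastic network); the default analysis window
is the 25 lowest-frequency nonrigid modes, i.e. modes 7-31.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import AVOGADRO, BOLTZMANN_J_MOL, HBAR_SI, EIGHT_PI2_OVER_3, kT_kcal
from .modes import ModeSet
from .pca import kabsch_rotation
from .structure_io import Structure

__all__ = [
    "ThermoParams",
    "ModeRange",
    "ResidueProfile",
    "mode_thermo",
    "rms_and_bfactors",
    "collectivity",
    "cross_correlation",
    "distance_fluctuation",
    "spacing",
    "overlap",
    "overlap_matrix",
    "structure_difference",
    "project_structure_along_mode",
]


@dataclass
class ThermoParams:
    """Temperature and physical constants for vibrational thermodynamics.

    ``boltzmann`` is the molar gas constant (J mol⁻¹ K⁻¹); ``hbar`` is the
    per-particle reduced Planck constant (J s) and is promoted to molar
    units internally so ℏω/kT stays dimensionless.
    """

    temperature: float = 300.0
    boltzmann: float = BOLTZMANN_J_MOL
    hbar: float = HBAR_SI

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def hbar_molar(self) -> float:
        return self.hbar * AVOGADRO

    @property
    def kT(self) -> float:
        return self.boltzmann * self.temperature


@dataclass
class ModeRange:
    """1-based mode window: ``start`` (default 7, skipping the six rigid
    modes) and ``count`` (default 25)."""

    start: int = 7
    count: int = 25

    def __post_init__(self):
        if self.start < 1 or self.count < 1:
            raise ValueError("start and count must be ≥ 1")

    def indices(self, modes: ModeSet) -> np.ndarray:
        """0-based mode indices, clipped to the available modes."""
        lo = self.start - 1
        hi = min(lo + self.count, modes.n_modes)
        if lo >= modes.n_modes:
            raise IndexError(
                f"mode range starts at {self.start} but only "
                f"{modes.n_modes} modes exist")
        return np.arange(lo, hi)


@dataclass
class ResidueProfile:
    """Per-site scalar track aligned to structure order."""

    values: np.ndarray
    labels: list = field(default_factory=list)  # (chain, resid) per site


def _range_indices(modes: ModeSet, mode_range: ModeRange | None) -> np.ndarray:
    return (mode_range or ModeRange()).indices(modes)


# ----------------------------------------------------------------------
# FREQ/EN
# ----------------------------------------------------------------------

def mode_thermo(modes: ModeSet, params: ThermoParams | None = None,
                mode_range: ModeRange | None = None) -> dict:
    """Per-mode frequency, free energy and entropy, with totals.

    For each mode of the range with ω > 0:

        G_v = −kT·ln[1/(1 − e^(−ℏω/kT))]                       (J/mol)
        S_v = k·[(ℏω/kT)/(e^(ℏω/kT) − 1) − ln(1 − e^(−ℏω/kT))] (J/mol/K)
        S'_v = (k/2)·ln[1 + (e·kT/ℏω)²]      (Schlitter bound, J/mol/K)

    Zero-frequency (rigid or zero-variance) modes carry no harmonic
    thermodynamics and are excluded with a warning.  Returns a dict with
    per-mode arrays and ``G_total``/``S_total``/``S_schlitter_total``.
    """
    params = params or ThermoParams()
    idx = _range_indices(modes, mode_range)
    omega = modes.frequencies(params.temperature)[idx]

    finite = np.isfinite(omega) & (omega > 0)
    if not np.all(finite):
        _warnings.warn(
            f"{int((~finite).sum())} zero/infinite-frequency modes excluded "
            f"from thermodynamic sums")
    om = omega[finite]
    x = params.hbar_molar * om / params.kT
    g = params.kT * np.log1p(-np.exp(-x))
    with np.errstate(over="ignore"):  # x/expm1(x) → 0 cleanly for large x
        s = params.boltzmann * (x / np.expm1(x) - np.log1p(-np.exp(-x)))
    s_schl = 0.5 * params.boltzmann * np.log1p((np.e / x) ** 2)

    freq = np.full(idx.size, np.nan)
    g_full = np.full(idx.size, np.nan)
    s_full = np.full(idx.size, np.nan)
    schl_full = np.full(idx.size, np.nan)
    freq[finite] = om
    g_full[finite] = g
    s_full[finite] = s
    schl_full[finite] = s_schl
    return {
        "mode_index": idx + 1,
        "frequency": freq,
        "G": g_full,
        "S": s_full,
        "S_schlitter": schl_full,
        "G_total": float(g.sum()),
        "S_total": float(s.sum()),
        "S_schlitter_total": float(s_schl.sum()),
    }


# ----------------------------------------------------------------------
# RMS/COLL
# ----------------------------------------------------------------------

def rms_and_bfactors(modes: ModeSet, structure: Structure,
                     params: ThermoParams | None = None,
                     mode_range: ModeRange | None = None,
                     per_residue: bool = False):
    """Per-site RMS fluctuation (Å) and predicted B-factor (Å²).

    The mean-square fluctuation of atom i sums kT·e_i²(v)/(m_i·ω_v²) over
    the mode window and the B-factor is (8π²/3) times it.  The mode window
    must not contain zero modes (an included zero mode raises, naming the
    offending 1-based mode).  With ``per_residue=True`` values are averaged
    over the (heavy) atoms of each residue.
    """
    params = params or ThermoParams()
    idx = _range_indices(modes, mode_range)
    amp = modes.amplitude_variances(params.temperature)[idx]  # kT/ω², Da Å²
    bad = ~np.isfinite(amp)
    if np.any(bad):
        raise ValueError(
            f"mode range includes zero-frequency mode {int(idx[bad][0]) + 1}")
    if modes.kind == "gnm":
        e2 = modes.eigenvectors[:, idx] ** 2  # (N, nv)
    else:
        e2 = (modes.eigenvectors[:, idx].reshape(structure.n_atoms, 3, -1) ** 2
              ).sum(axis=1)
    msf = (e2 * amp).sum(axis=1) / structure.masses  # Å²
    rmsf = np.sqrt(msf)
    b = EIGHT_PI2_OVER_3 * msf

    labels = [(a.chain_id, a.res_seq) for a in structure.atoms]
    if per_residue:
        res_idx = structure.residue_index()
        keys = structure.residue_keys()
        rmsf_r = np.array([rmsf[res_idx == r].mean() for r in range(len(keys))])
        b_r = np.array([b[res_idx == r].mean() for r in range(len(keys))])
        labels = [(c, r) for (c, r, _) in keys]
        return (ResidueProfile(rmsf_r, labels), ResidueProfile(b_r, labels))
    return (ResidueProfile(rmsf, labels), ResidueProfile(b, labels))


def collectivity(modes: ModeSet, mode_range: ModeRange | None = None
                 ) -> np.ndarray:
    """Degree of collectivity κ_v ∈ [1/N, 1] for each mode of the range.

    κ is the exponential of the Shannon entropy of the normalized per-atom
    squared amplitudes, divided by N: 1 for a uniformly delocalized mode,
    1/N for motion concentrated on a single atom.
    """
    idx = _range_indices(modes, mode_range)
    n = modes.n_atoms
    out = np.empty(idx.size)
    for k, v in enumerate(idx):
        w = modes.per_atom_square(int(v))
        total = w.sum()
        if total <= 0:
            raise ValueError(f"mode {int(v) + 1} has a zero eigenvector")
        p = w / total  # α·e_i² with α chosen so the weights sum to 1
        nz = p > 0
        entropy = -(p[nz] * np.log(p[nz])).sum()
        out[k] = np.exp(entropy) / n
    return out


# ----------------------------------------------------------------------
# CROSCOR
# ----------------------------------------------------------------------

def cross_correlation(modes: ModeSet, mode_range: ModeRange | None = None,
                      amplitude_weighted: bool = False) -> np.ndarray:
    """N×N cross-correlation of atomic motions over the mode range.

    C_ij = Σ_v e_i(v)·e_j(v) / (Σ_v|e_i(v)|² · Σ_v|e_j(v)|²)^½ — +1 for
    perfectly correlated, −1 for anti-correlated, 0 for orthogonal motion.
    The optional amplitude weighting multiplies each mode's contribution by
    its amplitude variance kT/ω² (off by default: the plain formula weights
    every mode equally).  Atoms with no motion in the range get a zero row
    with unit diagonal and a warning.
    """
    if modes.kind == "gnm":
        raise ValueError("cross-correlation requires 3-D (nma/pca) modes")
    idx = _range_indices(modes, mode_range)
    n = modes.n_atoms
    vecs = modes.eigenvectors[:, idx].reshape(n, 3, idx.size)
    if amplitude_weighted:
        w = modes.amplitude_variances()[idx]
        if np.any(~np.isfinite(w)):
            raise ValueError("amplitude weighting undefined for zero modes")
        vecs = vecs * np.sqrt(w)[None, None, :]
    x = vecs.reshape(n, -1)
    numer = x @ x.T
    den = np.diag(numer).copy()
    zero = den <= 0
    if np.any(zero):
        _warnings.warn(f"{int(zero.sum())} atoms have no motion in the mode "
                       f"range; their correlation rows are set to 0")
    safe = np.where(zero, 1.0, den)
    c = numer / np.sqrt(np.outer(safe, safe))
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


# ----------------------------------------------------------------------
# MOVEING / SPACING
# ----------------------------------------------------------------------

def distance_fluctuation(modes: ModeSet, structure: Structure,
                         mode_range: ModeRange | None = None,
                         temperature: float = 300.0) -> np.ndarray:
    """Mean-square inter-atom distance fluctuation δr²_ij (Å²).

    For each mode the eigenvector is applied as a displacement and the
    change of the squared inter-atom distance relative to equilibrium is
    accumulated, weighted by 1/ω² in the ModeSet's native eigenvalue units.
    Zero-frequency modes in the range raise.
    """
    if modes.kind == "gnm":
        raise ValueError("distance fluctuations require 3-D (nma/pca) modes")
    idx = _range_indices(modes, mode_range)
    lam = modes.eigenvalues[idx]
    if modes.kind == "pca":
        # native "ω²" of a PCA mode is kT/Q² in ENM units
        with np.errstate(divide="ignore"):
            lam = np.where(lam > 0, kT_kcal(temperature) / np.where(lam > 0, lam, 1), 0.0)
    if np.any(lam <= 0):
        raise ValueError(
            f"mode range includes zero-frequency mode "
            f"{int(idx[np.nonzero(lam <= 0)[0][0]]) + 1}")
    coords = structure.coords
    n = structure.n_atoms
    d0 = coords[:, None, :] - coords[None, :, :]  # (N, N, 3)
    r0_sq = (d0 ** 2).sum(axis=2)
    out = np.zeros((n, n))
    for v, l in zip(idx, lam):
        e = modes.eigenvectors[:, int(v)].reshape(n, 3)
        de = e[:, None, :] - e[None, :, :]
        out += (((d0 + de) ** 2).sum(axis=2) - r0_sq) / l
    return 0.5 * (out + out.T)


def spacing(structure: Structure) -> np.ndarray:
    """Euclidean inter-atom distance matrix (Å)."""
    coords = structure.coords
    return cdist(coords, coords)


# ----------------------------------------------------------------------
# OVERLAP / PDBDIFF / PROJECT
# ----------------------------------------------------------------------

def overlap(e1: np.ndarray, e2: np.ndarray) -> float:
    """Normalized inner product of two displacement vectors.

    1 means identical motion, 0 completely different; invariant to
    rescaling of either vector, sign flips negate it.
    """
    e1 = np.asarray(e1, dtype=float).reshape(-1)
    e2 = np.asarray(e2, dtype=float).reshape(-1)
    if e1.shape != e2.shape:
        raise ValueError("vectors must have equal length")
    n1, n2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if n1 == 0 or n2 == 0:
        raise ValueError("overlap undefined for a zero vector")
    return float(e1 @ e2 / (n1 * n2))


def overlap_matrix(modes1: ModeSet, modes2: ModeSet,
                   range1: ModeRange | None = None,
                   range2: ModeRange | None = None) -> np.ndarray:
    """Pairwise overlaps between two mode sets (rows: modes1 range)."""
    i1 = _range_indices(modes1, range1)
    i2 = _range_indices(modes2, range2)
    a = modes1.eigenvectors[:, i1]
    b = modes2.eigenvectors[:, i2]
    if a.shape[0] != b.shape[0]:
        raise ValueError("mode sets have different dimensions")
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("overlap undefined for a zero vector")
    return (a.T @ b) / np.outer(na, nb)


def structure_difference(struct_a: Structure, struct_b: Structure,
                         pairing: str = "by_order",
                         superpose: bool = True) -> np.ndarray:
    """3N displacement vector from structure a to structure b.

    Atoms are paired by order or by (chain, residue, name); b is rigidly
    superposed onto a (mass-weighted least squares) before differencing so
    the vector captures internal deformation only.  Ready for
    :func:`overlap` against mode eigenvectors.
    """
    if pairing == "by_order":
        if struct_a.n_atoms != struct_b.n_atoms:
            raise ValueError("structures have different atom counts")
        xa, xb = struct_a.coords, struct_b.coords
        masses = struct_a.masses
    elif pairing == "by_resid":
        key = lambda a: (a.chain_id, a.res_seq, a.insertion_code, a.name.strip())
        index_b = {key(a): i for i, a in enumerate(struct_b.atoms)}
        pairs, missing = [], []
        for i, a in enumerate(struct_a.atoms):
            j = index_b.get(key(a))
            if j is None:
                missing.append(key(a))
            else:
                pairs.append((i, j))
        if missing:
            raise ValueError(f"unpairable atoms: {missing}")
        ia = np.array([p[0] for p in pairs])
        ib = np.array([p[1] for p in pairs])
        xa, xb = struct_a.coords[ia], struct_b.coords[ib]
        masses = struct_a.masses[ia]
    else:
        raise ValueError("pairing must be 'by_order' or 'by_resid'")

    if superpose:
        w = masses / masses.sum()
        com_a = (w[:, None] * xa).sum(axis=0)
        com_b = (w[:, None] * xb).sum(axis=0)
        rot = kabsch_rotation(xb - com_b, xa - com_a, masses)
        xb = (xb - com_b) @ rot.T + com_a
    return (xb - xa).reshape(-1)


def project_structure_along_mode(structure: Structure, modes: ModeSet, v: int,
                                 amplitudes) -> list:
    """Perturbed coordinate sets x + a·m⁻¹ᐟ²·e(v) for each amplitude a.

    ``v`` is 0-based; amplitudes are in √Da·Å (the natural unit of a
    mass-weighted mode amplitude).  Returns one (N, 3) array per amplitude;
    write them out with :func:`modekit.structure_io.write_multi_model_pdb`.
    """
    if modes.kind == "gnm":
        raise ValueError("structure perturbation requires 3-D modes")
    if not (0 <= v < modes.n_modes):
        raise IndexError("mode index out of range")
    e = modes.eigenvectors[:, v].reshape(structure.n_atoms, 3)
    inv_sqrt_m = 1.0 / np.sqrt(structure.masses)
    x0 = structure.coords
    return [x0 + float(a) * inv_sqrt_m[:, None] * e for a in np.atleast_1d(amplitudes)]
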