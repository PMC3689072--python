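"""Mode container shared by normal mode analysis, GNM and trajectory PCA.

A :class:`ModeSet` is the universal currency of the toolbox: every analysis
(thermodynamics, B-factors, collectivity, correlations, overlaps, structure
perturbation) consumes one, regardless of whether it came from diagonalizing
an elastic-network Hessian, a Kirchhoff matrix, or a trajectory covariance
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ENM_EIGVAL_TO_S2, kT_kcal

__all__ = ["ModeSet"]


@dataclass
class ModeSet:
    """Eigenvalues and eigenvectors with mass-weighting metadata.

    Parameters
    ----------
    eigenvalues :
        For ``kind="nma"``/``"gnm"``: ω² in kcal mol⁻¹ Å⁻² Da⁻¹, sorted
        ascending.  For ``kind="pca"``: mass-weighted variances Q² in Da Å²,
        sorted descending (largest variance first).
    eigenvectors :
        Columns are modes; 3N components for nma/pca, N for gnm.  Orthonormal
        in the mass-weighted coordinate system they were solved in.
    kind :
        ``"nma"``, ``"gnm"`` or ``"pca"``.
    weighting :
        Mass mode used when the underlying matrix was built
        (``unit``/``atomic``/``residue``).
    n_zero_modes :
        Number of numerically-zero eigenvalues found at solve time (rigid-body
        modes for a connected 3-D network; more signals disconnection).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    kind: str = "nma"
    weighting: str = "unit"
    n_zero_modes: int = 0
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if self.eigenvectors.ndim != 2:
            raise ValueError("eigenvectors must be a (dim, n_modes) array")
        if self.eigenvectors.shape[1] != self.eigenvalues.shape[0]:
            raise ValueError("eigenvalue/eigenvector count mismatch")
        if self.kind not in ("nma", "gnm", "pca"):
            raise ValueError(f"unknown mode kind {self.kind!r}")

    # ------------------------------------------------------------------
    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def dim(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.dim if self.kind == "gnm" else self.dim // 3

    # ------------------------------------------------------------------
    def frequencies(self, temperature: float = 300.0) -> np.ndarray:
        """Angular frequencies ω in s⁻¹ for every mode.

        NMA/GNM eigenvalues are converted from kcal mol⁻¹ Å⁻² Da⁻¹; PCA
        variances are assigned the quasi-harmonic pseudo-frequency
        ω = √(kT/Q²), which is infinite for zero-variance modes.
        """
        if self.kind == "pca":
            with np.errstate(divide="ignore"):
                w2 = np.where(
                    self.eigenvalues > 0.0,
                    kT_kcal(temperature) / np.where(self.eigenvalues > 0.0, self.eigenvalues, 1.0),
                    np.inf,
                )
            return np.sqrt(w2 * ENM_EIGVAL_TO_S2)
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None) * ENM_EIGVAL_TO_S2)

    def amplitude_variances(self, temperature: float = 300.0) -> np.ndarray:
        """Equilibrium variance ⟨a_v²⟩ = kT/ω² of each mode amplitude, Da Å².

        For PCA modes this is the eigenvalue Q² itself; for NMA it follows
        from equipartition of the harmonic oscillator.  Zero-frequency modes
        get infinite variance (a rigid motion is unbounded).
        """
        if self.kind == "pca":
            return self.eigenvalues.copy()
        with np.errstate(divide="ignore"):
            return np.where(
                self.eigenvalues > 0.0,
                kT_kcal(temperature) / np.where(self.eigenvalues > 0.0, self.eigenvalues, 1.0),
                np.inf,
            )

    def per_atom_square(self, v: int) -> np.ndarray:
        """e_i²(v): squared eigenvector amplitude summed per atom."""
        e = self.eigenvectors[:, v]
        if self.kind == "gnm":
            return e**2
        return (e.reshape(-1, 3) ** 2).sum(axis=1)

    def select(self, indices) -> "ModeSet":
        """Sub-ModeSet with the given 0-based mode indices, order preserved."""
        idx = np.asarray(indices, dtype=int)
        return ModeSet(
            eigenvalues=self.eigenvalues[idx],
            eigenvectors=self.eigenvectors[:, idx],
            kind=self.kind,
            weighting=self.weighting,
            n_zero_modes=self.n_zero_modes,
            warnings=list(self.warnings),
        )
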