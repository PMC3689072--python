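"""Elastic and Gaussian network model construction.

The elastic network model replaces the detailed force field with Hookean
springs between all site pairs within a cutoff R_c (default 12 Å, spring
constant 1 kcal mol⁻¹ Å⁻²), taking the input structure as the energy
minimum.  The resulting mass-weighted Hessian D has 3×3 blocks
−k_ij/(√m_i m_j) · R̂⊗R̂ for each spring, and its eigenpairs are the normal
modes.  The Gaussian network model is the one-dimensional isotropic
counterpart built on the contact-graph Kirchhoff (Laplacian) matrix.

Spring-constant variants: uniform (default), empirical power decay
k·r⁻ᵖ within the cutoff, the Hinsen exponential k₀·exp(−r²/r₀²) applied to
all pairs (no cutoff), the Hinsen fitted two-regime distance function, and
per-pair values from a whitespace table with uniform fallback.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure

__all__ = [
    "SpringModel",
    "SpringNetwork",
    "HessianMatrix",
    "KirchhoffMatrix",
    "build_spring_network",
    "build_hessian",
    "build_kirchhoff",
    "read_pair_table",
    "write_matrix",
    "read_matrix",
]

# Hinsen fitted regime constants, converted from kJ/mol/nm² to kcal/mol/Å²
# (÷4.184 ÷100).  Below 4 Å: k = a·r + b; at and above: k = c·r⁻⁶.
_HINSEN_FIT_A = 8.6e2 / 418.4 / 10.0    # kcal mol⁻¹ Å⁻³ (r in Å)
_HINSEN_FIT_B = -2.39e3 / 418.4         # kcal mol⁻¹ Å⁻²
_HINSEN_FIT_C = 128.0e4 / 418.4 * 1.0e6  # kcal mol⁻¹ Å⁴ (·r⁻⁶, r in Å)
_HINSEN_FIT_SWITCH = 4.0                 # Å


@dataclass
class SpringModel:
    """Spring-constant law for the elastic network.

    ``base_k`` in kcal mol⁻¹ Å⁻², ``cutoff`` in Å.  ``power_exponent`` is the
    decay power p for the power-decay law; ``hinsen_scale``/``hinsen_amplitude``
    parameterize the exponential law k₀·exp(−r²/r₀²), which ignores the
    cutoff.  ``pair_table`` maps ((chain_i, resid_i), (chain_j, resid_j)) to a
    spring constant, with ``base_k`` as fallback.
    """

    kind: str = "uniform"
    base_k: float = 1.0
    cutoff: float = 12.0
    power_exponent: float = 2.0
    hinsen_scale: float = 3.0        # Å
    hinsen_amplitude: float = 86.0   # kcal mol⁻¹ Å⁻²
    pair_table: dict | None = None

    _KINDS = ("uniform", "power_decay", "hinsen_exponential", "hinsen_fitted",
              "per_pair_file")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown spring model kind {self.kind!r}")
        if self.base_k <= 0:
            raise ValueError("base_k must be positive")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def spring_constant(self, r: float, key_i=None, key_j=None) -> float:
        if self.kind == "uniform":
            return self.base_k
        if self.kind == "power_decay":
            return self.base_k * r ** (-self.power_exponent)
        if self.kind == "hinsen_exponential":
            return self.hinsen_amplitude * math.exp(-(r / self.hinsen_scale) ** 2)
        if self.kind == "hinsen_fitted":
            if r < _HINSEN_FIT_SWITCH:
                return max(_HINSEN_FIT_A * r + _HINSEN_FIT_B, 1e-12)
            return _HINSEN_FIT_C * r ** -6
        # per_pair_file
        if self.pair_table is not None and key_i is not None:
            k = self.pair_table.get((key_i, key_j))
            if k is None:
                k = self.pair_table.get((key_j, key_i))
            if k is not None:
                return k
        return self.base_k


@dataclass
class SpringNetwork:
    """Pairwise springs (i, j, k_ij, R_ij) with i < j, over N sites."""

    pairs: list
    n_atoms: int

    def __post_init__(self):
        for (i, j, k, r) in self.pairs:
            if i >= j:
                raise ValueError("spring pairs must satisfy i < j")
            if k <= 0:
                raise ValueError("spring constants must be positive")


@dataclass
class HessianMatrix:
    """3N×3N mass-weighted Hessian, kcal mol⁻¹ Å⁻² Da⁻¹."""

    array: np.ndarray
    weighting: str = "unit"
    kind: str = "nma"

    @property
    def dim(self) -> int:
        return self.array.shape[0]


@dataclass
class KirchhoffMatrix:
    """N×N Kirchhoff (connectivity Laplacian) matrix scaled by spring K."""

    array: np.ndarray
    spring_k: float = 1.0
    kind: str = "gnm"
    weighting: str = "unit"

    @property
    def dim(self) -> int:
        return self.array.shape[0]


def read_pair_table(path) -> dict:
    """Parse a per-pair spring file: lines ``chain resid chain resid k``."""
    table = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks or toks[0].startswith("#"):
                continue
            if len(toks) != 5:
                raise ValueError(f"line {lineno}: expected 'chain resid chain resid k'")
            key_i = (toks[0], int(toks[1]))
            key_j = (toks[2], int(toks[3]))
            table[(key_i, key_j)] = float(toks[4])
    return table


def write_matrix(matrix, path) -> None:
    """Write a Hessian/Kirchhoff matrix as text sparse triplets.

    Header ``matrix <hessian|kirchhoff> <dim> weighting <w>``, then one
    ``i j value`` line (0-based, upper triangle, 17 significant digits) per
    nonzero entry.
    """
    name = "kirchhoff" if isinstance(matrix, KirchhoffMatrix) else "hessian"
    arr = matrix.array
    with open(path, "w") as fh:
        fh.write(f"matrix {name} {arr.shape[0]} weighting {matrix.weighting}\n")
        rows, cols = np.nonzero(np.triu(arr))
        for i, j in zip(rows, cols):
            fh.write(f"{i} {j} {arr[i, j]:.17g}\n")


def read_matrix(path):
    """Read a matrix written by :func:`write_matrix`."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 5 or header[0] != "matrix":
            raise ValueError("malformed matrix file header")
        name, dim, weighting = header[1], int(header[2]), header[4]
        arr = np.zeros((dim, dim))
        for line in fh:
            toks = line.split()
            if not toks:
                continue
            i, j, v = int(toks[0]), int(toks[1]), float(toks[2])
            arr[i, j] = v
            arr[j, i] = v
    if name == "kirchhoff":
        return KirchhoffMatrix(arr, weighting=weighting)
    if name == "hessian":
        return HessianMatrix(arr, weighting=weighting)
    raise ValueError(f"unknown matrix type {name!r}")


def build_spring_network(structure: Structure, model: SpringModel | None = None
                         ) -> SpringNetwork:
    """Enumerate spring pairs for the structure under the given spring law.

    Cutoff-based laws include every pair with R_ij² ≤ R_c² (closed boundary);
    the Hinsen exponential law connects all pairs.  Sites left without any
    spring are reported with a warning — they produce extra zero modes
    downstream.
    """
    model = model or SpringModel()
    coords = structure.coords
    n = structure.n_atoms
    if n < 2:
        raise ValueError("need at least 2 atoms to build a spring network")

    if model.kind == "hinsen_exponential":
        idx_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        tree = cKDTree(coords)
        # closed boundary R² ≤ R_c²: nudge the radius up by a hair
        raw = tree.query_pairs(model.cutoff * (1 + 1e-12), output_type="ndarray")
        idx_pairs = [(min(i, j), max(i, j)) for i, j in raw]
        idx_pairs.sort()

    res_keys = [(a.chain_id, a.res_seq) for a in structure.atoms]
    pairs = []
    for i, j in idx_pairs:
        r = float(np.linalg.norm(coords[j] - coords[i]))
        if model.kind not in ("hinsen_exponential",) and r > model.cutoff:
            continue
        k = model.spring_constant(r, res_keys[i], res_keys[j])
        pairs.append((int(i), int(j), float(k), r))

    connected = np.zeros(n, dtype=bool)
    for i, j, _, _ in pairs:
        connected[i] = connected[j] = True
    for i in np.nonzero(~connected)[0]:
        a = structure.atoms[i]
        _warnings.warn(
            f"atom {a.name.strip()} {a.chain_id}:{a.res_seq} has no springs "
            f"within the cutoff; expect extra zero modes"
        )
    return SpringNetwork(pairs, n)


def build_hessian(network: SpringNetwork, structure: Structure,
                  mass_mode: str | None = None) -> HessianMatrix:
    """Assemble the mass-weighted Hessian D from the spring network.

    Each spring contributes the rank-1 block −k_ij·(R̂⊗R̂) off-diagonal and
    its negation to both diagonal blocks; every (i, j) block is then divided
    by √(m_i m_j).  Row sums of the unweighted Hessian vanish (rigid
    translations cost nothing).
    """
    n = network.n_atoms
    if structure.n_atoms != n:
        raise ValueError("network/structure atom-count mismatch")
    coords = structure.coords
    h = np.zeros((3 * n, 3 * n))
    for i, j, k, _ in network.pairs:
        d = coords[j] - coords[i]
        r2 = float(d @ d)
        if r2 == 0.0:
            raise ValueError(
                f"coincident atoms {i} and {j}: spring direction undefined"
            )
        block = -k * np.outer(d, d) / r2
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        h[sl_i, sl_j] += block
        h[sl_j, sl_i] += block
        h[sl_i, sl_i] -= block
        h[sl_j, sl_j] -= block

    weighting = mass_mode or (structure.selection.mass_mode
                              if structure.selection else "unit")
    sqrt_m = np.repeat(np.sqrt(structure.masses), 3)
    d = h / np.outer(sqrt_m, sqrt_m)
    d = 0.5 * (d + d.T)  # enforce exact symmetry
    return HessianMatrix(d, weighting=weighting)


def build_kirchhoff(structure: Structure, cutoff: float = 12.0,
                    spring_k: float = 1.0) -> KirchhoffMatrix:
    """Build the GNM Kirchhoff matrix Γ scaled by the spring constant K.

    Γ_ij = −1 for contacts within the cutoff, 0 otherwise; the diagonal is
    the contact degree, so row sums vanish.
    """
    coords = structure.coords
    n = structure.n_atoms
    if n < 2:
        raise ValueError("need at least 2 atoms to build a Kirchhoff matrix")
    tree = cKDTree(coords)
    gamma = np.zeros((n, n))
    for i, j in tree.query_pairs(cutoff * (1 + 1e-12)):
        gamma[i, j] = gamma[j, i] = -1.0
    np.fill_diagonal(gamma, -gamma.sum(axis=1))
    return KirchhoffMatrix(spring_k * gamma, spring_k=spring_k)
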