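"""Eigensolvers: full diagonalization and the rotation-translation-block
(RTB) projection, plus blocking strategies and the zero-mode diagnostic.

RTB coarse-grains the eigenproblem by restricting motion to rigid
translations and rotations of atom blocks (consecutive residue groups,
secondary-structure elements, or user-defined domains).  The projected
problem PᵀDP is solved in the block coordinate system and the eigenvectors
are expanded back to Cartesian components.  Because the projection spans a
subspace, every RTB eigenvalue bounds its full counterpart from above
(internal block stiffening); as blocks shrink to single atoms the RTB
spectrum converges to the full one.

A connected 3-D elastic network always has exactly six zero modes (rigid
translations and rotations); more indicate that a group of atoms sits
farther than the cutoff radius from the rest.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .enm import HessianMatrix, KirchhoffMatrix
from .modes import ModeSet
from .structure_io import Structure

__all__ = [
    "BlockPartition",
    "diagonalize_full",
    "make_blocks",
    "reorder_for_domains",
    "diagonalize_rtb",
    "zero_mode_report",
    "rtb_projection",
    "read_domain_file",
]

ZERO_MODE_TOL = 1e-9  # relative to the largest eigenvalue scale

DISCONNECT_WARNING = (
    "more than the expected number of near-zero modes: a group of atoms "
    "lies farther than the cutoff radius from the rest of the network"
)


@dataclass
class BlockPartition:
    """Atom-to-rigid-block assignment for the RTB projection."""

    assignment: np.ndarray  # per-atom block id, 0-based
    scheme: str = "n_residues"
    blocks_contiguous: bool = True

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        ids = np.unique(self.assignment)
        if ids.size == 0:
            raise ValueError("empty partition")
        # relabel to dense 0..B-1 preserving order of first appearance
        first = {}
        for b in self.assignment:
            if b not in first:
                first[b] = len(first)
        self.assignment = np.array([first[b] for b in self.assignment])

    @property
    def n_blocks(self) -> int:
        return int(self.assignment.max()) + 1

    def block_atoms(self, b: int) -> np.ndarray:
        return np.nonzero(self.assignment == b)[0]


# ----------------------------------------------------------------------
# Full diagonalization (DIAGSTD)
# ----------------------------------------------------------------------

def _as_array(matrix):
    if isinstance(matrix, (HessianMatrix, KirchhoffMatrix)):
        return matrix.array, matrix.kind, matrix.weighting
    arr = np.asarray(matrix, dtype=float)
    return arr, "nma", "unit"


def _count_zero_modes(eigenvalues: np.ndarray, scale: float) -> int:
    return int(np.sum(np.abs(eigenvalues) < ZERO_MODE_TOL * max(scale, 1e-300)))


def diagonalize_full(matrix, n_modes: int | None = None) -> ModeSet:
    """Solve the full symmetric eigenproblem; eigenvalues ascending.

    ``n_modes`` limits the solve to the lowest modes; by default all modes
    are returned for systems up to 1000 sites, the lowest 106 beyond that.
    Near-zero eigenvalues (below 1e-9 of the spectral scale) are counted;
    more than 6 for an elastic network (1 for a GNM) attaches the
    disconnection warning.
    """
    arr, kind, weighting = _as_array(matrix)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(arr, arr.T, rtol=0, atol=1e-8 * max(np.abs(arr).max(), 1e-300)):
        raise ValueError("matrix is not symmetric")
    dim = arr.shape[0]
    sites = dim if kind == "gnm" else dim // 3
    if n_modes is None:
        n_modes = dim if sites <= 1000 else min(dim, 106)
    n_modes = min(n_modes, dim)

    if n_modes == dim:
        lam, vec = scipy.linalg.eigh(arr)
    else:
        lam, vec = scipy.linalg.eigh(arr, subset_by_index=[0, n_modes - 1])

    scale = np.abs(arr).sum(axis=1).max()  # ≥ spectral radius
    n_zero = _count_zero_modes(lam, scale)
    warns = []
    expected = 1 if kind == "gnm" else 6
    if n_zero > expected:
        warns.append(DISCONNECT_WARNING)
        _warnings.warn(DISCONNECT_WARNING)
    elif n_zero < expected and n_modes == dim:
        msg = (f"only {n_zero} near-zero modes (expected {expected}): "
               f"degenerate geometry")
        warns.append(msg)
        _warnings.warn(msg)
    return ModeSet(lam, vec, kind=kind, weighting=weighting,
                   n_zero_modes=n_zero, warnings=warns)


# ----------------------------------------------------------------------
# Blocking (DIAGRTB schemes + DOMAINS)
# ----------------------------------------------------------------------

def read_domain_file(path) -> list:
    """Parse domain definitions: lines ``chain start_res end_res block_id``."""
    domains = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks or toks[0].startswith("#"):
                continue
            if len(toks) != 4:
                raise ValueError(
                    f"line {lineno}: expected 'chain start_res end_res block_id'")
            domains.append((toks[0], int(toks[1]), int(toks[2]), toks[3]))
    return domains


def make_blocks(structure: Structure, scheme: str, n_residues: int = 1,
                ss_string: str | None = None, domains=None) -> BlockPartition:
    """Assign every atom to a rigid block.

    ``n_residues``: consecutive runs of n residues per chain (last block of a
    chain may be short).  ``secondary_structure``: each contiguous
    helix/sheet element is one block and each intervening coil stretch one
    block, using the structure's HELIX/SHEET records or a one-letter-per-
    residue string (H/E = structured, anything else coil).
    ``custom_domains``: residue ranges from :func:`read_domain_file`;
    residues in no domain become singleton blocks with a warning.  Domain
    blocks may be non-contiguous in atom order — see
    :func:`reorder_for_domains`.
    """
    res_idx = structure.residue_index()
    res_keys = structure.residue_keys()
    n_res = len(res_keys)

    if scheme == "n_residues":
        if n_residues < 1:
            raise ValueError("n_residues must be ≥ 1")
        block_of_res = np.empty(n_res, dtype=int)
        next_block, count, prev_chain = -1, 0, None
        for r, (chain, _, _) in enumerate(res_keys):
            if chain != prev_chain or count == n_residues:
                next_block += 1
                count = 0
                prev_chain = chain
            block_of_res[r] = next_block
            count += 1
        contiguous = True

    elif scheme == "secondary_structure":
        if ss_string is not None:
            if len(ss_string) != n_res:
                raise ValueError("secondary-structure string length ≠ residue count")
            # distinguish separate elements of the same type by run index
            labels = []
            run = 0
            prev = None
            for c in ss_string:
                c = c.upper() if c.upper() in "HE" else "C"
                if c != prev:
                    run += 1
                    prev = c
                labels.append((c, run))
        else:
            element_of = {}
            for eid, (sskind, chain, start, end) in enumerate(structure.ss_elements):
                for r, (rchain, rseq, _) in enumerate(res_keys):
                    if rchain == chain and start <= rseq <= end:
                        element_of[r] = eid
            labels = []
            run, prev = 0, ("?", None)
            for r in range(n_res):
                tag = ("S", element_of[r]) if r in element_of else ("C", None)
                labels.append(tag)
            # split coil stretches into separate runs between elements
            out, run, prev = [], 0, object()
            for tag in labels:
                if tag != prev:
                    run += 1
                    prev = tag
                out.append((tag, run))
            labels = out
        block_of_res = np.empty(n_res, dtype=int)
        seen = {}
        for r, lab in enumerate(labels):
            if lab not in seen:
                seen[lab] = len(seen)
            block_of_res[r] = seen[lab]
        contiguous = True

    elif scheme == "custom_domains":
        if domains is None:
            raise ValueError("custom_domains scheme requires domain definitions")
        block_of_res = np.full(n_res, -1, dtype=int)
        block_ids = {}
        for (chain, start, end, bid) in domains:
            if bid not in block_ids:
                block_ids[bid] = len(block_ids)
            for r, (rchain, rseq, _) in enumerate(res_keys):
                if rchain == chain and start <= rseq <= end:
                    block_of_res[r] = block_ids[bid]
        next_free = len(block_ids)
        for r in range(n_res):
            if block_of_res[r] < 0:
                chain, rseq, _ = res_keys[r]
                _warnings.warn(
                    f"residue {chain}:{rseq} is in no domain; assigned its "
                    f"own singleton block")
                block_of_res[r] = next_free
                next_free += 1
        assignment = block_of_res[res_idx]
        contiguous = bool(np.all(np.diff(assignment) >= 0))
        return BlockPartition(assignment, scheme=scheme,
                              blocks_contiguous=contiguous)
    else:
        raise ValueError(f"unknown blocking scheme {scheme!r}")

    return BlockPartition(block_of_res[res_idx], scheme=scheme,
                          blocks_contiguous=contiguous)


def reorder_for_domains(structure: Structure, partition: BlockPartition):
    """Reorder atoms so every block is contiguous (DOMAINS behaviour).

    Returns (reordered structure, matching partition).  Stable within
    blocks: atom order inside each block is preserved.
    """
    order = np.argsort(partition.assignment, kind="stable")
    atoms = [structure.atoms[i] for i in order]
    new = Structure(atoms, structure.masses[order], structure.selection,
                    list(structure.ss_elements), list(structure.source_lines))
    part = BlockPartition(partition.assignment[order], scheme=partition.scheme,
                          blocks_contiguous=True)
    return new, part


# ----------------------------------------------------------------------
# RTB projection (DIAGRTB)
# ----------------------------------------------------------------------

def rtb_projection(structure: Structure, partition: BlockPartition) -> np.ndarray:
    """Orthonormal projection P (3N × ≤6B) onto block rigid-body motions.

    Per block: 3 mass-weighted rigid translations and up to 3 rigid
    rotations about the block's centre of mass, orthonormalized by SVD;
    singular rotation directions (single atoms, collinear blocks) are
    dropped at relative tolerance 1e-10.
    """
    if partition.assignment.shape[0] != structure.n_atoms:
        raise ValueError("partition does not cover the structure")
    coords = structure.coords
    masses = structure.masses
    n = structure.n_atoms
    cols = []
    col_rows = []
    for b in range(partition.n_blocks):
        idx = partition.block_atoms(b)
        if idx.size == 0:
            raise ValueError(f"block {b} is empty")
        m = masses[idx]
        total = m.sum()
        if total <= 0:
            raise ValueError(f"block {b} has zero total mass")
        x = coords[idx]
        com = (m[:, None] * x).sum(axis=0) / total
        sqrt_m = np.sqrt(m)
        raw = np.zeros((3 * idx.size, 6))
        for alpha in range(3):
            t = np.zeros((idx.size, 3))
            t[:, alpha] = 1.0
            raw[:, alpha] = (sqrt_m[:, None] * t).reshape(-1)
        rel = x - com
        axes = np.eye(3)
        for alpha in range(3):
            rot = np.cross(axes[alpha], rel)
            raw[:, 3 + alpha] = (sqrt_m[:, None] * rot).reshape(-1)
        u, s, _ = np.linalg.svd(raw, full_matrices=False)
        keep = s > 1e-10 * s[0]
        cols.append(u[:, keep])
        col_rows.append(idx)

    total_cols = sum(c.shape[1] for c in cols)
    p = np.zeros((3 * n, total_cols))
    start = 0
    for idx, c in zip(col_rows, cols):
        rows = (3 * idx[:, None] + np.arange(3)[None, :]).reshape(-1)
        p[rows, start:start + c.shape[1]] = c
        start += c.shape[1]
    return p


def diagonalize_rtb(hessian: HessianMatrix, structure: Structure,
                    partition: BlockPartition, n_modes: int | None = None
                    ) -> ModeSet:
    """Solve the RTB-projected eigenproblem PᵀDP and expand back to 3N.

    Eigenvalues are those of the projected problem (variational upper bounds
    on the full spectrum); expanded eigenvectors are renormalized and remain
    orthonormal because P has orthonormal columns.
    """
    arr = hessian.array
    p = rtb_projection(structure, partition)
    hp = p.T @ arr @ p
    hp = 0.5 * (hp + hp.T)
    dim = hp.shape[0]
    if n_modes is None or n_modes >= dim:
        lam, v = scipy.linalg.eigh(hp)
    else:
        lam, v = scipy.linalg.eigh(hp, subset_by_index=[0, n_modes - 1])
    expanded = p @ v
    norms = np.linalg.norm(expanded, axis=0)
    expanded = expanded / np.where(norms > 0, norms, 1.0)

    scale = np.abs(arr).sum(axis=1).max()
    n_zero = _count_zero_modes(lam, scale)
    warns = []
    if n_zero > 6:
        warns.append(DISCONNECT_WARNING)
        _warnings.warn(DISCONNECT_WARNING)
    return ModeSet(lam, expanded, kind="nma", weighting=hessian.weighting,
                   n_zero_modes=n_zero, warnings=warns)


# ----------------------------------------------------------------------
# Zero-mode diagnostic
# ----------------------------------------------------------------------

def zero_mode_report(modes: ModeSet) -> dict:
    """Check the near-zero mode count against the connected-network
    expectation: 6 for a 3-D elastic network, 1 for a GNM."""
    if modes.kind not in ("nma", "gnm"):
        raise ValueError("zero-mode diagnostic applies to nma/gnm modes")
    expected = 1 if modes.kind == "gnm" else 6
    verdict = "ok" if modes.n_zero_modes <= expected else "disconnected"
    return {
        "n_zero_modes": modes.n_zero_modes,
        "expected": expected,
        "verdict": verdict,
    }
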