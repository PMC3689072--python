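"""Structure and trajectory I/O, atom selection, and format conversion.

Reads fixed-column PDB files (ATOM/HETATM/MODEL/ENDMDL plus HELIX/SHEET
records for secondary-structure blocking), plain-text trajectory dumps
(multi-model PDB, Amber ASCII mdcrd-style, DL_POLY HISTORY-style, GRO
series), and the package's own text eigenfile and NMWiz ``.nmd`` formats.

Atom selection mirrors the conventions of coarse-grained elastic-network
modelling: Cα-only reduction (optionally keeping C4'/C1' sites of nucleic
acids), HETATM inclusion on request, hydrogen and alternate-conformer
removal, and three mass conventions (unit mass, true atomic masses, or
whole-residue masses placed on the Cα site).
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .modes import ModeSet

__all__ = [
    "AtomRecord",
    "SelectionSpec",
    "Structure",
    "Trajectory",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "fix_periodic_and_write_pdb",
    "reduce_full_to_ca",
    "write_nmd",
    "read_nmd",
    "paint_values_onto_pdb",
    "write_modes",
    "read_modes",
]

# Average atomic masses (Da) keyed on the PDB element column.
ELEMENT_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
    "MG": 24.305, "CA": 40.078, "MN": 54.938, "CU": 63.546, "NA": 22.990,
    "K": 39.098, "CL": 35.45, "F": 18.998, "BR": 79.904, "I": 126.904,
}
DEFAULT_ATOMIC_MASS = 12.011

# Average amino-acid residue masses (Da, residue = amino acid − H2O),
# assigned to the Cα site under the residue-mass convention.
RESIDUE_MASSES = {
    "GLY": 57.05, "ALA": 71.08, "SER": 87.08, "PRO": 97.12, "VAL": 99.13,
    "THR": 101.10, "CYS": 103.14, "LEU": 113.16, "ILE": 113.16, "ASN": 114.10,
    "ASP": 115.09, "GLN": 128.13, "LYS": 128.17, "GLU": 129.12, "MET": 131.19,
    "HIS": 137.14, "PHE": 147.18, "ARG": 156.19, "TYR": 163.18, "TRP": 186.21,
    # nucleotides (for DNA-mode Cα-equivalent sites)
    "DA": 313.21, "DC": 289.18, "DG": 329.21, "DT": 304.20,
    "A": 329.21, "C": 305.18, "G": 345.21, "U": 306.17,
}
DEFAULT_RESIDUE_MASS = 110.0

_DNA_CA_NAMES = {"C4'", "C1'", "C4*", "C1*"}


@dataclass
class AtomRecord:
    """One ATOM/HETATM record; coordinates in Å, B-factor in Å²."""

    serial: int
    name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    insertion_code: str
    coord: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    element: str = ""
    is_hetatm: bool = False
    line_index: int | None = None  # index into Structure.source_lines

    def residue_key(self):
        return (self.chain_id, self.res_seq, self.insertion_code)


@dataclass
class SelectionSpec:
    """Which atoms to keep and how to assign masses.

    ``mass_mode="residue"`` is only meaningful together with ``ca_only``
    (one site per residue carries the whole residue mass).
    """

    ca_only: bool = False
    include_hetatm: bool = False
    dna_mode: bool = False
    drop_hydrogens: bool = True
    drop_alt_locs: bool = True
    mass_mode: str = "unit"  # unit | atomic | residue

    def __post_init__(self):
        if self.mass_mode not in ("unit", "atomic", "residue"):
            raise ValueError(f"unknown mass_mode {self.mass_mode!r}")
        if self.mass_mode == "residue" and not self.ca_only:
            raise ValueError("residue mass_mode requires ca_only selection")


@dataclass
class Structure:
    """Ordered atom list with per-atom masses.

    Atom order is stable and defines the index ``i`` used in every downstream
    matrix.  ``ss_elements`` holds (kind, chain, first_res, last_res) tuples
    parsed from HELIX ('H') and SHEET ('E') records.
    """

    atoms: list
    masses: np.ndarray
    selection: SelectionSpec | None = None
    ss_elements: list = field(default_factory=list)
    source_lines: list = field(default_factory=list)

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.atoms) != self.masses.shape[0]:
            raise ValueError("atom/mass count mismatch")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def is_ca(self) -> np.ndarray:
        names = [a.name.strip() for a in self.atoms]
        return np.array(
            [n == "CA" or n in _DNA_CA_NAMES for n in names], dtype=bool
        )

    def residue_index(self) -> np.ndarray:
        """Per-atom index of the residue (in order of first appearance)."""
        seen = {}
        idx = np.empty(self.n_atoms, dtype=int)
        for i, a in enumerate(self.atoms):
            key = a.residue_key()
            if key not in seen:
                seen[key] = len(seen)
            idx[i] = seen[key]
        return idx

    def residue_keys(self) -> list:
        out, seen = [], set()
        for a in self.atoms:
            key = a.residue_key()
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        atoms = [replace(a, coord=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms, self.masses.copy(), self.selection,
                         list(self.ss_elements), list(self.source_lines))


# ----------------------------------------------------------------------
# PDB reading
# ----------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    line = line.rstrip("\n")
    if len(line) < 54:
        raise ValueError(f"line {lineno}: ATOM record too short to hold coordinates")
    padded = line.ljust(80)
    try:
        serial = int(padded[6:11])
        x = float(padded[30:38])
        y = float(padded[38:46])
        z = float(padded[46:54])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparseable ATOM record: {exc}") from None
    occ_s, b_s = padded[54:60].strip(), padded[60:66].strip()
    res_seq_s = padded[22:26].strip()
    try:
        res_seq = int(res_seq_s) if res_seq_s else 0
        occupancy = float(occ_s) if occ_s else 1.0
        b_factor = float(b_s) if b_s else 0.0
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparseable ATOM record: {exc}") from None
    coord = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(coord)):
        raise ValueError(f"line {lineno}: non-finite coordinate")
    return AtomRecord(
        serial=serial,
        name=padded[12:16].strip(),
        alt_loc=padded[16],
        res_name=padded[17:20].strip(),
        chain_id=padded[21],
        res_seq=res_seq,
        insertion_code=padded[26],
        coord=coord,
        occupancy=occupancy,
        b_factor=b_factor,
        element=padded[76:78].strip().upper(),
        is_hetatm=padded.startswith("HETATM"),
        line_index=lineno - 1,
    )


def _is_hydrogen(atom: AtomRecord) -> bool:
    if atom.element in ("H", "D"):
        return True
    if atom.element:
        return False
    name = atom.name.strip().lstrip("0123456789")
    return name[:1] in ("H", "D")


def _element_of(atom: AtomRecord) -> str:
    if atom.element:
        return atom.element
    name = atom.name.strip().lstrip("0123456789")
    return name[:1].upper()


def _assign_masses(atoms: list, mass_mode: str) -> np.ndarray:
    if mass_mode == "unit":
        return np.ones(len(atoms))
    if mass_mode == "atomic":
        return np.array(
            [ELEMENT_MASSES.get(_element_of(a), DEFAULT_ATOMIC_MASS) for a in atoms]
        )
    # residue: whole residue mass on the Cα (or nucleic C4'/C1') site
    return np.array(
        [RESIDUE_MASSES.get(a.res_name, DEFAULT_RESIDUE_MASS) for a in atoms]
    )


def read_pdb(path, spec: SelectionSpec | None = None) -> Structure:
    """Read a PDB file, apply the selection, assign masses.

    HETATM records are kept only with ``spec.include_hetatm``; hydrogens and
    alternate conformers (all but the first-listed location of each atom) are
    dropped by default; ``spec.ca_only`` keeps CA atoms (plus C4'/C1' under
    ``dna_mode``).  Raises ``ValueError("no atoms selected")`` if nothing
    survives.
    """
    spec = spec or SelectionSpec()
    with open(path) as fh:
        lines = fh.read().splitlines()

    atoms, ss_elements = [], []
    seen_alt = set()
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec == "HELIX ":
            try:
                ss_elements.append(("H", line[19], int(line[21:25]), int(line[33:37])))
            except (ValueError, IndexError):
                pass
            continue
        if rec == "SHEET ":
            try:
                ss_elements.append(("E", line[21], int(line[22:26]), int(line[33:37])))
            except (ValueError, IndexError):
                pass
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        atom = _parse_atom_line(line, lineno)
        if atom.is_hetatm and not spec.include_hetatm:
            continue
        if spec.drop_hydrogens and _is_hydrogen(atom):
            continue
        if spec.drop_alt_locs:
            key = (atom.chain_id, atom.res_seq, atom.insertion_code, atom.name)
            if key in seen_alt:
                continue
            seen_alt.add(key)
        if spec.ca_only:
            name = atom.name.strip()
            keep = name == "CA" or (spec.dna_mode and name in _DNA_CA_NAMES)
            if not keep:
                continue
        atoms.append(atom)

    if not atoms:
        raise ValueError("no atoms selected")
    return Structure(
        atoms=atoms,
        masses=_assign_masses(atoms, spec.mass_mode),
        selection=spec,
        ss_elements=ss_elements,
        source_lines=lines,
    )


# ----------------------------------------------------------------------
# PDB writing
# ----------------------------------------------------------------------

def format_atom_line(atom: AtomRecord, coord=None, b_factor=None) -> str:
    coord = atom.coord if coord is None else coord
    b = atom.b_factor if b_factor is None else b_factor
    name = atom.name.strip()
    if len(name) < 4 and not name[:1].isdigit():
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    record = "HETATM" if atom.is_hetatm else "ATOM  "
    return (
        f"{record}{atom.serial:5d} {name_field}{atom.alt_loc}{atom.res_name:>3s} "
        f"{atom.chain_id}{atom.res_seq:4d}{atom.insertion_code}   "
        f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
        f"{atom.occupancy:6.2f}{b:6.2f}          {atom.element:>2s}"
    )


def write_pdb(structure: Structure, path, coords=None) -> None:
    """Write the structure's atoms as ATOM/HETATM records."""
    coords = structure.coords if coords is None else np.asarray(coords).reshape(-1, 3)
    with open(path, "w") as fh:
        for i, atom in enumerate(structure.atoms):
            fh.write(format_atom_line(atom, coords[i]) + "\n")
        fh.write("END\n")


def write_multi_model_pdb(structure: Structure, frames, path) -> int:
    """Write frames as a MODEL/ENDMDL multi-model PDB; returns frame count."""
    n = 0
    with open(path, "w") as fh:
        for k, frame in enumerate(frames, start=1):
            fh.write(f"MODEL     {k:4d}\n")
            frame = np.asarray(frame).reshape(-1, 3)
            for i, atom in enumerate(structure.atoms):
                fh.write(format_atom_line(atom, frame[i]) + "\n")
            fh.write("ENDMDL\n")
            n += 1
        fh.write("END\n")
    return n


# ----------------------------------------------------------------------
# Trajectories
# ----------------------------------------------------------------------

@dataclass
class Trajectory:
    """Frame coordinates in Å, shape (n_frames, n_atoms, 3)."""

    frames: np.ndarray
    frame_times: np.ndarray | None = None
    source_format: str = "generated"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


TRAJ_FORMATS = ("multi_model_pdb", "amber_ascii", "dlpoly_history", "gro_series")


def read_trajectory(path, format: str, atom_count: int | None = None) -> Trajectory:
    """Read a trajectory in one of the plain-text dialects.

    ``atom_count`` is required for ``amber_ascii`` (the format carries no
    atom count) and is validated against the file for the others.  A
    truncated final frame is dropped with a warning; an atom-count mismatch
    raises.
    """
    if format not in TRAJ_FORMATS:
        raise ValueError(f"unknown trajectory format {format!r}")
    reader = {
        "multi_model_pdb": _read_multi_model_pdb,
        "amber_ascii": _read_amber_ascii,
        "dlpoly_history": _read_dlpoly_history,
        "gro_series": _read_gro_series,
    }[format]
    traj = reader(path, atom_count)
    if atom_count is not None and traj.n_atoms != atom_count:
        raise ValueError(
            f"atom-count mismatch: expected {atom_count}, file has {traj.n_atoms}"
        )
    return traj


def _read_multi_model_pdb(path, atom_count) -> Trajectory:
    frames, current = [], []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model, current = True, []
            elif rec == "ENDMDL":
                frames.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                current.append(atom.coord)
                if not in_model and not frames:
                    in_model = None  # single implicit model
    if in_model is None and current:
        frames.append(current)
    elif in_model is True and current:
        _warnings.warn("dropping truncated final MODEL")
    if not frames:
        raise ValueError("no frames found in multi-model PDB")
    counts = {len(f) for f in frames}
    if len(counts) != 1:
        raise ValueError(f"inconsistent atom counts across models: {sorted(counts)}")
    return Trajectory(np.array(frames), source_format="multi_model_pdb")


def _read_amber_ascii(path, atom_count) -> Trajectory:
    if atom_count is None:
        raise ValueError("amber_ascii requires atom_count")
    values = []
    with open(path) as fh:
        fh.readline()  # title
        for line in fh:
            line = line.rstrip("\n")
            for start in range(0, len(line), 8):
                tok = line[start:start + 8].strip()
                if tok:
                    values.append(float(tok))
    per_frame = 3 * atom_count
    n_frames, leftover = divmod(len(values), per_frame)
    if leftover:
        _warnings.warn(f"dropping truncated final frame ({leftover} stray values)")
    if n_frames == 0:
        raise ValueError("no complete frames in amber_ascii file")
    arr = np.array(values[: n_frames * per_frame]).reshape(n_frames, atom_count, 3)
    return Trajectory(arr, source_format="amber_ascii")


def _read_dlpoly_history(path, atom_count) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ValueError("HISTORY file too short")
    frames, times = [], []
    i = 2  # skip title + levcfg/imcon/natms header
    while i < len(lines):
        if not lines[i].startswith("timestep"):
            i += 1
            continue
        toks = lines[i].split()
        natms = int(toks[2])
        imcon = int(toks[4]) if len(toks) > 4 else 0
        tstep = float(toks[5]) if len(toks) > 5 else 0.0
        nstep = int(toks[1])
        i += 1
        if imcon > 0:
            i += 3  # cell vectors
        need = 2 * natms
        if i + need > len(lines):
            _warnings.warn("dropping truncated final frame in HISTORY file")
            break
        frame = np.empty((natms, 3))
        for a in range(natms):
            frame[a] = [float(v) for v in lines[i + 2 * a + 1].split()[:3]]
        frames.append(frame)
        times.append(nstep * tstep)
        i += need
    if not frames:
        raise ValueError("no frames found in HISTORY file")
    return Trajectory(np.array(frames), frame_times=np.array(times),
                      source_format="dlpoly_history")


def _read_gro_series(path, atom_count) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames, times = [], []
    i = 0
    while i < len(lines):
        title = lines[i]
        if i + 1 >= len(lines):
            break
        try:
            natms = int(lines[i + 1].strip())
        except ValueError:
            break
        if i + 2 + natms + 1 > len(lines):
            _warnings.warn("dropping truncated final frame in GRO series")
            break
        frame = np.empty((natms, 3))
        for a in range(natms):
            ln = lines[i + 2 + a]
            # columns 21-44: three %8.3f fields in nm → Å
            frame[a] = [float(ln[20:28]) * 10.0, float(ln[28:36]) * 10.0,
                        float(ln[36:44]) * 10.0]
        frames.append(frame)
        if "t=" in title:
            try:
                times.append(float(title.split("t=")[1].split()[0]))
            except (ValueError, IndexError):
                times.append(float(len(times)))
        else:
            times.append(float(len(times)))
        i += 2 + natms + 1  # title, count, atoms, box line
    if not frames:
        raise ValueError("no frames found in GRO series")
    return Trajectory(np.array(frames), frame_times=np.array(times),
                      source_format="gro_series")


def write_trajectory(traj: Trajectory, path, format: str,
                     structure: Structure | None = None) -> None:
    """Write a trajectory in any of the supported text dialects."""
    if format == "multi_model_pdb":
        struct = structure or synthetic_ca_structure(traj.n_atoms)
        write_multi_model_pdb(struct, traj.frames, path)
    elif format == "amber_ascii":
        with open(path, "w") as fh:
            fh.write("modekit trajectory\n")
            for frame in traj.frames:
                flat = frame.reshape(-1)
                for start in range(0, flat.size, 10):
                    fh.write("".join(f"{v:8.3f}" for v in flat[start:start + 10]) + "\n")
    elif format == "dlpoly_history":
        with open(path, "w") as fh:
            fh.write("modekit trajectory\n")
            fh.write(f"{0:10d}{0:10d}{traj.n_atoms:10d}\n")
            for k, frame in enumerate(traj.frames, start=1):
                fh.write(f"timestep {k:9d} {traj.n_atoms:9d} {0:9d} {0:9d} {0.0:11.6f}\n")
                for a in range(traj.n_atoms):
                    fh.write(f"X{a + 1:<7d} {a + 1:9d} {1.0:11.6f} {0.0:11.6f}\n")
                    x, y, z = frame[a]
                    fh.write(f"{x:16.8f}{y:16.8f}{z:16.8f}\n")
    elif format == "gro_series":
        struct = structure
        with open(path, "w") as fh:
            for k, frame in enumerate(traj.frames):
                t = traj.frame_times[k] if traj.frame_times is not None else float(k)
                fh.write(f"modekit frame t= {t:.4f}\n")
                fh.write(f"{traj.n_atoms:5d}\n")
                for a in range(traj.n_atoms):
                    if struct is not None:
                        atom = struct.atoms[a]
                        resid, resname, name = atom.res_seq, atom.res_name, atom.name
                    else:
                        resid, resname, name = a + 1, "UNK", "CA"
                    x, y, z = frame[a] / 10.0  # Å → nm
                    fh.write(f"{resid:5d}{resname:<5s}{name:>5s}{a + 1:5d}"
                             f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
                fh.write(f"{0.0:10.5f}{0.0:10.5f}{0.0:10.5f}\n")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def synthetic_ca_structure(n_atoms: int, coords=None) -> Structure:
    """Minimal one-CA-per-residue structure used when only coordinates exist."""
    coords = np.zeros((n_atoms, 3)) if coords is None else np.asarray(coords)
    atoms = [
        AtomRecord(serial=i + 1, name="CA", alt_loc=" ", res_name="GLY",
                   chain_id="A", res_seq=i + 1, insertion_code=" ",
                   coord=coords[i].astype(float), element="C")
        for i in range(n_atoms)
    ]
    return Structure(atoms, np.ones(n_atoms))


# ----------------------------------------------------------------------
# Periodic-boundary fixing (TRAJPDB)
# ----------------------------------------------------------------------

def fix_periodic_and_write_pdb(traj: Trajectory, reference: Structure, out_path,
                               box=None) -> int:
    """Unwrap periodic-image jumps and write a multi-model PDB.

    Each atom is shifted by integer box multiples to the image nearest its
    position in the previous frame (first frame: nearest the reference
    structure).  A jump of exactly half a box length is resolved toward no
    shift.  ``box`` is a length-3 array of box edges in Å, or an
    (n_frames, 3) array; it must be supplied.
    Returns the number of frames written.
    """
    if box is None:
        raise ValueError("box dimensions required to fix periodic images")
    box = np.asarray(box, dtype=float)
    if box.ndim == 1:
        box = np.broadcast_to(box, (traj.n_frames, 3))
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    if reference.n_atoms != traj.n_atoms:
        raise ValueError("reference/trajectory atom-count mismatch")

    fixed = np.empty_like(traj.frames)
    prev = reference.coords
    for t in range(traj.n_frames):
        q = (prev - traj.frames[t]) / box[t]
        # nearest image; exact half-box ties resolved toward zero shift
        n = np.sign(q) * np.ceil(np.abs(q) - 0.5)
        fixed[t] = traj.frames[t] + n * box[t]
        prev = fixed[t]
    return write_multi_model_pdb(reference, fixed, out_path)


# ----------------------------------------------------------------------
# Full → Cα reduction (FULL2CA)
# ----------------------------------------------------------------------

def reduce_full_to_ca(modes_or_struct, structure_full: Structure):
    """Keep only the Cα rows of a ModeSet (or the Cα atoms of a Structure).

    Eigenvector components are extracted in order and NOT renormalized;
    renormalization, where wanted, is a separate explicit step.
    """
    mask = structure_full.is_ca
    if not mask.any():
        raise ValueError("structure contains no CA atoms")
    if isinstance(modes_or_struct, Structure):
        s = modes_or_struct
        atoms = [a for a, keep in zip(s.atoms, mask) if keep]
        return Structure(atoms, s.masses[mask], s.selection,
                         list(s.ss_elements), list(s.source_lines))
    modes: ModeSet = modes_or_struct
    if modes.kind == "gnm":
        vecs = modes.eigenvectors[mask, :]
    else:
        if modes.dim != 3 * structure_full.n_atoms:
            raise ValueError("mode dimension does not match full structure")
        row_mask = np.repeat(mask, 3)
        vecs = modes.eigenvectors[row_mask, :]
    return ModeSet(modes.eigenvalues.copy(), vecs, kind=modes.kind,
                   weighting=modes.weighting, n_zero_modes=modes.n_zero_modes,
                   warnings=list(modes.warnings))


# ----------------------------------------------------------------------
# NMWiz .nmd (NMWIZWT)
# ----------------------------------------------------------------------

def write_nmd(structure: Structure, modes: ModeSet, out_path) -> None:
    """Write modes in the NMWiz ``.nmd`` text format.

    The per-mode scale is the RMS atomic amplitude of the (unit-norm)
    eigenvector, √(Σ_i e_i²/N).
    """
    if modes.kind == "gnm":
        raise ValueError("nmd output requires 3-D (nma/pca) modes")
    if modes.dim != 3 * structure.n_atoms:
        raise ValueError("mode/structure dimension mismatch")
    n = structure.n_atoms
    with open(out_path, "w") as fh:
        fh.write("title modekit modes\n")
        fh.write("names " + " ".join(a.name.strip() for a in structure.atoms) + "\n")
        fh.write("resnames " + " ".join(a.res_name for a in structure.atoms) + "\n")
        fh.write("resids " + " ".join(str(a.res_seq) for a in structure.atoms) + "\n")
        fh.write("chainids " + " ".join(a.chain_id if a.chain_id.strip() else "A"
                                        for a in structure.atoms) + "\n")
        flat = structure.coords.reshape(-1)
        fh.write("coordinates " + " ".join(f"{v:.3f}" for v in flat) + "\n")
        for v in range(modes.n_modes):
            e = modes.eigenvectors[:, v]
            scale = math.sqrt(float(e @ e) / n)
            comps = " ".join(f"{c:.17g}" for c in e)
            fh.write(f"mode {v + 1} {scale:.17g} {comps}\n")


def read_nmd(path):
    """Parse an ``.nmd`` file; returns (coordinates, [(index, scale, components)])."""
    coords, mode_list = None, []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if not toks:
                continue
            if toks[0] == "coordinates":
                coords = np.array([float(v) for v in toks[1:]])
            elif toks[0] == "mode":
                idx = int(toks[1])
                scale = float(toks[2])
                comps = np.array([float(v) for v in toks[3:]])
                mode_list.append((idx, scale, comps))
    return coords, mode_list


# ----------------------------------------------------------------------
# Painting values into the B-factor column (PLOTPDB)
# ----------------------------------------------------------------------

def paint_values_onto_pdb(structure: Structure, values, out_path) -> None:
    """Write per-residue (or per-atom) values into the B-factor column.

    All bytes outside columns 61-66 of the painted ATOM lines are identical
    to the input file (the structure must have been read from a PDB file).
    Values overflowing the 6-column field are clamped with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] == structure.n_atoms:
        per_atom = values
    elif values.shape[0] == structure.n_residues:
        per_atom = values[structure.residue_index()]
    else:
        raise ValueError(
            f"need {structure.n_atoms} per-atom or {structure.n_residues} "
            f"per-residue values, got {values.shape[0]}"
        )
    if not structure.source_lines:
        # structure built in memory: synthesize canonical lines first
        lines = [format_atom_line(a) for a in structure.atoms]
        line_of_atom = list(range(len(lines)))
    else:
        lines = list(structure.source_lines)
        line_of_atom = [a.line_index for a in structure.atoms]

    lo, hi = -99.99, 999.99
    clamped = np.clip(per_atom, lo, hi)
    if np.any(clamped != per_atom):
        _warnings.warn("values clamped to fit the 6-column B-factor field")
    for i, li in enumerate(line_of_atom):
        line = lines[li].ljust(66)
        lines[li] = line[:60] + f"{clamped[i]:6.2f}" + line[66:]
    with open(out_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Package eigenfile
# ----------------------------------------------------------------------

def write_modes(modes: ModeSet, path) -> None:
    """Write a ModeSet in the package text eigenfile format.

    Header ``nmodes N natoms M weighting <w>``; then per mode a line
    ``mode <v> eigenvalue <λ>`` followed by the components, one per line,
    printed at 17 significant digits (bit-exact float64 round-trip).
    """
    with open(path, "w") as fh:
        fh.write(f"nmodes {modes.n_modes} natoms {modes.n_atoms} "
                 f"weighting {modes.weighting}\n")
        for v in range(modes.n_modes):
            fh.write(f"mode {v + 1} eigenvalue {modes.eigenvalues[v]:.17g}\n")
            for c in modes.eigenvectors[:, v]:
                fh.write(f"{c:.17g}\n")


def read_modes(path, kind: str | None = None) -> ModeSet:
    """Read an eigenfile.  ``kind`` defaults to gnm when components-per-mode
    equals natoms, nma otherwise; pass ``kind="pca"`` for covariance modes."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 6 or header[0] != "nmodes" or header[2] != "natoms":
            raise ValueError("malformed eigenfile header")
        n_modes, n_atoms = int(header[1]), int(header[3])
        weighting = header[5]
        eigenvalues, columns = [], []
        current = None
        for line in fh:
            toks = line.split()
            if not toks:
                continue
            if toks[0] == "mode":
                eigenvalues.append(float(toks[3]))
                current = []
                columns.append(current)
            else:
                current.extend(float(v) for v in toks)
    if len(eigenvalues) != n_modes:
        raise ValueError(f"expected {n_modes} modes, found {len(eigenvalues)}")
    lengths = {len(c) for c in columns}
    if len(lengths) != 1:
        raise ValueError("inconsistent component counts across modes")
    dim = lengths.pop()
    if kind is None:
        kind = "gnm" if dim == n_atoms else "nma"
    if kind == "gnm" and dim != n_atoms:
        raise ValueError("gnm eigenfile must have natoms components per mode")
    if kind in ("nma", "pca") and dim != 3 * n_atoms:
        raise ValueError("nma/pca eigenfile must have 3·natoms components per mode")
    vecs = np.array(columns).T
    lam = np.array(eigenvalues)
    n_zero = 0
    if kind in ("nma", "gnm") and lam.size:
        n_zero = int(np.sum(lam < 1e-9 * max(lam.max(), 1e-300)))
    return ModeSet(lam, vecs, kind=kind, weighting=weighting, n_zero_modes=n_zero)
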