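import numpy as np
import pytest

from modekit import (ModeSet, SelectionSpec, Trajectory, read_modes, read_pdb,
                     read_trajectory, reduce_full_to_ca, write_modes,
                     write_pdb, write_trajectory)
from modekit.structure_io import (fix_periodic_and_write_pdb,
                                  paint_values_onto_pdb, read_nmd,
                                  synthetic_ca_structure, write_nmd)

from conftest import BAD_PDB, ONE_RESIDUE_PDB


# ----------------------------------------------------------------------
# PDB reading and selection
# ----------------------------------------------------------------------

class TestSelection:
    def test_ca_only_keeps_single_site_with_unit_mass(self, tmp_path):
        p = tmp_path / "res.pdb"
        p.write_text(ONE_RESIDUE_PDB)
        s = read_pdb(p, SelectionSpec(ca_only=True))
        assert s.n_atoms == 1
        assert s.atoms[0].name == "CA"
        assert s.masses[0] == 1.0

    @pytest.mark.parametrize("include,expected", [(False, False), (True, True)])
    def test_hetatm_flag_controls_ligand(self, mixed_pdb, include, expected):
        s = read_pdb(mixed_pdb, SelectionSpec(include_hetatm=include))
        has_ligand = any(a.is_hetatm for a in s.atoms)
        assert has_ligand is expected

    def test_alternate_conformers_keep_first_listed(self, mixed_pdb):
        s = read_pdb(mixed_pdb, SelectionSpec(ca_only=True))
        cas = [a for a in s.atoms if a.res_seq == 1]
        assert len(cas) == 1
        assert cas[0].alt_loc == "A"  # first-listed location survives

    def test_hydrogens_dropped_by_default(self, mixed_pdb):
        s = read_pdb(mixed_pdb)
        assert all(a.element != "H" for a in s.atoms)
        s_h = read_pdb(mixed_pdb, SelectionSpec(drop_hydrogens=False))
        assert s_h.n_atoms == s.n_atoms + 1

    def test_atomic_and_residue_masses(self, mixed_pdb):
        s = read_pdb(mixed_pdb, SelectionSpec(mass_mode="atomic"))
        by_name = {a.name: m for a, m in zip(s.atoms, s.masses)}
        assert by_name["CA"] == pytest.approx(12.011)
        assert by_name["N"] == pytest.approx(14.007)
        s_res = read_pdb(mixed_pdb, SelectionSpec(ca_only=True, mass_mode="residue"))
        assert s_res.masses[0] == pytest.approx(71.08)   # ALA
        assert s_res.masses[1] == pytest.approx(57.05)   # GLY

    def test_residue_masses_require_ca(self):
        with pytest.raises(ValueError, match="ca_only"):
            SelectionSpec(mass_mode="residue")

    def test_empty_selection_raises(self, tmp_path):
        p = tmp_path / "het_only.pdb"
        p.write_text("HETATM    1 ZN    ZN A 101       5.000   5.000  -5.000"
                     "  1.00 20.00          ZN\n")
        with pytest.raises(ValueError, match="no atoms selected"):
            read_pdb(p)

    def test_unparseable_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(BAD_PDB)
        with pytest.raises(ValueError, match="line 2"):
            read_pdb(p)

    def test_read_write_read_idempotent(self, mixed_pdb, tmp_path):
        s1 = read_pdb(mixed_pdb, SelectionSpec(include_hetatm=True))
        out = tmp_path / "roundtrip.pdb"
        write_pdb(s1, out)
        s2 = read_pdb(out, SelectionSpec(include_hetatm=True))
        assert s1.n_atoms == s2.n_atoms
        for a1, a2 in zip(s1.atoms, s2.atoms):
            assert (a1.name, a1.res_name, a1.chain_id, a1.res_seq) == \
                   (a2.name, a2.res_name, a2.chain_id, a2.res_seq)
            np.testing.assert_allclose(a1.coord, a2.coord, atol=5e-4)


# ----------------------------------------------------------------------
# Trajectories
# ----------------------------------------------------------------------

class TestTrajectory:
    def _toy_traj(self, n_frames=3, n_atoms=2):
        rng = np.random.default_rng(0)
        frames = np.round(rng.uniform(-40, 40, (n_frames, n_atoms, 3)), 3)
        return Trajectory(frames)

    def test_multi_model_frame_counting(self, tmp_path):
        traj = self._toy_traj(3, 2)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path, "multi_model_pdb")
        back = read_trajectory(path, "multi_model_pdb", atom_count=2)
        assert back.n_frames == 3 and back.n_atoms == 2

    def test_gro_stores_angstrom(self, tmp_path):
        path = tmp_path / "t.gro"
        path.write_text("frame t= 0.0\n    1\n    1UNK     CA    1"
                        "   0.100   0.200   0.300\n   0.0   0.0   0.0\n")
        traj = read_trajectory(path, "gro_series", atom_count=1)
        np.testing.assert_allclose(traj.frames[0, 0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("fmt", ["amber_ascii", "dlpoly_history", "gro_series"])
    def test_write_read_write_is_bit_identical(self, tmp_path, fmt):
        traj = self._toy_traj(4, 3)
        p1, p2 = tmp_path / "a", tmp_path / "b"
        write_trajectory(traj, p1, fmt)
        back = read_trajectory(p1, fmt, atom_count=3)
        write_trajectory(back, p2, fmt)
        assert p1.read_bytes() == p2.read_bytes()

    def test_truncated_final_frame_dropped_with_warning(self, tmp_path):
        traj = self._toy_traj(3, 10)  # 3 lines of 10 values per frame
        path = tmp_path / "t.crd"
        write_trajectory(traj, path, "amber_ascii")
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # cut into frame 3
        with pytest.warns(UserWarning, match="truncated"):
            back = read_trajectory(path, "amber_ascii", atom_count=10)
        assert back.n_frames == 2

    def test_atom_count_mismatch_raises(self, tmp_path):
        traj = self._toy_traj(2, 3)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path, "multi_model_pdb")
        with pytest.raises(ValueError, match="mismatch"):
            read_trajectory(path, "multi_model_pdb", atom_count=5)


class TestPeriodicFix:
    def test_hop_across_boundary_is_unwrapped(self, tmp_path):
        L = 50.0
        ref = synthetic_ca_structure(1, coords=np.array([[0.4 * L, 0, 0]]))
        frames = np.array([[[0.4 * L, 0.0, 0.0]], [[0.6 * L - L, 0.0, 0.0]]])
        out = tmp_path / "fixed.pdb"
        fix_periodic_and_write_pdb(Trajectory(frames), ref, out, box=[L, L, L])
        fixed = read_trajectory(out, "multi_model_pdb", atom_count=1)
        assert fixed.frames[1, 0, 0] == pytest.approx(0.6 * L, abs=1e-2)

    def test_continuous_trajectory_unchanged(self, tmp_path):
        rng = np.random.default_rng(1)
        frames = np.cumsum(rng.uniform(-1, 1, (5, 3, 3)), axis=0) + 25.0
        ref = synthetic_ca_structure(3, coords=frames[0])
        out = tmp_path / "fixed.pdb"
        fix_periodic_and_write_pdb(Trajectory(frames), ref, out, box=[100.0] * 3)
        fixed = read_trajectory(out, "multi_model_pdb", atom_count=3)
        np.testing.assert_allclose(fixed.frames, frames, atol=5e-4)

    def test_exact_half_box_jump_resolves_to_no_shift(self, tmp_path):
        L = 20.0
        ref = synthetic_ca_structure(1, coords=np.array([[0.0, 0.0, 0.0]]))
        frames = np.array([[[0.0, 0.0, 0.0]], [[L / 2, 0.0, 0.0]]])
        out = tmp_path / "fixed.pdb"
        fix_periodic_and_write_pdb(Trajectory(frames), ref, out, box=[L, L, L])
        fixed = read_trajectory(out, "multi_model_pdb", atom_count=1)
        assert fixed.frames[1, 0, 0] == pytest.approx(L / 2, abs=1e-2)

    def test_missing_box_raises(self):
        ref = synthetic_ca_structure(1)
        with pytest.raises(ValueError, match="box"):
            fix_periodic_and_write_pdb(Trajectory(np.zeros((2, 1, 3))), ref,
                                       "/dev/null", box=None)

    def test_output_displacements_below_half_box(self, tmp_path, blob20):
        rng = np.random.default_rng(3)
        L = 40.0
        walk = np.cumsum(rng.uniform(-2, 2, (10, 20, 3)), axis=0) + blob20.coords
        wrapped = walk % L
        out = tmp_path / "fixed.pdb"
        fix_periodic_and_write_pdb(Trajectory(wrapped), blob20, out, box=[L] * 3)
        fixed = read_trajectory(out, "multi_model_pdb", atom_count=20)
        steps = np.abs(np.diff(fixed.frames, axis=0))
        assert steps.max() <= L / 2 + 1e-6


# ----------------------------------------------------------------------
# Full → Cα reduction
# ----------------------------------------------------------------------

class TestFull2Ca:
    def test_mode_rows_extracted_verbatim(self, mixed_pdb):
        full = read_pdb(mixed_pdb)
        vec = np.zeros((3 * full.n_atoms, 1))
        ca_rows = np.nonzero(np.repeat(full.is_ca, 3))[0]
        vec[ca_rows[0]] = 0.1
        modes = ModeSet(np.array([1.0]), vec)
        red = reduce_full_to_ca(modes, full)
        assert red.dim == 3 * int(full.is_ca.sum())
        assert red.eigenvectors[0, 0] == 0.1  # not renormalized

    def test_structure_reduction_keeps_only_ca(self, mixed_pdb):
        full = read_pdb(mixed_pdb)
        ca = reduce_full_to_ca(full, full)
        assert ca.n_atoms == int(full.is_ca.sum())
        assert all(a.name == "CA" for a in ca.atoms)

    def test_overlap_commutes_with_reduction_for_ca_motion(self, mixed_pdb):
        from modekit import overlap
        full = read_pdb(mixed_pdb)
        rng = np.random.default_rng(5)
        mask = np.repeat(full.is_ca, 3)
        v1, v2 = np.zeros(3 * full.n_atoms), np.zeros(3 * full.n_atoms)
        v1[mask] = rng.standard_normal(mask.sum())
        v2[mask] = rng.standard_normal(mask.sum())
        before = overlap(v1, v2)
        after = overlap(v1[mask], v2[mask])
        assert before == pytest.approx(after, abs=1e-12)

    def test_structure_without_ca_raises(self, tmp_path):
        p = tmp_path / "no_ca.pdb"
        p.write_text("ATOM      1  N   ALA A   1      11.104   6.134  -6.504"
                     "  1.00 10.00           N\n")
        s = read_pdb(p)
        with pytest.raises(ValueError, match="no CA"):
            reduce_full_to_ca(s, s)


# ----------------------------------------------------------------------
# NMWiz output
# ----------------------------------------------------------------------

class TestNmd:
    def test_format_arithmetic_and_roundtrip(self, tmp_path):
        s = synthetic_ca_structure(2, coords=np.array([[0., 0, 0], [3.8, 0, 0]]))
        vec = np.array([1.0, 0, 0, -1.0, 0, 0]) / np.sqrt(2)
        modes = ModeSet(np.array([2.0]), vec[:, None])
        out = tmp_path / "m.nmd"
        write_nmd(s, modes, out)
        lines = out.read_text().splitlines()
        mode_lines = [l for l in lines if l.startswith("mode ")]
        coord_line = next(l for l in lines if l.startswith("coordinates"))
        assert len(mode_lines) == 1
        assert len(mode_lines[0].split()) == 3 + 6  # mode idx scale + 3N comps
        assert len(coord_line.split()) == 1 + 6
        coords, parsed = read_nmd(out)
        idx, scale, comps = parsed[0]
        assert idx == 1
        assert scale == pytest.approx(np.sqrt(0.5))  # RMS amplitude, N=2
        np.testing.assert_array_equal(comps, vec)  # full precision

    def test_dimension_mismatch_raises(self, tmp_path):
        s = synthetic_ca_structure(3)
        modes = ModeSet(np.array([1.0]), np.ones((6, 1)))
        with pytest.raises(ValueError, match="mismatch"):
            write_nmd(s, modes, tmp_path / "x.nmd")


# ----------------------------------------------------------------------
# B-factor painting
# ----------------------------------------------------------------------

class TestPaint:
    def test_fixed_format_rounding(self, mixed_pdb, tmp_path):
        s = read_pdb(mixed_pdb, SelectionSpec(ca_only=True))
        out = tmp_path / "painted.pdb"
        paint_values_onto_pdb(s, np.array([12.345, 0.0]), out)
        lines = out.read_text().splitlines()
        painted = [lines[a.line_index] for a in s.atoms]
        assert painted[0][60:66] == " 12.35"
        assert painted[1][60:66] == "  0.00"

    def test_non_bfactor_bytes_identical(self, mixed_pdb, tmp_path):
        s = read_pdb(mixed_pdb, SelectionSpec(include_hetatm=True))
        out = tmp_path / "painted.pdb"
        paint_values_onto_pdb(s, np.arange(s.n_atoms, dtype=float), out)
        for orig, new in zip(mixed_pdb.read_text().splitlines(),
                             out.read_text().splitlines()):
            assert orig[:60] == new[:60]
            assert orig[66:] == new[66:]

    def test_overflow_clamped_with_warning(self, mixed_pdb, tmp_path):
        s = read_pdb(mixed_pdb, SelectionSpec(ca_only=True))
        with pytest.warns(UserWarning, match="clamp"):
            paint_values_onto_pdb(s, np.array([1e6, -1e6]), tmp_path / "p.pdb")


# ----------------------------------------------------------------------
# Eigenfile round-trip
# ----------------------------------------------------------------------

class TestEigenfile:
    def test_bit_exact_roundtrip(self, tmp_path, blob20_modes):
        p1, p2 = tmp_path / "a.eig", tmp_path / "b.eig"
        write_modes(blob20_modes, p1)
        back = read_modes(p1)
        np.testing.assert_array_equal(back.eigenvalues, blob20_modes.eigenvalues)
        np.testing.assert_array_equal(back.eigenvectors, blob20_modes.eigenvectors)
        assert back.weighting == blob20_modes.weighting
        assert back.n_zero_modes == blob20_modes.n_zero_modes
        write_modes(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_header_format(self, tmp_path, blob20_modes):
        p = tmp_path / "a.eig"
        write_modes(blob20_modes, p)
        header = p.read_text().splitlines()[0]
        assert header == "nmodes 60 natoms 20 weighting unit"

    def test_gnm_kind_inferred_from_component_count(self, tmp_path, blob20):
        from modekit import build_kirchhoff, diagonalize_full
        modes = diagonalize_full(build_kirchhoff(blob20, 12.0, 1.0))
        p = tmp_path / "g.eig"
        write_modes(modes, p)
        assert read_modes(p).kind == "gnm"
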