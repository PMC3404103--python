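"""Structure model, PDB I/O, selection, superposition, distances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sfcollapse import (
    AtomRecord,
    StructureModel,
    Trajectory,
    pair_distance,
    pair_distance_by_chain,
    read_pdb,
    read_structure,
    select,
    superpose,
    write_pdb,
)
from sfcollapse.errors import (
    FitError,
    LookupAtomError,
    PDBParseError,
    SelectionError,
    TopologyError,
)


def _atom(chain, resnum, name, pos, resname="GLY", element=None):
    return AtomRecord(chain, resnum, resname, name, element or name[0], np.asarray(pos, float))


def toy_model():
    atoms = [
        _atom("A", 1, "N", (0, 0, 0)),
        _atom("A", 1, "CA", (1.5, 0, 0)),
        _atom("A", 1, "C", (2.2, 1.2, 0)),
        _atom("A", 1, "O", (2.0, 2.4, 0)),
        _atom("A", 2, "N", (3.5, 1.0, 0.5)),
    ]
    return StructureModel(atoms)


class TestPDBIO:
    def test_single_atom_roundtrip(self, tmp_path):
        m = StructureModel([_atom("A", 7, "CA", (1.234, -5.678, 9.012))])
        p = tmp_path / "one.pdb"
        write_pdb(m, p)
        m2 = read_structure(p)
        assert m2.n_atoms == 1
        np.testing.assert_allclose(m2.coords, m.coords, atol=5e-4)
        assert m2.atoms[0].key == ("A", 7, "CA")

    def test_structure_roundtrip_preserves_identity(self, tmp_path, reference_pair):
        ref_a, _, _ = reference_pair
        p = tmp_path / "ref.pdb"
        write_pdb(ref_a, p)
        back = read_structure(p)
        assert [a.key for a in back.atoms] == [a.key for a in ref_a.atoms]
        assert [a.residue_name for a in back.atoms] == [
            a.residue_name for a in ref_a.atoms
        ]
        np.testing.assert_allclose(back.coords, ref_a.coords, atol=5e-4)

    def test_atom_line_byte_layout(self, tmp_path):
        m = StructureModel([_atom("B", 629, "ND2", (1.0, -2.5, 30.125), "ASN", "N")])
        p = tmp_path / "layout.pdb"
        write_pdb(m, p)
        line = p.read_text().splitlines()[0]
        assert line[:6] == "ATOM  "
        assert line[12:16] == " ND2"
        assert line[17:20] == "ASN"
        assert line[21] == "B"
        assert int(line[22:26]) == 629
        assert line[30:38] == "   1.000"
        assert line[38:46] == "  -2.500"
        assert line[46:54] == "  30.125"
        assert line[76:78].strip() == "N"

    def test_multimodel_file_becomes_trajectory(self, tmp_path):
        m = toy_model()
        coords = np.stack([m.coords, m.coords + 1.0, m.coords + 2.0])
        traj = Trajectory(m, [0.0, 1.0, 2.0], coords)
        p = tmp_path / "traj.pdb"
        write_pdb(traj, p)
        top, back = read_pdb(p)
        assert back.n_frames == 3
        np.testing.assert_array_equal(back.times, [0.0, 1.0, 2.0])
        np.testing.assert_allclose(back.coords, coords, atol=5e-4)

    def test_roundtrip_against_biotite(self, tmp_path, reference_pair):
        """Independent reader oracle: biotite parses what we write."""
        biotite_pdb = pytest.importorskip("biotite.structure.io.pdb")
        ref_a, _, _ = reference_pair
        p = tmp_path / "ref.pdb"
        write_pdb(ref_a, p)
        arr = biotite_pdb.PDBFile.read(str(p)).get_structure(model=1)
        assert arr.array_length() == ref_a.n_atoms
        np.testing.assert_allclose(arr.coord, ref_a.coords, atol=5e-4)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "ATOM      1  CA  GLY A   1       1.000   2.000   3.000\n"
            "ATOM      2  CA  GLY A   2       BADX.000   2.000   3.000\n"
        )
        with pytest.raises(PDBParseError, match="line 2"):
            read_pdb(p)

    def test_insertion_code_rejected(self, tmp_path):
        p = tmp_path / "icode.pdb"
        p.write_text(
            "ATOM      1  CA  GLY A   1A      1.000   2.000   3.000\n"
        )
        with pytest.raises(PDBParseError, match="insertion"):
            read_pdb(p)

    def test_inconsistent_models_rejected(self, tmp_path):
        lines = ["MODEL     1",
                 "ATOM      1  CA  GLY A   1       1.000   2.000   3.000",
                 "ENDMDL",
                 "MODEL     2",
                 "ATOM      1  CA  GLY A   1       1.000   2.000   3.000",
                 "ATOM      2  CB  GLY A   1       1.000   2.000   3.000",
                 "ENDMDL"]
        p = tmp_path / "inc.pdb"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(TopologyError):
            read_pdb(p)

    def test_hetatm_and_altloc_b_ignored(self, tmp_path):
        lines = [
            "ATOM      1  CA  GLY A   1       1.000   2.000   3.000",
            "ATOM      2  CA BGLY A   2       9.000   9.000   9.000",
            "HETATM    3  O   HOH A 100       5.000   5.000   5.000",
        ]
        p = tmp_path / "het.pdb"
        p.write_text("\n".join(lines) + "\n")
        m = read_pdb(p)
        assert m.n_atoms == 1


class TestCanonicalOrder:
    def test_order_independent_of_record_order(self):
        atoms = [
            _atom("A", 2, "CA", (1, 1, 1)),
            _atom("A", 1, "O", (0, 0, 3)),
            _atom("A", 1, "N", (0, 0, 0)),
            _atom("A", 1, "CB", (0, 1, 1), element="C"),
            _atom("A", 1, "CA", (0, 0, 1)),
        ]
        m1 = StructureModel(list(atoms))
        m2 = StructureModel(list(reversed(atoms)))
        assert [a.key for a in m1.atoms] == [a.key for a in m2.atoms]
        # backbone first (N, CA, ... O), side chain after
        assert [a.atom_name for a in m1.atoms[:4]] == ["N", "CA", "O", "CB"]

    def test_duplicate_atom_rejected(self):
        atoms = [_atom("A", 1, "CA", (0, 0, 0)), _atom("A", 1, "CA", (1, 1, 1))]
        with pytest.raises(TopologyError, match="duplicate"):
            StructureModel(atoms)


class TestSelect:
    def test_carbonyl_selection_on_tetramer(self, reference_pair):
        ref_a, _, _ = reference_pair
        sel = select(ref_a, "resnum 624-627 and name O")
        assert len(sel) == 16  # 4 residues x 4 chains
        assert all(ref_a.atoms[i].atom_name == "O" for i in sel.indices)

    def test_chain_clause_selects_whole_chain(self):
        m = toy_model()
        assert len(select(m, "chain A")) == m.n_atoms

    def test_unknown_name_gives_empty_selection(self):
        assert len(select(toy_model(), "name XX")) == 0

    def test_conjunction_and_multivalue(self, reference_pair):
        ref_a, _, _ = reference_pair
        sel = select(ref_a, "chain A B and resnum 620 and name CB OG")
        names = sorted(ref_a.atoms[i].atom_name for i in sel.indices)
        assert names == ["CB", "CB", "OG", "OG"]

    def test_syntax_error_reports_position(self):
        with pytest.raises(SelectionError, match="token 1"):
            select(toy_model(), "bogus 5")
        with pytest.raises(SelectionError, match="no values"):
            select(toy_model(), "name")

    def test_selection_indices_are_ordered_unique(self, reference_pair):
        ref_a, _, _ = reference_pair
        sel = select(ref_a, "resnum 624-628 and name N CA C O")
        assert np.all(np.diff(sel.indices) > 0)


class TestSuperpose:
    def test_identical_sets_rmsd_zero(self, rng):
        pts = rng.normal(size=(10, 3))
        sup = superpose(pts, pts)
        assert sup.rmsd < 1e-12
        np.testing.assert_allclose(sup.apply(pts), pts, atol=1e-12)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(8, 3)) * 5
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([1.0, 2.0, 3.0])
        sup = superpose(moved, pts)
        assert sup.rmsd <= 1e-9
        np.testing.assert_allclose(sup.apply(moved), pts, atol=1e-9)

    def test_never_returns_reflection(self, rng):
        for _ in range(5):
            a = rng.normal(size=(4, 3))
            b = rng.normal(size=(4, 3))
            sup = superpose(a, b)
            assert np.linalg.det(sup.rotation) > 0.99

    def test_rmsd_matches_rotation_grid_oracle(self, rng):
        """Brute-force oracle: grid search over rotations, refined twice."""
        a = rng.normal(size=(4, 3)) * 2
        b = rng.normal(size=(4, 3)) * 2
        sup = superpose(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def grid_best(center, half_width, n=24):
            axes = [np.linspace(c - half_width, c + half_width, n) for c in center]
            euler = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            mats = Rotation.from_euler("zyz", euler).as_matrix()
            fitted = np.einsum("rij,nj->rni", mats, ac)
            rmsds = np.sqrt(np.mean(np.sum((fitted - bc) ** 2, axis=2), axis=1))
            i = int(rmsds.argmin())
            return euler[i], float(rmsds[i])

        center, width = np.array([np.pi, np.pi / 2, np.pi]), np.pi
        for _ in range(4):
            center, best = grid_best(center, width)
            width /= 10.0
        assert sup.rmsd <= best + 1e-9
        assert abs(sup.rmsd - best) < 1e-3

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(FitError):
            superpose(line, line + 1)
        with pytest.raises(FitError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPairDistance:
    def test_axis_distance(self):
        m = StructureModel(
            [_atom("A", 1, "CA", (0, 0, 0)), _atom("A", 2, "CA", (0, 0, 5))]
        )
        assert pair_distance(m, ("A", 1, "CA"), ("A", 2, "CA")) == pytest.approx(5.0)
        assert pair_distance(m, ("A", 1, "CA"), ("A", 1, "CA")) == 0.0

    def test_programmed_per_chain_separations(self):
        atoms = []
        for i, (chain, d) in enumerate(zip("ABCD", [5.0, 6.0, 7.0, 8.0])):
            base = np.array([10.0 * i, 0, 0])
            atoms.append(_atom(chain, 620, "CB", base, "SER", "C"))
            atoms.append(_atom(chain, 629, "CB", base + [0, 0, d], "ASN", "C"))
        m = StructureModel(atoms)
        out = pair_distance_by_chain(m, 620, "CB", 629, "CB")
        assert [out[c] for c in "ABCD"] == pytest.approx([5.0, 6.0, 7.0, 8.0])

    def test_missing_atom_names_target(self):
        with pytest.raises(LookupAtomError, match="629"):
            pair_distance(toy_model(), ("A", 1, "CA"), ("A", 629, "CB"))
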