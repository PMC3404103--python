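"""Hydrogen-bond detection: oracle equivalence, classification, toggles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sfcollapse import (
    AtomRecord,
    HBondCriteria,
    HBondDetector,
    StructureModel,
    contact_fraction,
    detect_hbonds,
    hbond_series,
)
from sfcollapse.hbondnet import HBondSeries
from sfcollapse.structio import AtomSelection
from sfcollapse.errors import CriteriaError, SelectionError, WindowError
from sfcollapse.synthgen import make_hbond_toggle


def _atom(chain, resnum, name, element, pos, resname="XXX"):
    return AtomRecord(chain, resnum, resname, name, element, np.asarray(pos, float))


def _sel(model, names):
    idx = np.array(
        [i for i, a in enumerate(model.atoms) if a.atom_name in names], dtype=int
    )
    return AtomSelection(idx, f"names {names}")


def brute_force_hbonds(model, donors, acceptors, criteria, coords=None):
    """O(n^2) reference detector applying the same geometric rules."""
    xyz = model.coords if coords is None else coords
    atoms = model.atoms
    heavy = [i for i, a in enumerate(atoms) if a.element != "H"]
    found = []
    for d in map(int, donors.indices):
        ante = [
            c for c in heavy
            if c != d and np.linalg.norm(xyz[c] - xyz[d]) < 1.8
        ]
        for a in map(int, acceptors.indices):
            if a == d:
                continue
            dist = np.linalg.norm(xyz[a] - xyz[d])
            if dist > criteria.max_da_distance or dist < 1.8:
                continue
            if (
                atoms[d].chain_id == atoms[a].chain_id
                and atoms[d].residue_number == atoms[a].residue_number
                and dist < 2.8
            ):
                continue
            ok = True
            for c in ante:
                v1, v2 = xyz[c] - xyz[d], xyz[a] - xyz[d]
                cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cos, -1, 1))) < 90.0:
                    ok = False
                    break
            if ok:
                found.append((d, a))
    return sorted(found)


class TestDetect:
    def test_ideal_linear_bond_detected(self):
        m = StructureModel([
            _atom("A", 1, "ND2", "N", (0, 0, 0)),
            _atom("A", 1, "HD2", "H", (0, 0, 1.0)),
            _atom("B", 2, "O", "O", (0, 0, 2.9)),
        ])
        crit = HBondCriteria(hydrogen_mode="explicit")
        recs = detect_hbonds(m, _sel(m, {"ND2"}), _sel(m, {"O"}), crit)
        assert len(recs) == 1
        assert recs[0].da_distance == pytest.approx(2.9)
        assert recs[0].hda_angle == pytest.approx(0.0, abs=1e-9)
        assert not recs[0].intra

    def test_beyond_cutoff_not_detected(self):
        m = StructureModel([
            _atom("A", 1, "ND2", "N", (0, 0, 0)),
            _atom("B", 2, "O", "O", (0, 0, 4.0)),
        ])
        assert detect_hbonds(m, _sel(m, {"ND2"}), _sel(m, {"O"})) == []

    def test_bent_hydrogen_rejected_in_explicit_mode(self):
        m = StructureModel([
            _atom("A", 1, "ND2", "N", (0, 0, 0)),
            _atom("A", 1, "HD2", "H", (1.0, 0, 0)),  # 90 deg off the D->A line
            _atom("B", 2, "O", "O", (0, 0, 2.9)),
        ])
        crit = HBondCriteria(hydrogen_mode="explicit")
        assert detect_hbonds(m, _sel(m, {"ND2"}), _sel(m, {"O"}), crit) == []

    def test_explicit_mode_without_hydrogens_errors(self):
        m = StructureModel([
            _atom("A", 1, "ND2", "N", (0, 0, 0)),
            _atom("B", 2, "O", "O", (0, 0, 2.9)),
        ])
        with pytest.raises(CriteriaError, match="heavy"):
            detect_hbonds(
                m, _sel(m, {"ND2"}), _sel(m, {"O"}),
                HBondCriteria(hydrogen_mode="explicit"),
            )

    def test_antecedent_in_front_rejected_in_heavy_mode(self):
        """Acceptor on the same side as the donor's covalent neighbour."""
        m = StructureModel([
            _atom("A", 1, "ND2", "N", (0, 0, 0)),
            _atom("A", 1, "CG", "C", (0, 0, 1.3)),
            _atom("B", 2, "O", "O", (0, 0.5, 3.0)),
        ])
        recs = detect_hbonds(m, _sel(m, {"ND2"}), _sel(m, {"O"}))
        assert recs == []

    def test_matches_bruteforce_oracle_on_random_toys(self, rng):
        """Identical bond sets to the O(n^2) oracle on 100 seeded frames."""
        crit = HBondCriteria()
        det = HBondDetector()
        for frame in range(100):
            atoms = []
            for i in range(30):
                name, el = [("ND2", "N"), ("O", "O"), ("CG", "C")][i % 3]
                atoms.append(
                    _atom("AB"[i % 2], i, name, el, rng.uniform(0, 12, 3))
                )
            m = StructureModel(atoms)
            donors = _sel(m, {"ND2"})
            acceptors = _sel(m, {"O"})
            got = sorted(
                (r.donor_index, r.acceptor_index)
                for r in det.detect(m, donors, acceptors)
            )
            assert got == brute_force_hbonds(m, donors, acceptors, crit)

    def test_distance_cutoff_monotonicity(self, rng):
        """Enlarging max_da_distance never removes a detected bond."""
        atoms = [
            _atom("AB"[i % 2], i, ["ND2", "O"][i % 2], "NO"[i % 2],
                  rng.uniform(0, 10, 3))
            for i in range(20)
        ]
        m = StructureModel(atoms)
        donors, acceptors = _sel(m, {"ND2"}), _sel(m, {"O"})
        prev: set = set()
        for cutoff in (2.5, 3.0, 3.5, 4.0, 5.0):
            crit = HBondCriteria(max_da_distance=cutoff)
            got = {
                (r.donor_index, r.acceptor_index)
                for r in detect_hbonds(m, donors, acceptors, crit)
            }
            assert prev <= got
            prev = got

    def test_rigid_motion_invariance(self, rng):
        atoms = [
            _atom("AB"[i % 2], i, ["ND2", "O"][i % 2], "NO"[i % 2],
                  rng.uniform(0, 10, 3))
            for i in range(20)
        ]
        m = StructureModel(atoms)
        donors, acceptors = _sel(m, {"ND2"}), _sel(m, {"O"})
        base = {
            (r.donor_index, r.acceptor_index)
            for r in detect_hbonds(m, donors, acceptors)
        }
        R = Rotation.from_euler("xyz", [0.5, 1.0, -0.3]).as_matrix()
        moved = m.with_coords(m.coords @ R.T + np.array([3.0, -2.0, 8.0]))
        got = {
            (r.donor_index, r.acceptor_index)
            for r in detect_hbonds(moved, donors, acceptors)
        }
        assert got == base


class TestSeries:
    def test_pure_intra_geometry_has_no_inter(self):
        traj, truth = make_hbond_toggle(n_frames=50, inter_fraction=0.0, seed=1)
        series = hbond_series(traj)
        assert series.n_inter.sum() == 0
        assert np.all(series.n_intra > 0)

    def test_inter_bond_to_adjacent_G628_carbonyl(self):
        """The programmed inter configuration bonds ND2 to the next chain's
        glycine-628 backbone carbonyl and is classified inter."""
        traj, _ = make_hbond_toggle(n_frames=4, inter_fraction=1.0, seed=2)
        series = hbond_series(traj, keep_records=True)
        assert np.all(series.n_inter == 4)  # one per subunit
        assert series.n_intra.sum() == 0
        top = traj.topology
        for r in series.records:
            acceptor = top.atoms[r.acceptor_index]
            assert (acceptor.residue_number, acceptor.atom_name) == (628, "O")
            assert r.donor_chain != r.acceptor_chain

    def test_toggle_fraction_recovered(self):
        """Programmed 30% inter frames recovered within binomial 95% CI."""
        n = 2000
        p = 0.30
        traj, truth = make_hbond_toggle(n_frames=n, inter_fraction=p, seed=3)
        series = hbond_series(traj)
        total = series.n_intra + series.n_inter
        est = series.n_inter.sum() / total.sum()
        ci = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(est - p) <= ci
        # and per-frame classification matches the truth labels exactly
        np.testing.assert_array_equal(
            (series.n_inter > 0).astype(int), truth["inter"].values
        )

    def test_conservation_intra_plus_inter(self):
        traj, _ = make_hbond_toggle(n_frames=100, inter_fraction=0.5, seed=4)
        series = hbond_series(traj, keep_records=True)
        assert np.all(series.n_intra + series.n_inter == 4)

    def test_missing_focal_residue_errors(self, reference_pair):
        ref_a, _, _ = reference_pair
        from sfcollapse import Trajectory
        traj = Trajectory(ref_a, [0.0], ref_a.coords[None])
        with pytest.raises(SelectionError):
            hbond_series(traj, focal_resnum=999)


class TestContactFraction:
    def _series(self, intra, inter):
        n = len(intra)
        return HBondSeries(
            np.arange(float(n)), np.array(intra), np.array(inter), "test"
        )

    def test_all_intra(self):
        out = contact_fraction(self._series([2, 2, 2, 2], [0, 0, 0, 0]), window=2)
        assert (out["intra_fraction"] == 1.0).all()
        assert (out["inter_fraction"] == 0.0).all()

    def test_empty_bond_frames_guarded(self):
        out = contact_fraction(self._series([0, 0], [0, 0]), window=2)
        assert np.isnan(out["intra_fraction"]).all()

    def test_alternating_intra_inter_half(self):
        out = contact_fraction(self._series([1, 0, 1, 0], [0, 1, 0, 1]), window=4)
        assert out.loc[0, "intra_fraction"] == pytest.approx(0.5)
        assert out.loc[0, "inter_fraction"] == pytest.approx(0.5)

    def test_bad_window_rejected(self):
        with pytest.raises(WindowError):
            contact_fraction(self._series([1], [0]), window=5)
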