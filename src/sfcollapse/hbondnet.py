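"""Geometric hydrogen-bond detection and intra-/inter-subunit bookkeeping.

A donor-acceptor pair is counted as hydrogen bonded when the heavy-atom
distance is below a cutoff (default 3.5 A) and a geometric angle test
passes.  With explicit hydrogens the test is the deviation of the hydrogen
from the donor->acceptor line (default <= 30 deg).  Without hydrogens
(the common case for the idealized models here) the covalent antecedent
of the donor must lie behind it: every heavy atom bonded to the donor has
to form an angle antecedent-donor...acceptor >= 90 deg, which suppresses
geometrically impossible approaches.

Classification is per chain: a bond is *intra* when donor and acceptor
belong to the same subunit and *inter* otherwise ("neighboring subunit"
means any other chain of the tetramer, not only ring-adjacent ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .errors import CriteriaError, SelectionError, WindowError
from .structio import AtomSelection, StructureModel, Trajectory, select

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "HBondSeries",
    "HBondDetector",
    "detect_hbonds",
    "hbond_series",
    "contact_fraction",
    "DEFAULT_DONOR_NAMES",
    "DEFAULT_ACCEPTOR_NAMES",
]

#: Protein donor heavy atoms (carry at least one hydrogen).
DEFAULT_DONOR_NAMES = (
    "N", "ND1", "ND2", "NE", "NE1", "NE2", "NH1", "NH2", "NZ",
    "OG", "OG1", "OH", "SG",
)
#: Protein acceptor heavy atoms.
DEFAULT_ACCEPTOR_NAMES = (
    "O", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH", "ND1", "NE2", "OXT",
)

_COVALENT_CUTOFF = 1.8  # A, heavy-atom covalent neighbour search
_GEMINAL_CUTOFF = 2.8  # A, same-residue 1-3 pairs are never H-bonds
_H_COVALENT_CUTOFF = 1.25  # A, H attached to its donor


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance criteria for a hydrogen bond."""

    max_da_distance: float = 3.5  # A
    max_hda_angle: float = 30.0  # deg, H deviation from the D->A line
    hydrogen_mode: str = "heavy"  # "explicit" | "heavy"

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise CriteriaError("max_da_distance must be positive")
        if not 0 < self.max_hda_angle <= 90:
            raise CriteriaError("max_hda_angle must be in (0, 90] degrees")
        if self.hydrogen_mode not in ("explicit", "heavy"):
            raise CriteriaError("hydrogen_mode must be 'explicit' or 'heavy'")


@dataclass(frozen=True)
class HBondRecord:
    """One detected hydrogen bond in one frame."""

    frame: int
    donor_index: int
    hydrogen_index: int | None
    acceptor_index: int
    donor_chain: str
    acceptor_chain: str
    da_distance: float
    hda_angle: float | None

    @property
    def intra(self) -> bool:
        return self.donor_chain == self.acceptor_chain


@dataclass
class HBondSeries:
    """Per-frame intra/inter hydrogen-bond counts of a focal side chain."""

    times: np.ndarray
    n_intra: np.ndarray
    n_inter: np.ndarray
    focal: str
    records: list = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ps": self.times, "n_intra": self.n_intra, "n_inter": self.n_inter}
        )

    def rolling_mean(self, window: int) -> pd.DataFrame:
        """Smoothed counts for presentation; raw counts stay untouched."""
        df = self.to_frame().set_index("time_ps")
        return df.rolling(window, min_periods=1, center=True).mean()


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


class HBondDetector(BaseEstimator):
    """Detect hydrogen bonds in frames under fixed geometric criteria.

    Parameters mirror :class:`HBondCriteria`; ``fit`` is a no-op (the
    detector is stateless) and exists for pipeline compatibility.
    """

    def __init__(
        self,
        max_da_distance: float = 3.5,
        max_hda_angle: float = 30.0,
        hydrogen_mode: str = "heavy",
    ):
        self.max_da_distance = max_da_distance
        self.max_hda_angle = max_hda_angle
        self.hydrogen_mode = hydrogen_mode

    @property
    def criteria(self) -> HBondCriteria:
        return HBondCriteria(self.max_da_distance, self.max_hda_angle, self.hydrogen_mode)

    def fit(self, X=None, y=None):
        _ = self.criteria  # validate
        return self

    # -- detection -------------------------------------------------------
    def detect(
        self,
        model: StructureModel,
        donors: AtomSelection,
        acceptors: AtomSelection,
        coords: np.ndarray | None = None,
        frame: int = 0,
    ) -> list[HBondRecord]:
        crit = self.criteria
        xyz = model.coords if coords is None else np.asarray(coords, dtype=float)
        atoms = model.atoms

        hydrogens_by_donor: dict[int, list[int]] = {}
        if crit.hydrogen_mode == "explicit":
            h_idx = [i for i, a in enumerate(atoms) if a.element == "H"]
            if not h_idx:
                raise CriteriaError(
                    "hydrogen_mode='explicit' but the model has no hydrogens; "
                    "use hydrogen_mode='heavy'"
                )
            h_tree = cKDTree(xyz[h_idx])
            for d in donors.indices:
                near = h_tree.query_ball_point(xyz[d], _H_COVALENT_CUTOFF)
                hydrogens_by_donor[int(d)] = [h_idx[j] for j in near]

        heavy_idx = [i for i, a in enumerate(atoms) if a.element != "H"]
        heavy_tree = cKDTree(xyz[heavy_idx])
        antecedents: dict[int, list[int]] = {}
        for d in donors.indices:
            near = heavy_tree.query_ball_point(xyz[d], _COVALENT_CUTOFF)
            antecedents[int(d)] = [heavy_idx[j] for j in near if heavy_idx[j] != d]

        acc_idx = np.asarray(acceptors.indices, dtype=int)
        if len(acc_idx) == 0 or len(donors.indices) == 0:
            return []
        acc_tree = cKDTree(xyz[acc_idx])

        out: list[HBondRecord] = []
        for d in map(int, donors.indices):
            cand = acc_tree.query_ball_point(xyz[d], crit.max_da_distance)
            for j in sorted(cand, key=lambda j: int(acc_idx[j])):
                a = int(acc_idx[j])
                if a == d:
                    continue
                dist = float(np.linalg.norm(xyz[a] - xyz[d]))
                if dist > crit.max_da_distance:
                    continue
                same_residue = (
                    atoms[d].chain_id == atoms[a].chain_id
                    and atoms[d].residue_number == atoms[a].residue_number
                )
                if dist < _COVALENT_CUTOFF or (same_residue and dist < _GEMINAL_CUTOFF):
                    continue  # covalent or geminal pair, not an H-bond
                hda = None
                h_used = None
                if crit.hydrogen_mode == "explicit":
                    ok = False
                    for h in hydrogens_by_donor.get(d, []):
                        ang = _angle_deg(xyz[h] - xyz[d], xyz[a] - xyz[d])
                        if ang <= crit.max_hda_angle:
                            ok, h_used, hda = True, h, ang
                            break
                    if not ok:
                        continue
                else:
                    # every covalent neighbour must sit behind the donor
                    bad = False
                    for c in antecedents.get(d, []):
                        if _angle_deg(xyz[c] - xyz[d], xyz[a] - xyz[d]) < 90.0:
                            bad = True
                            break
                    if bad:
                        continue
                out.append(
                    HBondRecord(
                        frame=frame,
                        donor_index=d,
                        hydrogen_index=h_used,
                        acceptor_index=a,
                        donor_chain=atoms[d].chain_id,
                        acceptor_chain=atoms[a].chain_id,
                        da_distance=dist,
                        hda_angle=hda,
                    )
                )
        out.sort(key=lambda r: (r.donor_index, r.acceptor_index))
        return out

    # -- focal-residue time series ---------------------------------------
    def series(
        self,
        traj: Trajectory,
        focal_resnum: int = 629,
        partners: str = "all",
        keep_records: bool = False,
    ) -> HBondSeries:
        """Intra/inter bond counts of the focal residue's side chain per frame.

        The focal side chain (backbone N, CA, C, O excluded) is counted both
        as donor and as acceptor; counts are computed per chain and summed
        over the four subunits.  A bond joining the focal side chains of two
        different chains is counted once per involved focal residue (as
        inter for each).
        """
        top = traj.topology
        focal_sets: dict[str, set[int]] = {}
        for c in top.chain_order:
            sel = select(top, f"chain {c} and resnum {focal_resnum}")
            side = {
                int(i)
                for i in sel.indices
                if top.atoms[i].atom_name not in ("N", "CA", "C", "O")
            }
            if not side:
                raise SelectionError(
                    f"focal residue {focal_resnum} has no side chain in chain {c}"
                )
            focal_sets[c] = side

        partner_sel = select(top, partners)
        partner_set = set(map(int, partner_sel.indices))
        donor_names = set(DEFAULT_DONOR_NAMES)
        acceptor_names = set(DEFAULT_ACCEPTOR_NAMES)
        donor_idx = np.array(
            sorted(
                i for i in partner_set if top.atoms[i].atom_name in donor_names
            ),
            dtype=int,
        )
        acceptor_idx = np.array(
            sorted(
                i for i in partner_set if top.atoms[i].atom_name in acceptor_names
            ),
            dtype=int,
        )
        donors = AtomSelection(donor_idx, "hbond donors")
        acceptors = AtomSelection(acceptor_idx, "hbond acceptors")

        n_intra = np.zeros(traj.n_frames, dtype=int)
        n_inter = np.zeros(traj.n_frames, dtype=int)
        all_records: list[HBondRecord] = []
        for f in range(traj.n_frames):
            recs = self.detect(top, donors, acceptors, coords=traj.coords[f], frame=f)
            for r in recs:
                for c, side in focal_sets.items():
                    if r.donor_index in side:
                        partner_chain = r.acceptor_chain
                    elif r.acceptor_index in side:
                        partner_chain = r.donor_chain
                    else:
                        continue
                    if partner_chain == c:
                        n_intra[f] += 1
                    else:
                        n_inter[f] += 1
                    if keep_records:
                        all_records.append(r)
        return HBondSeries(
            traj.times.copy(), n_intra, n_inter, f"resnum {focal_resnum} sidechain",
            all_records,
        )


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def detect_hbonds(
    model: StructureModel,
    donors: AtomSelection,
    acceptors: AtomSelection,
    criteria: HBondCriteria | None = None,
    coords: np.ndarray | None = None,
    frame: int = 0,
) -> list[HBondRecord]:
    crit = criteria or HBondCriteria()
    det = HBondDetector(crit.max_da_distance, crit.max_hda_angle, crit.hydrogen_mode)
    return det.detect(model, donors, acceptors, coords=coords, frame=frame)


def hbond_series(
    traj: Trajectory,
    focal_resnum: int = 629,
    partners: str = "all",
    criteria: HBondCriteria | None = None,
    keep_records: bool = False,
) -> HBondSeries:
    crit = criteria or HBondCriteria()
    det = HBondDetector(crit.max_da_distance, crit.max_hda_angle, crit.hydrogen_mode)
    return det.series(traj, focal_resnum, partners, keep_records)


def contact_fraction(series: HBondSeries, window: int) -> pd.DataFrame:
    """Intra/inter fractions of total focal bonds over consecutive windows.

    Frames with no bonds contribute nothing; a window whose total is zero
    yields NaN fractions rather than a division error.
    """
    n = len(series.times)
    if window <= 0 or window > n:
        raise WindowError(f"window {window} invalid for series of length {n}")
    rows = []
    for start in range(0, n, window):
        sl = slice(start, min(start + window, n))
        intra = int(series.n_intra[sl].sum())
        inter = int(series.n_inter[sl].sum())
        total = intra + inter
        rows.append(
            {
                "window_start_ps": float(series.times[start]),
                "intra_fraction": intra / total if total else np.nan,
                "inter_fraction": inter / total if total else np.nan,
                "n_bonds": total,
            }
        )
    return pd.DataFrame(rows)
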