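"""Per-atom RMSF with residue/subunit aggregation and distance-scan tables.

RMSF is computed about the trajectory-mean structure after a two-pass
superposition: frames are first fitted to frame 0 on the alignment
selection, the mean structure of that pass is formed, and the original
frames are then refitted onto the mean before fluctuations are measured.
This removes the bias of aligning to an arbitrary single frame.  No mass
weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import SelectionError, WindowError
from .structio import Trajectory, select, superpose

__all__ = ["RMSFProfile", "RMSFCalculator", "rmsf", "rmsf_vs_scan"]


@dataclass(frozen=True)
class RMSFProfile:
    """Per-atom RMSF (Angstrom) of a measured selection plus aggregates."""

    atom_keys: list  # (chain, resnum, atom name) per measured atom
    residue_names: list  # residue 3-letter code per measured atom
    rmsf_per_atom: np.ndarray
    measure_expression: str
    align_expression: str

    def by_residue(self) -> pd.Series:
        """Mean RMSF per residue number, averaged over atoms and chains."""
        df = pd.DataFrame(
            {
                "resnum": [k[1] for k in self.atom_keys],
                "rmsf": self.rmsf_per_atom,
            }
        )
        return df.groupby("resnum")["rmsf"].mean()

    def by_residue_chain(self) -> pd.Series:
        df = pd.DataFrame(
            {
                "chain": [k[0] for k in self.atom_keys],
                "resnum": [k[1] for k in self.atom_keys],
                "rmsf": self.rmsf_per_atom,
            }
        )
        return df.groupby(["chain", "resnum"])["rmsf"].mean()

    def residue_labels(self) -> dict[int, str]:
        """Residue number -> one-letter-ish label like 'S624' (first chain wins)."""
        out: dict[int, str] = {}
        for k, rn in zip(self.atom_keys, self.residue_names):
            out.setdefault(k[1], f"{_ONE.get(rn, 'X')}{k[1]}")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [k[0] for k in self.atom_keys],
                "resnum": [k[1] for k in self.atom_keys],
                "resname": self.residue_names,
                "atom": [k[2] for k in self.atom_keys],
                "rmsf_A": self.rmsf_per_atom,
            }
        )


_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


class RMSFCalculator(BaseEstimator, TransformerMixin):
    """Root-mean-square fluctuation of selected atoms about the mean structure.

    Parameters
    ----------
    measure_selection : str
        Atoms whose fluctuation is reported (e.g. the carbonyl oxygens of
        the filter residues 624-627: ``"resnum 624-627 and name O"``).
    align_selection : str or None
        Atoms used for the rigid fit; ``None`` uses the measured selection.
    """

    def __init__(
        self,
        measure_selection: str = "resnum 624-627 and name O",
        align_selection: str | None = None,
    ):
        self.measure_selection = measure_selection
        self.align_selection = align_selection

    def fit(self, X: Trajectory, y=None):
        traj = X
        if traj.n_frames < 2:
            raise WindowError("RMSF is undefined for a single-frame trajectory")
        top = traj.topology
        measure = select(top, self.measure_selection)
        if len(measure) == 0:
            raise SelectionError(
                f"measure selection {self.measure_selection!r} selects no atoms"
            )
        align_expr = self.align_selection or self.measure_selection
        align = select(top, align_expr)
        if len(align) < 3:
            raise SelectionError(
                f"alignment selection {align_expr!r} has {len(align)} atoms (< 3)"
            )
        ai = align.indices
        mi = measure.indices

        # pass 1: fit every frame to frame 0, form the mean structure
        ref0 = traj.coords[0][ai]
        fitted = np.empty_like(traj.coords)
        for f in range(traj.n_frames):
            sup = superpose(traj.coords[f][ai], ref0)
            fitted[f] = sup.apply(traj.coords[f])
        mean_struct = fitted.mean(axis=0)

        # pass 2: refit original frames onto the mean, measure fluctuations
        mean_align = mean_struct[ai]
        dev_sq = np.zeros(len(mi))
        measured = np.empty((traj.n_frames, len(mi), 3))
        for f in range(traj.n_frames):
            sup = superpose(traj.coords[f][ai], mean_align)
            measured[f] = sup.apply(traj.coords[f][mi])
        mean_measured = measured.mean(axis=0)
        dev_sq = ((measured - mean_measured) ** 2).sum(axis=2).mean(axis=0)
        # atoms bitwise constant across frames fluctuate exactly zero
        # (guards against rounding in the frame mean)
        constant = np.all(measured == measured[0], axis=0).all(axis=1)
        dev_sq[constant] = 0.0

        self.profile_ = RMSFProfile(
            atom_keys=[top.atoms[i].key for i in mi],
            residue_names=[top.atoms[i].residue_name for i in mi],
            rmsf_per_atom=np.sqrt(dev_sq),
            measure_expression=self.measure_selection,
            align_expression=align_expr,
        )
        return self

    def transform(self, X: Trajectory) -> np.ndarray:
        """Per-atom RMSF array of a trajectory (fits on the fly)."""
        return self.fit(X).profile_.rmsf_per_atom


def rmsf(
    traj: Trajectory,
    measure_selection: str = "resnum 624-627 and name O",
    align_selection: str | None = None,
) -> RMSFProfile:
    """Two-pass RMSF profile of a trajectory."""
    calc = RMSFCalculator(measure_selection, align_selection).fit(traj)
    return calc.profile_


def rmsf_vs_scan(profiles: dict[float, RMSFProfile]) -> pd.DataFrame:
    """Distance-scan summary: one row per scan distance d.

    Columns are residue labels (e.g. S624, V625, G626, F627) holding the
    per-residue RMSF averaged over the four subunits, plus an overall mean.
    Rows are sorted by d regardless of input order.
    """
    if len(profiles) < 1:
        raise WindowError("scan table needs at least one scan point")
    ref_expr = None
    rows = []
    for d in sorted(profiles):
        p = profiles[d]
        if ref_expr is None:
            ref_expr = (p.measure_expression, p.align_expression)
        elif (p.measure_expression, p.align_expression) != ref_expr:
            raise SelectionError(
                "scan points use inconsistent selections; refuse to tabulate"
            )
        labels = p.residue_labels()
        per_res = p.by_residue()
        row = {"d_A": float(d)}
        row.update({labels[rn]: v for rn, v in per_res.items()})
        row["mean_rmsf_A"] = float(p.rmsf_per_atom.mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("d_A")
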