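"""Conductive-to-collapsed collective coordinate and trajectory projection.

The reaction coordinate is the normalized difference vector between two
superposed reference conformations of the selectivity-filter backbone
(conductive, e.g. a 1K4C-like geometry, and collapsed, e.g. 1K4D-like).
For a two-structure set this direction is exactly the first principal
component of the pair: after mean-centering, the 2 x 3N data matrix has a
single non-degenerate principal axis, which is the (B - A) direction.  We
therefore build the coordinate as the explicit normalized difference, which
is numerically exact and fixes the sign so the collapsed reference maps
to s = +1 (the eigen-decomposition route exists only as a test oracle).

Each frame is rigid-body superposed onto the conductive reference on the
coordinate's own atom selection before projecting, so s is invariant to
global translation/rotation of the frame.  s = 0 at the conductive
reference, s = 1 at the collapsed one; excursions outside [0, 1] are
allowed and meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateCoordinateError, EnsembleError, MappingError, WindowError
from .structio import StructureModel, Trajectory, select, superpose

__all__ = [
    "CollapseCoordinate",
    "ProjectionTrace",
    "EnsembleTrace",
    "build_reaction_coordinate",
    "project_frame",
    "endpoint_projection",
    "ensemble_trace",
]

#: Default burn-in before endpoint averaging, ps (40 ns).
DEFAULT_BURN_IN_PS = 40_000.0


@dataclass(frozen=True)
class ProjectionTrace:
    """Collapse coordinate per frame of one trajectory."""

    times: np.ndarray  # ps
    s_values: np.ndarray  # dimensionless
    displacement: np.ndarray  # s * span, Angstrom

    def endpoint(self, burn_in_ps: float = DEFAULT_BURN_IN_PS) -> float:
        mask = self.times >= burn_in_ps
        if not np.any(mask):
            raise WindowError(
                f"no frames at or after burn-in {burn_in_ps} ps "
                f"(last frame at {self.times[-1]} ps)"
            )
        return float(np.mean(self.s_values[mask]))


@dataclass(frozen=True)
class EnsembleTrace:
    """Mean +/- SEM collapse coordinate across independent runs."""

    times: np.ndarray
    mean_s: np.ndarray
    sem_s: np.ndarray
    n_runs: int


class CollapseCoordinate(BaseEstimator, TransformerMixin):
    """Project trajectories onto the conductive->collapsed difference vector.

    Parameters
    ----------
    selection : str
        Atom selection defining the coordinate (default: backbone N, CA, C, O
        of the filter residues 624-628).
    align_selection : str or None
        Selection used to superpose frames before projecting.  ``None`` means
        the coordinate's own selection (the filter backbone itself).
    burn_in_ps : float
        Time discarded before endpoint averaging (default 40 ns).

    Attributes (after :meth:`fit`)
    ------------------------------
    unit_vector_ : (3N,) float array, |unit_vector_| = 1
    span_ : float, |B - A| in Angstrom
    ref_coords_ : (N, 3) conductive reference coordinates of the selection
    ref_collapsed_coords_ : (N, 3) collapsed reference after superposition
    atom_keys_ : list of (chain, resnum, atom name) identifying the N atoms
    """

    def __init__(
        self,
        selection: str = "resnum 624-628 and name N CA C O",
        align_selection: str | None = None,
        burn_in_ps: float = DEFAULT_BURN_IN_PS,
    ):
        self.selection = selection
        self.align_selection = align_selection
        self.burn_in_ps = burn_in_ps

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None):
        """Build the coordinate from ``X = (ref_conductive, ref_collapsed)``."""
        ref_a, ref_b = X
        sel_a = select(ref_a, self.selection)
        if len(sel_a) < 3:
            raise MappingError(
                f"selection {self.selection!r} resolves to {len(sel_a)} atoms (< 3)"
            )
        keys = [ref_a.atoms[i].key for i in sel_a.indices]
        coords_a = ref_a.coords[sel_a.indices]
        coords_b = self._resolve_coords(ref_b, keys)
        sup = superpose(coords_b, coords_a)
        coords_b = sup.apply(coords_b)
        diff = (coords_b - coords_a).ravel()
        span = float(np.linalg.norm(diff))
        if span < 1e-6:
            raise DegenerateCoordinateError(
                "reference structures coincide after superposition "
                f"(span {span:.2e} A); the coordinate is undefined"
            )
        self.atom_keys_ = keys
        self.ref_coords_ = coords_a
        self.ref_collapsed_coords_ = coords_b
        self.unit_vector_ = diff / span
        self.span_ = span
        return self

    @staticmethod
    def _resolve_coords(model: StructureModel, keys) -> np.ndarray:
        try:
            idx = [model.index_of(*k) for k in keys]
        except Exception as exc:
            raise MappingError(f"cannot map coordinate atoms onto structure: {exc}") from exc
        return model.coords[idx]

    def _frame_selection_indices(self, topology: StructureModel) -> np.ndarray:
        try:
            return np.array([topology.index_of(*k) for k in self.atom_keys_])
        except Exception as exc:
            raise MappingError(
                f"trajectory topology lacks coordinate atoms: {exc}"
            ) from exc

    # -- projection ------------------------------------------------------
    def project_coords(self, sel_coords: np.ndarray) -> float:
        """Project already-extracted selection coordinates of one frame."""
        sup = superpose(sel_coords, self.ref_coords_)
        fitted = sup.apply(sel_coords)
        return float((fitted - self.ref_coords_).ravel() @ self.unit_vector_ / self.span_)

    def project_frame(self, frame: StructureModel) -> float:
        """Collapse coordinate s of a single structure."""
        coords = self._resolve_coords(frame, self.atom_keys_)
        return self.project_coords(coords)

    def project(self, traj: Trajectory) -> ProjectionTrace:
        """Projection time trace of a trajectory."""
        idx = self._frame_selection_indices(traj.topology)
        s = np.array([self.project_coords(traj.coords[f][idx]) for f in range(traj.n_frames)])
        return ProjectionTrace(traj.times.copy(), s, s * self.span_)

    def transform(self, X):
        """s values for a Trajectory, a StructureModel, or a list of either."""
        if isinstance(X, Trajectory):
            return self.project(X).s_values
        if isinstance(X, StructureModel):
            return np.array([self.project_frame(X)])
        return [self.transform(x) for x in X]

    def endpoint(self, traj: Trajectory, burn_in_ps: float | None = None) -> float:
        """Mean s over frames with t >= burn-in (default 40 ns)."""
        burn = self.burn_in_ps if burn_in_ps is None else burn_in_ps
        return self.project(traj).endpoint(burn)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def build_reaction_coordinate(
    ref_conductive: StructureModel,
    ref_collapsed: StructureModel,
    selection: str = "resnum 624-628 and name N CA C O",
    **kwargs,
) -> CollapseCoordinate:
    return CollapseCoordinate(selection=selection, **kwargs).fit(
        (ref_conductive, ref_collapsed)
    )


def project_frame(frame: StructureModel, rc: CollapseCoordinate) -> float:
    return rc.project_frame(frame)


def endpoint_projection(
    traj: Trajectory, rc: CollapseCoordinate, burn_in_ps: float = DEFAULT_BURN_IN_PS
) -> float:
    return rc.endpoint(traj, burn_in_ps)


def ensemble_trace(
    traces: list[ProjectionTrace] | list[Trajectory],
    rc: CollapseCoordinate | None = None,
    grid: np.ndarray | None = None,
) -> EnsembleTrace:
    """Mean and SEM of s across independent runs on a common time grid.

    Runs are matched to the grid by nearest frame time (no interpolation or
    smoothing); the default grid is the first run's times.  SEM uses the
    sample standard deviation over runs divided by sqrt(n_runs).
    """
    if rc is not None:
        traces = [rc.project(t) for t in traces]  # type: ignore[arg-type]
    if len(traces) < 2:
        raise EnsembleError(f"ensemble statistics need >= 2 runs, got {len(traces)}")
    grid = traces[0].times if grid is None else np.asarray(grid, dtype=float)
    stacked = np.empty((len(traces), len(grid)))
    for r, tr in enumerate(traces):
        nearest = np.abs(tr.times[None, :] - grid[:, None]).argmin(axis=1)
        stacked[r] = tr.s_values[nearest]
    mean = stacked.mean(axis=0)
    sem = stacked.std(axis=0, ddof=1) / np.sqrt(len(traces))
    return EnsembleTrace(grid.copy(), mean, sem, len(traces))
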