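"""Grid-based probe accessibility and pocket volume of a spherical region.

A cubic grid (default spacing 0.5 A) is anchored at the region center; a
grid point is *accessible* when its distance to every protein heavy atom
is at least that atom's van der Waals radius plus the probe radius
(probe-center accessibility, default probe 1.4 A, i.e. a water-sized
molecule).  Accessible points inside the region sphere are partitioned
into 26-connected components; the volume is the point count times the
grid-cell volume.  Anchoring the grid at the region center makes results
translation-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from .errors import RadiusTableError, SFCollapseError
from .structio import AtomRecord, StructureModel, Trajectory, write_pdb

__all__ = [
    "BONDI_VDW_RADII",
    "ProbeSpec",
    "RegionSpec",
    "PocketResult",
    "PocketVolume",
    "grid_accessibility",
    "pocket_timeseries",
    "open_fraction",
    "write_points_pdb",
]

#: Bondi-style van der Waals radii, Angstrom.
BONDI_VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "K": 2.75, "NA": 2.27,
    "MG": 1.73, "CA": 2.31, "ZN": 1.39, "SE": 1.90,
}


@dataclass(frozen=True)
class ProbeSpec:
    """Probe and grid parameters for accessibility."""

    probe_radius: float = 1.4  # A, water-sized molecule
    grid_spacing: float = 0.5  # A
    vdw_radii: dict = field(default_factory=lambda: dict(BONDI_VDW_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0 or self.grid_spacing <= 0:
            raise SFCollapseError("probe radius and grid spacing must be positive")


@dataclass(frozen=True)
class RegionSpec:
    """Spherical analysis region (default 18 A around the S620 position)."""

    center: object  # 3-vector, or atom spec like "A:620:CB"
    radius: float = 18.0  # A
    bulk_exclusion: bool = False  # drop components touching the region boundary

    def resolve_center(self, model: StructureModel) -> np.ndarray:
        c = self.center
        if isinstance(c, str):
            parts = c.split(":")
            if len(parts) == 3:
                idx = [model.index_of(parts[0], int(parts[1]), parts[2])]
            else:
                # centroid over all chains of this residue atom
                idx = [
                    model.index_of(ch, int(parts[0]), parts[1])
                    for ch in model.chain_order
                ]
            return model.coords[idx].mean(axis=0)
        return np.asarray(c, dtype=float)


@dataclass
class PocketResult:
    """Accessible grid points of one frame and derived volumes (A^3)."""

    accessible_points: np.ndarray  # (M, 3)
    volume: float
    component_count: int
    largest_component_volume: float
    component_labels: np.ndarray  # (M,), 1-based component id per point
    grid_spacing: float


class PocketVolume(BaseEstimator):
    """Probe-accessible volume of a region across frames.

    Parameters
    ----------
    center, radius, bulk_exclusion : region definition (see :class:`RegionSpec`)
    probe_radius, grid_spacing : probe definition (see :class:`ProbeSpec`)
    """

    def __init__(
        self,
        center=(0.0, 0.0, 0.0),
        radius: float = 18.0,
        probe_radius: float = 1.4,
        grid_spacing: float = 0.5,
        bulk_exclusion: bool = False,
    ):
        self.center = center
        self.radius = radius
        self.probe_radius = probe_radius
        self.grid_spacing = grid_spacing
        self.bulk_exclusion = bulk_exclusion

    def fit(self, X=None, y=None):
        if self.radius <= self.probe_radius:
            raise SFCollapseError("region radius must exceed the probe radius")
        return self

    # -- single frame ----------------------------------------------------
    def evaluate(
        self, model: StructureModel, coords: np.ndarray | None = None
    ) -> PocketResult:
        self.fit()
        probe = ProbeSpec(self.probe_radius, self.grid_spacing)
        region = RegionSpec(self.center, self.radius, self.bulk_exclusion)
        center = region.resolve_center(model)
        h = probe.grid_spacing
        xyz = model.coords if coords is None else np.asarray(coords, dtype=float)

        radii = np.empty(len(model.atoms))
        heavy = np.ones(len(model.atoms), dtype=bool)
        for i, a in enumerate(model.atoms):
            el = a.element.upper()
            if el == "H":
                heavy[i] = False
                radii[i] = 0.0
                continue
            if el not in probe.vdw_radii:
                raise RadiusTableError(
                    f"no van der Waals radius for element {a.element!r}"
                )
            radii[i] = probe.vdw_radii[el]
        xyz = xyz[heavy]
        radii = radii[heavy]

        k = int(np.floor(region.radius / h))
        axis = np.arange(-k, k + 1)
        nside = len(axis)
        # squared distance from the center per axis offset, grid units -> A
        blocked = np.zeros((nside, nside, nside), dtype=bool)

        block_r = radii + probe.probe_radius
        rel = (xyz - center) / h  # atom positions in grid units
        reach = block_r / h
        for (ax, ay, az), rr in zip(rel, reach):
            lo = np.floor([ax - rr, ay - rr, az - rr]).astype(int)
            hi = np.ceil([ax + rr, ay + rr, az + rr]).astype(int)
            lo = np.maximum(lo, -k)
            hi = np.minimum(hi, k)
            if np.any(lo > hi):
                continue
            gx = np.arange(lo[0], hi[0] + 1)
            gy = np.arange(lo[1], hi[1] + 1)
            gz = np.arange(lo[2], hi[2] + 1)
            dx2 = (gx - ax) ** 2
            dy2 = (gy - ay) ** 2
            dz2 = (gz - az) ** 2
            sub = (
                dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
            ) < rr * rr
            blocked[
                lo[0] + k : hi[0] + k + 1,
                lo[1] + k : hi[1] + k + 1,
                lo[2] + k : hi[2] + k + 1,
            ] |= sub

        g2 = axis**2
        in_sphere = (
            g2[:, None, None] + g2[None, :, None] + g2[None, None, :]
        ) <= (region.radius / h) ** 2
        accessible = in_sphere & ~blocked

        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        labels, ncomp = ndimage.label(accessible, structure=structure)

        if region.bulk_exclusion and ncomp:
            shell = in_sphere & ~ndimage.binary_erosion(in_sphere, structure)
            bulk_ids = np.unique(labels[shell & accessible])
            for bid in bulk_ids:
                if bid:
                    accessible[labels == bid] = False
            labels, ncomp = ndimage.label(accessible, structure=structure)

        pts_idx = np.argwhere(accessible)
        points = center + (pts_idx - k) * h
        cell = h**3
        comp_labels = labels[accessible]
        if ncomp:
            sizes = np.bincount(comp_labels, minlength=ncomp + 1)[1:]
            largest = float(sizes.max() * cell)
        else:
            largest = 0.0
        return PocketResult(
            accessible_points=points,
            volume=float(len(points) * cell),
            component_count=int(ncomp),
            largest_component_volume=largest,
            component_labels=comp_labels,
            grid_spacing=h,
        )

    def transform(self, X) -> np.ndarray:
        """Largest-component volume per frame of a Trajectory (or one model)."""
        if isinstance(X, StructureModel):
            return np.array([self.evaluate(X).largest_component_volume])
        return np.array(
            [
                self.evaluate(X.topology, coords=X.coords[f]).largest_component_volume
                for f in range(X.n_frames)
            ]
        )


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def grid_accessibility(
    model: StructureModel,
    region: RegionSpec,
    probe: ProbeSpec | None = None,
    coords: np.ndarray | None = None,
) -> PocketResult:
    probe = probe or ProbeSpec()
    pv = PocketVolume(
        center=region.center,
        radius=region.radius,
        probe_radius=probe.probe_radius,
        grid_spacing=probe.grid_spacing,
        bulk_exclusion=region.bulk_exclusion,
    )
    return pv.evaluate(model, coords=coords)


def pocket_timeseries(
    traj: Trajectory, region: RegionSpec, probe: ProbeSpec | None = None
) -> pd.DataFrame:
    """Largest-component pocket volume per frame."""
    probe = probe or ProbeSpec()
    rows = []
    for f in range(traj.n_frames):
        try:
            res = grid_accessibility(traj.topology, region, probe, coords=traj.coords[f])
        except SFCollapseError as exc:
            raise type(exc)(f"frame {f}: {exc}") from exc
        rows.append(
            {
                "frame": f,
                "time_ps": float(traj.times[f]),
                "volume_A3": res.volume,
                "largest_component_A3": res.largest_component_volume,
                "components": res.component_count,
            }
        )
    return pd.DataFrame(rows)


def open_fraction(volumes, threshold: float) -> float:
    """Fraction of frames whose pocket volume reaches the open threshold."""
    v = np.asarray(volumes, dtype=float)
    return float(np.mean(v >= threshold))


def write_points_pdb(result: PocketResult, path) -> None:
    """Write accessible points as pseudo-atoms for visualization."""
    atoms = [
        AtomRecord("P", i + 1, "PNT", "O", "O", p)
        for i, p in enumerate(result.accessible_points)
    ]
    write_pdb(StructureModel(atoms), path)
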