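"""Distance-scan orchestration: endpoints, RMSF, H-bond fractions per d.

A YAML/JSON manifest lists trajectories grouped by the scan label d (the
target Cb-Cb separation of the S620/N629 stand-ins), the two reference
structures and the analysis defaults.  ``run_scan`` builds the collapse
coordinate, processes every group and returns a :class:`ScanReport` with
one :class:`ScanPoint` per d plus an ordinary-least-squares line of the
endpoint collapse vs d over a declared window (default 5-11 A; larger
separations leave the near-linear regime and are excluded from the fit).

The scan label d and the realized mean Cb-Cb distance are reported side
by side: the label is the restraint target of the original simulations,
the measured value is recomputed from the trajectories.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .collapsecoord import CollapseCoordinate, ensemble_trace
from .errors import FitError, ManifestError
from .flexanalysis import rmsf, rmsf_vs_scan
from .hbondnet import HBondCriteria, hbond_series
from .structio import pair_distance_by_chain, read_structure, read_trajectory

__all__ = ["ScanPoint", "ScanReport", "run_scan", "linear_fit", "load_manifest"]

logger = logging.getLogger("sfcollapse.scanpipe")


@dataclass(frozen=True)
class ScanPoint:
    """Summary of all runs at one scan distance d."""

    d_target: float  # A, scan label
    d_measured: float  # A, mean realized Cb-Cb distance
    s_endpoint: float  # mean post-burn-in collapse over runs
    s_endpoint_sem: float
    rmsf_summary: float  # mean carbonyl-O RMSF, A
    intra_fraction: float
    inter_fraction: float
    n_runs: int


@dataclass
class ScanReport:
    """Ordered scan points plus the linear endpoint-vs-d fit."""

    points: list[ScanPoint]
    slope: float | None = None
    intercept: float | None = None
    residuals: np.ndarray | None = None
    fit_window: tuple[float, float] | None = None
    rmsf_table: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "d_target_A": p.d_target,
                    "d_measured_A": p.d_measured,
                    "s_endpoint": p.s_endpoint,
                    "s_endpoint_sem": p.s_endpoint_sem,
                    "rmsf_A": p.rmsf_summary,
                    "intra_fraction": p.intra_fraction,
                    "inter_fraction": p.inter_fraction,
                    "n_runs": p.n_runs,
                }
            for p in self.points
            ]
        )

    def write(self, out_dir: str | Path) -> None:
        """Write report tables as TSV with parameter header comments."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = [f"# sfcollapse {__version__}"]
        if self.fit_window is not None and self.slope is not None:
            header.append(
                f"# fit_window_A={self.fit_window[0]:g}-{self.fit_window[1]:g} "
                f"slope={self.slope:.6f} intercept={self.intercept:.6f}"
            )
        body = self.to_frame().to_csv(sep="\t", index=False, float_format="%.6f")
        (out_dir / "scan.tsv").write_text("\n".join(header) + "\n" + body)
        if self.rmsf_table is not None:
            body = self.rmsf_table.to_csv(sep="\t", float_format="%.6f")
            (out_dir / "rmsf_scan.tsv").write_text(header[0] + "\n" + body)


def linear_fit(points, d_window: tuple[float, float]):
    """OLS of endpoint collapse against d over a window of scan labels.

    ``points`` is an iterable of :class:`ScanPoint` or (d, s) pairs.
    Returns (slope, intercept, residuals).
    """
    pairs = [
        (p.d_target, p.s_endpoint) if isinstance(p, ScanPoint) else tuple(p)
        for p in points
    ]
    lo, hi = d_window
    sel = [(d, s) for d, s in pairs if lo <= d <= hi]
    if len(sel) < 2:
        raise FitError(
            f"linear fit needs >= 2 points in window [{lo}, {hi}], got {len(sel)}"
        )
    d = np.array([p[0] for p in sel])
    s = np.array([p[1] for p in sel])
    res = stats.linregress(d, s)
    residuals = s - (res.slope * d + res.intercept)
    return float(res.slope), float(res.intercept), residuals


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest {path} does not exist")
    text = path.read_text()
    manifest = (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    )
    manifest["_base_dir"] = path.parent
    return manifest


def run_scan(manifest: dict | str | Path, out_dir: str | Path | None = None) -> ScanReport:
    """Run the full distance-scan analysis described by a manifest.

    Fails fast (before any computation) if a referenced file is missing.
    Deterministic: identical manifest and inputs give byte-identical
    report tables.
    """
    if not isinstance(manifest, dict):
        manifest = load_manifest(manifest)
    base = Path(manifest.get("_base_dir", "."))

    def _resolve(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    try:
        refs = manifest["references"]
        groups = manifest["groups"]
    except KeyError as exc:
        raise ManifestError(f"manifest missing required key {exc}") from exc
    if not groups:
        raise ManifestError("manifest has no scan groups")

    # fail-fast file check
    paths = [_resolve(refs["conductive"]), _resolve(refs["collapsed"])]
    for g in groups:
        if not g.get("trajectories"):
            raise ManifestError(f"group d={g.get('d')} lists no trajectories")
        paths.extend(_resolve(t) for t in g["trajectories"])
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise ManifestError(f"missing input files: {', '.join(missing)}")

    selection = manifest.get("selection", "resnum 624-628 and name N CA C O")
    burn_in = float(manifest.get("burn_in_ps", 40_000.0))
    dt_ps = manifest.get("dt_ps")
    dist = manifest.get(
        "distance_atoms",
        {"residue_a": 620, "name_a": "CB", "residue_b": 629, "name_b": "CB"},
    )
    rmsf_cfg = manifest.get("rmsf", {}) or {}
    measure = rmsf_cfg.get("measure", "resnum 624-627 and name O")
    align = rmsf_cfg.get("align") or None
    hb_cfg = manifest.get("hbond", {}) or {}
    criteria = HBondCriteria(
        float(hb_cfg.get("max_da_distance", 3.5)),
        float(hb_cfg.get("max_hda_angle", 30.0)),
        hb_cfg.get("hydrogen_mode", "heavy"),
    )
    focal = int(hb_cfg.get("focal_resnum", 629))

    logger.info("building collapse coordinate from %s / %s", *[refs[k] for k in ("conductive", "collapsed")])
    ref_a = read_structure(_resolve(refs["conductive"]))
    ref_b = read_structure(_resolve(refs["collapsed"]))
    rc = CollapseCoordinate(selection=selection, burn_in_ps=burn_in).fit((ref_a, ref_b))

    points: list[ScanPoint] = []
    profiles = {}
    for g in sorted(groups, key=lambda g: float(g["d"])):
        d = float(g["d"])
        logger.info("scan point d=%g A (%d runs)", d, len(g["trajectories"]))
        trajs = [read_trajectory(_resolve(t), dt_ps=dt_ps) for t in g["trajectories"]]
        endpoints = np.array([rc.endpoint(t) for t in trajs])
        d_meas = float(
            np.mean(
                [
                    list(
                        pair_distance_by_chain(
                            t.topology,
                            int(dist["residue_a"]), dist["name_a"],
                            int(dist["residue_b"]), dist["name_b"],
                            coords=t.coords[f],
                        ).values()
                    )
                    for t in trajs
                    for f in range(t.n_frames)
                ]
            )
        )
        prof = [rmsf(t, measure, align) for t in trajs]
        rmsf_mean = float(np.mean([p.rmsf_per_atom.mean() for p in prof]))
        profiles[d] = prof[0]
        intra = inter = 0
        for t in trajs:
            series = hbond_series(t, focal_resnum=focal, criteria=criteria)
            intra += int(series.n_intra.sum())
            inter += int(series.n_inter.sum())
        total = intra + inter
        sem = (
            float(endpoints.std(ddof=1) / np.sqrt(len(endpoints)))
            if len(endpoints) > 1
            else 0.0
        )
        points.append(
            ScanPoint(
                d_target=d,
                d_measured=d_meas,
                s_endpoint=float(endpoints.mean()),
                s_endpoint_sem=sem,
                rmsf_summary=rmsf_mean,
                intra_fraction=intra / total if total else float("nan"),
                inter_fraction=inter / total if total else float("nan"),
                n_runs=len(trajs),
            )
        )

    report = ScanReport(points, rmsf_table=rmsf_vs_scan(profiles))
    window = manifest.get("fit_window", [5.0, 11.0])
    in_window = [p for p in points if window[0] <= p.d_target <= window[1]]
    if len(in_window) >= 2:
        slope, intercept, residuals = linear_fit(points, tuple(window))
        report.slope = slope
        report.intercept = intercept
        report.residuals = residuals
        report.fit_window = (float(window[0]), float(window[1]))
    else:
        logger.info("fewer than 2 points in fit window; skipping linear fit")
    if out_dir is not None:
        report.write(out_dir)
    return report
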